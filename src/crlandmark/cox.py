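"""Model A: cause-specific Cox landmark supermodel.

Fits a proportional-hazards model for one cause on the stacked landmark
super dataset, treating competing events as censoring (cause-specific
convention) and using a cluster-robust sandwich variance (clustered on
patient) because a patient contributes correlated rows at several
landmarks. Covariate effects may interact linearly with landmark time s,
giving HR(s) = exp(beta + gamma*s); landmark time itself enters as a main
effect scaled to decades.

Within the supermodel, duration is measured on the conditional-survival
clock (time since the row's landmark). Pooling risk sets on that clock is
what identifies the landmark-time main effect: on the from-surgery clock
with delayed entry, every patient at risk at t carries an identical set of
landmark copies, so the landmark coefficient is determined only by tie
patterns and degenerates numerically. At a single landmark s=0 the two
clocks coincide and the fit reduces to a standard cause-specific Cox model.

Continuous covariates are standardized internally (per-SD hazard ratios);
categorical covariates are expanded against their first sorted level.
Estimation is delegated to lifelines (Efron ties) behind this surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from ._utils import CAUSE_CODES, CAUSE_NAMES

__all__ = ["CoxLandmarkFit", "fit_cause_specific_cox", "hazard_ratio_at_landmark", "wald_tests", "landmark_hr_table"]

_INTER_SUFFIX = ":s"
_LANDMARK_TERM = "landmark_decade"


def _resolve_cause(cause) -> int:
    if isinstance(cause, str):
        return CAUSE_CODES[cause]
    if cause not in CAUSE_NAMES:
        raise ValueError(f"cause must be one of {sorted(CAUSE_NAMES)} or a cause name")
    return int(cause)


@dataclass
class CoxLandmarkFit:
    """Fitted cause-specific landmark supermodel."""

    cause: int
    params: pd.Series
    cov_robust: pd.DataFrame
    cov_model: pd.DataFrame | None
    term_columns: dict           # variable -> list of main-effect design columns
    scalers: dict                # variable -> (mean, sd) for continuous terms
    interactions: list
    landmark_range: tuple
    n_rows: int
    n_clusters: int
    converged: bool = True

    def design_matrix(self, df: pd.DataFrame) -> pd.DataFrame:
        """Main+interaction design for new data, using the training scalers."""
        X = pd.DataFrame(index=df.index)
        for var, cols in self.term_columns.items():
            if var == _LANDMARK_TERM:
                X[var] = df["landmark_s"].to_numpy() / 10.0
                continue
            if var in self.scalers:
                mu, sd = self.scalers[var]
                X[cols[0]] = (df[var].to_numpy(dtype=float) - mu) / sd
            elif len(cols) == 1 and cols[0] == var:
                X[var] = df[var].to_numpy(dtype=float)
            else:
                for col in cols:
                    level = col[len(var) + 1 : -1]
                    X[col] = (df[var].astype(str).to_numpy() == level).astype(float)
        s = df["landmark_s"].to_numpy(dtype=float) if "landmark_s" in df else np.zeros(len(df))
        for var in self.interactions:
            for col in self.term_columns[var]:
                X[col + _INTER_SUFFIX] = X[col].to_numpy() * s
        return X[list(self.params.index)]

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        """Risk score eta = x'beta for new rows (uses their landmark_s)."""
        return self.design_matrix(df).to_numpy() @ self.params.to_numpy()


def _build_design(
    super_df: pd.DataFrame, terms: Sequence[str], interactions: Sequence[str]
) -> tuple[pd.DataFrame, dict, dict]:
    term_columns: dict = {}
    scalers: dict = {}
    X = pd.DataFrame(index=super_df.index)
    for var in terms:
        if var not in super_df.columns:
            raise KeyError(f"term {var!r} not present in the super dataset")
        col = super_df[var]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype.kind in "US":
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"term {var!r} is constant; not identifiable")
            cols = []
            for level in levels[1:]:
                name = f"{var}[{level}]"
                X[name] = (col.astype(str) == level).astype(float)
                cols.append(name)
            term_columns[var] = cols
        else:
            x = col.to_numpy(dtype=float)
            uniq = np.unique(x)
            if len(uniq) < 2:
                raise ValueError(f"term {var!r} is constant; not identifiable")
            if set(uniq) <= {0.0, 1.0}:
                X[var] = x
            else:
                mu, sd = float(x.mean()), float(x.std())
                X[var] = (x - mu) / sd
                scalers[var] = (mu, sd)
            term_columns[var] = [var]
    s = super_df["landmark_s"].to_numpy(dtype=float) if "landmark_s" in super_df else np.zeros(len(super_df))
    if len(np.unique(s)) > 1:
        X[_LANDMARK_TERM] = s / 10.0
        term_columns[_LANDMARK_TERM] = [_LANDMARK_TERM]
    for var in interactions:
        if var not in term_columns:
            raise KeyError(f"interaction variable {var!r} is not among the model terms")
        for colname in term_columns[var]:
            X[colname + _INTER_SUFFIX] = X[colname].to_numpy() * s
    return X, term_columns, scalers


def fit_cause_specific_cox(
    super_df: pd.DataFrame,
    cause,
    terms: Sequence[str],
    interactions: Sequence[str] = (),
    compute_model_cov: bool = True,
) -> CoxLandmarkFit:
    """Fit the cause-specific Cox landmark supermodel for one cause.

    Other causes are treated as censoring; entry at ``landmark_s`` is
    honored via delayed-entry risk sets; the sandwich covariance clusters
    score residuals on ``patient_id``.
    """
    cause = _resolve_cause(cause)
    if (super_df["event"] == cause).sum() == 0:
        raise ValueError(f"no events of cause {cause} in the super dataset")
    X, term_columns, scalers = _build_design(super_df, terms, interactions)

    s_arr = (
        super_df["landmark_s"].to_numpy(dtype=float)
        if "landmark_s" in super_df
        else np.zeros(len(super_df))
    )
    df = X.copy()
    df["T"] = super_df["time"].to_numpy(dtype=float) - s_arr  # conditional-survival clock
    df["E"] = (super_df["event"].to_numpy() == cause).astype(int)
    df["patient_id"] = super_df["patient_id"].to_numpy()

    def _fit(robust: bool) -> CoxPHFitter:
        # damped Newton retries: rare near-separated terms (e.g. extreme
        # metastasis effects emptying late landmarks) overshoot at step 1
        last_err = None
        for step in (None, 0.25, 0.1):
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(
                        df,
                        duration_col="T",
                        event_col="E",
                        cluster_col="patient_id" if robust else None,
                        robust=robust,
                        fit_options=None if step is None else {"step_size": step},
                    )
                return cph
            except ConvergenceError as err:
                last_err = err
        raise RuntimeError(f"Cox fit for cause {cause} did not converge: {last_err}") from last_err

    fitted = _fit(robust=True)
    cov_robust = fitted.variance_matrix_
    cov_model = _fit(robust=False).variance_matrix_ if compute_model_cov else None

    s_all = s_arr
    return CoxLandmarkFit(
        cause=cause,
        params=fitted.params_.copy(),
        cov_robust=cov_robust,
        cov_model=cov_model,
        term_columns=term_columns,
        scalers=scalers,
        interactions=list(interactions),
        landmark_range=(float(s_all.min()), float(s_all.max())),
        n_rows=len(df),
        n_clusters=int(df["patient_id"].nunique()),
    )


def hazard_ratio_at_landmark(fit: CoxLandmarkFit, variable: str, s: float) -> pd.DataFrame:
    """HR(s) = exp(beta + gamma*s) with a delta-method 95% CI on the robust covariance.

    One row per design column of ``variable`` (several for categoricals).
    Extrapolation outside the fitted landmark range triggers a warning but
    is still computed.
    """
    if variable not in fit.term_columns:
        raise KeyError(f"{variable!r} is not a model term")
    lo_s, hi_s = fit.landmark_range
    if not (lo_s <= s <= hi_s):
        warnings.warn(f"landmark s={s} outside fitted range [{lo_s}, {hi_s}]; extrapolating")
    rows = []
    for col in fit.term_columns[variable]:
        icol = col + _INTER_SUFFIX
        beta = float(fit.params[col])
        if icol in fit.params.index:
            gamma = float(fit.params[icol])
            var = (
                fit.cov_robust.loc[col, col]
                + s**2 * fit.cov_robust.loc[icol, icol]
                + 2 * s * fit.cov_robust.loc[col, icol]
            )
        else:
            gamma = 0.0
            var = fit.cov_robust.loc[col, col]
        eta = beta + gamma * s
        se = float(np.sqrt(max(var, 0.0)))
        rows.append(
            {
                "term": col,
                "s": s,
                "hr": float(np.exp(eta)),
                "ci_low": float(np.exp(eta - 1.959963984540054 * se)),
                "ci_high": float(np.exp(eta + 1.959963984540054 * se)),
            }
        )
    return pd.DataFrame(rows)


def wald_tests(fit: CoxLandmarkFit, variable: str) -> dict:
    """Joint Wald tests on the robust covariance.

    ``global_p``: all main and interaction coefficients of the variable are 0.
    ``interaction_p``: interaction coefficients only; NaN when the variable
    has no interaction with landmark time.
    """
    if variable not in fit.term_columns:
        raise KeyError(f"{variable!r} is not a model term")
    mains = list(fit.term_columns[variable])
    inters = [c + _INTER_SUFFIX for c in mains if c + _INTER_SUFFIX in fit.params.index]

    def _joint_p(cols: list[str]) -> float:
        b = fit.params[cols].to_numpy()
        V = fit.cov_robust.loc[cols, cols].to_numpy()
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular covariance for {variable!r}") from err
        return float(stats.chi2.sf(stat, df=len(cols)))

    return {
        "global_p": _joint_p(mains + inters),
        "interaction_p": _joint_p(inters) if inters else float("nan"),
    }


def landmark_hr_table(fit: CoxLandmarkFit, report_s: Sequence[float] = (1.0, 3.0, 5.0)) -> pd.DataFrame:
    """Per-variable HRs at the report landmarks with global and interaction p-values."""
    rows = []
    for var in fit.term_columns:
        tests = wald_tests(fit, var)
        for col in fit.term_columns[var]:
            row = {"variable": var, "term": col}
            for s in report_s:
                hr = hazard_ratio_at_landmark(fit, var, s)
                hr = hr[hr["term"] == col].iloc[0]
                row[f"hr_{s:g}y"] = hr["hr"]
                row[f"ci_{s:g}y"] = f"({hr['ci_low']:.2f}-{hr['ci_high']:.2f})"
            row["global_p"] = tests["global_p"]
            row["interaction_p"] = tests["interaction_p"]
            rows.append(row)
    return pd.DataFrame(rows)
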