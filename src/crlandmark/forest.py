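"""Model B: competing-risk random survival forest over landmark super datasets.

Trees are grown on cluster bootstraps (all landmark rows of a sampled
patient enter together), split by a generalized event-specific log-rank
statistic — cause-k events count as events, other causes as censoring
inside the split score; the default composite rule averages the three
per-cause statistics so a single forest yields all three CIFs. Terminal
nodes carry delayed-entry Aalen–Johansen CIFs of their member rows;
ensemble predictions average terminal CIFs, and out-of-bag (OOB) error is
a cause-specific concordance error computed for each patient using only
trees whose bootstrap excluded that patient's whole cluster. Variable
importance is minimal depth: the forest-averaged depth of the first split
on each variable, with never-split variables contributing that tree's
maximal depth + 1.

Landmark time enters the forest as an ordinary splitting covariate, and
delayed entry at the landmark is honored in every risk-set computation.
The split search is compiled with numba; all randomness flows from the
config seed (one child stream per tree), so a fixed seed reproduces the
forest, its OOB error and its minimal-depth table exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numba
import numpy as np
import pandas as pd

from ._utils import CAUSES, child_rng
from .cif import StepCIF, aalen_johansen

__all__ = [
    "ForestConfig",
    "CompetingRiskForest",
    "cluster_bootstrap",
    "split_statistic",
    "grow_tree",
    "fit_forest",
    "predict_cif",
    "tune_hyperparameters",
    "minimal_depth",
]

_EPS = 1e-12
_RESERVED = ("patient_id", "time", "event")


# ---------------------------------------------------------------------------
# configuration and encoding
# ---------------------------------------------------------------------------

@dataclass
class ForestConfig:
    """Hyperparameters of the competing-risk forest.

    ``split_cause`` is ``"composite"`` (average the three per-cause log-rank
    scores; one shared forest producing all CIFs) or a single cause code for
    a cause-specific forest. ``max_grid`` caps the number of risk-set time
    points used inside a node's split score (coarsened log-rank); terminal
    CIFs always use exact event times. ``horizon`` is the evaluation horizon
    for OOB concordance (default: 90th percentile of observed times).
    """

    ntree: int = 100
    mtry: int | None = None
    nodesize: int = 15
    seed: int = 0
    split_cause: object = "composite"
    max_grid: int = 32
    horizon: float | None = None

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.split_cause != "composite" and self.split_cause not in CAUSES:
            raise ValueError("split_cause must be 'composite' or a cause code 1/2/3")


def _build_encoders(df: pd.DataFrame, variables: Sequence[str]) -> dict:
    encoders: dict = {}
    for var in variables:
        col = df[var]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype.kind in "US":
            levels = sorted(col.astype(str).unique())
            encoders[var] = ("cat", levels)
        else:
            encoders[var] = ("num", None)
    return encoders


def _encode_frame(df: pd.DataFrame, encoders: Mapping, variables: Sequence[str]):
    """Numeric design for splitting: categoricals become level-vs-rest indicators."""
    cols, col_var, names = [], [], []
    for vi, var in enumerate(variables):
        kind, levels = encoders[var]
        if kind == "num":
            cols.append(df[var].to_numpy(dtype=float))
            col_var.append(vi)
            names.append(var)
        else:
            values = df[var].astype(str).to_numpy()
            unseen = set(values) - set(levels)
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} for variable {var!r}")
            use = levels[1:] if len(levels) == 2 else levels
            for level in use:
                cols.append((values == level).astype(float))
                col_var.append(vi)
                names.append(f"{var}[{level}]")
    X = np.ascontiguousarray(np.column_stack(cols)) if cols else np.empty((len(df), 0))
    return X, np.asarray(col_var, dtype=np.int64), names


# ---------------------------------------------------------------------------
# split statistic (numba kernel + reference implementation)
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _scan_columns(Xc, lo, hi, ecause, W, ck, Y, nodesize, cause_w):  # pragma: no cover
    n, ncols = Xc.shape
    m = Y.shape[0]
    best_score = 0.0
    best_col = -1
    best_thr = 0.0
    for c in range(ncols):
        x = Xc[:, c].copy()
        order = np.argsort(x)
        YL = np.zeros(m)
        numev = np.zeros(3)
        sumYw = np.zeros(3)
        for i in range(n - 1):
            r = order[i]
            for t in range(lo[r], hi[r] + 1):
                YL[t] += 1.0
            if ecause[r] >= 0:
                numev[ecause[r]] += 1.0
            for k in range(3):
                sumYw[k] += W[k, hi[r] + 1] - W[k, lo[r]]
            xi = x[order[i]]
            xj = x[order[i + 1]]
            if xi < xj and (i + 1) >= nodesize and (n - i - 1) >= nodesize:
                score = 0.0
                for k in range(3):
                    if cause_w[k] == 0.0:
                        continue
                    num = numev[k] - sumYw[k]
                    var = 0.0
                    for t in range(m):
                        var += ck[k, t] * YL[t] * (Y[t] - YL[t])
                    if var > 1e-12:
                        score += cause_w[k] * num * num / var
                if score > best_score + 1e-12:
                    best_score = score
                    best_col = c
                    best_thr = 0.5 * (xi + xj)
    return best_col, best_thr, best_score


def _node_tables(time, event, entry, max_grid):
    """Risk-set tables for one node: coarsened event-time grid, per-row
    at-risk interval [lo, hi] on the grid, event cause index, pooled counts."""
    is_event = event > 0
    grid = np.unique(time[is_event])
    if grid.size > max_grid:
        take = np.unique(np.linspace(0, grid.size - 1, max_grid).round().astype(int))
        grid = grid[take]
    m = grid.size
    if m == 0:
        return None
    lo = np.searchsorted(grid, entry, side="right")
    hi = np.searchsorted(grid, time, side="right") - 1
    ecause = np.where(is_event, event - 1, -1).astype(np.int64)
    # pooled at-risk and event counts per grid point
    Y = np.zeros(m)
    valid = hi >= lo
    np.add.at(Y, lo[valid], 1.0)
    over = hi[valid] + 1
    inb = over < m
    np.add.at(Y, over[inb], -1.0)
    Y = np.cumsum(Y)
    d = np.zeros((3, m))
    for k in range(3):
        tk = time[(ecause == k) & (hi >= lo)]
        if tk.size:
            np.add.at(d[k], np.searchsorted(grid, tk, side="right") - 1, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(Y > 0, d / np.maximum(Y, 1.0), 0.0)
        ck = np.where(Y > 1, d * (Y - d) / (np.maximum(Y - 1.0, 1.0) * np.maximum(Y, 1.0) ** 2), 0.0)
    W = np.concatenate([np.zeros((3, 1)), np.cumsum(w, axis=1)], axis=1)
    return grid, lo.astype(np.int64), hi.astype(np.int64), ecause, Y, d, W, ck


def split_statistic(time, event, entry, group, cause="composite", max_grid: int = 10_000) -> float:
    """Generalized log-rank split score between two daughters.

    ``group`` is a boolean mask (True = left daughter). The per-cause score
    is the squared log-rank numerator over its hypergeometric variance,
    with cause-k events as events and everything else as censoring;
    ``cause='composite'`` averages the three per-cause scores. Returns 0
    when there is no separation or either daughter is empty of information.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    entry = np.zeros(len(time)) if entry is None else np.asarray(entry, dtype=float)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        return 0.0
    tables = _node_tables(time, event, entry, max_grid)
    if tables is None:
        return 0.0
    grid, lo, hi, ecause, Y, d, W, ck = tables
    m = grid.size
    YL = np.zeros(m)
    for r in np.flatnonzero(group):
        if hi[r] >= lo[r]:
            YL[lo[r] : hi[r] + 1] += 1.0
    cause_w = np.full(3, 1.0 / 3.0) if cause == "composite" else np.eye(3)[int(cause) - 1]
    score = 0.0
    for k in range(3):
        if cause_w[k] == 0:
            continue
        dL = np.zeros(m)
        tk = time[group & (ecause == k) & (hi >= lo)]
        if tk.size:
            np.add.at(dL, np.searchsorted(grid, tk, side="right") - 1, 1.0)
        num = dL.sum() - float(YL @ (d[k] / np.maximum(Y, 1.0) * (Y > 0)))
        var = float((YL * (Y - YL)) @ ck[k])
        if var > _EPS:
            score += cause_w[k] * num * num / var
    return float(score)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("col", "thr", "left", "right", "cif", "n_members", "depth")

    def __init__(self, depth: int):
        self.col = -1
        self.thr = 0.0
        self.left = None
        self.right = None
        self.cif: StepCIF | None = None
        self.n_members = 0
        self.depth = depth

    @property
    def is_terminal(self) -> bool:
        return self.col < 0


@dataclass
class _Tree:
    root: _Node
    min_depth: np.ndarray       # per-variable first-split depth (inf if never split)
    max_depth: int
    inbag_clusters: np.ndarray  # cluster codes with multiplicity
    oob_clusters: np.ndarray


def cluster_bootstrap(super_df: pd.DataFrame, rng: np.random.Generator):
    """Sample patients (clusters) with replacement, n_clusters draws.

    All rows of a drawn cluster enter in-bag together (with multiplicity);
    OOB clusters are those never drawn. Returns (in-bag row index array,
    OOB cluster id array).
    """
    if len(super_df) == 0:
        raise ValueError("super dataset is empty")
    ids = super_df["patient_id"].to_numpy()
    clusters, codes = np.unique(ids, return_inverse=True)
    draws = rng.integers(0, len(clusters), size=len(clusters))
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(len(clusters)))
    ends = np.append(starts[1:], len(codes))
    inbag = np.concatenate([order[starts[c] : ends[c]] for c in draws]) if len(draws) else np.array([], int)
    oob = clusters[np.setdiff1d(np.arange(len(clusters)), draws, assume_unique=False)]
    return inbag, oob


def _grow(time, event, entry, X, rows, col_var, n_vars, config, rng):
    """Grow one tree on the (bootstrap) ``rows``; returns root, min-depth, max-depth."""
    mtry = min(config.mtry or max(1, int(np.sqrt(n_vars))), n_vars)
    if config.split_cause == "composite":
        cause_w = np.full(3, 1.0 / 3.0)
    else:
        cause_w = np.eye(3)[int(config.split_cause) - 1]
    min_depth = np.full(n_vars, np.inf)
    max_depth = 0
    root = _Node(depth=0)
    stack = [(root, rows)]
    while stack:
        node, idx = stack.pop()
        max_depth = max(max_depth, node.depth)
        node.n_members = len(idx)
        t_n, e_n, s_n = time[idx], event[idx], entry[idx]
        split_done = False
        if len(idx) >= 2 * config.nodesize and (e_n > 0).any():
            tables = _node_tables(t_n, e_n, s_n, config.max_grid)
            if tables is not None:
                grid, lo, hi, ecause, Y, d, W, ck = tables
                cand_vars = rng.choice(n_vars, size=mtry, replace=False)
                cand_cols = np.flatnonzero(np.isin(col_var, cand_vars))
                if cand_cols.size:
                    Xc = np.ascontiguousarray(X[np.ix_(idx, cand_cols)])
                    ci, thr, score = _scan_columns(
                        Xc, lo, hi, ecause, W, ck, Y, config.nodesize, cause_w
                    )
                    if ci >= 0 and score > 0:
                        col = int(cand_cols[ci])
                        node.col, node.thr = col, float(thr)
                        var = col_var[col]
                        min_depth[var] = min(min_depth[var], node.depth)
                        mask = X[idx, col] <= thr
                        left, right = _Node(node.depth + 1), _Node(node.depth + 1)
                        node.left, node.right = left, right
                        stack.append((left, idx[mask]))
                        stack.append((right, idx[~mask]))
                        split_done = True
        if not split_done:
            node.cif = aalen_johansen(t_n, e_n, s_n)
    return root, min_depth, max_depth


def grow_tree(super_df: pd.DataFrame, config: ForestConfig, rng: np.random.Generator):
    """Grow a single tree on the given rows (no bootstrap); mainly for inspection."""
    variables = [c for c in super_df.columns if c not in _RESERVED]
    encoders = _build_encoders(super_df, variables)
    X, col_var, _ = _encode_frame(super_df, encoders, variables)
    time = super_df["time"].to_numpy(dtype=float)
    event = super_df["event"].to_numpy()
    entry = super_df["landmark_s"].to_numpy(dtype=float) if "landmark_s" in super_df else np.zeros(len(super_df))
    root, md, _ = _grow(time, event, entry, X, np.arange(len(super_df)), col_var, len(variables), config, rng)
    return root


def _route(root: _Node, Xq: np.ndarray) -> list:
    """Terminal node per query row; returns list of _Node."""
    out = [None] * len(Xq)
    stack = [(root, np.arange(len(Xq)))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_terminal:
            for i in idx:
                out[i] = node
            continue
        mask = Xq[idx, node.col] <= node.thr
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))
    return out


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

@dataclass
class CompetingRiskForest:
    config: ForestConfig
    trees: list
    variables: list
    encoders: dict
    col_var: np.ndarray
    time_grid: np.ndarray
    horizon: float
    oob_error: dict | None = None          # cause -> 1 - Harrell C on OOB predictions
    min_depth_matrix: np.ndarray | None = None   # (ntree, p), never-split = max_depth+1

    # internal training arrays kept for OOB evaluation / profiling
    _train: dict = field(default_factory=dict, repr=False)

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        X, _, _ = _encode_frame(df, self.encoders, self.variables)
        return X


def _terminal_eval(node: _Node, times: np.ndarray) -> np.ndarray:
    """Terminal CIF evaluated at ``times``; shape (3, len(times))."""
    cif = node.cif
    return np.vstack([cif.evaluate(times, c) for c in CAUSES])


def fit_forest(super_df: pd.DataFrame, config: ForestConfig) -> CompetingRiskForest:
    """Fit the competing-risk forest on a landmark super dataset.

    Requires columns ``patient_id``, ``time``, ``event``; every other column
    (including ``landmark_s``) is a splitting covariate. Delayed entry uses
    ``landmark_s`` when present.
    """
    variables = [c for c in super_df.columns if c not in _RESERVED]
    if not variables:
        raise ValueError("no covariates to split on")
    encoders = _build_encoders(super_df, variables)
    X, col_var, _ = _encode_frame(super_df, encoders, variables)
    time = super_df["time"].to_numpy(dtype=float)
    event = super_df["event"].to_numpy()
    entry = (
        super_df["landmark_s"].to_numpy(dtype=float)
        if "landmark_s" in super_df
        else np.zeros(len(super_df))
    )
    ids = super_df["patient_id"].to_numpy()
    clusters, codes = np.unique(ids, return_inverse=True)
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(len(clusters)))
    ends = np.append(starts[1:], len(codes))

    trees: list[_Tree] = []
    md_rows = []
    for t in range(config.ntree):
        rng = child_rng(config.seed, "forest", t)
        draws = rng.integers(0, len(clusters), size=len(clusters))
        inbag = np.concatenate([order[starts[c] : ends[c]] for c in draws])
        oob = np.setdiff1d(np.arange(len(clusters)), draws)
        root, md, maxd = _grow(time, event, entry, X, inbag, col_var, len(variables), config, rng)
        md_rows.append(np.where(np.isfinite(md), md, maxd + 1.0))
        trees.append(_Tree(root, md, maxd, clusters[np.sort(draws)], clusters[oob]))

    horizon = config.horizon if config.horizon is not None else float(np.quantile(time, 0.9))
    forest = CompetingRiskForest(
        config=config,
        trees=trees,
        variables=variables,
        encoders=encoders,
        col_var=col_var,
        time_grid=np.unique(time[event > 0]),
        horizon=horizon,
        min_depth_matrix=np.vstack(md_rows),
    )
    forest._train = {
        "X": X, "time": time, "event": event, "entry": entry,
        "codes": codes, "clusters": clusters,
    }
    forest.oob_error = _oob_concordance_error(forest)
    return forest


def _oob_scores(forest: CompetingRiskForest):
    """Per-row OOB risk scores: conditional CIF mass of each cause on
    (landmark, horizon], averaged over trees excluding the row's cluster."""
    tr = forest._train
    X, entry = tr["X"], tr["entry"]
    n = len(X)
    tau = forest.horizon
    sumF_tau = np.zeros((3, n))
    sumF_s = np.zeros((3, n))
    sumS_s = np.zeros(n)
    count = np.zeros(n)
    for tree in forest.trees:
        oob_mask = np.isin(tr["clusters"][tr["codes"]], tree.oob_clusters)
        idx = np.flatnonzero(oob_mask)
        if idx.size == 0:
            continue
        leaves = _route(tree.root, X[idx])
        # group rows by leaf for vectorized evaluation
        by_leaf: dict[int, list] = {}
        for pos, leaf in enumerate(leaves):
            by_leaf.setdefault(id(leaf), (leaf, []))[1].append(pos)
        for leaf, members in by_leaf.values():
            members = np.asarray(members)
            rows = idx[members]
            F_tau = _terminal_eval(leaf, np.array([tau]))[:, 0]
            F_s = np.vstack([leaf.cif.evaluate(entry[rows], c) for c in CAUSES])
            sumF_tau[:, rows] += F_tau[:, None]
            sumF_s[:, rows] += F_s
            sumS_s[rows] += 1.0 - F_s.sum(axis=0)
            count[rows] += 1.0
    has = count > 0
    scores = np.full((3, n), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        Fbar_tau = sumF_tau[:, has] / count[has]
        Fbar_s = sumF_s[:, has] / count[has]
        Sbar_s = np.maximum(sumS_s[has] / count[has], _EPS)
        scores[:, has] = (Fbar_tau - Fbar_s) / Sbar_s
    return scores, has


def _oob_concordance_error(forest: CompetingRiskForest) -> dict | None:
    from .evaluation import harrell_c_competing

    tr = forest._train
    scores, has = _oob_scores(forest)
    if not has.any():
        warnings.warn("no OOB predictions available (too few trees/clusters); OOB error undefined")
        return None
    out = {}
    for k in CAUSES:
        try:
            c = harrell_c_competing(
                scores[k - 1, has], tr["time"][has], tr["event"][has], k, forest.horizon
            )
        except ValueError:
            c = np.nan
        out[k] = 1.0 - c
    return out


def predict_cif(
    forest: CompetingRiskForest,
    Z: Mapping | pd.DataFrame,
    s: float = 0.0,
    conditional: bool = True,
    trees: Sequence | None = None,
) -> StepCIF:
    """Ensemble CIF for one covariate profile at landmark ``s``.

    The profile is dropped down every tree with ``landmark_s`` set to ``s``;
    terminal CIFs are averaged on the pooled training event-time grid and,
    when ``conditional``, re-anchored to 0 at t=s (event-free at s).
    """
    lo, hi = 0.0, np.inf
    if "landmark_s" in forest.variables:
        train_s = forest._train["entry"]
        lo, hi = float(train_s.min()), float(train_s.max())
        if not (lo <= s <= hi):
            warnings.warn(f"landmark s={s} outside fitted range [{lo}, {hi}]")
    row = pd.DataFrame([dict(Z)]) if not isinstance(Z, pd.DataFrame) else Z.iloc[[0]].copy()
    if "landmark_s" in forest.variables:
        row["landmark_s"] = float(s)
    missing = [v for v in forest.variables if v not in row.columns]
    if missing:
        raise ValueError(f"profile is missing model variables: {missing}")
    Xq = forest.encode(row[forest.variables])
    use = forest.trees if trees is None else trees
    grid = forest.time_grid
    acc = np.zeros((3, grid.size))
    for tree in use:
        leaf = _route(tree.root, Xq)[0]
        acc += _terminal_eval(leaf, grid)
    acc /= len(use)
    cif = StepCIF(times=grid, values=acc)
    return cif.conditional(s) if conditional and s > 0 else cif


def minimal_depth(forest: CompetingRiskForest) -> pd.DataFrame:
    """Forest-averaged minimal depth per variable, ascending (most important first).

    In each tree a variable's minimal depth is the depth of its first
    (shallowest) split; variables never split in a tree contribute that
    tree's maximal depth + 1.
    """
    md = forest.min_depth_matrix.mean(axis=0)
    out = pd.DataFrame({"variable": forest.variables, "minimal_depth": md})
    return out.sort_values("minimal_depth", kind="stable").reset_index(drop=True)


def tune_hyperparameters(
    super_df: pd.DataFrame,
    mtry_grid: Sequence[int] = (5, 10, 15),
    nodesize_grid: Sequence[int] = (5, 15, 30, 50),
    ntree: int = 100,
    seed: int = 0,
    split_cause: object = "composite",
) -> tuple[ForestConfig, pd.DataFrame]:
    """Grid search minimizing the mean per-cause OOB concordance error.

    Every configuration is fitted with the same seed (common random
    numbers); ties break toward larger nodesize, then smaller mtry
    (parsimony). Returns (best config, full OOB error table).
    """
    rows = []
    best = None
    for nodesize in nodesize_grid:
        for mtry in mtry_grid:
            cfg = ForestConfig(
                ntree=ntree, mtry=int(mtry), nodesize=int(nodesize),
                seed=seed, split_cause=split_cause,
            )
            fitted = fit_forest(super_df, cfg)
            if fitted.oob_error is None:
                err = np.nan
            else:
                err = float(np.nanmean(list(fitted.oob_error.values())))
            rows.append({"mtry": mtry, "nodesize": nodesize, "oob_error": err})
            key = (err if np.isfinite(err) else np.inf, -nodesize, mtry)
            if best is None or key < best[0]:
                best = (key, cfg)
    return best[1], pd.DataFrame(rows)
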