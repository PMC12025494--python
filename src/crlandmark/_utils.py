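"""Shared helpers: seeding, event codes, validation."""

from __future__ import annotations

import numpy as np

#: event coding used throughout: 0 censored, 1 relapse, 2 cancer death, 3 other-cause death
CENSORED = 0
RELAPSE = 1
CANCER_DEATH = 2
OTHER_DEATH = 3

CAUSES = (RELAPSE, CANCER_DEATH, OTHER_DEATH)
CAUSE_NAMES = {RELAPSE: "relapse", CANCER_DEATH: "cancer_death", OTHER_DEATH: "other_death"}
CAUSE_CODES = {v: k for k, v in CAUSE_NAMES.items()}

# fixed stage keys so any pipeline stage can be re-run independently yet reproducibly
_STAGE_KEYS = {
    "covariates": 11,
    "events": 12,
    "forest": 21,
    "bootstrap": 22,
    "folds": 23,
    "tuning": 24,
    "pipeline": 31,
}


def child_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Derive an independent generator for a pipeline stage from one global seed.

    Uses a counter-based spawn key so re-running a single stage reproduces the
    stream it saw inside the full pipeline.
    """
    key = _STAGE_KEYS.get(stage)
    if key is None:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(_STAGE_KEYS)}")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key, int(index))))


def check_event_codes(event: np.ndarray) -> None:
    bad = ~np.isin(event, [0, 1, 2, 3])
    if bad.any():
        rows = np.flatnonzero(bad)[:10].tolist()
        raise ValueError(f"event codes must be in {{0,1,2,3}}; offending rows: {rows}")
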