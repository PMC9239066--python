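"""Scrambled-label permutation screen for false-discovery control.

The growth-community pairing is scrambled (response values permuted
across samples within each association test), the full selection
procedure is rerun with identical settings, and any test whose scrambled
run still confirms more than one feature has *all* of its real
associations removed - a deliberately conservative screen rather than a
formal FDR procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TEST_KEY = ["treatment", "stage", "response", "kind"]


def scramble_pairing(responses: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Permute response values across samples within each test.

    Each (treatment, stage, response) test's values are uniformly
    permuted over its own samples, preserving group sizes and the value
    multiset; community data are untouched.
    """
    rng = np.random.default_rng(seed)
    out = responses.copy()
    for _, idx in out.groupby(["treatment", "stage", "response"]).groups.items():
        idx = list(idx)
        if len(idx) < 2:
            warnings.warn("test with a single sample: scrambling is a no-op")
            continue
        perm = rng.permutation(len(idx))
        out.loc[idx, "value"] = out.loc[idx, "value"].to_numpy()[perm]
    return out


@dataclass
class ScreenReport:
    counts: pd.DataFrame  # per test: features at each stage, real and scrambled
    flagged_tests: pd.DataFrame
    removed: pd.DataFrame  # real associations removed by the screen
    kept: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "n_tests": int(len(self.counts)),
            "n_flagged": int(len(self.flagged_tests)),
            "n_removed": int(len(self.removed)),
            "n_kept": int(len(self.kept)),
            "flagged_tests": self.flagged_tests.to_dict(orient="records"),
        }


def _per_test_counts(df: pd.DataFrame, tests: pd.DataFrame, name: str) -> pd.Series:
    if df is None or df.empty:
        return pd.Series(0, index=pd.MultiIndex.from_frame(tests), name=name)
    counts = df.groupby(TEST_KEY).size()
    full = counts.reindex(pd.MultiIndex.from_frame(tests), fill_value=0)
    full.name = name
    return full


def fdr_screen(
    real_bayes: pd.DataFrame,
    scrambled_bayes: pd.DataFrame,
    real_tests: pd.DataFrame,
    scrambled_tests: pd.DataFrame,
    real_stability: pd.DataFrame | None = None,
    scrambled_stability: pd.DataFrame | None = None,
    flag_threshold: int = 1,
) -> ScreenReport:
    """Remove real associations from tests that fire under scrambling.

    ``*_bayes`` are association tables after univariate Bayesian
    confirmation (columns include treatment/stage/response/kind/feature);
    ``*_tests`` enumerate every test that was run (the two grids must
    match).  A test is flagged when its scrambled run confirms more than
    ``flag_threshold`` features while its real run confirmed at least
    one; all real associations of flagged tests are removed.
    """
    real_grid = set(map(tuple, real_tests[TEST_KEY].itertuples(index=False)))
    scr_grid = set(map(tuple, scrambled_tests[TEST_KEY].itertuples(index=False)))
    if real_grid != scr_grid:
        missing = sorted(real_grid ^ scr_grid)
        raise ValueError(f"real and scrambled test grids differ: {missing}")

    tests = real_tests[TEST_KEY].drop_duplicates().reset_index(drop=True)
    frames = [
        _per_test_counts(real_bayes, tests, "real_bayes"),
        _per_test_counts(scrambled_bayes, tests, "scrambled_bayes"),
    ]
    if real_stability is not None:
        frames.append(_per_test_counts(real_stability, tests, "real_stability"))
    if scrambled_stability is not None:
        frames.append(_per_test_counts(scrambled_stability, tests, "scrambled_stability"))
    counts = pd.concat(frames, axis=1).reset_index()

    flagged = counts[
        (counts["scrambled_bayes"] > flag_threshold) & (counts["real_bayes"] > 0)
    ][TEST_KEY].reset_index(drop=True)

    if real_bayes is None or real_bayes.empty:
        removed = pd.DataFrame(columns=(real_bayes.columns if real_bayes is not None else TEST_KEY))
        kept = removed.copy()
    else:
        flagged_keys = set(map(tuple, flagged.itertuples(index=False)))
        is_flagged = real_bayes[TEST_KEY].apply(tuple, axis=1).isin(flagged_keys)
        removed = real_bayes[is_flagged].reset_index(drop=True)
        kept = real_bayes[~is_flagged].reset_index(drop=True)
    return ScreenReport(counts=counts, flagged_tests=flagged, removed=removed, kept=kept)
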