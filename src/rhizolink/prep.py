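"""Count-table transforms and feature filtering.

Cumulative sum scaling (CSS) normalization, Bray-Curtis dissimilarities
and the day-2-referenced trajectory, alpha diversity, core-community
extraction, rank/prevalence feature filtering, and the centered log-ratio
transform with a pooled remainder part that preserves compositionality.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from rhizolink.containers import REMAINDER

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CSS normalization
# ---------------------------------------------------------------------------

def css_percentile(counts: pd.DataFrame, grid: int = 100, instability: float = 0.1) -> float:
    """Data-driven CSS percentile.

    For each sample the quantiles of its nonzero counts are compared to
    the median quantile profile across samples; the chosen percentile is
    the smallest one at which the median absolute deviation from the
    reference profile starts changing by more than ``instability``
    (relative), i.e. where sample count distributions begin to diverge.
    Falls back to 0.5 when no such point exists.
    """
    probs = np.arange(1, grid) / grid
    qmat = np.full((len(probs), counts.shape[0]), np.nan)
    for j, (_, row) in enumerate(counts.iterrows()):
        nz = row.to_numpy(dtype=float)
        nz = nz[nz > 0]
        if nz.size == 0:
            raise ValueError("all-zero sample in count table")
        qmat[:, j] = np.quantile(nz, probs)
    ref = np.median(qmat, axis=1)
    d = np.median(np.abs(qmat - ref[:, None]), axis=1)
    rel = np.abs(np.diff(d)) / np.where(d[1:] > 0, d[1:], np.inf)
    unstable = np.nonzero(rel > instability)[0]
    if unstable.size == 0:
        return 0.5
    return float(max(probs[unstable[0]], 0.5))


def css_transform(counts: pd.DataFrame, percentile: float | None = None,
                  scale: float = 1000.0) -> pd.DataFrame:
    """Cumulative-sum-scaling normalized counts.

    Each sample is divided by the sum of its counts up to the sample's
    ``percentile`` quantile (computed over nonzero counts) and multiplied
    by ``scale``.  With ``percentile=None`` the percentile is chosen
    adaptively by :func:`css_percentile`.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample in count table")
    if percentile is None:
        percentile = css_percentile(counts)
    factors = np.empty(arr.shape[0])
    for i in range(arr.shape[0]):
        nz = arr[i][arr[i] > 0]
        q = np.quantile(nz, percentile)
        factors[i] = arr[i][arr[i] <= q].sum()
    if (factors <= 0).any():
        raise ValueError("nonpositive CSS scaling factor")
    out = counts.astype(float).div(factors, axis=0) * scale
    out.attrs["css_percentile"] = float(percentile)
    return out


# ---------------------------------------------------------------------------
# dissimilarity and diversity
# ---------------------------------------------------------------------------

def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples (rows)."""
    arr = np.asarray(matrix, dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    zero = arr.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis undefined between all-zero samples")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def dissimilarity_trajectory(bc: pd.DataFrame, metadata: pd.DataFrame,
                             reference_day: float = 2) -> pd.DataFrame:
    """Per-day Bray-Curtis dissimilarities to the reference-day samples.

    Within each treatment, day d != reference contributes all pairwise
    values between day-d and reference-day samples; the reference day
    contributes its within-day pairs only.
    """
    meta = metadata.loc[bc.index]
    if not (meta["day"] == reference_day).any():
        raise ValueError(f"reference day {reference_day} absent from metadata")
    rows = []
    for treatment, tm in meta.groupby("treatment"):
        ref_ids = list(tm.index[tm["day"] == reference_day])
        if not ref_ids:
            log.info("no reference-day samples for treatment %s; skipped", treatment)
            continue
        for day, dm in tm.groupby("day"):
            ids = list(dm.index)
            if day == reference_day:
                vals = [bc.loc[a, b] for i, a in enumerate(ids) for b in ids[i + 1:]]
            else:
                vals = [bc.loc[a, b] for a in ids for b in ref_ids]
            if not vals:
                log.info("day %s has no samples for treatment %s; skipped", day, treatment)
                continue
            rows.extend(
                {"treatment": treatment, "day": float(day), "dissimilarity": float(v)}
                for v in vals
            )
    return pd.DataFrame(rows)


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Observed feature count and Shannon index (natural log) per sample."""
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample")
    observed = (arr > 0).sum(axis=1)
    p = arr / arr.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"observed_features": observed, "shannon": shannon}, index=counts.index
    )


# ---------------------------------------------------------------------------
# feature selection support
# ---------------------------------------------------------------------------

def core_community(counts: pd.DataFrame, min_prevalence: float = 1.0):
    """Features present in >= ``min_prevalence`` of samples, and their read share."""
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    prevalence = (counts > 0).mean(axis=0)
    core = sorted(prevalence.index[prevalence >= min_prevalence])
    total = counts.to_numpy().sum()
    fraction = float(counts[core].to_numpy().sum() / total) if total else 0.0
    return core, fraction


def rank_prevalence_filter(counts: pd.DataFrame, top_n: int = 200,
                           min_prevalence: float = 0.3) -> list[str]:
    """Most-abundant features passing a prevalence cutoff.

    Features are ranked by mean relative abundance within the table
    (depths are uniform in this study design, so this matches ranking by
    mean counts), ties broken lexicographically by feature id; the list
    is truncated to ``top_n`` and then filtered to features detected in
    at least ``min_prevalence`` of samples.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    rel = counts.div(counts.sum(axis=1), axis=0)
    mean_abund = rel.mean(axis=0)
    order = sorted(mean_abund.index, key=lambda f: (-mean_abund[f], f))
    top = order[:top_n]
    prevalence = (counts > 0).mean(axis=0)
    kept = [f for f in top if prevalence[f] >= min_prevalence]
    if not kept:
        raise ValueError(
            "no features pass the rank/prevalence filter; loosen top_n or min_prevalence"
        )
    return kept


#: (loose, strict) prevalence presets by treatment, as used in the study design
PREVALENCE_PRESETS = {
    "disrupted": {"loose": 0.3, "strict": 0.5},
    "inoculated": {"loose": 0.5, "strict": 0.9},
}


def clr_with_remainder(counts: pd.DataFrame, selected_features,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """CLR matrix over the selected features plus one pooled remainder part.

    Unselected feature counts are summed into a single remainder column so
    the composition stays closed; a pseudocount is added to every part
    before taking logs.  Each output row sums to zero.
    """
    selected = list(selected_features)
    if not selected:
        raise ValueError("selected feature set is empty")
    missing = set(selected) - set(counts.columns)
    if missing:
        raise ValueError(f"selected features not in table: {sorted(missing)[:5]}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    rest = [c for c in counts.columns if c not in set(selected)]
    parts = counts[selected].astype(float).copy()
    parts[REMAINDER] = counts[rest].sum(axis=1) if rest else 0.0
    logs = np.log(parts.to_numpy() + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=counts.index, columns=parts.columns)
    out.attrs["pseudocount"] = pseudocount
    out.attrs["n_selected"] = len(selected)
    return out
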