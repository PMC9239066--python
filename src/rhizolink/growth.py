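"""Plant-growth responses for association testing.

Computes per-plant projected leaf area (PA), per-pot relative growth
rates (RGR, slopes of log PA over consecutive intervals), covariate-
adjusted residuals of PA and biomass, and the promotion categories used
for treatment-level comparisons.  Per-pot values are means across the
plants in the pot; aggregation happens before any response computation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def pa_per_plant(green_pixel_area: float, n_seedlings: int) -> float:
    """Green pixels per pot divided by the number of seedlings present."""
    if n_seedlings < 1:
        raise ValueError("n_seedlings must be >= 1")
    return green_pixel_area / n_seedlings


def relative_growth_rate(pa_series) -> list[tuple[tuple[float, float], float]]:
    """Interval RGRs (day^-1) from an ordered (day, PA) series for one pot.

    rgr = (ln pa2 - ln pa1) / (day2 - day1) for each consecutive interval.
    """
    pairs = sorted(pa_series)
    if len(pairs) < 2:
        raise ValueError("need at least two PA time points")
    days = [d for d, _ in pairs]
    if len(set(days)) < len(days):
        raise ValueError("duplicate measurement days")
    out = []
    for (d1, p1), (d2, p2) in zip(pairs, pairs[1:]):
        if p1 <= 0 or p2 <= 0:
            raise ValueError("PA must be positive to take logs")
        out.append(((d1, d2), (np.log(p2) - np.log(p1)) / (d2 - d1)))
    return out


def pot_rgr(pa_series) -> float:
    """Single per-pot RGR: the mean of consecutive-interval RGRs."""
    intervals = relative_growth_rate(pa_series)
    return float(np.mean([r for _, r in intervals]))


def growth_residuals(values, covariates: pd.DataFrame, categorical=()) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus ``covariates``.

    Columns named in ``categorical`` are dummy-coded (e.g. collection
    date treated as a factor).  Residuals sum to zero; a rank-deficient
    design raises an error naming the collinear covariate.
    """
    y = np.asarray(values, dtype=float)
    cols = []
    names = []
    for name in covariates.columns:
        col = covariates[name]
        if name in categorical or not np.issubdtype(np.asarray(col).dtype, np.number):
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            for dname in dummies.columns:
                cols.append(dummies[dname].to_numpy(dtype=float))
                names.append(dname)
        else:
            arr = col.to_numpy(dtype=float)
            if np.ptp(arr) == 0:
                # constant covariate is absorbed by the intercept
                log.info("covariate %s is constant; dropped", name)
                continue
            cols.append(arr)
            names.append(name)
    X = np.column_stack([np.ones(len(y))] + cols) if cols else np.ones((len(y), 1))
    p = X.shape[1]
    if len(y) < p + 1:
        raise ValueError(f"need at least {p + 1} observations for {p - 1} covariates")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify which added column kills the rank
        for k in range(1, p):
            if np.linalg.matrix_rank(X[:, : k + 1]) < k + 1:
                raise ValueError(f"collinear covariate: {names[k - 1]}")
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def categorize_promotion(inoculated_value: float, matched_disrupted_value: float) -> str:
    """Promotion category from the inoculated/disrupted percentage.

    ratio > 107%: promoted; 100-107% inclusive: possibly_promoted;
    < 100%: not_promoted.
    """
    if matched_disrupted_value <= 0:
        raise ValueError("reference (disrupted) value must be positive")
    pct = 100.0 * inoculated_value / matched_disrupted_value
    if pct > 107.0:
        return "promoted"
    if pct >= 100.0:
        return "possibly_promoted"
    return "not_promoted"


# ---------------------------------------------------------------------------
# response construction
# ---------------------------------------------------------------------------

#: (response_name, stage) pairs evaluated per treatment
DEFAULT_PAIRINGS = (
    ("pa_day3", "early"),
    ("pa_resid_early", "early"),
    ("biomass_resid_early", "early"),
    ("avg_pa_day10_11", "late"),
    ("pa_day13", "late"),
    ("pa_resid_late", "late"),
    ("biomass_resid_late", "late"),
    ("rgr_late", "late"),
    ("rgr_all", "all"),
)


def build_responses(growth: pd.DataFrame, pairing_config=DEFAULT_PAIRINGS,
                    date_as_categorical: bool = True) -> pd.DataFrame:
    """Per-pot response values for each configured (response, stage) pair.

    ``growth`` is the long table produced by the synthetic generator or
    read from TSV: one row per (pot, day) with columns pot_id, treatment,
    block, day, pa, biomass (harvest row only), collection_date.

    Residual responses regress the harvest-window measurement on days
    grown (biomass) or days grown plus collection date (PA).  RGR
    responses use the per-pot mean of interval RGRs; pots harvested at
    day 2 (a single PA point) are excluded.  Missing data for a response
    produces a warning and the response is skipped.
    """
    rows = []
    harvest = growth.dropna(subset=["biomass"]).copy()
    harvest["day"] = harvest["day"].astype(float)
    per_pot = {pid: g.sort_values("day") for pid, g in growth.groupby("pot_id")}

    for treatment, tgrowth in growth.groupby("treatment"):
        tharvest = harvest[harvest["treatment"] == treatment]
        for response, stage in pairing_config:
            try:
                vals = _one_response(response, tgrowth, tharvest, per_pot, date_as_categorical)
            except KeyError as exc:
                warnings.warn(f"skipping {treatment}/{response}: missing data ({exc})")
                continue
            if vals is None or vals.empty:
                warnings.warn(f"skipping {treatment}/{response}: no growth data")
                continue
            for pot_id, value in vals.items():
                rows.append(
                    {
                        "pot_id": pot_id,
                        "treatment": treatment,
                        "stage": stage,
                        "response": response,
                        "value": float(value),
                    }
                )
    out = pd.DataFrame(rows)
    if not out.empty and out.duplicated(["pot_id", "response"]).any():
        raise ValueError("duplicate (pot, response) pair")
    return out


def _harvest_window(harvest: pd.DataFrame, days) -> pd.DataFrame:
    return harvest[harvest["day"].isin([float(d) for d in days])]


def _one_response(response, growth, harvest, per_pot, date_as_categorical):
    if response == "pa_day3":
        sub = growth[growth["day"] == 3.0]
        return sub.set_index("pot_id")["pa"]
    if response == "pa_day13":
        sub = growth[growth["day"] == 13.0]
        return sub.set_index("pot_id")["pa"]
    if response == "avg_pa_day10_11":
        sub = growth[growth["day"].isin([10.0, 11.0])]
        return sub.groupby("pot_id")["pa"].mean()
    if response in ("pa_resid_early", "pa_resid_late"):
        days = (3, 4) if response.endswith("early") else (13, 14)
        sub = _harvest_window(harvest, days)
        if sub.empty:
            return None
        covs = sub[["day", "collection_date"]].rename(columns={"day": "days_grown"})
        cats = ("collection_date",) if date_as_categorical else ()
        resid = growth_residuals(sub["pa"], covs, categorical=cats)
        return pd.Series(resid, index=sub["pot_id"])
    if response in ("biomass_resid_early", "biomass_resid_late"):
        days = (3, 4) if response.endswith("early") else (13, 14)
        sub = _harvest_window(harvest, days)
        if sub.empty:
            return None
        resid = growth_residuals(sub["biomass"], sub[["day"]].rename(columns={"day": "days_grown"}))
        return pd.Series(resid, index=sub["pot_id"])
    if response in ("rgr_late", "rgr_all"):
        if response == "rgr_late":
            pots = harvest[harvest["day"].isin([13.0, 14.0])]["pot_id"]
        else:
            pots = harvest[harvest["day"] > 2.0]["pot_id"]
        vals = {}
        for pid in pots:
            series = list(zip(per_pot[pid]["day"], per_pot[pid]["pa"]))
            if len(series) >= 2:
                vals[pid] = pot_rgr(series)
        return pd.Series(vals)
    raise KeyError(response)
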