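"""Repeated cross-validated LASSO stability selection.

Growth responses are regressed on CLR-transformed feature abundances with
an L1 penalty; the penalty is chosen per run by k-fold cross-validated
MSE, the fold partition is re-randomized across runs, and features with
nonzero coefficients in at least ``threshold`` of ``n_runs`` runs are
"selected".  Each association test is run under both a loose and a strict
prevalence preset; a feature is a candidate if selected under either,
with a flag recording agreement between the two.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from rhizolink.containers import REMAINDER, CountTable
from rhizolink.prep import PREVALENCE_PRESETS, clr_with_remainder, rank_prevalence_filter

log = logging.getLogger(__name__)


@dataclass
class LassoFit:
    coef: pd.Series  # standardized-scale coefficients at the chosen lambda
    intercept: float
    lambda_: float
    lambda_path: np.ndarray
    cv_mse: np.ndarray


@dataclass
class StabilityResult:
    treatment: str
    stage: str
    response: str
    frequency: pd.Series  # runs with a nonzero coefficient, per feature
    n_runs: int
    threshold: int
    lambdas: list = field(default_factory=list)  # chosen penalty per run

    @property
    def selected(self) -> list[str]:
        return [f for f, c in self.frequency.items() if c >= self.threshold]


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def make_lambda_path(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                     ratio: float | None = None) -> np.ndarray:
    """Log-spaced decreasing penalty path from the full-shrinkage penalty.

    With ``ratio=None`` the path floor follows the reference-tool
    convention: 0.01 of the full-shrinkage penalty when n < p, 1e-4
    otherwise.
    """
    n = len(y)
    if ratio is None:
        ratio = 0.01 if n < X.shape[1] else 1e-4
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    if lam_max <= 0:
        raise ValueError("degenerate design: lambda_max is zero")
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def cv_lasso(X, y, n_folds: int = 10, lambdas=None, fold_seed: int = 0,
             n_lambda: int = 100, lambda_min_ratio: float | None = None) -> LassoFit:
    """L1-penalized Gaussian regression with the penalty chosen by CV MSE.

    Predictors are standardized internally and coefficients are reported
    on the standardized scale; the intercept is unpenalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is not None:
        lambdas = np.asarray(lambdas, dtype=float)
    n, p = X.shape
    if np.std(y) == 0:
        raise ValueError("constant response")
    if n < n_folds:
        raise ValueError(f"n={n} smaller than n_folds={n_folds}")
    if n_folds < 3:
        raise ValueError("need at least 3 folds")

    Xs, _, _ = standardize(X)
    yc = y - y.mean()
    if lambdas is None:
        lambdas = make_lambda_path(Xs, yc, n_lambda, lambda_min_ratio)
    lambdas = np.sort(lambdas)[::-1]

    folds = KFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    mse = np.zeros((n_folds, len(lambdas)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k, (tr, te) in enumerate(folds.split(Xs)):
            Xt, _, _ = standardize(X[tr])
            yt = y[tr] - y[tr].mean()
            _, coefs, _ = lasso_path(Xt, yt, alphas=lambdas, max_iter=3000)
            # evaluate on held-out rows using the training standardization
            mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xe = (X[te] - mu) / sd
            pred = Xe @ coefs + y[tr].mean()
            mse[k] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
        mean_mse = mse.mean(axis=0)
        best = int(np.argmin(mean_mse))

        _, coefs_full, _ = lasso_path(Xs, yc, alphas=lambdas, max_iter=3000)
    coef = coefs_full[:, best]
    return LassoFit(
        coef=pd.Series(coef),
        intercept=float(y.mean()),
        lambda_=float(lambdas[best]),
        lambda_path=lambdas,
        cv_mse=mean_mse,
    )


def kkt_residual(X, y, coef, lam) -> float:
    """Largest KKT violation of a LASSO solution (standardized inputs)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coef = np.asarray(coef, dtype=float)
    n = len(y)
    grad = X.T @ (y - y.mean() - X @ coef) / n
    viol = np.where(
        coef != 0,
        np.abs(grad - lam * np.sign(coef)),
        np.maximum(np.abs(grad) - lam, 0.0),
    )
    return float(viol.max())


def stability_select(X: pd.DataFrame, y, n_runs: int = 100, threshold: int = 80,
                     base_seed: int = 0, n_folds: int = 10, n_lambda: int = 100,
                     lambda_min_ratio: float | None = None, subsample_frac: float | None = 0.8,
                     treatment: str = "", stage: str = "", response: str = "") -> StabilityResult:
    """Count, per feature, the runs in which the CV-LASSO keeps it.

    Run-to-run variation comes from re-randomized CV fold partitions
    plus row subsampling (``subsample_frac`` of the samples per run, the
    stability-selection device that keeps dataset-level chance
    correlations from being selected in every run; set it to None for
    fold randomization only).  Run seeds derive deterministically from
    ``base_seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 1 <= threshold <= n_runs:
        raise ValueError("threshold must be in [1, n_runs]")
    features = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_runs) % (2**31)
    counts = np.zeros(len(features), dtype=int)
    lambdas = []
    for r in range(n_runs):
        Xr, yr = Xa, ya
        if subsample_frac is not None:
            rng = np.random.default_rng(int(seeds[2 * r + 1]))
            keep = rng.choice(len(ya), size=max(n_folds, int(subsample_frac * len(ya))),
                              replace=False)
            Xr, yr = Xa[keep], ya[keep]
        fit = cv_lasso(Xr, yr, n_folds=n_folds, fold_seed=int(seeds[2 * r]),
                       n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
        counts += (fit.coef.to_numpy() != 0).astype(int)
        lambdas.append(fit.lambda_)
    return StabilityResult(
        treatment=treatment,
        stage=stage,
        response=response,
        frequency=pd.Series(counts, index=features),
        n_runs=n_runs,
        threshold=threshold,
        lambdas=lambdas,
    )


# ---------------------------------------------------------------------------
# the association suite
# ---------------------------------------------------------------------------

@dataclass
class StabilitySettings:
    n_runs: int = 100
    threshold: int = 80
    n_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float | None = None  # None: 0.01 when n < p, else 1e-4
    pseudocount: float = 0.5
    top_n: int = 200
    subsample_frac: float | None = 0.8
    module_min_prevalence: float = 0.27  # low-prevalence module omission rule


@dataclass
class TestCandidates:
    """Stability-selection outcome of one (group, response) test."""

    treatment: str
    stage: str
    response: str
    kind: str  # "asv" or "module"
    sample_ids: list
    stability: dict  # preset name -> StabilityResult
    clr: dict  # preset name -> FeatureMatrix used
    y: pd.Series

    @property
    def candidates(self) -> pd.DataFrame:
        """Union of per-preset selections; the remainder part never counts."""
        frames = []
        for preset, res in self.stability.items():
            df = pd.DataFrame(
                {
                    "feature": res.frequency.index,
                    f"freq_{preset}": res.frequency.to_numpy(),
                    f"selected_{preset}": [
                        f in set(res.selected) for f in res.frequency.index
                    ],
                }
            )
            frames.append(df.set_index("feature"))
        merged = pd.concat(frames, axis=1)
        merged = merged[merged.index != REMAINDER]
        sel_cols = [c for c in merged.columns if c.startswith("selected_")]
        merged[sel_cols] = merged[sel_cols].astype("boolean").fillna(False).astype(bool)
        freq_cols = [c for c in merged.columns if c.startswith("freq_")]
        merged[freq_cols] = merged[freq_cols].fillna(0).astype(int)
        merged["candidate"] = merged[sel_cols].any(axis=1)
        merged["both_presets"] = merged[sel_cols].all(axis=1) if len(sel_cols) > 1 else merged[sel_cols].any(axis=1)
        out = merged[merged["candidate"]].reset_index()
        out.insert(0, "treatment", self.treatment)
        out.insert(1, "stage", self.stage)
        out.insert(2, "response", self.response)
        out.insert(3, "kind", self.kind)
        return out


def run_association_suite(
    count_table: CountTable,
    responses: pd.DataFrame,
    pairings=None,
    settings: StabilitySettings | None = None,
    base_seed: int = 0,
    kind: str = "asv",
    presets=None,
    treatments=("inoculated", "disrupted"),
) -> list[TestCandidates]:
    """Stability selection for every (treatment, stage, response) pairing.

    ``responses`` is sample-level: columns sample_id, treatment, stage,
    response, value.  For ASV tables each test filters features at both
    the loose and strict prevalence preset before the CLR transform; for
    module tables no rank filter is applied, only the low-prevalence
    module omission rule.
    """
    settings = settings or StabilitySettings()
    if pairings is None:
        pairings = sorted(
            {(s, r) for s, r in responses[["stage", "response"]].itertuples(index=False)}
        )
    results = []
    seed_seq = np.random.SeedSequence(base_seed)
    test_seeds = seed_seq.generate_state(len(pairings) * len(treatments) * 4) % (2**31)
    i = 0
    for treatment in treatments:
        for stage, response in pairings:
            sample_ids = count_table.group_samples(treatment, stage)
            ysub = responses[
                (responses["treatment"] == treatment)
                & (responses["response"] == response)
                & (responses["sample_id"].isin(sample_ids))
            ].set_index("sample_id")["value"]
            common = [s for s in sample_ids if s in ysub.index]
            i += 1
            if len(common) < settings.n_folds:
                log.info("skipping %s/%s/%s: only %d samples", treatment, stage, response, len(common))
                continue
            if len(common) < 10:
                warnings.warn(
                    f"test {treatment}/{stage}/{response} has only {len(common)} samples"
                )
            counts = count_table.select_samples(common).counts
            y = ysub.loc[common]

            if kind == "module":
                prevalence = (counts > 0).mean(axis=0)
                keep = list(prevalence.index[prevalence >= settings.module_min_prevalence])
                preset_features = {"all": keep}
            else:
                use = presets or PREVALENCE_PRESETS[treatment]
                preset_features = {}
                for name, min_prev in use.items():
                    try:
                        preset_features[name] = rank_prevalence_filter(
                            counts, top_n=settings.top_n, min_prevalence=min_prev
                        )
                    except ValueError:
                        log.info("preset %s empty for %s/%s/%s", name, treatment, stage, response)
            if not preset_features or all(len(v) == 0 for v in preset_features.values()):
                log.info("no features for %s/%s/%s; skipped", treatment, stage, response)
                continue

            stability, clrs = {}, {}
            for j, (name, feats) in enumerate(sorted(preset_features.items())):
                if not feats:
                    continue
                clr = clr_with_remainder(counts, feats, settings.pseudocount)
                stability[name] = stability_select(
                    clr,
                    y,
                    n_runs=settings.n_runs,
                    threshold=settings.threshold,
                    base_seed=int(test_seeds[(i - 1) * 4 + j]),
                    n_folds=min(settings.n_folds, len(common)),
                    n_lambda=settings.n_lambda,
                    lambda_min_ratio=settings.lambda_min_ratio,
                    subsample_frac=settings.subsample_frac,
                    treatment=treatment,
                    stage=stage,
                    response=response,
                )
                clrs[name] = clr
            results.append(
                TestCandidates(
                    treatment=treatment,
                    stage=stage,
                    response=response,
                    kind=kind,
                    sample_ids=common,
                    stability=stability,
                    clr=clrs,
                    y=y,
                )
            )
    return results


def candidate_table(suite: list[TestCandidates]) -> pd.DataFrame:
    frames = [t.candidates for t in suite if not t.candidates.empty]
    if not frames:
        return pd.DataFrame(
            columns=["treatment", "stage", "response", "kind", "feature", "candidate", "both_presets"]
        )
    return pd.concat(frames, ignore_index=True)
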