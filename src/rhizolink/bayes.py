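"""Bayesian hierarchical confirmation of candidate growth associations.

The model is a Gaussian linear mixed model with a random intercept and a
random slope for every greenhouse block:

    y_i = b0 + sum_j b_j x_ij + u_{blk(i)} + sum_j v_{blk(i),j} x_ij + e_i
    e_i ~ Normal(0, sigma^2),  u_blk ~ Normal(0, tau_0^2),
    v_{blk,j} ~ Normal(0, tau_j^2)

Priors are weakly informative and scale with the data: Normal(mean(y),
(2.5 sd(y))^2) on the intercept, Normal(0, (2.5 sd(y)/sd(x_j))^2) on each
slope, half-t (via the Huang-Wand inverse-gamma parameter expansion) on
every random-effect SD, and inverse-gamma on sigma^2.  All conditionals
are conjugate, so posterior draws come from a blocked Gibbs sampler: the
full location vector (fixed + random effects) is drawn jointly from its
multivariate normal conditional, which mixes rapidly for this model.

R^2 follows the Bayesian posterior-predictive definition: per draw,
var(fit) / (var(fit) + sigma^2), with the fit restricted to fixed
effects (marginal) or including block effects (conditional).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    draws: int = 1000
    warmup: int = 500
    chains: int = 2
    seed: int = 0
    nu: float = 2.0  # half-t degrees of freedom for random-effect SDs
    prior_scale: float = 2.5
    rhat_limit: float = 1.05


@dataclass
class HierarchicalFit:
    """Posterior draws and summaries for one hierarchical model."""

    features: list
    blocks: list
    beta: np.ndarray  # (chains, draws, 1 + k); column 0 is the intercept
    sigma: np.ndarray  # (chains, draws)
    tau: np.ndarray  # (chains, draws, 1 + k)
    r2_marginal: np.ndarray  # (chains, draws)
    r2_conditional: np.ndarray  # (chains, draws)
    log_lik: np.ndarray  # (chains, draws, n)
    converged: bool = True
    rhat: float = np.nan

    @property
    def n_obs(self) -> int:
        return self.log_lik.shape[-1]

    def slope_draws(self, j: int = 0) -> np.ndarray:
        return self.beta[..., 1 + j].ravel()

    def slope_ci(self, j: int = 0, level: float = 0.95) -> tuple[float, float]:
        a = (1 - level) / 2
        d = self.slope_draws(j)
        return float(np.quantile(d, a)), float(np.quantile(d, 1 - a))

    def slope_median(self, j: int = 0) -> float:
        return float(np.median(self.slope_draws(j)))

    def direction(self, j: int = 0) -> str:
        return "positive" if self.slope_median(j) > 0 else "negative"

    @property
    def marginal_R2(self) -> float:
        return float(self.r2_marginal.mean())

    @property
    def conditional_R2(self) -> float:
        return float(self.r2_conditional.mean())

    def to_inference_data(self) -> az.InferenceData:
        posterior = {
            "beta": self.beta,
            "sigma": self.sigma,
            "tau": self.tau,
        }
        return az.from_dict(
            posterior=posterior, log_likelihood={"y": self.log_lik}
        )

    def elpd_loo(self, pointwise: bool = False):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = az.loo(self.to_inference_data(), pointwise=True)
        if pointwise:
            return float(res.elpd_loo), np.asarray(res.loo_i.values)
        return float(res.elpd_loo)

    def summary(self) -> dict:
        out = {
            "features": self.features,
            "marginal_R2": self.marginal_R2,
            "conditional_R2": self.conditional_R2,
            "sigma_median": float(np.median(self.sigma)),
            "converged": bool(self.converged),
            "rhat": float(self.rhat),
            "slopes": {},
        }
        for j, f in enumerate(self.features):
            lo, hi = self.slope_ci(j)
            out["slopes"][f] = {
                "median": self.slope_median(j),
                "ci95": [lo, hi],
                "direction": self.direction(j),
            }
        return out


def _invgamma(rng, shape, scale):
    return scale / rng.gamma(shape)


def fit_hierarchical(X, y, block_labels, config: SamplerConfig | None = None) -> HierarchicalFit:
    """Gibbs-sample the random-intercept/random-slope model.

    ``X`` is n x k (k may be 0 for an intercept-only model), ``y`` length
    n, ``block_labels`` length n.  Needs at least 2 blocks.
    """
    config = config or SamplerConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = X.shape[1] if X.size else 0
    if X.size == 0:
        X = np.empty((n, 0))
    if np.std(y) == 0:
        raise ValueError("constant response: zero variance")
    blocks, block_idx = np.unique(np.asarray(block_labels), return_inverse=True)
    B = len(blocks)
    if B < 2:
        raise ValueError("need at least 2 blocks")
    sx = X.std(axis=0) if k else np.array([])
    if k and (sx == 0).any():
        raise ValueError("zero-variance feature column")
    if k > 1:
        corr = np.corrcoef(X, rowvar=False)
        off = np.abs(corr[np.triu_indices(k, 1)])
        if off.size and off.max() > 0.999:
            warnings.warn("collinear feature columns in multivariate model")
    if n <= k + 2:
        raise ValueError("need n > number of features + 2")

    sy = y.std()
    my = y.mean()
    ps = config.prior_scale

    # design: [1, x_1..x_k | per-block intercept, per-block slope_j]
    Xf = np.column_stack([np.ones(n), X]) if k else np.ones((n, 1))
    Zcols = []
    for b in range(B):
        ind = (block_idx == b).astype(float)
        Zcols.append(ind)
        for j in range(k):
            Zcols.append(ind * X[:, j])
    Z = np.column_stack(Zcols)
    W = np.column_stack([Xf, Z])
    d_fixed = 1 + k
    d = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y

    prior_var_fixed = np.concatenate([[(ps * sy) ** 2], (ps * sy / sx) ** 2]) if k else np.array([(ps * sy) ** 2])
    prior_mean = np.zeros(d)
    prior_mean[0] = my
    # half-t scale for each random-effect SD (intercepts then each slope)
    A_tau = np.concatenate([[sy], sy / sx]) if k else np.array([sy])
    nu = config.nu
    a_sigma, b_sigma = 2.0, sy**2

    n_keep = config.draws
    beta_out = np.empty((config.chains, n_keep, d_fixed))
    sigma_out = np.empty((config.chains, n_keep))
    tau_out = np.empty((config.chains, n_keep, 1 + k))
    r2m_out = np.empty((config.chains, n_keep))
    r2c_out = np.empty((config.chains, n_keep))
    ll_out = np.empty((config.chains, n_keep, n))

    seeds = np.random.SeedSequence(config.seed).generate_state(config.chains) % (2**31)
    re_index = np.arange(d_fixed, d)
    # which tau governs each random column: intercept (0) or slope j (1+j)
    tau_map = np.tile(np.arange(1 + k), B)

    for c in range(config.chains):
        rng = np.random.default_rng(int(seeds[c]))
        sigma2 = sy**2 * float(rng.uniform(0.5, 1.5))
        tau2 = (0.5 * A_tau) ** 2 * rng.uniform(0.5, 1.5, 1 + k)
        a_aux = 1.0 / rng.gamma(0.5, 1.0 / A_tau**2)
        theta = np.zeros(d)
        for it in range(config.warmup + n_keep):
            # location block
            prior_prec = np.empty(d)
            prior_prec[:d_fixed] = 1.0 / prior_var_fixed
            prior_prec[d_fixed:] = 1.0 / tau2[tau_map]
            Q = WtW / sigma2 + np.diag(prior_prec)
            rhs = Wty / sigma2 + prior_prec * prior_mean
            L = np.linalg.cholesky(Q)
            mu = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            z = rng.standard_normal(d)
            theta = mu + np.linalg.solve(L.T, z)

            resid = y - W @ theta
            sigma2 = _invgamma(rng, a_sigma + n / 2, b_sigma + 0.5 * resid @ resid)

            re = theta[re_index]
            for t in range(1 + k):
                vals = re[tau_map == t]
                tau2[t] = _invgamma(rng, (nu + B) / 2, nu / a_aux[t] + 0.5 * vals @ vals)
                a_aux[t] = _invgamma(rng, (nu + 1) / 2, nu / tau2[t] + 1.0 / A_tau[t] ** 2)

            if it >= config.warmup:
                s = it - config.warmup
                fit_fixed = Xf @ theta[:d_fixed]
                fit_full = W @ theta
                beta_out[c, s] = theta[:d_fixed]
                sigma_out[c, s] = np.sqrt(sigma2)
                tau_out[c, s] = np.sqrt(tau2)
                vf = fit_fixed.var()
                vc = fit_full.var()
                r2m_out[c, s] = vf / (vf + sigma2)
                r2c_out[c, s] = vc / (vc + sigma2)
                ll_out[c, s] = -0.5 * np.log(2 * np.pi * sigma2) - 0.5 * (y - fit_full) ** 2 / sigma2

    fit = HierarchicalFit(
        features=list(getattr(X, "columns", [f"x{j + 1}" for j in range(k)])) if k else [],
        blocks=list(blocks),
        beta=beta_out,
        sigma=sigma_out,
        tau=tau_out,
        r2_marginal=r2m_out,
        r2_conditional=r2c_out,
        log_lik=ll_out,
    )
    if config.chains >= 2 and k:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(az.from_dict(posterior={"beta": beta_out}))
        fit.rhat = float(np.nanmax(rhat["beta"].values))
        fit.converged = fit.rhat <= config.rhat_limit
        if not fit.converged:
            log.warning("sampler convergence flag: max R-hat %.3f", fit.rhat)
    return fit


def fit_univariate(x, y, block_labels, config: SamplerConfig | None = None,
                   feature: str = "x1") -> HierarchicalFit:
    """Hierarchical fit of one feature's CLR abundance against a response."""
    x = np.asarray(x, dtype=float)
    fit = fit_hierarchical(x.reshape(-1, 1), y, block_labels, config)
    fit.features = [feature]
    return fit


def fit_multivariate(X: pd.DataFrame, y, block_labels,
                     config: SamplerConfig | None = None) -> HierarchicalFit:
    """Hierarchical fit with multiple feature slopes."""
    if X.shape[1] < 1:
        raise ValueError("multivariate model needs at least one feature")
    fit = fit_hierarchical(X.to_numpy(), y, block_labels, config)
    fit.features = list(X.columns)
    return fit


def credible_gate(fits: dict, level: float = 0.95) -> pd.DataFrame:
    """Keep features whose slope credible interval excludes zero.

    ``fits`` maps feature id -> univariate HierarchicalFit.  Non-converged
    fits are excluded (and flagged in the output).
    """
    rows = []
    for feature, fit in fits.items():
        lo, hi = fit.slope_ci(0, level)
        excludes = lo > 0 or hi < 0
        rows.append(
            {
                "feature": feature,
                "ci_low": lo,
                "ci_high": hi,
                "median_slope": fit.slope_median(0),
                "direction": fit.direction(0),
                "R2_univariate": fit.marginal_R2,
                "converged": fit.converged,
                "kept": bool(excludes and fit.converged),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# leave-one-out refinement
# ---------------------------------------------------------------------------

@dataclass
class LooComparison:
    kept_features: list
    table: pd.DataFrame  # one row per model evaluated
    final_fit: HierarchicalFit | None


def _elpd(fit: HierarchicalFit):
    return fit.elpd_loo(pointwise=True)


def loo_refine(candidates: pd.DataFrame, y, block_labels,
               config: SamplerConfig | None = None) -> LooComparison:
    """Greedy backward elimination by expected log predictive density.

    Starting from the model with every candidate feature, repeatedly drop
    the feature whose removal most improves (or least harms) PSIS-LOO
    ELPD; stop when the best removal is worse than the current model by
    more than one standard error of the pointwise ELPD difference.  A
    final comparison against the intercept-only (block effects only)
    model decides whether anything is kept at all.
    """
    config = config or SamplerConfig()
    features = list(candidates.columns)
    rows = []

    def fit_set(feats, seed_offset):
        cfg = SamplerConfig(**{**config.__dict__, "seed": config.seed + seed_offset})
        if feats:
            return fit_multivariate(candidates[feats], y, block_labels, cfg)
        return fit_hierarchical(np.empty((len(np.asarray(y)), 0)), y, block_labels, cfg)

    null_fit = fit_set([], 10_000)
    null_elpd, null_pw = _elpd(null_fit)
    rows.append({"features": (), "elpd": null_elpd})
    if not features:
        return LooComparison([], pd.DataFrame(rows), null_fit)

    current = list(features)
    fit = fit_set(current, 0)
    elpd, pw = _elpd(fit)
    rows.append({"features": tuple(current), "elpd": elpd})
    step = 0
    while current:
        step += 1
        best = None
        for idx, f in enumerate(current):
            reduced = [g for g in current if g != f]
            if reduced:
                rfit = fit_set(reduced, 100 * step + idx)
                relpd, rpw = _elpd(rfit)
            else:
                rfit, relpd, rpw = null_fit, null_elpd, null_pw
            rows.append({"features": tuple(reduced), "elpd": relpd})
            if best is None or relpd > best[1]:
                best = (f, relpd, rfit, rpw)
        f, relpd, rfit, rpw = best
        diff_pw = rpw - pw
        se = float(np.sqrt(len(diff_pw) * np.var(diff_pw)))
        # drop the feature if the reduced model is within one SE of (or
        # better than) the current one: parsimony wins ties
        if relpd + se >= elpd:
            current.remove(f)
            fit, elpd, pw = rfit, relpd, rpw
        else:
            break
    table = pd.DataFrame(rows)
    return LooComparison(current, table, fit if current else null_fit)
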