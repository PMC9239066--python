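"""Seeded synthetic rhizosphere experiments with annotated ground truth.

The generator emulates the statistical structure of a two-treatment
greenhouse time series: pots arranged in spatial blocks, harvested
destructively on a fixed schedule with dense diel sampling at early
(days 3-4) and late (days 13-14) growth stages; exponential plant growth
with treatment, block and pot rate effects; and compositional ASV count
tables drawn from a logistic-normal multinomial whose latent
log-abundances have a block-diagonal sparse precision matrix (modules),
plus additive block-, stage- and treatment-specific shifts for designated
biomarker features.

Growth responses are generated *from* the community: for each planted
association the response equals a baseline plus ``slope x CLR(feature)``
plus block intercepts and Gaussian noise, matching the direction of the
downstream regression.  Every random draw flows from a single integer
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from rhizolink.containers import CountTable, stage_of_day

DEFAULT_DAYS = (2, 3, 4, 6, 8, 10, 13, 14)
DEFAULT_DIEL_DAYS = (3, 4, 13, 14)
#: additional harvest times on diel days; all days include the 1400 h harvest
DEFAULT_DIEL_TIMES = ("0900", "1800", "2200", "0400")

#: the nine (stage, response) pairings tested per treatment
DEFAULT_RESPONSES = (
    ("early", "pa_day3"),
    ("early", "pa_resid_early"),
    ("early", "biomass_resid_early"),
    ("late", "avg_pa_day10_11"),
    ("late", "pa_day13"),
    ("late", "pa_resid_late"),
    ("late", "biomass_resid_late"),
    ("late", "rgr_late"),
    ("all", "rgr_all"),
)


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------

def generate_design(
    n_blocks: int = 6,
    pots_per_block_per_treatment: int = 1,
    days=DEFAULT_DAYS,
    diel_days=DEFAULT_DIEL_DAYS,
    diel_times=DEFAULT_DIEL_TIMES,
    seed: int = 0,
) -> pd.DataFrame:
    """One rhizosphere sample per pot per scheduled harvest.

    Every day carries an afternoon (1400 h) harvest; days in ``diel_days``
    additionally carry each time in ``diel_times``.  At each harvest,
    ``pots_per_block_per_treatment`` pots per block and treatment are
    destructively sampled.  Pot numbering cycles round-robin through
    blocks, so the layout is deterministic given the arguments.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if pots_per_block_per_treatment < 1:
        raise ValueError("pots_per_block_per_treatment must be >= 1")
    days = sorted(set(days))
    if not days:
        raise ValueError("days must be non-empty")

    rows = []
    pot_counter = 0
    for day in days:
        times = ["1400"] + [t for t in diel_times if day in set(diel_days)]
        for time in times:
            for treatment in ("inoculated", "disrupted"):
                for rep in range(pots_per_block_per_treatment):
                    for block in range(1, n_blocks + 1):
                        pot_counter += 1
                        pot_id = f"pot{pot_counter:04d}"
                        rows.append(
                            {
                                "sample_id": f"S{pot_counter:04d}",
                                "pot_id": pot_id,
                                "treatment": treatment,
                                "block": block,
                                "day": float(day),
                                "harvest_time": time,
                                "stage": stage_of_day(day),
                            }
                        )
    design = pd.DataFrame(rows)
    assert design["sample_id"].is_unique and design["pot_id"].is_unique
    return design


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

@dataclass
class GrowthParams:
    """Parameters of the exponential growth model on the log-PA scale.

    log PA(pot, t) = log pa0 + (r_treatment + u_block + pot effect) * t + eps

    Rates are per day; intrinsic rates default to realistic fast-cycling
    Brassica values with a modest inoculation benefit.  ``biomass_coef``
    converts PA (green-pixel units) to aboveground dry mass (mg).
    """

    pa0: float = 40.0
    r_inoculated: float = 0.33
    r_disrupted: float = 0.30
    block_rate_sd: float = 0.010
    pot_rate_sd: float = 0.015
    resid_sd: float = 0.05
    biomass_coef: float = 0.20
    biomass_noise_sd: float = 0.10
    start_date: str = "2018-12-10"  # germination (T0) date

    def rate(self, treatment: str) -> float:
        return {"inoculated": self.r_inoculated, "disrupted": self.r_disrupted}[treatment]

    def __post_init__(self) -> None:
        for name in ("block_rate_sd", "pot_rate_sd", "resid_sd", "biomass_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_growth(design: pd.DataFrame, params: GrowthParams | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Per-pot projected-area time series plus destructive-harvest biomass.

    Returns a long table with one row per (pot, measurement day): columns
    pot_id, treatment, block, day, n_seedlings, green_pixels, pa, and on
    the harvest row additionally biomass and collection_date (ISO-8601).
    The realized per-pot rate is stored in the attribute
    ``result.attrs["true_rates"]``.
    """
    params = params or GrowthParams()
    rng = np.random.default_rng(seed)

    pots = design.drop_duplicates("pot_id").set_index("pot_id")
    blocks = sorted(design["block"].unique())
    u_block = dict(zip(blocks, rng.normal(0.0, params.block_rate_sd, len(blocks))))

    start = pd.Timestamp(params.start_date)
    rows, true_rates = [], {}
    for pot_id, pot in pots.iterrows():
        harvest_day = float(pot["day"])
        r_pot = params.rate(pot["treatment"]) + u_block[pot["block"]] + rng.normal(
            0.0, params.pot_rate_sd
        )
        true_rates[pot_id] = r_pot
        # early-harvest pots are sown densely, late pots thinned to 2 plants
        n_seedlings = int(rng.integers(3, 8)) if harvest_day <= 8 else 2
        meas_days = [float(d) for d in range(1, int(np.floor(harvest_day)) + 1)]
        if meas_days[-1] < harvest_day:
            meas_days.append(harvest_day)
        for d in meas_days:
            log_pa = np.log(params.pa0) + r_pot * d + rng.normal(0.0, params.resid_sd)
            pa = float(np.exp(log_pa))
            row = {
                "pot_id": pot_id,
                "treatment": pot["treatment"],
                "block": int(pot["block"]),
                "day": d,
                "n_seedlings": n_seedlings,
                "pa": pa,
                "green_pixels": pa * n_seedlings,
                "biomass": np.nan,
                "collection_date": pd.NA,
            }
            if d == meas_days[-1]:
                row["biomass"] = float(
                    params.biomass_coef * pa * np.exp(rng.normal(0.0, params.biomass_noise_sd))
                )
                # pre-dawn (0400) harvests fall on the next calendar date, so
                # collection date is not collinear with days grown
                rollover = 1 if str(pot.get("harvest_time", "1400")) == "0400" else 0
                row["collection_date"] = (
                    (start + pd.Timedelta(days=harvest_day + rollover)).date().isoformat()
                )
            rows.append(row)
    growth = pd.DataFrame(rows)
    growth.attrs["true_rates"] = true_rates
    growth.attrs["params"] = asdict(params)
    return growth


# ---------------------------------------------------------------------------
# community counts
# ---------------------------------------------------------------------------

@dataclass
class CommunityParams:
    """Structure of the latent log-abundance field.

    Modules are random ``within_degree``-regular graphs in the precision
    matrix with off-diagonal entries ``-partial_corr`` (unit diagonal,
    padded if needed for positive definiteness).  ``mu_sd`` sets the
    spread of feature-level mean log abundances (the rank-abundance
    curve).  Biomarker shifts are additive on the log scale.
    """

    n_features: int = 150
    module_size: int = 15
    within_degree: int = 4
    partial_corr: float = 0.2
    topology: str = "circulant"  # or "random" (random regular graph)
    mu_sd: float = 1.2
    n_block_biomarkers: int = 12
    block_shift: float = 1.0
    n_stage_biomarkers: int = 12
    stage_shift: float = 1.0
    n_treatment_biomarkers: int = 12
    treatment_shift: float = 1.0
    planted_in_modules: bool = False


@dataclass
class PlantedAssociation:
    """One true feature-growth coupling with its sample-group context."""

    feature: str
    treatment: str
    stage: str  # early / late / all
    response: str
    sign: int  # +1 or -1
    target_r2: float = 0.30
    slope: float = 1.0  # growth units per CLR unit (sign applied)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    planted: list
    block_biomarkers: list  # (feature, block)
    stage_biomarkers: list  # (feature, stage)
    treatment_biomarkers: list  # (feature, treatment)
    module_membership: dict
    true_precision: np.ndarray
    true_edges: list  # (feature_i, feature_j) with i < j, within-module
    latent_clr: pd.DataFrame  # samples x features, noiseless CLR
    coupled_responses: pd.DataFrame  # sample-level response values
    response_noise: dict  # (treatment, stage, response) -> sigma

    def planted_features(self) -> set:
        return {p.feature for p in self.planted}

    def to_json_dict(self) -> dict:
        return {
            "planted": [asdict(p) for p in self.planted],
            "block_biomarkers": self.block_biomarkers,
            "stage_biomarkers": self.stage_biomarkers,
            "treatment_biomarkers": self.treatment_biomarkers,
            "module_membership": self.module_membership,
            "true_edges": self.true_edges,
            "response_noise": {" / ".join(k): v for k, v in self.response_noise.items()},
        }


def _circulant_graph(size: int, degree: int) -> nx.Graph:
    """Ring-with-chords circulant graph: vertex-transitive, no cheap cuts.

    Offsets are spread over the half-ring so that every balanced or
    unbalanced vertex split cuts many edges, which keeps each module a
    single community under modularity optimization.
    """
    n_off = max(1, degree // 2)
    offsets = []
    for k in range(n_off):
        o = max(1, round((k * (size // 2 - 1)) / n_off) + 1) if k else 1
        if o not in offsets and o <= size // 2:
            offsets.append(o)
    g = nx.Graph()
    g.add_nodes_from(range(size))
    for i in range(size):
        for o in offsets:
            g.add_edge(i, (i + o) % size)
    return g


def module_precision(sizes, degree, strength, rng, topology: str = "circulant") -> tuple[np.ndarray, list, list]:
    """Block-diagonal sparse precision over latent log-abundances.

    Each module is a ``degree``-regular-ish graph (circulant by default;
    ``topology="random"`` gives an independent random regular graph) with
    off-diagonal precision ``-strength``.  The diagonal is padded so the
    smallest eigenvalue is at least 0.05, then the matrix is rescaled to
    unit diagonal (so ``strength`` is approximately the partial
    correlation of each true edge).
    """
    p = sum(sizes)
    omega = np.zeros((p, p))
    labels, edges = [], []
    offset = 0
    for m, size in enumerate(sizes):
        deg = min(degree, size - 1)
        if (deg * size) % 2 == 1:
            deg -= 1
        if topology == "circulant":
            g = _circulant_graph(size, deg)
        else:
            g = nx.random_regular_graph(deg, size, seed=int(rng.integers(2**31)))
        block = np.eye(size)
        for i, j in g.edges():
            block[i, j] = block[j, i] = -strength
            a, b = sorted((offset + i, offset + j))
            edges.append((a, b))
        omega[offset:offset + size, offset:offset + size] = block
        labels.extend([f"M{m + 1:02d}"] * size)
        offset += size
    w = np.linalg.eigvalsh(omega)
    if w.min() < 0.05:
        omega += (0.05 - w.min()) * np.eye(p)
    d = np.sqrt(np.diag(omega))
    omega = omega / np.outer(d, d)
    return omega, labels, edges


def _balanced_sizes(n: int, target: int) -> list[int]:
    k = max(1, round(n / target))
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def simulate_counts(
    design: pd.DataFrame,
    n_features: int | None = None,
    depth: int = 2000,
    community_params: CommunityParams | None = None,
    ground_truth_spec: list | None = None,
    seed: int = 0,
    responses=DEFAULT_RESPONSES,
    baseline: float = 100.0,
    block_noise_share: float = 0.2,
) -> tuple[CountTable, GroundTruth]:
    """Compositional counts plus ground-truth-coupled growth responses.

    Latent log-abundances are multivariate normal with a block-diagonal
    sparse precision (modules); designated biomarker features receive
    additive block/stage/treatment shifts; counts are multinomial at
    exactly ``depth`` reads per sample.  For each (treatment, stage,
    response) test in ``responses`` a per-sample response value is drawn:
    planted tests as ``baseline + sum(slope * latent CLR) + block
    intercept + noise`` with the noise variance solved so the planted
    features jointly explain ``target_r2`` of the response variance; all
    other tests as pure noise of comparable scale.
    """
    cp = community_params or CommunityParams()
    if n_features is not None:
        cp = CommunityParams(**{**asdict(cp), "n_features": n_features})
    if depth < 100:
        raise ValueError("depth must be >= 100")
    if cp.n_features < 20:
        raise ValueError("n_features must be >= 20")
    rng = np.random.default_rng(seed)
    p = cp.n_features
    features = [f"ASV{i + 1:04d}" for i in range(p)]
    findex = {f: i for i, f in enumerate(features)}

    sizes = _balanced_sizes(p, cp.module_size)
    omega, labels, edge_idx = module_precision(sizes, cp.within_degree, cp.partial_corr, rng, cp.topology)

    planted = _normalize_spec(ground_truth_spec, features, rng)
    planted_set = {pa.feature for pa in planted}
    if planted and not cp.planted_in_modules:
        # planted features become module singletons so the planted
        # couplings are the only true marginal associations in the table
        pidx = sorted(findex[f] for f in planted_set)
        omega[pidx, :] = 0.0
        omega[:, pidx] = 0.0
        omega[pidx, pidx] = 1.0
        edge_idx = [(i, j) for i, j in edge_idx if i not in pidx and j not in pidx]
        for k, i in enumerate(pidx):
            labels[i] = f"S{k + 1:02d}"

    sigma = np.linalg.inv(omega)
    chol = np.linalg.cholesky(sigma)
    module_membership = dict(zip(features, labels))
    true_edges = [(features[i], features[j]) for i, j in edge_idx]

    # biomarker assignment avoids planted features so planted couplings stay
    # free of design-driven abundance shifts
    free = [f for f in features if f not in planted_set]
    rng.shuffle(free)
    blocks = sorted(design["block"].unique())
    block_biomarkers = [
        (free.pop(), int(blocks[i % len(blocks)])) for i in range(min(cp.n_block_biomarkers, len(free) - 2))
    ]
    stage_biomarkers = [
        (free.pop(), ("early", "late")[i % 2]) for i in range(min(cp.n_stage_biomarkers, len(free) - 2))
    ]
    treatment_biomarkers = [
        (free.pop(), ("inoculated", "disrupted")[i % 2])
        for i in range(min(cp.n_treatment_biomarkers, len(free) - 2))
    ]

    mu = rng.normal(0.0, cp.mu_sd, p)
    # planted features are abundant community members (they must clear the
    # downstream rank/prevalence filter to be discoverable): give each the
    # mean log-abundance of a top-quantile feature by swapping mu values
    planted_idx = {findex[pa.feature] for pa in planted}
    for rank_q, pa in zip(np.linspace(0.08, 0.25, max(1, len(planted))), planted):
        i = findex[pa.feature]
        order = [j for j in np.argsort(-mu) if j not in planted_idx or j == i]
        target = int(order[int(rank_q * p)])
        mu[i], mu[target] = mu[target], mu[i]
    n = len(design)
    shift = np.zeros((n, p))
    design = design.reset_index(drop=True)
    for f, b in block_biomarkers:
        shift[(design["block"] == b).to_numpy(), findex[f]] += cp.block_shift
    for f, s in stage_biomarkers:
        shift[(design["stage"] == s).to_numpy(), findex[f]] += cp.stage_shift
    for f, t in treatment_biomarkers:
        shift[(design["treatment"] == t).to_numpy(), findex[f]] += cp.treatment_shift

    z = rng.standard_normal((n, p)) @ chol.T
    eta = mu[None, :] + shift + z
    latent_clr = eta - eta.mean(axis=1, keepdims=True)

    probs = np.exp(eta - eta.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, probs[i]) for i in range(n)])

    sample_ids = design["sample_id"].tolist()
    counts_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=features)
    metadata = design.set_index("sample_id")[
        ["pot_id", "treatment", "block", "day", "harvest_time", "stage"]
    ]
    table = CountTable(counts_df, metadata)
    latent_df = pd.DataFrame(latent_clr, index=counts_df.index, columns=features)

    resp_df, noise_used = _simulate_responses(
        design, latent_df, sigma, findex, planted, responses, baseline,
        block_noise_share, rng,
    )

    truth = GroundTruth(
        planted=planted,
        block_biomarkers=block_biomarkers,
        stage_biomarkers=stage_biomarkers,
        treatment_biomarkers=treatment_biomarkers,
        module_membership=module_membership,
        true_precision=omega,
        true_edges=true_edges,
        latent_clr=latent_df,
        coupled_responses=resp_df,
        response_noise=noise_used,
    )
    return table, truth


def _normalize_spec(spec, features, rng) -> list[PlantedAssociation]:
    if not spec:
        return []
    out = []
    for item in spec:
        if isinstance(item, PlantedAssociation):
            pa = item
        else:
            pa = PlantedAssociation(**item)
        if pa.feature is None:
            raise ValueError("planted association requires a feature id")
        if pa.feature not in features:
            raise ValueError(f"planted feature {pa.feature!r} not in the count table")
        if pa.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        out.append(pa)
    return out


def group_mask(design: pd.DataFrame, treatment: str, stage: str) -> np.ndarray:
    mask = (design["treatment"] == treatment).to_numpy()
    if stage == "all":
        mask &= (design["day"] > 2).to_numpy()
    else:
        mask &= (design["stage"] == stage).to_numpy()
    return mask


def _clr_variance(sigma: np.ndarray, coef: np.ndarray) -> float:
    """Variance of coef . CLR(z) when z ~ N(0, sigma), CLR = center rows."""
    p = sigma.shape[0]
    g = np.eye(p) - np.ones((p, p)) / p
    a = g @ coef
    return float(a @ sigma @ a)


def _simulate_responses(design, latent_df, sigma, findex, planted, responses,
                        baseline, block_noise_share, rng):
    rows = []
    noise_used = {}
    blocks = sorted(design["block"].unique())
    tests = [
        (treatment, stage, response)
        for treatment in ("inoculated", "disrupted")
        for stage, response in responses
    ]
    by_test = {}
    for pa in planted:
        by_test.setdefault((pa.treatment, pa.stage, pa.response), []).append(pa)
    latent = latent_df.to_numpy()

    for treatment, stage, response in tests:
        mask = group_mask(design, treatment, stage)
        if not mask.any():
            continue
        members = by_test.get((treatment, stage, response), [])
        coef = np.zeros(sigma.shape[0])
        for pa in members:
            coef[findex[pa.feature]] += pa.sign * pa.slope
        signal = latent[mask] @ coef
        centered = signal - signal.mean()
        if members and centered.std() > 0:
            # scale the noise to the REALIZED signal variance so the planted
            # coupling explains its target share of response variance in
            # this dataset, not merely in expectation
            v_signal = centered.var()
            r2 = members[0].target_r2
            v_noise = v_signal * (1 - r2) / r2
        else:
            # null test: noise scale comparable to a planted test's total
            v_noise = 1.0
        tau2 = block_noise_share * v_noise
        sig2 = v_noise - tau2
        u = dict(zip(blocks, rng.normal(0.0, np.sqrt(tau2), len(blocks))))
        block_eff = design.loc[mask, "block"].map(u).to_numpy()
        noise = block_eff + rng.normal(0.0, np.sqrt(sig2), mask.sum())
        if members and centered.std() > 0:
            # orthogonalize the noise to the signal (keeping its block
            # structure) so the realized variance split is exact
            noise = noise - noise.mean()
            noise = noise - (noise @ centered) / (centered @ centered) * centered
            noise *= np.sqrt(v_noise) / noise.std()
        values = baseline + signal + noise
        noise_used[(treatment, stage, response)] = float(np.sqrt(v_noise))
        sub = design.loc[mask]
        for sid, pid, blk, val in zip(sub["sample_id"], sub["pot_id"], sub["block"], values):
            rows.append(
                {
                    "sample_id": sid,
                    "pot_id": pid,
                    "treatment": treatment,
                    "stage": stage,
                    "block": int(blk),
                    "response": response,
                    "value": float(val),
                }
            )
    return pd.DataFrame(rows), noise_used


# ---------------------------------------------------------------------------
# one-call experiment
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Study conditions for a complete synthetic experiment."""

    n_blocks: int = 6
    pots_per_block_per_treatment: int = 1
    days: tuple = DEFAULT_DAYS
    diel_days: tuple = DEFAULT_DIEL_DAYS
    diel_times: tuple = DEFAULT_DIEL_TIMES
    depth: int = 2000
    community: CommunityParams = field(default_factory=CommunityParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    planted: list = field(default_factory=list)
    responses: tuple = DEFAULT_RESPONSES
    baseline: float = 100.0
    block_noise_share: float = 0.2


@dataclass
class SyntheticExperiment:
    design: pd.DataFrame
    growth: pd.DataFrame
    counts: CountTable
    responses: pd.DataFrame
    truth: GroundTruth


def default_planted(n_positive: int = 3, n_negative: int = 2,
                    target_r2: float = 0.30) -> list[PlantedAssociation]:
    """The standard planted-truth scenario: 5 couplings across distinct tests."""
    slots = [
        ("inoculated", "early", "pa_day3"),
        ("inoculated", "late", "pa_day13"),
        ("disrupted", "early", "pa_resid_early"),
        ("disrupted", "late", "avg_pa_day10_11"),
        ("inoculated", "all", "rgr_all"),
        ("disrupted", "all", "rgr_all"),
        ("inoculated", "late", "rgr_late"),
    ]
    planted = []
    signs = [1] * n_positive + [-1] * n_negative
    for i, sign in enumerate(signs):
        treatment, stage, response = slots[i % len(slots)]
        planted.append(
            PlantedAssociation(
                feature=f"ASV{10 * (i + 1):04d}",
                treatment=treatment,
                stage=stage,
                response=response,
                sign=sign,
                target_r2=target_r2,
            )
        )
    return planted


def network_recovery_scenario(seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Fixed study conditions for benchmarking network inference.

    Counts for one 200-sample group over 60 features whose latent
    precision is block-diagonal with three 20-feature modules, each a
    circulant expander graph (degree 4) with partial correlations at the
    positive-definiteness limit (~0.24).  Abundances are kept even
    (mu_sd=0.5) and sequencing deep (25,438 reads) so recovery reflects
    the graphical-lasso stage rather than counting noise.

    Returns the group count matrix and the ground truth (true edges and
    module membership).
    """
    design = generate_design(
        n_blocks=2, pots_per_block_per_treatment=10, days=(3, 4),
        diel_days=(3, 4), diel_times=("0900", "1800", "2200", "0400"),
    )
    cp = CommunityParams(
        n_features=60, module_size=20, within_degree=4, partial_corr=0.24,
        mu_sd=0.5, n_block_biomarkers=0, n_stage_biomarkers=0,
        n_treatment_biomarkers=0,
    )
    counts, truth = simulate_counts(design, depth=25438, community_params=cp, seed=seed)
    ids = counts.group_samples("inoculated", "early")
    return counts.select_samples(ids).counts, truth


def simulate_experiment(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticExperiment:
    """Design, growth series, counts, coupled responses and ground truth."""
    config = config or SyntheticConfig()
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    design = generate_design(
        config.n_blocks,
        config.pots_per_block_per_treatment,
        config.days,
        config.diel_days,
        config.diel_times,
        seed=int(seeds[0]),
    )
    growth = simulate_growth(design, config.growth, seed=int(seeds[1]))
    counts, truth = simulate_counts(
        design,
        depth=config.depth,
        community_params=config.community,
        ground_truth_spec=config.planted,
        seed=int(seeds[2]),
        responses=config.responses,
        baseline=config.baseline,
        block_noise_share=config.block_noise_share,
    )
    return SyntheticExperiment(design, growth, counts, truth.coupled_responses, truth)
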