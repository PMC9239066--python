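"""End-to-end orchestration: data -> stability selection -> Bayesian
confirmation -> multivariate refinement -> permutation screen -> networks
and module associations -> reports.

Every stage draws its randomness from seeds derived deterministically
from the single config seed, so a rerun with the same config reproduces
the same association tables.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rhizolink import io as rio
from rhizolink import network as net
from rhizolink.bayes import SamplerConfig, credible_gate, fit_univariate, loo_refine
from rhizolink.config import PipelineConfig
from rhizolink.containers import CountTable
from rhizolink.growth import build_responses
from rhizolink.screen import fdr_screen, scramble_pairing
from rhizolink.select import (
    StabilitySettings,
    TestCandidates,
    candidate_table,
    run_association_suite,
)
from rhizolink.synthetic import (
    CommunityParams,
    SyntheticConfig,
    default_planted,
    simulate_experiment,
)

log = logging.getLogger(__name__)

ASSOC_COLUMNS = [
    "treatment", "stage", "response", "kind", "feature",
    "selection_frequency", "both_presets", "direction", "median_slope",
    "ci_low", "ci_high", "R2_univariate", "univariate_kept",
    "multivariate_kept", "post_permutation_kept",
]


@dataclass
class ResultBundle:
    associations: pd.DataFrame
    module_associations: pd.DataFrame
    network_stats: pd.DataFrame
    networks: dict
    screen: object
    recovery: pd.DataFrame | None
    manifest: dict
    truth: object = None


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _synthetic_config(section) -> SyntheticConfig:
    community = CommunityParams(
        n_features=section.n_features,
        module_size=section.module_size,
        within_degree=section.within_degree,
        partial_corr=section.partial_corr,
    )
    planted = list(section.planted)
    if not planted and section.use_default_planted:
        planted = default_planted(target_r2=section.target_r2)
    return SyntheticConfig(
        n_blocks=section.n_blocks,
        pots_per_block_per_treatment=section.pots_per_block_per_treatment,
        days=tuple(section.days),
        diel_days=tuple(section.diel_days),
        diel_times=tuple(section.diel_times),
        depth=section.depth,
        community=community,
        planted=planted,
        baseline=section.baseline,
        block_noise_share=section.block_noise_share,
    )


def _load_data(config: PipelineConfig, seed: int):
    """Returns (CountTable, responses df with sample_id column, truth-or-None)."""
    if config.synthetic is not None:
        exp = simulate_experiment(_synthetic_config(config.synthetic), seed=seed)
        return exp.counts, exp.responses, exp.truth, exp
    inp = config.inputs
    if inp.biom_json:
        table = rio.read_biom_v1(inp.biom_json)
    else:
        table = rio.read_counts_tsv(inp.counts_tsv, inp.metadata_tsv)
    growth = pd.read_csv(inp.growth_tsv, sep="\t")
    pot_level = build_responses(growth)
    # map pot-level responses onto the pot's rhizosphere sample
    pot_to_sample = {
        pot: sid for sid, pot in table.metadata["pot_id"].items()
    }
    pot_level["sample_id"] = pot_level["pot_id"].map(pot_to_sample)
    responses = pot_level.dropna(subset=["sample_id"]).copy()
    return table, responses, None, None


def _pairings(config: PipelineConfig, responses: pd.DataFrame) -> dict:
    """Per-treatment list of (stage, response) pairings to test."""
    if config.tests:
        out = {t: [] for t in config.treatments}
        for treatment, stage, response in config.tests:
            out.setdefault(treatment, []).append((stage, response))
        return out
    if config.responses:
        pairs = [tuple(p) for p in config.responses]
    else:
        pairs = sorted(
            {(s, r) for s, r in responses[["stage", "response"]].itertuples(index=False)}
        )
    return {t: pairs for t in config.treatments}


def _run_suite(count_table, responses, pairings_by_treatment, settings, base_seed,
               kind="asv"):
    suite = []
    for i, (treatment, pairs) in enumerate(sorted(pairings_by_treatment.items())):
        if not pairs:
            continue
        suite.extend(
            run_association_suite(
                count_table, responses, pairings=pairs, settings=settings,
                base_seed=base_seed + i, kind=kind, treatments=(treatment,),
            )
        )
    return suite


def _confirm_univariate(suite: list[TestCandidates], counts: CountTable,
                        bayes_cfg, ci_level: float, seed: int):
    """Univariate hierarchical fit + credible gate for every candidate."""
    rows = []
    fits = {}
    seeds = iter(_derive_seeds(seed, max(1, sum(len(t.candidates) for t in suite)) + 1))
    for test in suite:
        cand = test.candidates
        if cand.empty:
            continue
        blocks = counts.metadata.loc[test.sample_ids, "block"].to_numpy()
        test_fits = {}
        for _, row in cand.iterrows():
            feature = row["feature"]
            clr = _clr_for(test, feature)
            cfg = SamplerConfig(
                draws=bayes_cfg.draws, warmup=bayes_cfg.warmup,
                chains=bayes_cfg.chains, seed=next(seeds),
                prior_scale=bayes_cfg.prior_scale,
            )
            fit = fit_univariate(
                clr.loc[test.sample_ids, feature], test.y.loc[test.sample_ids],
                blocks, cfg, feature=feature,
            )
            test_fits[feature] = fit
            fits[(test.treatment, test.stage, test.response, test.kind, feature)] = fit
        gate = credible_gate(test_fits, level=ci_level)
        gate = gate.merge(cand, on="feature")
        rows.append(gate)
    if not rows:
        return pd.DataFrame(), fits
    return pd.concat(rows, ignore_index=True), fits


def _clr_for(test: TestCandidates, feature: str) -> pd.DataFrame:
    for preset in sorted(test.clr):
        if feature in test.clr[preset].columns:
            return test.clr[preset]
    raise KeyError(feature)


def _tests_frame(suite: list[TestCandidates], kind: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"treatment": t.treatment, "stage": t.stage, "response": t.response, "kind": kind}
            for t in suite
        ]
    )


def _refine_multivariate(suite, confirmed, counts, bayes_cfg, seed):
    """LOO-guided backward refinement per test over all stability candidates."""
    kept_keys = set()
    refined = {}
    seeds = iter(_derive_seeds(seed, len(suite) + 1))
    for test in suite:
        s = next(seeds)
        cand = test.candidates
        if cand.empty or len(cand) < 1:
            continue
        feats = list(cand["feature"])
        X = pd.concat([_clr_for(test, f)[f] for f in feats], axis=1).loc[test.sample_ids]
        blocks = counts.metadata.loc[test.sample_ids, "block"].to_numpy()
        cfg = SamplerConfig(
            draws=max(400, bayes_cfg.draws // 2), warmup=bayes_cfg.warmup,
            chains=1, seed=s, prior_scale=bayes_cfg.prior_scale,
        )
        comp = loo_refine(X, test.y.loc[test.sample_ids], blocks, cfg)
        refined[(test.treatment, test.stage, test.response, test.kind)] = comp
        if comp.final_fit is not None and comp.kept_features:
            for j, f in enumerate(comp.final_fit.features):
                lo, hi = comp.final_fit.slope_ci(j)
                if lo > 0 or hi < 0:
                    kept_keys.add((test.treatment, test.stage, test.response, test.kind, f))
    return kept_keys, refined


def run_pipeline(config: PipelineConfig, write: bool = True) -> ResultBundle:
    t0 = time.time()
    (seed_data, seed_suite, seed_bayes, seed_scramble, seed_scr_suite,
     seed_scr_bayes, seed_net, seed_mod_suite, seed_mod_bayes, seed_refine,
     seed_mod_refine) = _derive_seeds(config.seed, 11)

    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    counts, responses, truth, exp = _load_data(config, seed_data)
    pairings = _pairings(config, responses)
    log.info("data ready: %d samples x %d features, %d pairings (%.1fs)",
             counts.n_samples, counts.n_features, len(pairings), time.time() - t0)

    settings = StabilitySettings(
        n_runs=config.stability.n_runs,
        threshold=config.stability.threshold,
        n_folds=config.stability.n_folds,
        n_lambda=config.stability.n_lambda,
        lambda_min_ratio=config.stability.lambda_min_ratio,
        pseudocount=config.stability.pseudocount,
        top_n=config.stability.top_n,
        subsample_frac=config.stability.subsample_frac,
        module_min_prevalence=config.stability.module_min_prevalence,
    )
    bayes_cfg = config.bayes

    # --- stage 1: stability selection ------------------------------------
    suite = _run_suite(counts, responses, pairings, settings, seed_suite)
    candidates = candidate_table(suite)
    log.info("stability selection: %d candidate associations (%.1fs)",
             len(candidates), time.time() - t0)

    # --- stage 2: univariate Bayesian confirmation ------------------------
    confirmed, fits = _confirm_univariate(
        suite, counts, bayes_cfg, bayes_cfg.ci_level, seed_bayes
    )

    # --- stage 3: multivariate LOO refinement ------------------------------
    multi_keys, refined = _refine_multivariate(suite, confirmed, counts, bayes_cfg, seed_refine)

    # --- stage 4: permutation screen ---------------------------------------
    scrambled_assoc_frames = []
    scr_tests = None
    for rep in range(config.permutation.n_replicates):
        scr_responses = scramble_pairing(responses, seed=seed_scramble + rep)
        scr_suite = _run_suite(counts, scr_responses, pairings, settings, seed_scr_suite)
        scr_confirmed, _ = _confirm_univariate(
            scr_suite, counts, bayes_cfg, bayes_cfg.ci_level, seed_scr_bayes + rep
        )
        scr_tests = _tests_frame(scr_suite, "asv")
        if not scr_confirmed.empty:
            scrambled_assoc_frames.append(scr_confirmed[scr_confirmed["kept"]])
    scrambled_kept = (
        pd.concat(scrambled_assoc_frames, ignore_index=True).drop_duplicates(
            ["treatment", "stage", "response", "kind", "feature"]
        )
        if scrambled_assoc_frames
        else pd.DataFrame(columns=["treatment", "stage", "response", "kind", "feature"])
    )

    associations = _association_table(candidates, confirmed, multi_keys)
    real_kept = associations[associations["univariate_kept"] | associations["multivariate_kept"]]
    report = fdr_screen(
        real_kept,
        scrambled_kept,
        _tests_frame(suite, "asv"),
        scr_tests if scr_tests is not None else _tests_frame(suite, "asv"),
        real_stability=candidates,
    )
    removed_keys = set(map(tuple, report.flagged_tests.itertuples(index=False)))
    associations["post_permutation_kept"] = associations.apply(
        lambda r: bool(
            (r["univariate_kept"] or r["multivariate_kept"])
            and (r["treatment"], r["stage"], r["response"], r["kind"]) not in removed_keys
        ),
        axis=1,
    )
    log.info("screen: %d flagged tests, %d associations kept (%.1fs)",
             len(report.flagged_tests), int(associations["post_permutation_kept"].sum()),
             time.time() - t0)

    # --- stage 5: co-occurrence networks ----------------------------------
    networks, network_stats, module_associations = network_stage(
        config, counts, responses, pairings, settings, bayes_cfg,
        seed_net, seed_mod_suite, seed_mod_bayes, seed_mod_refine,
    )

    # --- recovery report ---------------------------------------------------
    recovery = recovery_report_frames(associations, candidates, truth) if truth else None

    manifest = {
        "seed": config.seed,
        "config": config.model_dump(),
        "n_samples": counts.n_samples,
        "n_features": counts.n_features,
        "runtime_s": round(time.time() - t0, 2),
        "outputs": {},
    }
    bundle = ResultBundle(
        associations=associations,
        module_associations=module_associations,
        network_stats=network_stats,
        networks=networks,
        screen=report,
        recovery=recovery,
        manifest=manifest,
        truth=truth,
    )
    if write:
        _write_bundle(bundle, counts, responses, exp, outdir)
    return bundle


def network_stage(config, counts, responses, pairings, settings, bayes_cfg,
                  seed_net, seed_mod_suite, seed_mod_bayes, seed_mod_refine):
    """Per-group network inference, module detection and module associations."""
    networks, stats_rows = {}, []
    module_associations = pd.DataFrame(columns=ASSOC_COLUMNS)
    if not config.network.enabled:
        return networks, pd.DataFrame(stats_rows), module_associations
    stars = net.StarsConfig(
        subsample_ratio=config.network.subsample_ratio,
        n_subsamples=config.network.n_subsamples,
        instability_threshold=config.network.instability_threshold,
    )
    net_seeds = iter(_derive_seeds(seed_net, 2 * len(config.treatments) * len(config.network.groups) + 1))
    mod_frames = []
    for treatment in config.treatments:
        for stage in config.network.groups:
            group = f"{stage} {treatment}"
            ids = counts.group_samples(treatment, stage)
            if len(ids) < 10:
                log.info("network %s skipped: %d samples", group, len(ids))
                continue
            sub = counts.select_samples(ids).counts
            try:
                feats = net.network_filter(
                    sub, config.network.min_samples, config.network.min_mean_rel_abund
                )
            except ValueError:
                log.info("network %s skipped: filter left no features", group)
                continue
            network = net.infer_network(
                sub[feats],
                lambda_min_ratio=config.network.lambda_min_ratio,
                n_lambda=config.network.n_lambda,
                stability=stars,
                seed=next(net_seeds),
                pseudocount=config.stability.pseudocount,
                sample_group=group,
            )
            modules = net.detect_modules(network, seed=next(net_seeds))
            stats = net.network_stats(network, modules)
            stats_rows.append({"sample_group": group, "count": len(ids), **stats.as_dict()})
            networks[group] = network

            if config.modules.enabled:
                mod_counts = net.module_abundances(sub, modules)
                mod_table = CountTable(
                    mod_counts.astype(np.int64), counts.metadata.loc[ids]
                )
                mod_pairs = [p for p in pairings.get(treatment, []) if p[0] == stage]
                if not mod_pairs:
                    continue
                mod_suite = run_association_suite(
                    mod_table, responses, pairings=mod_pairs, settings=settings,
                    base_seed=seed_mod_suite, kind="module", treatments=(treatment,),
                )
                mod_confirmed, _ = _confirm_univariate(
                    mod_suite, mod_table, bayes_cfg, bayes_cfg.ci_level, seed_mod_bayes
                )
                mod_cand = candidate_table(mod_suite)
                mod_keys, _ = _refine_multivariate(
                    mod_suite, mod_confirmed, mod_table, bayes_cfg, seed_mod_refine
                )
                mframe = _association_table(mod_cand, mod_confirmed, mod_keys)
                mframe["post_permutation_kept"] = (
                    mframe["univariate_kept"] | mframe["multivariate_kept"]
                )
                mframe["sample_group"] = group
                mod_frames.append(mframe)
    mod_frames = [f for f in mod_frames if not f.empty]
    if mod_frames:
        module_associations = pd.concat(mod_frames, ignore_index=True)
    return networks, pd.DataFrame(stats_rows), module_associations


def _association_table(candidates: pd.DataFrame, confirmed: pd.DataFrame,
                       multi_keys: set) -> pd.DataFrame:
    if candidates.empty:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    df = candidates.copy()
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    df["selection_frequency"] = df[freq_cols].max(axis=1)
    if not confirmed.empty:
        conf = confirmed[[
            "treatment", "stage", "response", "kind", "feature",
            "median_slope", "ci_low", "ci_high", "direction", "R2_univariate", "kept",
        ]].rename(columns={"kept": "univariate_kept"})
        df = df.merge(conf, on=["treatment", "stage", "response", "kind", "feature"], how="left")
    else:
        df[["median_slope", "ci_low", "ci_high", "R2_univariate"]] = np.nan
        df["direction"] = pd.NA
        df["univariate_kept"] = False
    df["univariate_kept"] = df["univariate_kept"].fillna(False).astype(bool)
    df["multivariate_kept"] = [
        (r["treatment"], r["stage"], r["response"], r["kind"], r["feature"]) in multi_keys
        for _, r in df.iterrows()
    ]
    df["post_permutation_kept"] = False
    keep = [c for c in ASSOC_COLUMNS if c in df.columns] + [
        c for c in df.columns if c.startswith(("freq_", "selected_"))
    ]
    return df[keep]


def recovery_report_frames(associations: pd.DataFrame, candidates: pd.DataFrame,
                           truth) -> pd.DataFrame:
    """Precision/recall/sign-accuracy per pipeline stage against planted truth."""
    planted = {
        (p.treatment, p.stage, p.response, p.feature): p.sign for p in truth.planted
    }
    key_cols = ["treatment", "stage", "response", "feature"]

    def stage_set(df, mask=None):
        if df is None or df.empty:
            return set()
        sub = df if mask is None else df[mask]
        return set(map(tuple, sub[key_cols].itertuples(index=False)))

    asv = associations[associations["kind"] == "asv"] if not associations.empty else associations
    stages = {
        "stability": stage_set(candidates[candidates["kind"] == "asv"] if not candidates.empty else candidates),
        "univariate_bayes": stage_set(asv, asv["univariate_kept"] if not asv.empty else None),
        "multivariate_bayes": stage_set(asv, asv["multivariate_kept"] if not asv.empty else None),
        "post_screen": stage_set(asv, asv["post_permutation_kept"] if not asv.empty else None),
    }
    direction = {}
    if not asv.empty and "direction" in asv.columns:
        for _, r in asv.iterrows():
            direction[(r["treatment"], r["stage"], r["response"], r["feature"])] = r["direction"]

    rows = []
    for name, found in stages.items():
        tp = found & set(planted)
        fp = found - set(planted)
        sign_ok = sum(
            1 for k in tp
            if direction.get(k) == ("positive" if planted[k] > 0 else "negative")
        )
        rows.append(
            {
                "stage": name,
                "true_positives": len(tp),
                "false_positives": len(fp),
                "n_planted": len(planted),
                "recall": len(tp) / len(planted) if planted else np.nan,
                "precision": len(tp) / len(found) if found else np.nan,
                "sign_accuracy": sign_ok / len(tp) if tp else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_bundle(bundle: ResultBundle, counts, responses, exp, outdir: Path) -> None:
    outputs = {}

    def save_tsv(df, name):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = _sha256(path)

    rio.write_counts_tsv(counts, outdir / "counts.tsv", outdir / "metadata.tsv")
    outputs["counts.tsv"] = _sha256(outdir / "counts.tsv")
    outputs["metadata.tsv"] = _sha256(outdir / "metadata.tsv")
    save_tsv(responses, "responses.tsv")
    save_tsv(bundle.associations, "associations.tsv")
    save_tsv(bundle.module_associations, "module_associations.tsv")
    if not bundle.network_stats.empty:
        save_tsv(bundle.network_stats, "network_stats.tsv")
    for group, network in bundle.networks.items():
        slug = group.replace(" ", "_")
        save_tsv(network.edge_table(), f"edges_{slug}.tsv")
        net.write_graphml(network, outdir / f"network_{slug}.graphml")
        outputs[f"network_{slug}.graphml"] = _sha256(outdir / f"network_{slug}.graphml")
    rio.write_json(bundle.screen.to_json_dict(), outdir / "screen_report.json")
    outputs["screen_report.json"] = _sha256(outdir / "screen_report.json")
    if bundle.recovery is not None:
        save_tsv(bundle.recovery, "recovery.tsv")
    if exp is not None:
        save_tsv(exp.growth, "growth.tsv")
        rio.write_json(exp.truth.to_json_dict(), outdir / "ground_truth.json")
        outputs["ground_truth.json"] = _sha256(outdir / "ground_truth.json")
    bundle.manifest["outputs"] = outputs
    rio.write_json(bundle.manifest, outdir / "manifest.json")
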