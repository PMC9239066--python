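"""The generator must embody the structure the pipeline assumes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhizolink.synthetic import (
    CommunityParams,
    GrowthParams,
    PlantedAssociation,
    default_planted,
    generate_design,
    module_precision,
    simulate_counts,
    simulate_experiment,
    simulate_growth,
)


class TestDesign:
    def test_paper_schedule_sizes(self, paper_design):
        # 6 pots per treatment per harvest; diel days have 5 harvests
        d = paper_design
        per_point = d.groupby(["treatment", "day", "harvest_time"]).size()
        assert (per_point == 6).all()
        early = d[(d.treatment == "inoculated") & (d.stage == "early")]
        assert len(early) == 60  # the study's per-group community count

    def test_minimal_counting(self):
        d = generate_design(n_blocks=2, pots_per_block_per_treatment=1,
                            days=[3], diel_days=[], diel_times=[])
        assert len(d) == 4  # 2 blocks x 2 treatments

    def test_determinism_and_invariants(self):
        a = generate_design(seed=5)
        b = generate_design(seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert a.sample_id.is_unique
        # every pot maps to exactly one block and treatment
        assert (a.groupby("pot_id")[["block", "treatment"]].nunique() == 1).all().all()
        # stage is a pure function of day
        assert (a.loc[a.day.isin([3, 4]), "stage"] == "early").all()
        assert (a.loc[a.day.isin([13, 14]), "stage"] == "late").all()
        assert (a.loc[a.day == 2, "stage"] == "mid").all()

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_design(pots_per_block_per_treatment=0)
        with pytest.raises(ValueError):
            generate_design(days=[])


class TestGrowth:
    def test_noiseless_doubling(self):
        d = generate_design(n_blocks=2, days=[3, 4], diel_days=[], diel_times=[])
        params = GrowthParams(r_inoculated=np.log(2), r_disrupted=np.log(2),
                              block_rate_sd=0, pot_rate_sd=0, resid_sd=0,
                              biomass_noise_sd=0)
        g = simulate_growth(d, params, seed=0)
        for _, pot in g.groupby("pot_id"):
            pa = pot.sort_values("day")["pa"].to_numpy()
            assert np.allclose(pa[1:] / pa[:-1], 2.0)

    def test_treatment_ordering_with_zero_noise(self):
        d = generate_design(n_blocks=2, days=[3, 13], diel_days=[], diel_times=[])
        params = GrowthParams(r_inoculated=0.4, r_disrupted=0.3,
                              block_rate_sd=0, pot_rate_sd=0, resid_sd=0)
        g = simulate_growth(d, params, seed=0)
        by_day = g.groupby(["day", "treatment"])["pa"].mean().unstack()
        assert (by_day["inoculated"] > by_day["disrupted"]).all()

    def test_fitted_slopes_recover_rate(self):
        # Monte-Carlo: mean fitted per-pot log-slope within 2 SE of true r
        d = generate_design(n_blocks=6, pots_per_block_per_treatment=9,
                            days=[8], diel_days=[], diel_times=[])
        params = GrowthParams()
        g = simulate_growth(d, params, seed=3)
        slopes = []
        for _, pot in g[g.treatment == "inoculated"].groupby("pot_id"):
            x, y = pot["day"].to_numpy(), np.log(pot["pa"].to_numpy())
            slopes.append(stats.linregress(x, y).slope)
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - params.r_inoculated) < 2 * se + 1e-9

    def test_rejects_negative_sd(self):
        with pytest.raises(ValueError):
            GrowthParams(resid_sd=-0.1)


class TestCounts:
    def test_multinomial_closure(self, small_experiment):
        counts, _ = small_experiment
        assert (counts.depths() == 2000).all()

    def test_determinism(self, paper_design):
        a, ta = simulate_counts(paper_design, ground_truth_spec=default_planted(), seed=9)
        b, tb = simulate_counts(paper_design, ground_truth_spec=default_planted(), seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(ta.coupled_responses, tb.coupled_responses)

    def test_rejects_unknown_planted_feature(self, paper_design):
        spec = [PlantedAssociation("ASV9999", "inoculated", "early", "pa_day3", 1)]
        with pytest.raises(ValueError, match="ASV9999"):
            simulate_counts(paper_design, ground_truth_spec=spec, seed=0)

    def test_truth_coupling_recovers_slope(self, small_experiment):
        # regressing the response on the true latent CLR recovers the
        # planted slope within 2 SE
        counts, truth = small_experiment
        for pa in truth.planted[:2]:
            ids = counts.group_samples(pa.treatment, pa.stage)
            resp = truth.coupled_responses
            y = resp[
                (resp.treatment == pa.treatment)
                & (resp.stage == pa.stage)
                & (resp.response == pa.response)
            ].set_index("sample_id")["value"].loc[ids]
            x = truth.latent_clr.loc[ids, pa.feature]
            fit = stats.linregress(x, y)
            assert abs(fit.slope - pa.sign * pa.slope) < 2.5 * fit.stderr

    def test_null_features_uncorrelated(self, paper_design):
        # with zero planted slopes, |r| between any feature CLR and the
        # response stays below 0.3 for >= 95% of features at n=60
        counts, truth = simulate_counts(paper_design, ground_truth_spec=None, seed=5)
        ids = counts.group_samples("inoculated", "early")
        resp = truth.coupled_responses
        y = resp[
            (resp.treatment == "inoculated")
            & (resp.stage == "early")
            & (resp.response == "pa_day3")
        ].set_index("sample_id")["value"].loc[ids]
        lat = truth.latent_clr.loc[ids]
        r = np.array([stats.pearsonr(lat[f], y)[0] for f in lat.columns])
        assert (np.abs(r) < 0.3).mean() >= 0.95

    def test_module_partial_correlation_structure(self):
        # same-module pairs have higher mean |partial correlation| than
        # cross-module pairs, checked on the true precision
        rng = np.random.default_rng(0)
        omega, labels, edges = module_precision([15, 15, 15], 4, 0.2, rng)
        d = np.sqrt(np.diag(omega))
        pcor = -omega / np.outer(d, d)
        same = np.equal.outer(labels, labels)
        iu = np.triu_indices(45, 1)
        within = np.abs(pcor[iu])[same[iu]]
        cross = np.abs(pcor[iu])[~same[iu]]
        assert within.mean() > cross.mean()
        assert np.allclose(omega, omega.T)
        assert np.linalg.eigvalsh(omega).min() > 0

    def test_experiment_bundle(self):
        exp = simulate_experiment(seed=1)
        assert set(exp.responses.columns) >= {"sample_id", "response", "value"}
        assert exp.counts.n_samples == len(exp.design)
        assert exp.growth["pot_id"].nunique() == len(exp.design)
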