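"""Compositional preparation: CSS, Bray-Curtis, diversity, filtering, CLR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhizolink.containers import REMAINDER
from rhizolink.prep import (
    alpha_diversity,
    bray_curtis,
    clr_with_remainder,
    core_community,
    css_transform,
    dissimilarity_trajectory,
    rank_prevalence_filter,
)


class TestCSS:
    def test_identical_samples_identical_rows(self):
        counts = pd.DataFrame([[5, 10, 85], [5, 10, 85]], columns=list("abc"))
        out = css_transform(counts, percentile=0.5)
        assert np.allclose(out.iloc[0], out.iloc[1])

    def test_scale_invariance_at_matched_quantiles(self):
        counts = pd.DataFrame([[5, 10, 85], [10, 20, 170]], columns=list("abc"))
        out = css_transform(counts, percentile=0.5)
        assert np.allclose(out.iloc[0], out.iloc[1])

    def test_matches_stepwise_hand_computation(self, toy_counts):
        # brute-force CSS at a fixed percentile: per sample, divide by the
        # sum of counts at or below the p-quantile of nonzero counts
        p, scale = 0.5, 1000.0
        expected = np.empty(toy_counts.shape, dtype=float)
        for i, (_, row) in enumerate(toy_counts.iterrows()):
            nz = row[row > 0].to_numpy(dtype=float)
            q = np.quantile(nz, p)
            s = row[row <= q].sum()
            expected[i] = row.to_numpy() / s * scale
        got = css_transform(toy_counts, percentile=p, scale=scale)
        assert np.allclose(got.to_numpy(), expected)

    def test_adaptive_percentile_in_range(self, toy_counts):
        out = css_transform(toy_counts)
        assert 0.5 <= out.attrs["css_percentile"] <= 0.99

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], columns=list("ab"))
        with pytest.raises(ValueError):
            css_transform(counts)


class TestBrayCurtis:
    def test_examples(self):
        m = pd.DataFrame(
            [[2, 2, 0], [0, 2, 2], [2, 2, 0], [3, 0, 0]],
            index=list("wxyz"), columns=list("abc"),
        )
        bc = bray_curtis(m)
        assert bc.loc["w", "x"] == pytest.approx(0.5)  # hand computation
        assert bc.loc["w", "y"] == 0  # identical rows
        assert bc.loc["x", "z"] == 1  # disjoint supports
        assert np.allclose(bc, bc.T)
        assert np.allclose(np.diag(bc), 0)
        assert ((bc.to_numpy() >= 0) & (bc.to_numpy() <= 1)).all()

    def test_two_zero_rows_rejected(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 1]])
        with pytest.raises(ValueError):
            bray_curtis(m)


class TestTrajectory:
    def test_identical_samples_give_zero(self):
        m = pd.DataFrame([[1, 2]] * 6, index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame(
            {"treatment": ["inoculated"] * 6, "day": [2, 2, 3, 3, 4, 4]},
            index=m.index,
        )
        traj = dissimilarity_trajectory(bray_curtis(m), meta)
        assert (traj["dissimilarity"] == 0).all()

    def test_reference_day_pair_count(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(1, 50, (6, 4)), index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame(
            {"treatment": ["inoculated"] * 6, "day": [2, 2, 3, 3, 3, 4]},
            index=m.index,
        )
        traj = dissimilarity_trajectory(bray_curtis(m), meta)
        # day 2: within-day pairs only (1); day 3: 3x2 cross pairs; day 4: 1x2
        sizes = traj.groupby("day").size()
        assert sizes[2.0] == 1 and sizes[3.0] == 6 and sizes[4.0] == 2

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.integers(1, 50, (6, 5)), index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame(
            {"treatment": ["disrupted"] * 6, "day": [2, 2, 2, 6, 6, 8]},
            index=m.index,
        )
        bc = bray_curtis(m)
        traj = dissimilarity_trajectory(bc, meta)
        day6 = sorted(traj[traj.day == 6]["dissimilarity"])
        expected = sorted(
            bc.loc[a, b] for a in ["s3", "s4"] for b in ["s0", "s1", "s2"]
        )
        assert np.allclose(day6, expected)

    def test_missing_reference_day_rejected(self):
        m = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"])
        meta = pd.DataFrame({"treatment": ["x", "x"], "day": [3, 4]}, index=m.index)
        with pytest.raises(ValueError):
            dissimilarity_trajectory(bray_curtis(m), meta)


class TestAlphaDiversity:
    def test_examples(self):
        counts = pd.DataFrame(
            [[25, 25, 25, 25], [99, 0, 0, 0], [10, 30, 60, 0]],
            columns=list("abcd"),
        )
        div = alpha_diversity(counts)
        assert div["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert div["shannon"].iloc[1] == 0
        assert div["observed_features"].tolist() == [4, 1, 3]
        expected = -sum(p * np.log(p) for p in (0.1, 0.3, 0.6))
        assert div["shannon"].iloc[2] == pytest.approx(expected)


class TestCoreCommunity:
    def test_membership_and_read_fraction(self, toy_counts):
        core, frac = core_community(toy_counts, min_prevalence=1.0)
        # brute force: only asvD is present in all 5 samples
        assert core == ["asvD"]
        assert frac == pytest.approx(toy_counts["asvD"].sum() / toy_counts.to_numpy().sum())

    def test_feature_absent_once_excluded(self, toy_counts):
        core, _ = core_community(toy_counts, min_prevalence=1.0)
        assert "asvA" not in core  # zero in sample s2

    def test_lower_prevalence_grows_core(self, toy_counts):
        core80, _ = core_community(toy_counts, min_prevalence=0.8)
        core100, _ = core_community(toy_counts, min_prevalence=1.0)
        assert set(core100) <= set(core80)


class TestRankPrevalenceFilter:
    def test_all_features_ordered(self, toy_counts):
        got = rank_prevalence_filter(toy_counts, top_n=100, min_prevalence=0)
        rel = toy_counts.div(toy_counts.sum(axis=1), axis=0).mean()
        assert got == sorted(toy_counts.columns, key=lambda f: (-rel[f], f))

    def test_low_prevalence_excluded(self):
        counts = pd.DataFrame(
            {"rare": [100] + [0] * 9, "common": [1] * 10}
        )
        got = rank_prevalence_filter(counts, top_n=10, min_prevalence=0.3)
        assert got == ["common"]

    def test_matches_brute_force(self, toy_counts):
        top_n, min_prev = 3, 0.5
        rel = toy_counts.div(toy_counts.sum(axis=1), axis=0).mean()
        prev = (toy_counts > 0).mean()
        order = sorted(toy_counts.columns, key=lambda f: (-rel[f], f))[:top_n]
        expected = [f for f in order if prev[f] >= min_prev]
        assert rank_prevalence_filter(toy_counts, top_n, min_prev) == expected

    def test_empty_result_is_error(self):
        counts = pd.DataFrame({"a": [1, 0, 0, 0]})
        with pytest.raises(ValueError, match="loosen"):
            rank_prevalence_filter(counts, top_n=1, min_prevalence=0.9)


class TestCLR:
    def test_uniform_composition_all_zero(self):
        counts = pd.DataFrame([[10, 10, 10]], columns=list("abc"))
        out = clr_with_remainder(counts, list("abc"))
        # remainder is empty and uniform parts split symmetrically around it
        sel = out[list("abc")]
        assert np.allclose(sel.to_numpy() - sel.to_numpy().mean(), 0, atol=1e-12)

    def test_matches_hand_computed_three_part(self):
        counts = pd.DataFrame([[8, 3, 9]], columns=list("abc"))
        out = clr_with_remainder(counts, ["a", "b"], pseudocount=0.5)
        logs = np.log(np.array([8.5, 3.5, 9.5]))
        expected = logs - logs.mean()
        assert np.allclose(out.iloc[0][["a", "b", REMAINDER]], expected)

    def test_remainder_and_exclusions(self, toy_counts):
        out = clr_with_remainder(toy_counts, ["asvA", "asvB"])
        assert REMAINDER in out.columns
        assert list(out.columns).count(REMAINDER) == 1
        with pytest.raises(ValueError):
            clr_with_remainder(toy_counts, [])
        with pytest.raises(ValueError):
            clr_with_remainder(toy_counts, ["nope"])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.lists(st.integers(0, 500), min_size=4, max_size=4),
                    min_size=2, max_size=6))
    def test_rows_sum_to_zero(self, rows):
        counts = pd.DataFrame(rows, columns=list("abcd"))
        out = clr_with_remainder(counts, ["a", "b"])
        assert np.abs(out.sum(axis=1)).max() < 1e-8

    def test_agrees_with_reference_clr(self):
        # cross-check the full-selection case against scikit-bio's clr
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 100, (4, 6)))
        ours = clr_with_remainder(counts, list(counts.columns), pseudocount=0.5)
        # the remainder of a full selection is an all-pseudocount part
        composition = np.hstack([counts.to_numpy() + 0.5, np.full((4, 1), 0.5)])
        theirs = skbio_clr(composition)
        assert np.allclose(ours.to_numpy(), theirs, atol=1e-10)
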