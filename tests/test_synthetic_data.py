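"""Synthetic tumor-pair generator: determinism, drift behavior, and
whether the cut-off-90 classifier can recover the true pair labels."""

import numpy as np
import pytest
from scipy.stats import binomtest

from mplcdx import (
    Call,
    Marker,
    MarkerDistribution,
    PairGenParams,
    PairRelation,
    ValidationError,
    classify,
    default_marker_distributions,
    generate_cohort,
    generate_pair,
    pair_profiles,
    read_specimen_table,
    sample_specimen_percent,
    total_dvalue,
)


def dispersed_params(drift_sd=5.0):
    dists = {
        m: MarkerDistribution(m, zero_inflation=d.zero_inflation, alpha=0.5, beta=0.5)
        for m, d in default_marker_distributions().items()
    }
    return PairGenParams(drift_sd=drift_sd, marker_dists=dists)


class TestSampling:
    def test_degenerate_zero_inflation_always_negative(self):
        dist = MarkerDistribution(Marker.P53, zero_inflation=1.0)
        rng = np.random.default_rng(0)
        assert all(sample_specimen_percent(dist, rng) == 0.0 for _ in range(50))

    def test_symmetric_beta_mean_near_fifty(self):
        dist = MarkerDistribution(Marker.P16, zero_inflation=0.0, alpha=2.0, beta=2.0)
        rng = np.random.default_rng(1)
        draws = [sample_specimen_percent(dist, rng) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(50, abs=2)
        assert all(0 <= d <= 100 for d in draws)

    def test_fixed_seed_reproduces_draws(self):
        dist = MarkerDistribution(Marker.P27, zero_inflation=0.3)
        a = [sample_specimen_percent(dist, np.random.default_rng(7)) for _ in range(1)]
        b = [sample_specimen_percent(dist, np.random.default_rng(7)) for _ in range(1)]
        assert a == b

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            MarkerDistribution(Marker.P53, zero_inflation=1.5)
        with pytest.raises(ValidationError):
            MarkerDistribution(Marker.P53, zero_inflation=0.5, alpha=0)
        with pytest.raises(ValidationError):
            PairGenParams(drift_sd=-1)


class TestGeneratePair:
    def test_zero_drift_clonal_pair_has_zero_dvalue(self):
        params = dispersed_params(drift_sd=0.0)
        t1, t2, label = generate_pair(params, np.random.default_rng(3))
        assert label == "IPM"
        assert total_dvalue(t1, t2).total == 0

    def test_degenerate_distributions_give_no_signal(self):
        # all-negative marker laws: independent pairs are indistinguishable
        dists = {m: MarkerDistribution(m, zero_inflation=1.0) for m in Marker}
        params = PairGenParams(relation=PairRelation.INDEPENDENT, marker_dists=dists)
        t1, t2, label = generate_pair(params, np.random.default_rng(4))
        assert label == "MPLC"
        assert total_dvalue(t1, t2).total == 0

    def test_fixed_seed_reproduces_pair(self):
        params = dispersed_params()
        pair_a = generate_pair(params, np.random.default_rng(11))
        pair_b = generate_pair(params, np.random.default_rng(11))
        assert pair_a == pair_b


class TestGenerateCohort:
    def test_group_sizes_and_csv_determinism(self):
        spec_a, lab_a = generate_cohort(30, 14, seed=1)
        spec_b, lab_b = generate_cohort(30, 14, seed=1)
        assert spec_a.to_csv(index=False) == spec_b.to_csv(index=False)
        assert lab_a.to_csv(index=False) == lab_b.to_csv(index=False)
        assert len(lab_a) == 44
        assert (lab_a["true_label"] == "IPM").sum() == 30
        assert (lab_a["true_label"] == "MPLC").sum() == 14
        # two lesions x four markers per pair
        assert len(spec_a) == 44 * 8

    def test_single_group_cohort(self):
        _, labels = generate_cohort(0, 5, seed=2)
        assert list(labels["true_label"].unique()) == ["MPLC"]

    def test_empty_request_rejected(self):
        with pytest.raises(ValidationError):
            generate_cohort(0, 0)

    def test_cohort_feeds_scoring_pipeline(self):
        specimens, labels = generate_cohort(3, 3, seed=5)
        profiles = read_specimen_table(specimens)
        pairs = pair_profiles(profiles)
        assert len(pairs) == len(labels)


class TestStatisticalBehavior:
    def test_mean_clonal_dvalue_non_decreasing_in_drift(self):
        means = []
        for drift in (0.0, 5.0, 20.0, 50.0):
            params = dispersed_params(drift_sd=drift)
            rng = np.random.default_rng(42)
            totals = [
                total_dvalue(*generate_pair(params, rng)[:2]).total for _ in range(300)
            ]
            means.append(np.mean(totals))
        assert means == sorted(means)

    def test_independent_pairs_separate_from_clonal_at_small_drift(self):
        rng = np.random.default_rng(13)
        clonal = dispersed_params(drift_sd=5.0)
        indep = PairGenParams(
            relation=PairRelation.INDEPENDENT, marker_dists=clonal.marker_dists
        )
        clonal_totals = [
            total_dvalue(*generate_pair(clonal, rng)[:2]).total for _ in range(300)
        ]
        indep_totals = [
            total_dvalue(*generate_pair(indep, rng)[:2]).total for _ in range(300)
        ]
        assert np.mean(indep_totals) > np.mean(clonal_totals)

    def test_cutoff90_recovers_labels_above_chance(self):
        """On 200 pairs (drift 5, dispersed Beta(0.5, 0.5) laws) the
        default classifier beats coin-flipping (one-sided binomial test)."""
        specimens, labels = generate_cohort(
            100, 100, params=dispersed_params(drift_sd=5.0), seed=17
        )
        profiles = read_specimen_table(specimens)
        truth = dict(zip(labels["patient_id"], labels["true_label"]))
        correct = 0
        for t1, t2 in pair_profiles(profiles):
            call = classify(total_dvalue(t1, t2))
            predicted = "MPLC" if call.call is Call.MPLC else "IPM"
            correct += predicted == truth[t1.patient_id]
        result = binomtest(correct, 200, p=0.5, alternative="greater")
        assert result.pvalue < 0.01
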