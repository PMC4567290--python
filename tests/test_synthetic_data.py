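"""The hybrid-zone generator: calibration, determinism, round-trip calls."""

import numpy as np
import pytest

from afribee import (
    Call,
    DomainError,
    SimConfig,
    calibrate_morph_cov,
    calibrate_morph_means,
    coi_snp_call,
    estimate_frequency,
    individual_score,
    make_marker_sequences,
    pooled_t,
    rflp_mitotype,
    sample_population,
    sample_sites,
    spacer_lineage,
)
from afribee.morphometrics import INDIVIDUAL_COEFFS
from afribee.types import MorphMeasurements

BASE = (9.0, 6.0, 2.6, 3.2)


class TestCalibration:
    def test_target_equal_to_current_is_identity(self):
        current = individual_score(MorphMeasurements(*BASE))
        out = calibrate_morph_means(BASE, current)
        assert out == pytest.approx(BASE, abs=1e-12)

    @pytest.mark.parametrize("target", [-1.473, -0.428, 0.902, 3.0])
    def test_calibrated_means_hit_target(self, target):
        out = calibrate_morph_means(BASE, target)
        assert individual_score(MorphMeasurements(*out)) == pytest.approx(
            target, abs=1e-9
        )

    def test_zero_coefficients_rejected(self):
        with pytest.raises(DomainError):
            calibrate_morph_means(BASE, 0.0, coefficients=(0, 0, 0, 0), constant=0.0)

    def test_cov_scaling_hits_target_sd(self):
        w = np.asarray(INDIVIDUAL_COEFFS)
        cov = calibrate_morph_cov(np.eye(4) * 0.01, target_score_sd=0.5)
        assert float(w @ cov @ w) == pytest.approx(0.25, abs=1e-12)


class TestMakeMarkerSequences:
    def test_african_construction_round_trips(self, panel, rng):
        seqs = make_marker_sequences(Call.AFRICAN, panel, rng=rng)
        assert rflp_mitotype(seqs["cytb"]).call is Call.AFRICAN
        assert coi_snp_call(seqs["COI"], panel).call is Call.AFRICAN
        assert spacer_lineage(seqs["spacer"], panel).call is Call.LINEAGE_A

    def test_european_construction_round_trips(self, panel, rng):
        seqs = make_marker_sequences(Call.EUROPEAN, panel, rng=rng)
        assert rflp_mitotype(seqs["cytb"]).call is Call.EUROPEAN
        assert coi_snp_call(seqs["COI"], panel).call is Call.EUROPEAN
        assert spacer_lineage(seqs["spacer"], panel).call in (
            Call.LINEAGE_C,
            Call.LINEAGE_M,
            Call.LINEAGE_O,
        )

    def test_round_trip_with_mutations(self, panel, rng):
        """Light mutation never flips a call: protected sites are untouched."""
        for mito in (Call.AFRICAN, Call.EUROPEAN):
            seqs = make_marker_sequences(mito, panel, n_extra_mutations=5, rng=rng)
            assert rflp_mitotype(seqs["cytb"]).call is mito
            assert coi_snp_call(seqs["COI"], panel).call is mito

    def test_mutation_count_applied(self, panel):
        rng = np.random.default_rng(7)
        clean = make_marker_sequences(Call.AFRICAN, panel, seed=7)
        mutated = make_marker_sequences(Call.AFRICAN, panel, n_extra_mutations=4, seed=7)
        diffs = sum(a != b for a, b in zip(clean["COI"], mutated["COI"]))
        assert diffs == 4

    def test_excessive_mutations_rejected(self, panel):
        with pytest.raises(DomainError):
            make_marker_sequences(Call.AFRICAN, panel, n_extra_mutations=10_000, seed=0)

    def test_mass_round_trip_identity(self, panel):
        """0-mutation sequences are always called as generated (200 bees)."""
        rng = np.random.default_rng(99)
        for i in range(200):
            mito = Call.AFRICAN if i % 2 else Call.EUROPEAN
            seqs = make_marker_sequences(mito, panel, rng=rng)
            assert rflp_mitotype(seqs["cytb"]).call is mito
            assert coi_snp_call(seqs["COI"], panel).call is mito
            assert (spacer_lineage(seqs["spacer"], panel).call is Call.LINEAGE_A) == (
                mito is Call.AFRICAN
            )


class TestSamplePopulation:
    def test_determinism_byte_identical(self, panel):
        cfg = SimConfig(n_bees=40, seed=42)
        a = sample_population(cfg, panel)
        b = sample_population(cfg, panel)
        for s1, s2 in zip(a, b):
            assert s1.sequences == s2.sequences
            assert s1.morph.as_tuple() == s2.morph.as_tuple()
            assert s1.metadata == s2.metadata

    def test_p_african_one_yields_all_african(self, panel):
        cfg = SimConfig(p_african=0.999999, n_bees=30, seed=1, attach_sequences=False)
        pop = sample_population(cfg, panel)
        assert all(s.metadata["true_mitotype"] == "african" for s in pop)

    def test_frequency_recovered_at_n5000(self):
        cfg = SimConfig(
            p_african=0.65, n_bees=5000, seed=3, attach_sequences=False, attach_morph=False
        )
        pop = sample_population(cfg)
        p_hat = np.mean([s.metadata["true_mitotype"] == "african" for s in pop])
        assert 0.63 <= p_hat <= 0.67  # 99% binomial interval at n=5000

    def test_full_linkage_separates_scores(self):
        cfg = SimConfig(n_bees=2000, linkage=1.0, seed=5, attach_sequences=False)
        pop = sample_population(cfg)
        scores = {
            "african": [
                individual_score(s.morph)
                for s in pop
                if s.metadata["true_mitotype"] == "african"
            ],
            "european": [
                individual_score(s.morph)
                for s in pop
                if s.metadata["true_mitotype"] == "european"
            ],
        }
        r = pooled_t(scores["african"], scores["european"])
        assert abs(r.t) > 10
        assert r.mean_a < r.mean_b

    def test_no_linkage_scores_uninformative(self):
        cfg = SimConfig(n_bees=2000, linkage=0.0, seed=6, attach_sequences=False)
        pop = sample_population(cfg)
        a = [
            individual_score(s.morph)
            for s in pop
            if s.metadata["true_mitotype"] == "african"
        ]
        b = [
            individual_score(s.morph)
            for s in pop
            if s.metadata["true_mitotype"] == "european"
        ]
        assert abs(pooled_t(a, b).t) < 3

    def test_misclassification_rate_matches_configured_overlap(self):
        """At calibrated means, misclassifying against the midpoint
        threshold happens at the configured 9.9% rate (±2 points)."""
        cfg = SimConfig(n_bees=10_000, linkage=1.0, seed=8, attach_sequences=False)
        pop = sample_population(cfg)
        midpoint = (cfg.target_score_african + cfg.target_score_european) / 2
        wrong = 0
        for s in pop:
            score = individual_score(s.morph)
            called_african = score < midpoint
            truly_african = s.metadata["true_nuclear_class"] == "african"
            wrong += called_african != truly_african
        rate = wrong / len(pop)
        assert abs(rate - 0.099) < 0.02

    def test_calls_recover_generating_mitotype(self, panel):
        cfg = SimConfig(n_bees=60, seed=11, attach_morph=False)
        pop = sample_population(cfg, panel)
        for s in pop:
            assert (
                rflp_mitotype(s.sequences["cytb"]).call.value
                == s.metadata["true_mitotype"]
            )

    def test_non_psd_covariance_rejected(self):
        bad = np.eye(4)
        bad[0, 0] = -1.0
        with pytest.raises(DomainError):
            SimConfig(base_cov=tuple(map(tuple, bad)))


class TestSampleSites:
    def test_p_zero_limit(self):
        cfg = SimConfig(p_african=1e-12, n_sites=50, seed=2)
        sites = sample_sites(cfg)
        assert all(s.n_african_mito == 0 and not s.mixed for s in sites)

    def test_mixed_fraction_matches_binomial(self):
        cfg = SimConfig(p_african=0.65, n_sites=20_000, seed=4)
        sites = sample_sites(cfg)
        mixed_frac = np.mean([s.mixed for s in sites])
        # P(1 African) + P(2 African) under Binom(3, 0.65) = 0.6825
        assert abs(mixed_frac - 0.6825) < 0.01

    def test_determinism(self):
        cfg = SimConfig(n_sites=95, seed=9)
        assert sample_sites(cfg) == sample_sites(cfg)


class TestWilsonCoverage:
    @pytest.mark.parametrize("p_true", [0.1, 0.5, 0.65, 0.9])
    def test_ci_covers_truth(self, p_true):
        """Wilson 95% CI coverage stays >= 93% (true coverage ~95%).

        1,000 replicates keep the Monte-Carlo standard error of the
        coverage estimate (~0.7 points) well inside the 2-point margin.
        """
        rng = np.random.default_rng(int(1000 * p_true))
        from afribee import Marker, MarkerCall

        covered = 0
        n_rep = 1000
        for _ in range(n_rep):
            k = rng.binomial(2000, p_true)
            calls = [
                MarkerCall(Marker.CYTB_RFLP, Call.AFRICAN, "e", True)
            ] * k + [
                MarkerCall(Marker.CYTB_RFLP, Call.EUROPEAN, "e", True)
            ] * (2000 - k)
            est = estimate_frequency(calls)
            covered += est.ci_low <= p_true <= est.ci_high
        assert covered / n_rep >= 0.93
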