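"""Synthetic droplet generator: occupancy statistics, determinism,
dilution/LOD designs and the paired cohort."""

import math

import numpy as np
import pytest

from ddmrd import (
    ClassificationRules,
    CohortSpec,
    ConfigurationError,
    MrdClass,
    SimulationConfig,
    ValidationError,
    classify,
    quantify_plate,
    simulate_cohort,
    simulate_dilution_series,
    simulate_lod_experiment,
    simulate_well,
)
from ddmrd import datasets


class TestSimulateWell:
    def test_zero_concentration_no_rain_gives_zero_positives(self, config):
        rng = config.rng()
        for _ in range(20):
            assert simulate_well(0.0, config, rng=rng).k_positive == 0

    def test_negative_concentration_rejected(self, config):
        with pytest.raises(ValidationError):
            simulate_well(-1.0, config)

    def test_occupancy_closed_form(self, config):
        """At 123.95 copies/ul and Vd=8.5e-4 the positive fraction is
        1 - exp(-0.10536) ~ 0.1000; pooled over 50 wells it must sit within
        3 binomial SDs."""
        rng = config.rng()
        k = n = 0
        for _ in range(50):
            w = simulate_well(123.95, config, rng=rng)
            k += w.k_positive
            n += w.n_accepted
        p = -math.expm1(-123.95 * config.droplet_volume)
        assert abs(k / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_determinism_and_seed_sensitivity(self):
        a = simulate_well(10.0, SimulationConfig(seed=5))
        b = simulate_well(10.0, SimulationConfig(seed=5))
        c = simulate_well(10.0, SimulationConfig(seed=6))
        assert (a.n_accepted, a.k_positive) == (b.n_accepted, b.k_positive)
        assert (a.n_accepted, a.k_positive) != (c.n_accepted, c.k_positive)

    def test_amplitudes_cluster_sizes(self, config):
        w = simulate_well(100.0, config, with_amplitudes=True)
        assert len(w.amplitudes) == w.n_accepted
        # clusters are separable by construction: threshold mid-gap
        mid = (config.amplitude_neg_mean + config.amplitude_pos_mean) / 2
        assert int(np.count_nonzero(w.amplitudes > mid)) == w.k_positive

    def test_rain_adds_false_positives(self):
        cfg = SimulationConfig(rain_rate=0.01, seed=2)
        w = simulate_well(0.0, cfg)
        assert w.k_positive > 0


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"droplet_volume": 0.0},
            {"rain_rate": 1.0},
            {"partitioned_fraction": 0.0},
            {"partitioned_fraction": 1.5},
            {"amplitude_pos_mean": 1200.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestDilutionSeries:
    def test_anchor_concentration_recovered(self, config):
        """A 10x dilution of 437 copies/ul sits at 43.7 nominal; the pooled
        estimate must land within 3 SDs of it."""
        groups = simulate_dilution_series(437.0, [0.1], 8, config)
        (group,) = groups
        from ddmrd import quantify_wells

        q = quantify_wells(group)
        assert q.ci_low < 43.7 < q.ci_high or abs(q.concentration - 43.7) / 43.7 < 0.1
        assert all(w.replicate_group == "dil_0.1" for w in group)

    def test_identity_dilution(self, config):
        (group,) = simulate_dilution_series(50.0, [1.0], 2, config)
        assert len(group) == 2

    @pytest.mark.parametrize(
        "factors", [[], [0.1, 0.1], [0.01, 0.1], [1.5], [0.0]]
    )
    def test_bad_factor_lists_rejected(self, config, factors):
        with pytest.raises(ValidationError):
            simulate_dilution_series(437.0, factors, 2, config)

    def test_tenfold_ratio_recovered_on_average(self):
        """Over 200 series, the ratio of Poisson-corrected estimates between
        consecutive 10-fold points averages within 10% of 10."""
        from ddmrd import quantify_wells

        rng_seed = np.random.default_rng(11)
        ratios = []
        for i in range(200):
            cfg_i = SimulationConfig(seed=int(rng_seed.integers(2**31)))
            hi, lo = simulate_dilution_series(437.0, [0.1, 0.01], 2, cfg_i)
            ratios.append(
                quantify_wells(hi).concentration / quantify_wells(lo).concentration
            )
        assert abs(np.mean(ratios) - 10.0) < 1.0


class TestLodExperiment:
    def test_default_design_replicates(self, config):
        exp = simulate_lod_experiment(
            list(datasets.LOD_COPIES_BY_LABEL_LOGSCALE.values()),
            list(datasets.LOD_REPLICATE_DESIGN),
            config,
            labels=list(datasets.LOD_DILUTION_LABELS),
        )
        assert [len(p.wells) for p in exp.points] == [2, 6, 8, 12, 14]
        assert [p.label for p in exp.points] == [1e-4, 5e-5, 1e-5, 5e-6, 1e-6]

    def test_zero_copies_all_negative(self, config):
        exp = simulate_lod_experiment([0.0], [30], config)
        assert all(w.k_positive == 0 for w in exp.points[0].wells)

    def test_single_copy_detection_probability(self):
        """With one expected molecule and full partitioning, a replicate is
        positive with probability 1 - 1/e = 0.632; 10,000 replicates must land
        within 3 binomial SDs."""
        cfg = SimulationConfig(partitioned_fraction=1.0, seed=13)
        exp = simulate_lod_experiment([1.0], [10000], cfg)
        frac = np.mean([w.k_positive >= 1 for w in exp.points[0].wells])
        p = 1 - math.exp(-1)
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / 10000)

    def test_length_mismatch_rejected(self, config):
        with pytest.raises(ValidationError):
            simulate_lod_experiment([1.0, 2.0], [2], config)


class TestCohort:
    def test_all_zero_mix_is_all_negative_end_to_end(self, rules):
        """Every sample of a template-free cohort must classify NEG through
        the full quantify-and-classify pipeline."""
        spec = CohortSpec(
            n_samples=20,
            class_mix={"high": 0, "low_quantifiable": 0, "trace": 0, "zero": 1.0},
            seed=4,
        )
        cfg = SimulationConfig(rain_rate=0.0, seed=4)
        truth, samples = simulate_cohort(spec, cfg)
        assert set(truth["qrtpcr_class"]) == {"NEG"}
        wells = [w for s in samples for w in s.wells]
        measurements = quantify_plate(wells)
        assert len(measurements) == 20
        assert all(classify(m, rules) is MrdClass.NEG for m in measurements)

    def test_determinism(self, config):
        spec = CohortSpec(n_samples=88, seed=9)
        t1, s1 = simulate_cohort(spec, config)
        t2, s2 = simulate_cohort(spec, config)
        assert t1.equals(t2)
        assert [(w.well_id, w.k_positive) for s in s1 for w in s.wells] == [
            (w.well_id, w.k_positive) for s in s2 for w in s.wells
        ]

    def test_trace_samples_are_pnq_more_often_than_high(self, config):
        spec = CohortSpec(
            n_samples=400,
            class_mix={"high": 0.5, "low_quantifiable": 0, "trace": 0.5, "zero": 0},
            seed=21,
        )
        truth, _ = simulate_cohort(spec, config)
        pnq_rate = truth.groupby("level")["qrtpcr_class"].apply(
            lambda s: (s == "PNQ").mean()
        )
        assert pnq_rate["trace"] > pnq_rate["high"]

    def test_bad_mix_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(class_mix={"high": 0.5, "zero": 0.4})


class TestFixtures:
    def test_fixture_files_round_trip(self, tmp_path):
        from ddmrd.datasets import (
            read_diagnostic_csv,
            read_lod_positivity_csv,
            write_fixture_files,
        )
        from ddmrd.io import read_class_pairs

        paths = write_fixture_files(tmp_path)
        assert read_diagnostic_csv(paths["diagnostic_comparison"]) == datasets.DIAGNOSTIC_TABLE
        assert read_class_pairs(paths["followup_class_pairs"]) == datasets.followup_pairs()
        table = read_lod_positivity_csv(paths["lod_positivity"])
        assert [
            (r.label, r.n_replicates, r.n_positive_replicates) for r in table.rows
        ] == [(l, n, k) for l, (n, k) in datasets.LOD_POSITIVITY.items()]

    def test_verbatim_anchor_values(self):
        assert ("DX10", "p190", 63.6, 64.0) in datasets.DIAGNOSTIC_TABLE
        assert datasets.FOLLOWUP_CROSSTAB[0][0] == 10
        assert datasets.LOD_POSITIVITY[5e-6] == (12, 2)
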