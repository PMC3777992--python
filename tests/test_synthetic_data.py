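"""Generator contracts: determinism, planted truth, and null fidelity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hetprofile.assay_quant import chip_qpcr_enrichment, fit_input_standard_curve
from hetprofile.errors import CapacityError, ConfigError
from hetprofile.synthetic_data import (
    MUTANT,
    WILD_TYPE,
    ArmSpec,
    AssayClassTruth,
    QpcrLocusTruth,
    SimConfig,
    TeFamilySpec,
    build_genome_annotation,
    null_config,
    simulate_probe_signal,
    simulate_qpcr_plate,
    simulate_reporter_tables,
    true_m_at,
)


class TestAnnotation:
    def test_degenerate_single_arm_no_features(self):
        cfg = SimConfig(
            arm_specs=(ArmSpec("armA", 100_000, True, 60_000),),
            te_family_specs=(),
            cluster_specs=(),
        )
        fs = build_genome_annotation(cfg)
        assert list(fs.arms) == ["armA"]
        assert fs.te_instances.empty and fs.pirna_clusters.empty
        assert fs.arms["armA"].pericentric_span() == (60_000, 100_000)

    def test_same_config_and_seed_reproduces_coordinates(self, tiny_config):
        a = build_genome_annotation(tiny_config)
        b = build_genome_annotation(tiny_config)
        pd.testing.assert_frame_equal(a.te_instances, b.te_instances)
        pd.testing.assert_frame_equal(a.pirna_clusters, b.pirna_clusters)

    def test_different_seed_moves_features(self, tiny_config):
        other = dataclasses.replace(tiny_config, seed=tiny_config.seed + 1)
        a = build_genome_annotation(tiny_config)
        b = build_genome_annotation(other)
        assert not a.te_instances.equals(b.te_instances)

    def test_all_instances_within_arm_bounds_exhaustive(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config,
            te_family_specs=tuple(
                dataclasses.replace(s, n_instances=17) for s in tiny_config.te_family_specs
            ),
        )  # ~50 instances
        fs = build_genome_annotation(cfg)
        assert len(fs.te_instances) >= 50
        for _, row in fs.te_instances.iterrows():
            arm = fs.arms[row["chrom"]]
            assert 0 <= row["start"] < row["end"] <= arm.length
        # placed intervals never overlap one another
        for chrom, sub in fs.te_instances.groupby("chrom"):
            iv = sub.sort_values("start")
            assert (iv["start"].to_numpy()[1:] >= iv["end"].to_numpy()[:-1]).all()

    def test_capacity_error_when_features_exceed_genome(self):
        cfg = SimConfig(
            arm_specs=(ArmSpec("armA", 50_000, True, 40_000),),
            te_family_specs=(TeFamilySpec("roo", 100, (900, 1000), 0.0),),
            cluster_specs=(),
        )
        with pytest.raises(CapacityError):
            build_genome_annotation(cfg)


class TestProbeSignal:
    def test_null_run_probes_have_chip_equal_input(self):
        cfg = null_config()
        fs = build_genome_annotation(cfg)
        probes = simulate_probe_signal(fs, cfg, WILD_TYPE)
        np.testing.assert_array_equal(probes["chip"], probes["input"])

    def test_probe_in_family_baseline_two_gives_ratio_four(self):
        cfg = SimConfig(
            arm_specs=(ArmSpec("armA", 100_000, True, 99_000),),
            te_family_specs=(TeFamilySpec("gypsy5", 1, (10_000, 10_000), 2.0),),
            cluster_specs=(),
            pericentric_m=0.0,
            probe_noise_sd=0.0,
            input_lognormal_sd=0.0,
            nonunique_fraction=0.0,
            class_shift={},
        )
        fs = build_genome_annotation(cfg)
        probes = simulate_probe_signal(fs, cfg, WILD_TYPE)
        te = fs.te_instances.iloc[0]
        inside = probes[(probes["pos"] >= te["start"]) & (probes["pos"] < te["end"])]
        assert len(inside) > 0
        np.testing.assert_allclose(inside["chip"] / inside["input"], 4.0, atol=1e-9)
        outside = probes[(probes["pos"] < te["start"]) | (probes["pos"] >= te["end"])]
        np.testing.assert_allclose(outside["chip"] / outside["input"], 1.0, atol=1e-9)

    def test_noisy_class_mean_recovers_planted_value(self):
        """~10^4 probes in one class: mean M within 3 sd/sqrt(n) of truth."""
        sd = 0.3
        cfg = SimConfig(
            arm_specs=(ArmSpec("armA", 3_000_000, True, 10_000),),
            te_family_specs=(),
            cluster_specs=(),
            pericentric_m=1.5,
            probe_noise_sd=sd,
            nonunique_fraction=0.0,
            class_shift={},
            seed=11,
        )
        fs = build_genome_annotation(cfg)
        probes = simulate_probe_signal(fs, cfg, WILD_TYPE)
        peri = probes[probes["pos"] >= 10_000]
        n = len(peri)
        assert n >= 9000
        m = np.log2(peri["chip"] / peri["input"])
        assert abs(m.mean() - 1.5) < 3 * sd / np.sqrt(n)

    def test_mutant_condition_applies_relative_shift(self, tiny_config):
        fs = build_genome_annotation(tiny_config)
        pos = np.arange(150_000, 200_000, 1000)
        wt = true_m_at(fs, tiny_config, "armA", pos, WILD_TYPE)
        mut = true_m_at(fs, tiny_config, "armA", pos, MUTANT)
        # pericentric background shifts down by the configured fraction
        shift = tiny_config.class_shift["pericentric"].value
        bg = wt == tiny_config.pericentric_m
        np.testing.assert_allclose(mut[bg], wt[bg] * (1 + shift), atol=1e-12)

    def test_unknown_condition_rejected(self, tiny_config):
        fs = build_genome_annotation(tiny_config)
        with pytest.raises(ConfigError, match="condition"):
            simulate_probe_signal(fs, tiny_config, "heterozygote")

    def test_unique_flags_shared_between_conditions(self, tiny_config):
        fs = build_genome_annotation(tiny_config)
        wt = simulate_probe_signal(fs, tiny_config, WILD_TYPE)
        mut = simulate_probe_signal(fs, tiny_config, MUTANT)
        np.testing.assert_array_equal(wt["unique"], mut["unique"])

    def test_byte_identical_reproduction(self, tiny_config):
        a = simulate_probe_signal(build_genome_annotation(tiny_config), tiny_config, MUTANT)
        b = simulate_probe_signal(build_genome_annotation(tiny_config), tiny_config, MUTANT)
        pd.testing.assert_frame_equal(a, b)


class TestQpcrPlate:
    def _noiseless_cfg(self, fold=1.0):
        return SimConfig(
            qpcr_truth={
                "alpha_actinin": QpcrLocusTruth({WILD_TYPE: 1.0, MUTANT: 1.0}, 1.0, 0.0),
                "target": QpcrLocusTruth({WILD_TYPE: fold, MUTANT: fold}, 1.0, 0.0),
            }
        )

    def test_noiseless_unit_enrichment_ip_matches_input_fraction_well(self):
        plate = simulate_qpcr_plate(self._noiseless_cfg(1.0), WILD_TYPE)
        tgt = plate[plate["locus"] == "target"]
        ip_ct = tgt[tgt["role"] == "ip"]["ct"].unique()
        one_pct = tgt[
            (tgt["role"] == "input_dilution") & (tgt["dilution_fraction"] == 0.01)
        ]["ct"].unique()
        assert len(ip_ct) == 1 and len(one_pct) == 1
        assert ip_ct[0] == pytest.approx(one_pct[0], abs=1e-12)

    def test_planted_two_fold_round_trips_through_enrichment(self):
        plate = simulate_qpcr_plate(self._noiseless_cfg(2.0), WILD_TYPE)
        curve_t = fit_input_standard_curve(plate, locus="target")
        curve_c = fit_input_standard_curve(plate, locus="alpha_actinin")
        res = chip_qpcr_enrichment(plate, curve_t, curve_c, plate)
        assert res.relative_enrichment == pytest.approx(2.0, abs=1e-9)

    def test_noisy_plates_recover_enrichment_within_three_se(self):
        cfg = SimConfig(
            qpcr_truth={
                "alpha_actinin": QpcrLocusTruth({WILD_TYPE: 1.0, MUTANT: 1.0}, 1.0, 0.15),
                "target": QpcrLocusTruth({WILD_TYPE: 4.0, MUTANT: 4.0}, 1.0, 0.15),
            },
            qpcr_n_ip_replicates=100,
            seed=5,
        )
        plate = simulate_qpcr_plate(cfg, WILD_TYPE)
        curve_t = fit_input_standard_curve(plate, locus="target")
        curve_c = fit_input_standard_curve(plate, locus="alpha_actinin")
        res = chip_qpcr_enrichment(plate, curve_t, curve_c, plate)
        assert abs(res.relative_enrichment - 4.0) < 3 * res.enrichment_sem

    def test_missing_control_locus_rejected(self):
        cfg = SimConfig(
            qpcr_truth={"target": QpcrLocusTruth({WILD_TYPE: 2.0, MUTANT: 1.0})}
        )
        with pytest.raises(ConfigError, match="control locus"):
            simulate_qpcr_plate(cfg, WILD_TYPE)


class TestReporterTables:
    def test_noiseless_tables_have_exact_slopes(self):
        cfg = null_config()
        tables = simulate_reporter_tables(cfg)
        for (_, _), sub in tables.beta_gal.groupby(["genotype_class", "replicate"]):
            slope = np.polyfit(sub["time_min"], sub["od574"], 1)[0]
            assert slope == pytest.approx(1e-3, rel=1e-9)

    def test_equal_activity_classes_give_equal_pigment(self):
        tables = simulate_reporter_tables(null_config())
        assert tables.pigment["od480"].nunique() == 1

    def test_replicate_floor_enforced(self):
        cfg = null_config()
        cfg.assay_truth = {
            "beta_gal": {
                "C": AssayClassTruth(1e-3, 0.0, 1),
                "M": AssayClassTruth(2e-3, 0.0, 4),
            },
            "pigment": {
                "C": AssayClassTruth(0.1, 0.0, 4),
                "M": AssayClassTruth(0.2, 0.0, 4),
            },
        }
        with pytest.raises(ConfigError, match="SEM"):
            simulate_reporter_tables(cfg)

    def test_reproducible_given_seed(self, tiny_config):
        a = simulate_reporter_tables(tiny_config, seed=3)
        b = simulate_reporter_tables(tiny_config, seed=3)
        pd.testing.assert_frame_equal(a.beta_gal, b.beta_gal)
        pd.testing.assert_frame_equal(a.pigment, b.pigment)
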