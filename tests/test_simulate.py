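"""Synthetic genome construction, fragment weights and read sampling."""

import numpy as np
import pandas as pd
import pytest

import damidte as d
from damidte.simulate import fragment_truth
from conftest import small_config


def uniform_config(**overrides):
    """All occupancies/boosts at 1: fragment weights should be flat."""
    cfg = small_config(
        te_families={
            "LTR": d.TEFamilySpec(2, 600, 2, 1.0),
            "LINE": d.TEFamilySpec(2, 600, 1, 1.0),
        },
        chet_occupancy_boost=1.0,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


class TestBuildSyntheticGenome:
    def test_zero_te_copies_background_only(self):
        cfg = small_config(te_families={"LTR": d.TEFamilySpec(2, 500, 0, 4.0)})
        syn = d.build_synthetic_genome(cfg)
        assert syn.te_copies.empty
        assert len(syn.tes.frame) == 2  # consensus still generated

    def test_same_seed_identical_output(self, tmp_path):
        cfg = small_config(seed=42)
        a = d.build_synthetic_genome(cfg)
        b = d.build_synthetic_genome(cfg)
        assert a.genome.records == b.genome.records
        pd.testing.assert_frame_equal(a.te_copies, b.te_copies)

    def test_gatc_density_matches_binomial_expectation(self):
        """Uniform base composition: GATC ~ Binomial(L, 1/256)."""
        cfg = small_config(
            genome_length=100_000, n_chroms=1,
            te_families={"LTR": d.TEFamilySpec(1, 500, 0, 4.0)},
        )
        syn = d.build_synthetic_genome(cfg)
        sites = d.scan_gatc_sites(syn.genome)
        n = sum(len(v) for v in sites.values())
        expect = 100_000 / 256
        sd = np.sqrt(100_000 * (1 / 256) * (1 - 1 / 256))
        assert abs(n - expect) < 3 * sd

    def test_copies_non_overlapping_and_in_bounds(self):
        syn = d.build_synthetic_genome(small_config())
        for chrom, group in syn.te_copies.groupby("chrom"):
            group = group.sort_values("start")
            assert (group["start"].to_numpy()[1:] >= group["end"].to_numpy()[:-1]).all()
            assert (group["end"] <= syn.genome.lengths[chrom]).all()

    def test_copies_match_consensus_up_to_substitution_rate(self):
        cfg = small_config(substitution_rate=0.02)
        syn = d.build_synthetic_genome(cfg)
        row = syn.te_copies.iloc[0]
        copy_seq = syn.genome.records[row["chrom"]][row["start"]:row["end"]]
        cons = syn.tes.sequences[row["te_name"]]
        mismatch = sum(a != b for a, b in zip(copy_seq, cons)) / len(cons)
        assert mismatch < 0.1  # 2% substitutions, ~0.75% back-mutations aside

    def test_capacity_error(self):
        cfg = small_config(
            genome_length=10_000,
            n_chroms=1,
            te_families={"LTR": d.TEFamilySpec(10, 900, 3, 4.0)},
        )
        with pytest.raises(ValueError, match="capacity"):
            d.build_synthetic_genome(cfg)


class TestConfigValidation:
    def test_bad_reads(self):
        with pytest.raises(ValueError, match="reads_per_sample"):
            d.SimulationConfig(reads_per_sample=10).validate()

    def test_bad_chet_fraction(self):
        with pytest.raises(ValueError, match="chet_fraction"):
            d.SimulationConfig(chet_fraction=1.0).validate()

    def test_nonpositive_multiplier(self):
        cfg = d.SimulationConfig()
        cfg.conditions[1].occupancy_multipliers["LTR"] = 0.0
        with pytest.raises(ValueError, match="multipliers"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.to_yaml(tmp_path / "c.yaml")
        back = d.SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestFragmentWeights:
    def test_all_multipliers_one_uniform_weights(self):
        cfg = uniform_config()
        syn = d.build_synthetic_genome(cfg)
        fm = d.GatcFragmentMap.from_genome(syn.genome)
        weights = d.assign_fragment_weights(fm, syn, cfg.conditions[0], cfg)
        np.testing.assert_allclose(weights["occupancy"], 1.0)
        np.testing.assert_allclose(weights["accessibility"], 1.0)

    def test_family_multiplier_applied_exactly(self):
        cfg = small_config()
        cfg.conditions = [
            d.ConditionSpec("control"),
            d.ConditionSpec("mut", occupancy_multipliers={"LTR": 0.25}),
        ]
        syn = d.build_synthetic_genome(cfg)
        fm = d.GatcFragmentMap.from_genome(syn.genome)
        wa = d.assign_fragment_weights(fm, syn, cfg.conditions[0], cfg)
        wb = d.assign_fragment_weights(fm, syn, cfg.conditions[1], cfg)
        ltr = wa["family_class"] == "LTR"
        assert ltr.any()
        ratio = wb.loc[ltr, "occupancy"] / wa.loc[ltr, "occupancy"]
        np.testing.assert_allclose(ratio, 0.25)  # exact in truth
        other = ~ltr
        np.testing.assert_allclose(
            wb.loc[other, "occupancy"], wa.loc[other, "occupancy"]
        )

    def test_gamma_zero_accessibility_constant(self):
        cfg = small_config(accessibility_exponent=0.0)
        syn = d.build_synthetic_genome(cfg)
        fm = d.GatcFragmentMap.from_genome(syn.genome)
        weights = d.assign_fragment_weights(fm, syn, cfg.conditions[0], cfg)
        np.testing.assert_allclose(weights["accessibility"], 1.0)

    def test_gamma_couples_accessibility_inversely(self):
        cfg = small_config(accessibility_exponent=0.5)
        syn = d.build_synthetic_genome(cfg)
        fm = d.GatcFragmentMap.from_genome(syn.genome)
        weights = d.assign_fragment_weights(fm, syn, cfg.conditions[0], cfg)
        np.testing.assert_allclose(
            weights["accessibility"],
            weights["occupancy"] ** -0.5,
            rtol=1e-12,
        )


class TestSimulateSample:
    def test_read_count_and_determinism(self):
        cfg = small_config()
        syn = d.build_synthetic_genome(cfg)
        fm = d.GatcFragmentMap.from_genome(syn.genome)
        weights = d.assign_fragment_weights(fm, syn, cfg.conditions[0], cfg)
        a1, t1 = d.simulate_sample(
            weights, "dam_fusion", 5000, np.random.default_rng(5), cfg
        )
        a2, t2 = d.simulate_sample(
            weights, "dam_fusion", 5000, np.random.default_rng(5), cfg
        )
        assert len(a1) == 5000
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_reads_stay_inside_fragments(self):
        cfg = small_config()
        syn = d.build_synthetic_genome(cfg)
        fm = d.GatcFragmentMap.from_genome(syn.genome)
        weights = d.assign_fragment_weights(fm, syn, cfg.conditions[0], cfg)
        aln, _ = d.simulate_sample(
            weights, "dam_only", 5000, np.random.default_rng(1), cfg
        )
        assert (aln["end"] > aln["start"]).all()
        for chrom, length in syn.genome.lengths.items():
            sub = aln[aln["target"] == chrom]
            assert (sub["end"] <= length).all() and (sub["start"] >= 0).all()

    def test_te_records_in_consensus_coordinates(self):
        cfg = small_config()
        syn = d.build_synthetic_genome(cfg)
        fm = d.GatcFragmentMap.from_genome(syn.genome)
        weights = d.assign_fragment_weights(fm, syn, cfg.conditions[0], cfg)
        _, te_aln = d.simulate_sample(
            weights, "dam_fusion", 5000, np.random.default_rng(2), cfg
        )
        assert len(te_aln) > 0
        lengths = syn.tes.lengths
        for te, group in te_aln.groupby("target"):
            assert (group["start"] >= 0).all()
            assert (group["end"] <= lengths[te]).all()

    def test_uniform_occupancy_fusion_matches_dam_only(self):
        """With flat weights the fusion/Dam read ratio per TE is ~1.

        Genome sized so each TE draws ~1000 reads, where the 0.2-log2 band
        is a 3-sigma bound on the binomial ratio noise."""
        cfg = uniform_config(reads_per_sample=50_000, genome_length=60_000)
        syn = d.build_synthetic_genome(cfg)
        fm = d.GatcFragmentMap.from_genome(syn.genome)
        weights = d.assign_fragment_weights(fm, syn, cfg.conditions[0], cfg)
        _, fus = d.simulate_sample(
            weights, "dam_fusion", 50_000, np.random.default_rng(3), cfg
        )
        _, dam = d.simulate_sample(
            weights, "dam_only", 50_000, np.random.default_rng(4), cfg
        )
        for te in syn.tes.names:
            nf = (fus["target"] == te).sum()
            nd = (dam["target"] == te).sum()
            assert nf > 0 and nd > 0
            assert abs(np.log2(nf / nd)) < 0.2

    def test_multicopy_families_draw_low_mapq(self):
        cfg = small_config()
        syn = d.build_synthetic_genome(cfg)
        fm = d.GatcFragmentMap.from_genome(syn.genome)
        weights = d.assign_fragment_weights(fm, syn, cfg.conditions[0], cfg)
        _, te_aln = d.simulate_sample(
            weights, "dam_fusion", 5000, np.random.default_rng(6), cfg
        )
        multi = te_aln[te_aln["target"].str.startswith(("LTR", "LINE", "DNA"))]
        frac_low = (multi["mapq"] <= cfg.multimap_mapq_max).mean()
        assert 0.6 < frac_low < 0.95  # configured fraction 0.8
        single = te_aln[te_aln["target"].str.startswith("other")]
        if len(single):
            assert (single["mapq"] == cfg.unique_mapq).all()


class TestTruth:
    def test_configured_ratio_appears_exactly_in_truth(self):
        cfg = d.SimulationConfig()
        truth = d.true_te_effects(cfg, "control", "ago2mut")
        ltr = truth[truth["family_class"] == "LTR"]
        np.testing.assert_allclose(ltr["true_delta_log2_occupancy"], -2.0)
        other = truth[truth["family_class"] != "LTR"]
        np.testing.assert_allclose(other["true_delta_log2_occupancy"], 0.0)
        # accessibility through the monotone map: gamma=0.5 -> +1 on LTR
        np.testing.assert_allclose(ltr["true_log2fc_accessibility"], 1.0)

    def test_fragment_truth_probabilities_normalized(self, small_dataset):
        truth = fragment_truth(small_dataset.weight_tables, small_dataset.config)
        for col in truth.columns:
            if col.startswith("p_"):
                assert truth[col].sum() == pytest.approx(1.0)
                assert (truth[col] >= 0).all()


class TestEmitDataset:
    def test_default_manifest_has_eight_samples(self, tmp_path):
        cfg = small_config()
        out = d.emit_dataset(cfg, tmp_path / "ds")
        mf = d.SampleManifest.from_yaml(out / "manifest.yaml")
        assert len(mf.frame) == 8  # 2 conditions x 2 replicates x 2 fusions
        assert set(mf.frame["condition"]) == {"control", "ago2mut"}

    def test_alignment_files_have_configured_read_count(self, small_emitted):
        from damidte.counting import read_sam

        aln = read_sam(small_emitted / "control_dam_only_rep1.genome.sam")
        assert len(aln) == 5000

    def test_emitted_files_deterministic(self, tmp_path):
        cfg = small_config(seed=11)
        a = d.emit_dataset(cfg, tmp_path / "a")
        b = d.emit_dataset(cfg, tmp_path / "b")
        for name in ("genome.fa", "te_consensus.fa",
                     "control_dam_fusion_rep1.genome.sam", "truth_te.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_truth_files_present_but_separate(self, small_emitted):
        assert (small_emitted / "truth_te.tsv").exists()
        assert (small_emitted / "truth_fragments.tsv").exists()
        mf = d.SampleManifest.from_yaml(small_emitted / "manifest.yaml")
        for p in mf.frame["genome_alignments"]:
            assert "truth" not in p
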