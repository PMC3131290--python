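"""Generator invariants: geometry, planted signal, truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nullchip as nc
from nullchip.config import ConfigError
from nullchip.simulate import _peak_kernel, to_raw_intensities


def offsets_by_promoter(design):
    """Strand-oriented probe start offsets relative to each promoter's TSS."""
    first_gene = design.genes.drop_duplicates("promoter_id").set_index("promoter_id")
    out = {}
    for pid, grp in design.probes.groupby("promoter_id"):
        tss = first_gene.loc[pid, "tss"]
        if first_gene.loc[pid, "strand"] == "+":
            off = grp["start"].to_numpy() - tss
        else:
            off = tss - grp["end"].to_numpy()
        out[pid] = np.sort(off)
    return out


class TestDesign:
    def test_offsets_within_span_and_gaps_in_range(self):
        cfg = nc.SimConfig(n_promoters=40, seed=7)
        design = nc.gen_design(cfg)
        up, down = cfg.promoter_span_bp
        lo, hi = cfg.probe_spacing_bp
        for off in offsets_by_promoter(design).values():
            assert off.min() >= -up
            assert off.max() + cfg.probe_length_bp <= down
            gaps = np.diff(off)
            assert ((gaps >= lo) & (gaps <= hi)).all()

    def test_no_bidirectional_means_one_gene_per_promoter(self):
        cfg = nc.SimConfig(n_promoters=30, bidirectional_fraction=0.0, seed=1)
        design = nc.gen_design(cfg)
        assert (design.genes.groupby("promoter_id").size() == 1).all()

    def test_bidirectional_fraction_links_two_genes(self):
        cfg = nc.SimConfig(n_promoters=40, bidirectional_fraction=0.25, seed=2)
        design = nc.gen_design(cfg)
        sizes = design.genes.groupby("promoter_id").size()
        assert (sizes == 2).sum() == 10
        assert (sizes == 1).sum() == 30

    def test_fixed_seed_gives_byte_identical_files(self, tmp_path):
        cfg = nc.SimConfig(n_promoters=100, seed=7)
        for run in ("a", "b"):
            d = nc.gen_design(cfg)
            nc.write_design(d, tmp_path / f"{run}.bed", tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_nonpositive_promoter_count_rejected(self):
        with pytest.raises(ConfigError):
            nc.SimConfig(n_promoters=0)


class TestChipArrays:
    def test_null_arrays_are_zero_mean_noise(self):
        cfg = nc.SimConfig(n_promoters=100, noise_sd=0.35, seed=3)
        design = nc.gen_design(cfg)
        _, ko, _ = nc.gen_chip_arrays(design, cfg)
        x = ko.to_numpy().ravel()
        assert abs(x.mean()) < 4 * 0.35 / np.sqrt(len(x))
        assert abs(x.std() - 0.35) < 0.01

    def test_unbound_study_plants_nothing(self):
        cfg = nc.SimConfig(n_promoters=50, bound_fraction=0.0, seed=4)
        design = nc.gen_design(cfg)
        wt, ko, truth = nc.gen_chip_arrays(design, cfg)
        assert truth.bound_promoters.empty
        # wild-type and null matrices come from the same noise law
        _, p = stats.ks_2samp(wt.to_numpy().ravel(), ko.to_numpy().ravel())
        assert p > 1e-4

    def test_noiseless_peak_matches_kernel_exactly(self):
        cfg = nc.SimConfig(n_promoters=20, bound_fraction=0.1, noise_sd=0.0,
                           peak_amplitude_log2=2.0, seed=5)
        design = nc.gen_design(cfg)
        wt, _, truth = nc.gen_chip_arrays(design, cfg)
        mids = design.midpoints()
        prom = design.probes.set_index("probe_id")["promoter_id"]
        expected = pd.Series(0.0, index=wt.index)
        for _, row in truth.bound_promoters.iterrows():
            sel = (prom == row["promoter_id"]).to_numpy()
            expected[sel] = _peak_kernel(mids[sel].to_numpy() - row["site_pos"],
                                         2.0, cfg.peak_halfwidth_bp, "triangular")
        for col in wt.columns:
            np.testing.assert_allclose(wt[col].to_numpy(), expected.to_numpy(),
                                       atol=1e-12)
        # the planted maximum expected value equals the amplitude at the site
        assert np.isclose(_peak_kernel(np.array([0.0]), 2.0, 750.0, "triangular")[0], 2.0)

    def test_truth_ids_resolve_and_round_trip(self, tmp_path):
        cfg = nc.SimConfig(n_promoters=60, bound_fraction=0.2, seed=6)
        design = nc.gen_design(cfg)
        _, _, truth = nc.gen_chip_arrays(design, cfg)
        assert set(truth.bound_promoters["promoter_id"]) <= set(design.promoter_ids)
        truth.write(tmp_path / "truth")
        back = nc.SyntheticTruth.read(tmp_path / "truth")
        pd.testing.assert_frame_equal(
            back.bound_promoters, truth.bound_promoters, check_exact=False)
        assert back.seed == truth.seed

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ConfigError):
            nc.SimConfig(peak_amplitude_log2=-1.0)


class TestExpression:
    def test_null_study_has_uniform_t_test_pvalues(self):
        cfg = nc.SimConfig(n_genes=5000, de_fraction=0.0, litter_sd=0.0, seed=8)
        study, truth = nc.gen_expression(cfg)
        assert truth.de_genes.empty
        wt = study.expr.loc[:, (study.meta["genotype"] == "wt").to_numpy()]
        mut = study.expr.loc[:, (study.meta["genotype"] == "mut").to_numpy()]
        _, p = stats.ttest_ind(wt, mut, axis=1)
        d, ks_p = stats.kstest(p, "uniform")
        assert ks_p > 0.01

    def test_noiseless_effect_recovered_exactly(self):
        cfg = nc.SimConfig(n_genes=10, de_fraction=0.1, effect_size_log2=1.0,
                           expr_noise_sd=1e-12, litter_sd=0.0, seed=9)
        study, truth = nc.gen_expression(cfg)
        res = nc.fit_de(study, moderate=False)
        gene = truth.de_genes.iloc[0]
        assert np.isclose(res.loc[gene["gene_id"], "effect"], gene["effect"], atol=1e-6)

    def test_single_genotype_litter_warns(self):
        with pytest.warns(UserWarning, match="single genotype"):
            cfg = nc.SimConfig(n_genes=50, litters=((2, 2), (3, 0)), seed=10)
            nc.gen_expression(cfg)

    def test_metadata_matches_litter_composition(self):
        cfg = nc.SimConfig(n_genes=20, seed=11)
        study, _ = nc.gen_expression(cfg)
        counts = study.meta.groupby(["litter", "genotype"]).size()
        assert counts[("L1", "wt")] == 2 and counts[("L3", "wt")] == 1
        assert study.meta["genotype"].value_counts()["mut"] == 6

    def test_raw_wrapper_round_trips_through_preprocessing(self):
        cfg = nc.SimConfig(n_genes=400, de_fraction=0.0, seed=12)
        study, _ = nc.gen_expression(cfg)
        raw, controls = to_raw_intensities(study, cfg)
        corrected = nc.background_correct(raw, controls)
        back = nc.vst(corrected)
        # transformed values should track the original log2-scale signal
        r = np.corrcoef(back.to_numpy().ravel(), study.expr.to_numpy().ravel())[0, 1]
        assert r > 0.95


class TestSequences:
    def test_forced_prevalence_separates_sets(self):
        cfg = nc.SimConfig(motif_prevalence_target=1.0, motif_prevalence_background=0.0,
                           sequence_length_bp=300, seed=13)
        targets = [f"T{i}" for i in range(20)]
        background = [f"B{i}" for i in range(20)]
        seqs, truth = nc.gen_promoter_sequences(cfg, targets, background)
        hits = nc.scan_motif(cfg.planted_motif, seqs)
        assert all(hits[t] >= 1 for t in targets)
        assert all(hits[b] == 0 for b in background)
        assert set(truth.motif_positions["seq_id"]) == set(targets)

    def test_plant_positions_recorded_correctly(self):
        cfg = nc.SimConfig(motif_prevalence_target=1.0, motif_prevalence_background=0.0,
                           sequence_length_bp=200, seed=14)
        seqs, truth = nc.gen_promoter_sequences(cfg, ["T0", "T1"], [])
        for _, row in truth.motif_positions.iterrows():
            seq = seqs[row["seq_id"]]
            assert seq[row["position"]:row["position"] + 8] == row["variant"]

    def test_motif_longer_than_sequence_rejected(self):
        cfg = nc.SimConfig(sequence_length_bp=200, seed=15)
        cfg.sequence_length_bp = 4
        with pytest.raises(ConfigError):
            nc.gen_promoter_sequences(cfg, ["T0"], [])

    def test_gc_content_tracks_configuration(self):
        cfg = nc.SimConfig(gc_fraction=0.6, sequence_length_bp=2000,
                           motif_prevalence_target=0.0,
                           motif_prevalence_background=0.0, seed=16)
        seqs, _ = nc.gen_promoter_sequences(cfg, [f"S{i}" for i in range(10)], [])
        gc = np.mean([(s.count("G") + s.count("C")) / len(s) for s in seqs.values()])
        assert abs(gc - 0.6) < 0.02
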