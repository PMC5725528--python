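"""The synthetic-data generator: determinism and planted structure."""

import filecmp

import numpy as np
import pytest

from tailseg.coverage import project_to_transcript
from tailseg.mirna import find_seed_sites
from tailseg.simulate import (SimulationConfig, simulate_annotation,
                              simulate_coverage_pair, simulate_end_peaks,
                              simulate_region_counts, write_dataset)


class TestAnnotation:
    def test_identical_seeds_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(n_transcripts=10, seed=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_dataset(d1, cfg)
        p2 = write_dataset(d2, cfg)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_cleavage_prob_zero_plants_nothing(self):
        cfg = SimulationConfig(n_transcripts=15, seed=2, cleavage_prob=0.0)
        _, _, truth = simulate_annotation(cfg)
        assert not truth.table["cleaved"].any()
        assert (truth.table["cleavage_tx"] == -1).all()

    def test_majority_of_cleavages_near_stop_codon(self):
        cfg = SimulationConfig(n_transcripts=1000, seed=4, cleavage_prob=1.0)
        _, _, truth = simulate_annotation(cfg)
        t = truth.table
        off = t["cleavage_tx"] - t["cds_end_tx"]
        assert (off > 0).all()
        assert (off <= 500).mean() >= 0.6

    def test_cleavage_lies_in_utr_with_tail_margin(self, small_sim):
        _, _, _, truth = small_sim
        t = truth.table[truth.table["cleaved"]]
        assert (t["cleavage_tx"] > t["cds_end_tx"]).all()
        assert (t["length_tx"] - t["cleavage_tx"] >= 100).all()

    def test_planted_seed_sites_are_findable_and_unique(self, small_sim):
        cfg, _, seqs, truth = small_sim
        for row in truth.table.itertuples(index=False):
            hits = find_seed_sites(seqs[row.transcript_id], cfg.mirna)
            planted = {p for p in (row.body_seed_pos, row.tail_seed_pos)
                       if p >= 0}
            assert set(hits) == planted

    def test_both_strands_represented(self, small_sim):
        _, models, _, _ = small_sim
        assert {m.strand for m in models} == {"+", "-"}


class TestCoveragePair:
    def test_noiseless_step_at_true_cleavage(self):
        cfg = SimulationConfig(n_transcripts=4, seed=6, noise_sd=0.0,
                               cleavage_prob=1.0)
        models, _, truth = simulate_annotation(cfg)
        ctrl, trt = simulate_coverage_pair(models, truth, cfg, "tex")
        tx = models[0]
        c = int(truth.row(tx.transcript_id)["cleavage_tx"])
        ratio = (project_to_transcript(trt, tx)
                 / project_to_transcript(ctrl, tx))
        np.testing.assert_allclose(ratio[:c], 1.0, rtol=1e-12)
        np.testing.assert_allclose(ratio[c:], 0.66, rtol=1e-12)

    def test_tail_factor_one_equalizes_tracks(self):
        cfg = SimulationConfig(n_transcripts=3, seed=6, noise_sd=0.0,
                               cleavage_prob=1.0,
                               tail_factors={"tex": 1.0})
        models, _, truth = simulate_annotation(cfg)
        ctrl, trt = simulate_coverage_pair(models, truth, cfg, "tex")
        for tx in models:
            np.testing.assert_allclose(project_to_transcript(trt, tx),
                                       project_to_transcript(ctrl, tx))

    def test_tail_body_ratio_recovers_planted_factor(self):
        cfg = SimulationConfig(n_transcripts=60, seed=8, cleavage_prob=1.0)
        models, _, truth = simulate_annotation(cfg)
        ctrl, trt = simulate_coverage_pair(models, truth, cfg, "tex")
        ratios = []
        for tx in models:
            c = int(truth.row(tx.transcript_id)["cleavage_tx"])
            pc, pt = (project_to_transcript(cov, tx) for cov in (ctrl, trt))
            r_t = pt[c:].mean() / pt[:c].mean()
            r_c = pc[c:].mean() / pc[:c].mean()
            ratios.append(r_t / r_c)
        se = np.std(np.log(ratios)) / np.sqrt(len(ratios))
        assert np.mean(np.log(ratios)) == pytest.approx(np.log(0.66),
                                                        abs=2 * se + 0.01)

    def test_unknown_treatment_rejected(self, small_sim):
        cfg, models, _, truth = small_sim
        with pytest.raises(ValueError, match="unknown treatment"):
            simulate_coverage_pair(models, truth, cfg, "mock")


class TestEndPeaks:
    def test_uncleaved_transcripts_get_single_distal_peak(self):
        cfg = SimulationConfig(n_transcripts=10, seed=9, cleavage_prob=0.0)
        models, _, truth = simulate_annotation(cfg)
        before, after = simulate_end_peaks(models, truth, cfg)
        assert (before.groupby("transcript_id").size() == 1).all()
        assert (after.groupby("transcript_id").size() == 1).all()

    def test_noiseless_distal_ratio_change_is_exact(self):
        cfg = SimulationConfig(n_transcripts=10, seed=9, cleavage_prob=1.0,
                               peak_jitter_sd=0.0, peak_height_log_sd=0.0)
        models, _, truth = simulate_annotation(cfg)
        before, after = simulate_end_peaks(models, truth, cfg)
        for tid, sub_b in before.groupby("transcript_id"):
            sub_a = after[after["transcript_id"] == tid]
            rb = (sub_b["height"].iloc[sub_b["pos"].argmax()]
                  / sub_b["height"].iloc[sub_b["pos"].argmin()])
            ra = (sub_a["height"].iloc[sub_a["pos"].argmax()]
                  / sub_a["height"].iloc[sub_a["pos"].argmin()])
            assert ra / rb == pytest.approx(0.66, rel=1e-12)

    def test_proximal_peaks_near_true_cleavage(self):
        cfg = SimulationConfig(n_transcripts=500, seed=10, cleavage_prob=1.0)
        models, _, truth = simulate_annotation(cfg)
        before, _ = simulate_end_peaks(models, truth, cfg)
        prox = before.groupby("transcript_id")["pos"].min()
        true_c = truth.table.set_index("transcript_id")["cleavage_tx"]
        dist = (prox - true_c.loc[prox.index]).abs()
        assert (dist <= 100).mean() >= 0.8


class TestRegionCounts:
    def test_repression_factor_one_gives_identical_expectations(self):
        cfg = SimulationConfig(n_transcripts=10, seed=11, dispersion=0.0,
                               repression_factor=1.0)
        models, _, truth = simulate_annotation(cfg)
        counts, _ = simulate_region_counts(models, truth, cfg)
        ctrl = counts[[c for c in counts if c.startswith("ctrl")]].mean(axis=1)
        mir = counts[[c for c in counts if c.startswith("mir")]].mean(axis=1)
        np.testing.assert_allclose(ctrl, mir)

    def test_noiseless_body_only_repression(self):
        cfg = SimulationConfig(n_transcripts=40, seed=12, dispersion=0.0,
                               repression_factor=0.5, cleavage_prob=1.0,
                               body_seed_frac=1.0, tail_seed_frac=0.0)
        models, _, truth = simulate_annotation(cfg)
        counts, regions = simulate_region_counts(models, truth, cfg)
        meta = regions.set_index("region_id")
        for rid in counts.index:
            ratio = (counts.loc[rid, "mir_1"] / counts.loc[rid, "ctrl_1"])
            role = meta.loc[rid, "role"]
            if role == "body":
                assert ratio == pytest.approx(0.5, abs=0.02)
            elif role == "tail":
                assert ratio == pytest.approx(1.0, abs=0.02)

    def test_invalid_repression_factor_rejected(self):
        with pytest.raises(ValueError, match="repression"):
            SimulationConfig(repression_factor=0.0)
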