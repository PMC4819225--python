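"""Synthetic-study generator: determinism, geometry, signal models."""

from __future__ import annotations

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from gfap4c.config import SyntheticConfig
from gfap4c.e4c import compute_probe_ratios
from gfap4c.regions import GenomicInterval
from gfap4c.synthetic import (
    generate_bundle,
    simulate_e4c_arrays,
    simulate_expression,
    simulate_fish,
    simulate_genome,
)
from conftest import small_config


class TestSimulateGenome:
    def test_empty_annotation_valid_sizes(self):
        sizes, genes = simulate_genome(small_config(n_genes=0,
            n_planted_assoc_genes=0, n_planted_expr_genes=0,
            n_planted_overlap=0, n_assoc_other=0, n_assoc_shared=0,
            n_expr_lifminus=0, n_expr_shared=0))
        assert genes == []
        assert set(sizes) == {"chr1", "chr2", "chr3"}

    def test_same_seed_identical_outputs(self):
        cfg = small_config()
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_genes_within_bounds_and_non_overlapping(self):
        cfg = small_config(n_genes=30)
        sizes, genes = simulate_genome(cfg)
        assert len(genes) == 30
        by_chrom: dict[str, list] = {}
        for g in genes:
            iv = g.interval
            assert 0 <= iv.start < iv.end <= sizes[iv.chrom]
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_genome(
                small_config(chrom_length=20_000, n_genes=30,
                             gene_length_bp=(5_000, 10_000))
            )

    def test_strand_aware_tss(self):
        _, genes = simulate_genome(small_config())
        for g in genes:
            if g.strand == "+":
                assert g.tss == g.interval.start
            else:
                assert g.tss == g.interval.end


@pytest.fixture(scope="module")
def probes():
    return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(6)],
                "chrom": ["chr1"] * 6,
                "start": [100, 10_000, 20_000, 30_000, 40_000, 50_000],
                "end": [160, 10_060, 20_060, 30_060, 40_060, 50_060],
            }
        )

class TestE4CArrays:
    def test_noiseless_ratios_exact(self, probes):
        cfg = small_config(noise_sd=0.0, interaction_signal_log2=3.0)
        planted = {"LIF+": [GenomicInterval("chr1", 9_000, 21_000)]}
        signals, truth = simulate_e4c_arrays(probes, planted, cfg)
        ratios = compute_probe_ratios(
            signals[signals["condition"] == "LIF+"], pseudocount=0.0
        )
        planted_ids = set(
            truth.loc[truth["planted"] & (truth["condition"] == "LIF+"), "probe_id"]
        )
        assert planted_ids == {"p1", "p2"}
        for _, row in ratios.iterrows():
            expected = 3.0 if row["probe_id"] in planted_ids else 0.0
            assert row["log2_ratio"] == expected

    def test_replicates_distinct_but_correlated(self, probes):
        cfg = small_config(noise_sd=0.5)
        planted = {"LIF+": [GenomicInterval("chr1", 0, 60_060)]}
        signals, _ = simulate_e4c_arrays(probes, planted, cfg)
        sub = signals[signals["condition"] == "LIF+"]
        r1 = sub[sub["replicate"] == 1]["e4c"].to_numpy()
        r2 = sub[sub["replicate"] == 2]["e4c"].to_numpy()
        assert not np.array_equal(r1, r2)
        # all probes planted: both replicates fluctuate around the same mean
        assert abs(np.log2(r1).mean() - np.log2(r2).mean()) < 1.0

    def test_deterministic_given_seed(self, probes):
        cfg = small_config(noise_sd=0.5)
        planted = {"NPC": [GenomicInterval("chr1", 0, 1_000)]}
        s1, _ = simulate_e4c_arrays(probes, planted, cfg)
        s2, _ = simulate_e4c_arrays(probes, planted, cfg)
        pd.testing.assert_frame_equal(s1, s2)


class TestExpression:
    def test_noiseless_linear_model(self):
        cfg = small_config(expr_noise_sd=0.0, gain=10.0, background_floor=0.0)
        _, genes = simulate_genome(cfg)
        intensities, spikes, copies = simulate_expression(
            genes, set(), set(), cfg
        )
        merged = intensities.merge(copies, on="gene_id", suffixes=("_i", "_c"))
        for cond in ("NPC", "LIF+", "LIF-"):
            assert np.allclose(
                merged[f"{cond}_i"], 10.0 * merged[f"{cond}_c"]
            )

    def test_zero_dose_spike_sits_at_background_floor(self):
        cfg = small_config(
            expr_noise_sd=0.0, spike_copies=(0.0, 1.0, 10.0), background_floor=7.0
        )
        _, genes = simulate_genome(cfg)
        _, spikes, _ = simulate_expression(genes, set(), set(), cfg)
        zero = spikes[spikes["known_copies_per_cell"] == 0.0]
        assert (zero["intensity"] == 7.0).all()

    def test_planted_fold_in_true_copies(self):
        cfg = small_config()
        _, genes = simulate_genome(cfg)
        planted = {genes[0].gene_id, genes[5].gene_id}
        _, _, copies = simulate_expression(genes, planted, set(), cfg)
        copies = copies.set_index("gene_id")
        for gid in planted:
            assert copies.loc[gid, "LIF+"] / copies.loc[gid, "NPC"] == pytest.approx(
                cfg.expr_fold_planted
            )
            assert copies.loc[gid, "LIF-"] == pytest.approx(copies.loc[gid, "NPC"])

    def test_empty_or_degenerate_spikes_raise(self):
        cfg_empty = small_config(spike_copies=())
        cfg_one = small_config(spike_copies=(10.0, 10.0))
        _, genes = simulate_genome(cfg_empty)
        with pytest.raises(ValueError):
            simulate_expression(genes, set(), set(), cfg_empty)
        with pytest.raises(ValueError):
            simulate_expression(genes, set(), set(), cfg_one)


class TestFish:
    def test_all_signals_inside_nucleus(self):
        cfg = small_config(n_nuclei=40)
        ds = simulate_fish(cfg, [("Gfap", "Ogn")])
        merged = ds.signals.merge(ds.nuclei, on=["nucleus_id", "condition"])
        r = np.sqrt(
            merged["x_um"] ** 2 + merged["y_um"] ** 2 + merged["z_um"] ** 2
        )
        assert (r <= merged["diameter_um"] / 2 + 1e-9).all()

    def test_forced_association_always_called(self):
        from gfap4c.fish import association_frequencies

        cfg = small_config(n_nuclei=60)
        ds = simulate_fish(
            cfg, [("Gfap", "Ogn")], assoc_fraction={"LIF+": 1.0},
            conditions=("LIF+",),
        )
        freq, _ = association_frequencies(ds.signals, "Gfap", "Ogn")
        assert freq.loc[0, "fraction"] == 1.0

    def test_chance_proximity_matches_monte_carlo_oracle(self):
        from gfap4c.fish import association_frequencies

        cfg = small_config(n_nuclei=2000, nucleus_diameter=10.0)
        ds = simulate_fish(
            cfg, [("A", "B")], assoc_fraction={"flat": 0.0},
            conditions=("flat",),
        )
        freq, _ = association_frequencies(ds.signals, "A", "B")
        observed = freq.loc[0, "fraction"]

        # oracle: min over the 2x2 allele pairs of uniform points in a sphere
        rng = np.random.default_rng(99)
        n = 250_000
        pts = rng.normal(size=(n, 4, 3))
        pts /= np.linalg.norm(pts, axis=2, keepdims=True)
        pts *= 5.0 * rng.random((n, 4, 1)) ** (1 / 3)
        d = np.linalg.norm(pts[:, :2, None, :] - pts[:, None, 2:, :], axis=3)
        p_chance = float((d.min(axis=(1, 2)) <= 0.5).mean())
        se = np.sqrt(p_chance * (1 - p_chance) / cfg.n_nuclei)
        assert abs(observed - p_chance) < 3 * se + 3e-3

    def test_invalid_fraction_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            simulate_fish(cfg, [("A", "B")], assoc_fraction={"NPC": 1.5},
                          conditions=("NPC",))


class TestBundle:
    def test_deterministic(self, small_bundle):
        again = generate_bundle(small_config())
        pd.testing.assert_frame_equal(small_bundle.e4c_signals, again.e4c_signals)
        pd.testing.assert_frame_equal(
            small_bundle.expression_intensities, again.expression_intensities
        )
        assert small_bundle.truth_candidates == again.truth_candidates

    def test_truth_candidates_planted_in_both_sets(self, small_bundle):
        b = small_bundle
        assert b.truth_candidates <= b.planted_assoc["LIF+"]
        assert b.truth_candidates <= b.planted_expr["LIF+"]
        assert not b.truth_candidates & b.planted_assoc["NPC"]
        assert not b.truth_candidates & b.planted_expr["LIF-"]
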