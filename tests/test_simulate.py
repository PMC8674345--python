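"""Synthetic-data generator: planted parameters, determinism, and round trips."""

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cistromekit.annotation import read_gene_table
from cistromekit.intervals import intersect_partition, read_bed
from cistromekit.signal import read_bedgraph
from cistromekit.simulate import (
    SimConfig,
    SimConfigError,
    bump_track,
    generate_dataset,
    load_manifest_config,
    simulate_cistromes,
    simulate_expression,
    simulate_genome,
    write_dataset,
)

SMALL = dict(
    n_chroms=2,
    chrom_length=4_000_000,
    n_genes=80,
    n_peaks_a=120,
    n_peaks_b=90,
    n_samples=3,
    signature_size=5,
)


class TestSimulateGenome:
    def test_zero_genes_gives_empty_table(self):
        cfg = SimConfig(seed=0, **{**SMALL, "n_genes": 0})
        assert len(simulate_genome(cfg)) == 0

    def test_same_seed_reproduces_table(self):
        cfg = SimConfig(seed=1, **SMALL)
        pd.testing.assert_frame_equal(simulate_genome(cfg), simulate_genome(cfg))

    def test_tss_spacing_and_margins_respected(self):
        cfg = SimConfig(seed=2, **SMALL)
        genes = simulate_genome(cfg)
        for _, grp in genes.groupby("chrom"):
            tss = grp["tss"].to_numpy()
            assert np.all(np.diff(tss) >= cfg.tss_spacing)
            assert tss.min() >= cfg.genome_margin
            assert tss.max() <= cfg.chrom_length - cfg.genome_margin

    def test_per_chromosome_counts_near_even_split(self):
        cfg = SimConfig(seed=3, n_chroms=2, chrom_length=10_000_000, n_genes=200,
                        n_peaks_a=100, n_peaks_b=50, signature_size=1)
        genes = simulate_genome(cfg)
        counts = genes["chrom"].value_counts()
        # binomial(200, 1/2): 7 sigma ~ 50
        assert all(abs(c - 100) <= 50 for c in counts)
        # regenerating with the recorded seed reproduces the allocation
        assert counts.equals(simulate_genome(cfg)["chrom"].value_counts())

    def test_infeasible_spacing_names_constraint(self):
        cfg = SimConfig(seed=0, n_chroms=1, chrom_length=300_000, n_genes=50,
                        n_peaks_a=10, n_peaks_b=5, signature_size=1)
        with pytest.raises(SimConfigError, match="spacing"):
            simulate_genome(cfg)


class TestSimulateCistromes:
    def test_zero_cobinding_yields_no_common_b(self):
        cfg = SimConfig(seed=4, co_binding_fraction=0.0, **SMALL)
        cz = simulate_cistromes(cfg, simulate_genome(cfg))
        part = intersect_partition(cz.a_vehicle, cz.b_vehicle)
        assert len(part.b_common) == 0

    def test_full_cobinding_all_common(self):
        cfg = SimConfig(
            seed=5, co_binding_fraction=1.0,
            **{**SMALL, "n_peaks_b": 10, "signature_size": 1},
        )
        cz = simulate_cistromes(cfg, simulate_genome(cfg))
        part = intersect_partition(cz.a_vehicle, cz.b_vehicle)
        assert len(part.b_common) == 10

    def test_quarter_cobinding_exact_count_at_scale(self):
        cfg = SimConfig(
            seed=6,
            n_chroms=4,
            chrom_length=10_000_000,
            n_genes=400,
            n_peaks_a=700,
            n_peaks_b=2000,
            co_binding_fraction=0.25,
            signature_size=10,
        )
        cz = simulate_cistromes(cfg, simulate_genome(cfg))
        part = intersect_partition(cz.a_vehicle, cz.b_vehicle)
        assert len(part.b_common) == 500  # round(0.25 * 2000), by construction

    def test_treated_intensity_scaled_exactly_by_delta(self):
        cfg = SimConfig(seed=7, **SMALL)
        cz = simulate_cistromes(cfg, simulate_genome(cfg))
        vehicle = {iv.name: iv.score for iv in cz.b_vehicle}
        shared = [iv for iv in cz.b_treated if not iv.name.startswith("bg_")]
        assert shared  # some peaks persist under the default loss fraction
        ratios = [iv.score / vehicle[iv.name] for iv in shared]
        assert np.allclose(ratios, cfg.treated_intensity_scale, rtol=1e-12)

    def test_treated_counts_follow_loss_and_gain_fractions(self):
        cfg = SimConfig(seed=8, **SMALL)
        cz = simulate_cistromes(cfg, simulate_genome(cfg))
        n_b = cfg.n_peaks_b
        expected = n_b - round(cfg.loss_fraction * n_b) + round(cfg.gain_fraction * n_b)
        assert len(cz.b_treated) == expected


class TestTracks:
    def test_no_peaks_constant_background(self):
        track = bump_track([], {"chr1": 10_000}, background=0.7, resolution=10)
        s, e, v = track.runs["chr1"]
        assert len(v) == 1 and v[0] == 0.7 and e[-1] == 10_000

    def test_amplitude_at_center(self):
        track = bump_track([("chr1", 5_000, 400, 10.0)], {"chr1": 10_000}, 0.0, 10)
        assert track.value_at("chr1", 5_000) == pytest.approx(10.0)

    def test_gaussian_closed_form_at_quarter_width(self):
        # width 400 -> SD 100; at center +/- 100: 1 + 10*exp(-0.5)
        track = bump_track([("chr1", 5_000, 400, 10.0)], {"chr1": 10_000}, 1.0, 10)
        expected = 1.0 + 10.0 * math.exp(-0.5)
        assert track.value_at("chr1", 5_100) == pytest.approx(expected, rel=1e-9)
        assert track.value_at("chr1", 4_900) == pytest.approx(expected, rel=1e-9)


class TestSimulateExpression:
    def test_zero_effects_zero_noise_all_zero(self):
        cfg = SimConfig(
            seed=9, expr_effect_a=0.0, expr_effect_b=0.0, expr_noise_sd=0.0, **SMALL
        )
        genes = simulate_genome(cfg)
        cz = simulate_cistromes(cfg, genes)
        fc, _, _ = simulate_expression(genes, cz.gene_truth, cfg)
        assert (fc["log2fc"] == 0.0).all()

    def test_zero_noise_class_means_equal_planted_effects(self):
        cfg = SimConfig(seed=10, expr_noise_sd=0.0, **SMALL)
        genes = simulate_genome(cfg)
        cz = simulate_cistromes(cfg, genes)
        fc, _, _ = simulate_expression(genes, cz.gene_truth, cfg)
        merged = fc.merge(cz.gene_truth, on="gene_id")
        for cls, expect in [
            ("A_only", cfg.expr_effect_a),
            ("common", cfg.expr_effect_a),
            ("B_only", -cfg.expr_effect_b),
            ("none", 0.0),
        ]:
            sub = merged.loc[merged["true_class"] == cls, "log2fc"]
            if len(sub):
                assert np.allclose(sub, expect)

    def test_b_only_class_mean_within_analytic_se_band(self, default_dataset):
        cfg = SimConfig(seed=11, expr_noise_sd=0.2)
        genes = simulate_genome(cfg)
        cz = simulate_cistromes(cfg, genes)
        fc, _, _ = simulate_expression(genes, cz.gene_truth, cfg)
        merged = fc.merge(cz.gene_truth, on="gene_id")
        b_only = merged.loc[merged["true_class"] == "B_only", "log2fc"]
        se = cfg.expr_noise_sd / math.sqrt(len(b_only))
        assert abs(b_only.mean() - (-cfg.expr_effect_b)) <= 3 * se

    def test_signature_is_b_only_genes_and_size_enforced(self):
        cfg = SimConfig(seed=12, **SMALL)
        genes = simulate_genome(cfg)
        cz = simulate_cistromes(cfg, genes)
        _, _, sig = simulate_expression(genes, cz.gene_truth, cfg)
        truth = cz.gene_truth.set_index("gene_id")
        assert len(sig) == cfg.signature_size
        assert all(truth.loc[g, "true_class"] == "B_only" for g in sig)
        too_big = SimConfig(seed=12, **{**SMALL, "signature_size": 10_000})
        with pytest.raises(SimConfigError, match="signature_size"):
            simulate_expression(genes, cz.gene_truth, too_big)


@pytest.fixture(scope="module")
def small_written(tmp_path_factory):
    cfg = SimConfig(seed=13, **SMALL)
    ds = generate_dataset(cfg)
    outdir = tmp_path_factory.mktemp("small_ds")
    manifest = write_dataset(ds, outdir)
    return cfg, ds, outdir, manifest


class TestWriteDataset:
    def test_bed_roundtrip_matches_in_memory_objects(self, small_written):
        _, ds, outdir, _ = small_written
        back = read_bed(outdir / "peaks" / "b_vehicle.bed")
        assert [iv.key() for iv in back] == [
            iv.key() for iv in ds.cistromes.b_vehicle
        ]
        # BED6 convention: score = intensity * 1000, rounded
        for got, orig in zip(back, ds.cistromes.b_vehicle):
            assert got.score == round(orig.score * 1000)

    def test_bed_records_sorted_and_valid(self, small_written):
        from cistromekit.intervals import sort_and_validate

        _, _, outdir, _ = small_written
        for bed in (outdir / "peaks").glob("*.bed"):
            ps = read_bed(bed)
            assert sort_and_validate(ps).intervals == ps.intervals

    def test_track_and_tables_roundtrip(self, small_written):
        _, ds, outdir, _ = small_written
        assert read_bedgraph(outdir / "tracks" / "ac_vehicle.bedgraph") == ds.tracks["ac_vehicle"]
        pd.testing.assert_frame_equal(read_gene_table(outdir / "genes.tsv"), ds.genes)
        sig = (outdir / "signature.txt").read_text().split()
        assert sig == ds.signature

    def test_manifest_seed_replay_reproduces_identical_files(
        self, small_written, tmp_path
    ):
        _, _, outdir, manifest = small_written
        cfg2 = load_manifest_config(outdir / "manifest.json")
        ds2 = generate_dataset(cfg2)
        manifest2 = write_dataset(ds2, tmp_path / "replay")
        assert manifest2["files"] == manifest["files"]
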