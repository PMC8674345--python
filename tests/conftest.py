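"""Shared fixtures: random-interval helpers and a session-scoped synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cistromekit.intervals import GenomicInterval, PeakSet
from cistromekit.pipeline import PipelineConfig, run_pipeline
from cistromekit.simulate import SimConfig, generate_dataset, write_dataset


def random_peaks(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    max_pos: int = 1_000_000,
    max_len: int = 5_000,
    label: str = "peaks",
) -> PeakSet:
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length, f"{label}_{i}"))
    return PeakSet(ivs, label=label)


def brute_force_overlaps(a: PeakSet, b: PeakSet) -> list[bool]:
    """O(n^2) all-pairs oracle: does each a interval overlap any b interval."""
    return [any(iv.overlaps(other) for other in b) for iv in a]


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset (the package's study conditions), seed 1."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def dataset_dir(default_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("dataset")
    write_dataset(default_dataset, outdir)
    return outdir


def pipeline_config_for(dataset_dir, outdir, seed: int = 7) -> PipelineConfig:
    return PipelineConfig(
        peaks_a=str(dataset_dir / "peaks" / "a_vehicle.bed"),
        peaks_b=str(dataset_dir / "peaks" / "b_vehicle.bed"),
        peaks_b_treated=str(dataset_dir / "peaks" / "b_treated.bed"),
        se_peaks=str(dataset_dir / "peaks" / "ac_vehicle.bed"),
        track_ac=str(dataset_dir / "tracks" / "ac_vehicle.bedgraph"),
        track_ac_treated=str(dataset_dir / "tracks" / "ac_treated.bedgraph"),
        genes=str(dataset_dir / "genes.tsv"),
        fold_changes=str(dataset_dir / "expression" / "fold_changes.tsv"),
        expression_matrix=str(dataset_dir / "expression" / "matrix.tsv"),
        signature=str(dataset_dir / "signature.txt"),
        outdir=str(outdir),
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline_summary(dataset_dir, tmp_path_factory):
    """One full pipeline run on the default synthetic dataset."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    summary = run_pipeline(pipeline_config_for(dataset_dir, outdir))
    return summary, outdir
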