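"""Configuration-driven orchestration of the full analysis over a dataset.

Stages run in a fixed order — validation, peak partitioning, condition
dynamics, gene occupancy classes, resampling enrichment, regulatory-potential
association, super-enhancer calling and fold change, signal pileups, and
signature scoring — each writing a self-describing TSV plus a JSON summary of
headline numbers and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, regpotential, signal, stats, superenhancer
from .intervals import PeakSet, intersect_partition, classify_dynamics, read_bed

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cistromekit.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    Peak sets A and B play the roles of the condition-stable and the
    treatment-dynamic factor respectively; the acetylation-like track drives
    super-enhancer calling and pileups.
    """

    peaks_a: str
    peaks_b: str
    peaks_b_treated: str
    se_peaks: str
    track_ac: str
    track_ac_treated: str
    genes: str
    fold_changes: str
    expression_matrix: str
    signature: str
    outdir: str
    occupancy_window_kb: float = 10.0
    enrichment_window_kb: float = 20.0
    rp_half_window: int = 100_000
    stitch_distance: int = 12_500
    n_iter: int = 1000
    seed: int = 0
    fc_up: float = 0.585  # log2(1.5)
    fc_down: float = -0.585
    fc_static: float = 0.2
    se_pseudocount: float = 1.0
    profile_flank: int = 2000
    profile_bin: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        return {
            name: getattr(self, name)
            for name in (
                "peaks_a",
                "peaks_b",
                "peaks_b_treated",
                "se_peaks",
                "track_ac",
                "track_ac_treated",
                "genes",
                "fold_changes",
                "expression_matrix",
                "signature",
            )
        }

    def validate(self) -> None:
        if self.seed is None:
            raise PipelineError("seed is mandatory (resampling stages)")
        for name, p in self.input_paths().items():
            if not Path(p).is_file():
                raise PipelineError(f"stage validation: missing input {name}: {p}")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, params: dict) -> None:
    """TSV with header comments recording stage parameters."""
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the summary dict written to summary.json."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("load")
        peaks_a = read_bed(config.peaks_a, label="A")
        peaks_b = read_bed(config.peaks_b, label="B")
        peaks_bt = read_bed(config.peaks_b_treated, label="B_treated")
        se_peaks = read_bed(config.se_peaks, label="enhancer")
        track_ac = signal.read_bedgraph(config.track_ac)
        track_ac_t = signal.read_bedgraph(config.track_ac_treated)
        genes = annotation.read_gene_table(config.genes)
        fc = pd.read_csv(config.fold_changes, sep="\t", dtype={"gene_id": str})
        expr = pd.read_csv(
            config.expression_matrix, sep="\t", index_col="gene_id"
        )
        signature = [
            line.strip()
            for line in Path(config.signature).read_text().splitlines()
            if line.strip()
        ]
    except Exception as exc:
        raise PipelineError(f"stage load: {exc}") from exc

    # --- partition (shared vs factor-specific sites) ------------------------
    try:
        _stage("partition")
        part = intersect_partition(peaks_a, peaks_b)
        common_b_fraction = len(part.b_common) / len(peaks_b) if len(peaks_b) else 0.0
        _write_tsv(
            pd.DataFrame(
                {
                    "subset": ["a_unique", "a_common", "b_unique", "b_common"],
                    "count": [
                        len(part.a_unique),
                        len(part.a_common),
                        len(part.b_unique),
                        len(part.b_common),
                    ],
                }
            ),
            outdir / "partition.tsv",
            {"peaks_a": config.peaks_a, "peaks_b": config.peaks_b},
        )
        summary["partition"] = {
            "n_a": len(peaks_a),
            "n_b": len(peaks_b),
            "a_common": len(part.a_common),
            "b_common": len(part.b_common),
            "common_b_fraction": common_b_fraction,
        }
    except Exception as exc:
        raise PipelineError(f"stage partition: {exc}") from exc

    # --- condition dynamics of the B cistrome -------------------------------
    try:
        _stage("dynamics")
        dyn = classify_dynamics(peaks_b, peaks_bt)
        _write_tsv(
            pd.DataFrame(
                {
                    "subset": ["lost", "shared", "gained", "treated_total"],
                    "count": [
                        len(dyn.lost),
                        len(dyn.shared),
                        len(dyn.gained),
                        len(peaks_bt),
                    ],
                }
            ),
            outdir / "dynamics.tsv",
            {"vehicle": config.peaks_b, "treated": config.peaks_b_treated},
        )
        summary["dynamics"] = {
            "lost": len(dyn.lost),
            "shared": len(dyn.shared),
            "gained": len(dyn.gained),
        }
    except Exception as exc:
        raise PipelineError(f"stage dynamics: {exc}") from exc

    # --- gene occupancy classes + class-wise fold changes --------------------
    try:
        _stage("occupancy")
        occ = annotation.occupancy_classes(
            genes, peaks_a, peaks_b, window_kb=config.occupancy_window_kb
        )
        occ_fc = occ.merge(fc[["gene_id", "log2fc"]], on="gene_id", how="left")
        _write_tsv(
            occ_fc,
            outdir / "occupancy_classes.tsv",
            {"window_kb": config.occupancy_window_kb},
        )
        by_class = {
            lab: grp["log2fc"].dropna().to_numpy()
            for lab, grp in occ_fc.groupby("occupancy")
        }
        class_tests = stats.compare_groups(by_class)
        _write_tsv(class_tests, outdir / "class_tests.tsv", {})
        summary["occupancy"] = {
            "counts": occ["occupancy"].value_counts().to_dict(),
            "class_median_log2fc": {
                lab: float(np.median(v)) for lab, v in by_class.items() if len(v)
            },
        }
    except Exception as exc:
        raise PipelineError(f"stage occupancy: {exc}") from exc

    # --- resampling enrichment of regulated gene sets ------------------------
    try:
        _stage("enrichment")
        up_genes = fc.loc[fc["log2fc"] >= config.fc_up, "gene_id"].tolist()
        down_genes = fc.loc[fc["log2fc"] <= config.fc_down, "gene_id"].tolist()
        static_genes = fc.loc[fc["log2fc"].abs() < config.fc_static, "gene_id"].tolist()
        enrich_rows = []
        enrich_summary = {}
        for qname, qset in (("up", up_genes), ("down", down_genes)):
            for pname, pset in (("A", peaks_a), ("B", peaks_b)):
                if not qset:
                    continue
                sub_seed = config.seed * 10 + len(enrich_rows)
                res = annotation.resample_enrichment(
                    qset,
                    pset,
                    genes,
                    window_kb=config.enrichment_window_kb,
                    n_iter=config.n_iter,
                    seed=sub_seed,
                )
                log.info("enrichment %s x %s: seed=%d", qname, pname, sub_seed)
                enrich_rows.append(
                    {
                        "query": qname,
                        "peaks": pname,
                        "n_query": res.n_query,
                        "observed_pct": res.observed_pct,
                        "null_mean_pct": res.null_mean,
                        "odds_ratio": res.odds_ratio,
                        "p_empirical": res.p_empirical,
                        "p_t": res.p_t,
                        "seed": res.seed,
                    }
                )
                enrich_summary[f"{qname}_x_{pname}"] = {
                    "odds_ratio": res.odds_ratio,
                    "p_empirical": res.p_empirical,
                }
        _write_tsv(
            pd.DataFrame(enrich_rows),
            outdir / "enrichment.tsv",
            {
                "window_kb": config.enrichment_window_kb,
                "n_iter": config.n_iter,
                "seed": config.seed,
            },
        )
        summary["enrichment"] = enrich_summary
    except Exception as exc:
        raise PipelineError(f"stage enrichment: {exc}") from exc

    # --- regulatory-potential association ------------------------------------
    try:
        _stage("regulatory_potential")
        rp = regpotential.regulatory_potential_table(
            genes, peaks_a, half_window=config.rp_half_window
        )
        _write_tsv(rp, outdir / "regulatory_potential.tsv", {"half_window": config.rp_half_window})
        assoc = regpotential.beta_association(rp, up_genes, down_genes, static_genes)
        summary["rp_association"] = {
            lab: {"ks": r.ks_statistic, "p": r.p_value}
            for lab, r in assoc.items()
            if lab != "static"
        }
    except Exception as exc:
        raise PipelineError(f"stage regulatory_potential: {exc}") from exc

    # --- super-enhancers ------------------------------------------------------
    try:
        _stage("superenhancer")
        stitched = superenhancer.stitch_peaks(
            se_peaks, stitch_distance=config.stitch_distance
        )
        ranking = superenhancer.rank_enhancers(stitched, track_ac)
        se_table = ranking.to_frame()
        fc_table = superenhancer.se_fold_change(
            ranking, track_ac, track_ac_t, pseudocount=config.se_pseudocount
        )
        se_table = se_table.merge(
            fc_table[["name", "log2fc"]], on="name", how="left"
        )
        _write_tsv(
            se_table,
            outdir / "superenhancers.tsv",
            {
                "stitch_distance": config.stitch_distance,
                "pseudocount": config.se_pseudocount,
            },
        )
        summary["superenhancer"] = {
            "n_regions": len(ranking.regions),
            "n_super": ranking.n_super,
            "cutoff_signal": ranking.cutoff_signal,
            "median_log2fc": float(se_table["log2fc"].median()),
        }
    except Exception as exc:
        raise PipelineError(f"stage superenhancer: {exc}") from exc

    # --- pileup profiles ------------------------------------------------------
    try:
        _stage("profiles")
        prof_rows = {}
        for lab, ps in (
            ("a_unique", part.a_unique),
            ("common", part.a_common),
            ("b_unique", part.b_unique),
        ):
            if len(ps) == 0:
                continue
            mat = signal.profile_matrix(
                ps, track_ac, flank=config.profile_flank, bin_width=config.profile_bin
            )
            prof_rows[lab] = signal.mean_profile(mat)
        prof = pd.DataFrame(prof_rows)
        prof.insert(
            0,
            "bin_center_offset",
            -config.profile_flank
            + config.profile_bin // 2
            + config.profile_bin * np.arange(len(prof)),
        )
        _write_tsv(
            prof,
            outdir / "profiles.tsv",
            {"flank": config.profile_flank, "bin": config.profile_bin},
        )
        summary["profiles"] = {
            lab: float(np.max(v)) for lab, v in prof_rows.items()
        }
    except Exception as exc:
        raise PipelineError(f"stage profiles: {exc}") from exc

    # --- signature scores -----------------------------------------------------
    try:
        _stage("signature")
        sig_scores = stats.signature_zscore(expr, signature)
        _write_tsv(sig_scores, outdir / "signature_scores.tsv", {"n_signature": len(signature)})
        treated_mask = sig_scores["sample_id"].str.startswith("treated")
        summary["signature"] = {
            "n_genes_used": int(sig_scores["n_genes_used"].iloc[0]),
            "score_sum": float(sig_scores["score"].sum()),
        }
        if treated_mask.any() and (~treated_mask).any():
            summary["signature"]["treated_minus_vehicle_mean"] = float(
                sig_scores.loc[treated_mask, "score"].mean()
                - sig_scores.loc[~treated_mask, "score"].mean()
            )
    except Exception as exc:
        raise PipelineError(f"stage signature: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "inputs": {k: _digest(v) for k, v in config.input_paths().items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
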