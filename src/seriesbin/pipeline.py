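"""End-to-end pipeline orchestrator.

Composes the stages — optional synthetic-community generation, feature
building, ESOM training, bin delineation, quality control and refinement,
rpS3 community profiling and (when a metabolite table is supplied) group
statistics — into a single seeded run with a machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import bin_qc, community_profile, esom, features, group_stats, io
from . import synthetic_community as synth

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("seriesbin")

_REQUIRED = ("seed", "out_dir")


@dataclass
class PipelineConfig:
    """Everything a run needs; see ``from_dict`` for the file representation."""

    seed: int
    out_dir: str
    # either synthesize a community ...
    synth: dict | None = None  # {n_genomes, n_samples, overrides?, fragment?}
    # ... or point at existing inputs
    fasta: str | None = None
    coverage: str | None = None
    markers: str | None = None
    taxa: str | None = None
    rps3: str | None = None
    rps3_map: str | None = None  # rps3 seq id -> scaffold id TSV
    metabolites: str | None = None  # long-format analyte/group/value TSV

    min_length: int = 8000
    block_weights: tuple[float, float] = (0.1, 1.0)
    zscore_columns: bool = False
    som_rows: int | None = None
    som_cols: int | None = None
    epochs: int = 20
    radius_start: float | None = None
    radius_end: float = 1.0
    u_threshold_quantile: float = 0.6
    min_bin_scaffolds: int = 5
    duplication_cap: float = 0.10
    mad_cutoff: float = 3.5
    identity: float = 0.99
    span: float = 0.60
    alpha: float = 0.05
    umatrix_png: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        for key in _REQUIRED:
            if key not in d:
                raise ValueError(f"missing config field: {key!r}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        if "block_weights" in d:
            d["block_weights"] = tuple(d["block_weights"])
        return cls(**d)

    def validate(self) -> None:
        if not 0 < self.u_threshold_quantile < 1:
            raise ValueError("u_threshold_quantile must lie in (0, 1)")
        if not 0 < self.identity <= 1 or not 0 < self.span <= 1:
            raise ValueError("identity and span must lie in (0, 1]")
        if self.synth is None and (self.fasta is None or self.coverage is None):
            raise ValueError("provide either a synth block or fasta+coverage inputs")


@dataclass
class _Stage:
    name: str
    summary: dict[str, Any] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stages: list[_Stage] = []

    def fail(stage: str, exc: Exception) -> Exception:
        err = RuntimeError(f"pipeline stage {stage!r} failed: {exc}")
        err.__cause__ = exc
        return err

    # -- synthesize or load inputs -------------------------------------------------
    if config.synth is not None:
        stage = _Stage("synthesize")
        s = dict(config.synth)
        design = synth.design_community(
            int(s.get("n_genomes", 20)),
            int(s.get("n_samples", 10)),
            seed=config.seed,
            overrides=s.get("overrides"),
        )
        genomes = synth.generate_genome_sequences(design)
        scaffolds, coverage, truth, rps3_seqs = synth.fragment_and_cover(
            design, genomes, **(s.get("fragment") or {})
        )
        manifest.update(io.write_community(out, design, scaffolds, coverage, truth, rps3_seqs))
        sequences = scaffolds.sequences
        markers_df = scaffolds.markers
        taxa_map = scaffolds.taxon_of
        gc_map = scaffolds.gc.to_dict()
        rps3_map = dict(zip(scaffolds.rps3_loci["rps3_id"], scaffolds.rps3_loci["scaffold_id"]))
        rps3_taxa = {
            rid: truth.genome_taxon[gid] for gid, rid in truth.genome_rps3.items()
        }
        truth_labels = truth.scaffold_to_genome
        stage.summary = {
            "n_genomes": design.n_genomes,
            "n_samples": design.n_samples,
            "n_scaffolds": len(sequences),
        }
        stages.append(stage)
        logger.info("synthesized %d scaffolds from %d genomes", len(sequences), design.n_genomes)
    else:
        sequences = io.read_fasta(config.fasta)
        coverage = io.read_coverage(config.coverage)
        markers_df = io.read_table(config.markers) if config.markers else None
        taxa_map = (
            io.read_table(config.taxa, index_col="scaffold_id")["taxon"].to_dict()
            if config.taxa
            else None
        )
        gc_map = {
            sid: (seq.upper().count("G") + seq.upper().count("C")) / max(len(seq), 1)
            for sid, seq in sequences.items()
        }
        rps3_seqs = io.read_fasta(config.rps3) if config.rps3 else None
        rps3_map = (
            io.read_table(config.rps3_map, index_col="rps3_id")["scaffold_id"].to_dict()
            if config.rps3_map
            else None
        )
        rps3_taxa = None
        truth_labels = None

    # -- features ------------------------------------------------------------------
    try:
        normalized = features.normalize_coverage(coverage)
        fm = features.build_feature_matrix(
            sequences,
            normalized,
            min_length=config.min_length,
            block_weights=config.block_weights,
            zscore_columns=config.zscore_columns,
        )
    except Exception as exc:
        raise fail("features", exc)
    fm_df = fm.to_frame().rename_axis("scaffold_id")
    io.write_table(
        out / "features.tsv",
        fm_df,
        comments=["blocks:\t" + "\t".join(fm.column_blocks)],
    )
    manifest["features"] = str(out / "features.tsv")
    stages.append(_Stage("features", {"n_rows": len(fm.scaffold_ids), "n_columns": fm.values.shape[1]}))

    # -- ESOM binning --------------------------------------------------------------
    try:
        model = esom.train_esom(
            fm,
            rows=config.som_rows,
            cols=config.som_cols,
            epochs=config.epochs,
            radius_start=config.radius_start,
            radius_end=config.radius_end,
            seed=config.seed,
        )
        umatrix = esom.compute_umatrix(model)
        assignment = esom.delineate_bins(
            model, umatrix, config.u_threshold_quantile, config.min_bin_scaffolds
        )
    except Exception as exc:
        raise fail("esom", exc)
    io.write_table(
        out / "weights.tsv",
        pd.DataFrame(model.flat_weights, columns=model.feature_names),
        index=False,
    )
    io.write_table(out / "umatrix.tsv", pd.DataFrame(umatrix), index=False)
    io.write_table(out / "bins.tsv", assignment.to_frame())
    manifest.update(
        weights=str(out / "weights.tsv"),
        umatrix=str(out / "umatrix.tsv"),
        bins=str(out / "bins.tsv"),
    )
    if config.umatrix_png:
        esom.plot_umatrix(umatrix, out / "umatrix.png", assignment)
        manifest["umatrix_png"] = str(out / "umatrix.png")
    esom_summary: dict[str, Any] = {
        "grid": [model.rows, model.cols],
        "n_bins": len(assignment.bins),
        "unbinned_fraction": len(assignment.unbinned) / max(len(assignment.labels), 1),
        "quantization_error": model.quantization_error,
    }
    if truth_labels is not None:
        metrics = esom.evaluate_binning(assignment, truth_labels)
        esom_summary["ari_vs_truth"] = metrics.ari
    stages.append(_Stage("esom", esom_summary))
    logger.info("delineated %d bins", len(assignment.bins))

    # -- QC and refinement ---------------------------------------------------------
    if markers_df is not None:
        try:
            qual_rows = []
            all_flags = []
            for bin_id, members in assignment.bins.items():
                q = bin_qc.assess_bin(
                    members, markers_df, domain=None,
                    duplication_cap=config.duplication_cap, bin_id=bin_id,
                )
                qual_rows.append(
                    {"bin": bin_id, "domain": q.domain, "completeness": q.completeness,
                     "duplicated_markers": q.duplicated_marker_count,
                     "duplication_fraction": q.duplication_fraction,
                     "draft_quality": q.draft_quality}
                )
                all_flags.extend(
                    (bin_id, f)
                    for f in bin_qc.flag_contaminants(
                        members, gc_map, normalized, taxa_map, config.mad_cutoff
                    )
                )
            refined = bin_qc.refine_bins(assignment, [f for _, f in all_flags])
        except Exception as exc:
            raise fail("bin_qc", exc)
        io.write_table(
            out / "bin_quality.tsv",
            pd.DataFrame(
                qual_rows,
                columns=["bin", "domain", "completeness", "duplicated_markers",
                         "duplication_fraction", "draft_quality"],
            ),
            index=False,
        )
        io.write_table(
            out / "flags.tsv",
            pd.DataFrame(
                [
                    {"scaffold_id": f.scaffold_id, "bin": b, "reasons": ",".join(f.reasons)}
                    for b, f in all_flags
                ],
                columns=["scaffold_id", "bin", "reasons"],
            ),
            index=False,
        )
        io.write_table(out / "bins_refined.tsv", refined.to_frame())
        manifest.update(
            bin_quality=str(out / "bin_quality.tsv"),
            flags=str(out / "flags.tsv"),
            bins_refined=str(out / "bins_refined.tsv"),
        )
        stages.append(
            _Stage(
                "bin_qc",
                {
                    "n_draft_quality": int(sum(r["draft_quality"] for r in qual_rows)),
                    "n_flagged": len(all_flags),
                },
            )
        )

    # -- community profile ---------------------------------------------------------
    if rps3_seqs and rps3_map:
        try:
            clusters, excluded = community_profile.cluster_species(
                rps3_seqs, identity=config.identity, span=config.span
            )
            abundance = community_profile.abundance_table(
                clusters, normalized, rps3_map, taxa=rps3_taxa
            )
            phyla = community_profile.phylum_rollup(abundance)
            bc = community_profile.bray_curtis_matrix(abundance)
            ordination = community_profile.pcoa(bc, k=2)
        except Exception as exc:
            raise fail("community_profile", exc)
        io.write_table(
            out / "clusters.tsv",
            pd.DataFrame(
                [
                    {"cluster_id": c.cluster_id, "centroid_id": c.centroid_id,
                     "taxon": c.taxon or "", "members": ",".join(c.member_ids)}
                    for c in clusters
                ],
            ),
            index=False,
        )
        io.write_table(out / "abundance.tsv", abundance.values.rename_axis("cluster_id"))
        io.write_table(out / "phylum_abundance.tsv", phyla)
        io.write_table(out / "braycurtis.tsv", bc.rename_axis("sample_id"))
        io.write_table(out / "pcoa.tsv", ordination.coordinates.rename_axis("sample_id"))
        manifest.update(
            clusters=str(out / "clusters.tsv"),
            abundance=str(out / "abundance.tsv"),
            phylum_abundance=str(out / "phylum_abundance.tsv"),
            braycurtis=str(out / "braycurtis.tsv"),
            pcoa=str(out / "pcoa.tsv"),
        )
        stages.append(
            _Stage(
                "community_profile",
                {
                    "n_clusters": len(clusters),
                    "n_excluded": len(excluded),
                    "proportion_explained": np.asarray(
                        ordination.proportion_explained
                    ).tolist(),
                },
            )
        )

    # -- group statistics ----------------------------------------------------------
    if config.metabolites:
        try:
            table = io.read_table(config.metabolites)
            anova, tukey = group_stats.analyte_anova_table(table, alpha=config.alpha)
        except Exception as exc:
            raise fail("group_stats", exc)
        io.write_table(out / "anova.tsv", anova, index=False)
        io.write_table(out / "tukey.tsv", tukey, index=False)
        manifest.update(anova=str(out / "anova.tsv"), tukey=str(out / "tukey.tsv"))
        stages.append(
            _Stage(
                "group_stats",
                {"n_analytes": int(anova.shape[0]),
                 "n_significant_q05": int((anova["q_value"] <= 0.05).sum())},
            )
        )

    from . import __version__

    report = {
        "seed": config.seed,
        "version": __version__,
        "parameters": {
            k: v for k, v in vars(config).items() if not isinstance(v, (dict, list)) or k == "synth"
        },
        "stages": [{"name": s.name, **s.summary} for s in stages],
        "manifest": manifest,
    }
    report["parameters"] = json.loads(json.dumps(report["parameters"], default=str))
    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    missing = [p for p in manifest.values() if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"declared outputs missing: {missing}")
    return report
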