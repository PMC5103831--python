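"""Readers and writers for the pipeline's on-disk formats.

All tables are tab-delimited UTF-8 with a header row; readers tolerate
'#'-prefixed comment lines and CRLF line endings. FASTA is read and written
through Biopython (sequences wrapped at 80 columns, case preserved).
Coordinates in annotation files are 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .features import CoverageTable
from .synthetic_community import CommunityDesign, ScaffoldSet, TruthTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_coverage",
    "write_coverage",
    "read_table",
    "write_table",
    "write_community",
    "load_config",
]

_COMMENT_COORDS = "# coordinates are 1-based inclusive"


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered mapping id -> sequence (case preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_descriptions(path) -> list[tuple[str, str, str]]:
    """Read FASTA as (id, description, sequence) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.append((rec.id, desc, str(rec.seq)))
    return out


def write_fasta(path, sequences, descriptions: Mapping[str, str] | None = None) -> None:
    """Write sequences (mapping id -> seq, or (id, desc, seq) triples) wrapped at 80 columns."""
    if isinstance(sequences, Mapping):
        items = [(sid, (descriptions or {}).get(sid, ""), seq) for sid, seq in sequences.items()]
    else:
        items = list(sequences)
    records = [
        SeqRecord(Seq(seq), id=sid, description=desc) for sid, desc, seq in items
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(records)


def read_table(path, index_col: str | None = None) -> pd.DataFrame:
    """Read a TSV with '#' comments and tolerant line endings."""
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def write_table(path, df: pd.DataFrame, comments: list[str] | None = None, index: bool = True) -> None:
    """Write a TSV with optional leading '#' comment lines and a header row."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line.lstrip('# ')}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_coverage(path) -> CoverageTable:
    """Read coverage.tsv (scaffold_id + one column per sample)."""
    df = read_table(path, index_col="scaffold_id")
    return CoverageTable(df.astype(float), normalized=False)


def write_coverage(path, table: CoverageTable, comments: list[str] | None = None) -> None:
    df = table.values.rename_axis("scaffold_id")
    note = ["normalized coverage" if table.normalized else "raw fold coverage"]
    write_table(path, df, comments=(comments or []) + note)


def _design_to_dict(design: CommunityDesign) -> dict:
    return {
        "n_genomes": design.n_genomes,
        "n_samples": design.n_samples,
        "depth_effect": design.depth_effect,
        "seed": design.seed,
        "read_length": design.read_length,
        "sample_labels": [
            {"depth": lab.depth, "timepoint": lab.timepoint} for lab in design.sample_labels
        ],
        "sample_depth_factors": np.asarray(design.sample_depth_factors).tolist(),
        "genomes": [
            {
                "genome_id": s.genome_id,
                "domain": s.domain,
                "taxon": s.taxon,
                "length_bp": s.length_bp,
                "gc_target": s.gc_target,
                "markov_order": s.markov_order,
                "transition_seed": s.transition_seed,
                "rps3_divergence": s.rps3_divergence,
                "abundance_profile": np.asarray(s.abundance_profile).tolist(),
            }
            for s in design.genome_specs
        ],
    }


def write_community(
    out_dir,
    design: CommunityDesign,
    scaffolds: ScaffoldSet,
    coverage: CoverageTable,
    truth: TruthTable,
    rps3: Mapping[str, str],
) -> dict[str, str]:
    """Write the full synthetic-community bundle; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    write_fasta(out / "scaffolds.fasta", scaffolds.sequences)
    manifest["scaffolds"] = str(out / "scaffolds.fasta")

    write_coverage(out / "coverage.tsv", coverage)
    manifest["coverage"] = str(out / "coverage.tsv")

    write_table(out / "truth.tsv", truth.to_frame(), comments=["scaffold -> genome truth"])
    manifest["truth"] = str(out / "truth.tsv")

    write_table(
        out / "markers.tsv",
        scaffolds.markers,
        comments=["single-copy marker annotations", _COMMENT_COORDS],
        index=False,
    )
    manifest["markers"] = str(out / "markers.tsv")

    write_table(
        out / "rps3_loci.tsv",
        scaffolds.rps3_loci,
        comments=["rpS3 locus annotations", _COMMENT_COORDS],
        index=False,
    )
    manifest["rps3_loci"] = str(out / "rps3_loci.tsv")

    taxa = scaffolds.table[["taxon"]].rename_axis("scaffold_id")
    write_table(out / "taxa.tsv", taxa, comments=["per-scaffold taxon annotations"])
    manifest["taxa"] = str(out / "taxa.tsv")

    write_fasta(out / "rps3.faa", dict(rps3))
    manifest["rps3"] = str(out / "rps3.faa")

    with open(out / "design.json", "w", encoding="utf-8") as fh:
        json.dump(_design_to_dict(design), fh, indent=2)
    manifest["design"] = str(out / "design.json")
    return manifest


def load_config(path) -> dict:
    """Load a YAML key-value pipeline configuration file."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must hold a key-value mapping")
    return cfg
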