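"""Species-level community profiling from ribosomal protein S3 (rpS3).

rpS3 is a universal single-copy phylogenetic marker: clustering its
amino-acid sequences at 99% identity delineates species-level organism
units, and the normalized coverage of each rpS3-bearing scaffold measures
that organism's abundance in each sample. This module provides

* greedy centroid clustering of rpS3 sequences with a minimum aligned-span
  requirement (fragments covering <60% of the alignment are excluded),
* per-sample percent-abundance tables and phylum-level rollups for stacked
  community composition charts, and
* Bray-Curtis dissimilarities between samples with classical principal
  coordinates analysis (PCoA) for beta-diversity ordination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SpeciesCluster",
    "AbundanceTable",
    "PCoAResult",
    "cluster_species",
    "abundance_table",
    "phylum_rollup",
    "bray_curtis_matrix",
    "pcoa",
]

_AA_OK = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass
class SpeciesCluster:
    cluster_id: str
    centroid_id: str
    member_ids: list[str]
    taxon: str | None = None


@dataclass
class AbundanceTable:
    """Cluster x sample percent abundances; each column sums to 100."""

    values: pd.DataFrame
    taxon: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # sample x axis
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray  # for the returned axes
    negative_eigenvalues: np.ndarray


def _make_aligner(open_gap: float = 11.0, extend_gap: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    # free end gaps: fragments are not penalized for not reaching the ends
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


def _identity_and_span(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[float, float]:
    """Percent identity and aligned span of the best global alignment.

    The core of the alignment runs from the first to the last column in
    which both sequences are present; identity is matches / core columns
    (internal gaps count against identity) and span is core columns /
    total alignment columns (terminal gaps count against span).
    """
    aln = aligner.align(a, b)[0]
    s0, s1 = str(aln[0]), str(aln[1])
    both = [i for i in range(len(s0)) if s0[i] != "-" and s1[i] != "-"]
    if not both:
        return 0.0, 0.0
    lo, hi = both[0], both[-1] + 1
    core = hi - lo
    matches = sum(1 for i in range(lo, hi) if s0[i] == s1[i] and s0[i] != "-")
    return matches / core, core / len(s0)


def cluster_species(
    sequences: Mapping[str, str],
    identity: float = 0.99,
    span: float = 0.60,
) -> tuple[list[SpeciesCluster], list[str]]:
    """Greedy centroid clustering of amino-acid sequences.

    Sequences are processed longest-first; each query is globally aligned
    (free end gaps, BLOSUM62, affine gaps 11/1) to existing centroids in
    creation order and joins the first centroid whose identity meets the
    threshold over a sufficient aligned span. A query that reaches the
    identity threshold against centroids only over insufficient spans is
    excluded (typically a short fragment); otherwise it founds a new
    centroid.

    Returns ``(clusters, excluded_ids)``.
    """
    if not 0 < identity <= 1 or not 0 < span <= 1:
        raise ValueError("identity and span must lie in (0, 1]")
    if not sequences:
        return [], []
    for sid, seq in sequences.items():
        extra = set(seq.upper()) - _AA_OK
        if extra:
            warnings.warn(
                f"{sid}: non-amino-acid symbol(s) {sorted(extra)}", stacklevel=2
            )
    aligner = _make_aligner()
    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    centroids: list[SpeciesCluster] = []
    excluded: list[str] = []
    for sid in order:
        seq = sequences[sid]
        joined = False
        span_failed = False
        for cl in centroids:
            ident, sp = _identity_and_span(aligner, sequences[cl.centroid_id], seq)
            if ident >= identity:
                if sp >= span:
                    cl.member_ids.append(sid)
                    joined = True
                    break
                span_failed = True
        if joined:
            continue
        if span_failed:
            excluded.append(sid)
        else:
            centroids.append(
                SpeciesCluster(
                    cluster_id=f"cluster_{len(centroids) + 1:04d}",
                    centroid_id=sid,
                    member_ids=[sid],
                )
            )
    return centroids, excluded


def abundance_table(
    clusters: list[SpeciesCluster],
    coverage,
    seq_to_scaffold: Mapping[str, str],
    taxa: Mapping[str, str] | None = None,
) -> AbundanceTable:
    """Percent abundance of every species cluster in every sample.

    A cluster's abundance in a sample is the summed normalized coverage of
    the scaffolds carrying its member sequences; columns are rescaled to
    percent. ``taxa`` maps sequence ids to phylum labels; a cluster takes
    its centroid's label.
    """
    cov = coverage if isinstance(coverage, pd.DataFrame) else coverage.values
    rows = []
    taxon_map: dict[str, str] = {}
    for cl in clusters:
        scaffolds = {seq_to_scaffold[m] for m in cl.member_ids if m in seq_to_scaffold}
        scaffolds &= set(cov.index)
        if not scaffolds:
            raise ValueError(f"{cl.cluster_id}: no coverage-mapped scaffold")
        rows.append(cov.loc[sorted(scaffolds)].sum(axis=0).rename(cl.cluster_id))
        if taxa is not None:
            label = taxa.get(cl.centroid_id) or cl.taxon
            if label:
                taxon_map[cl.cluster_id] = label
            cl.taxon = label
    table = pd.DataFrame(rows)
    sums = table.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        warnings.warn(f"sample(s) with zero total abundance: {list(zero.index)}", stacklevel=2)
        sums = sums.replace(0, 1.0)
    return AbundanceTable(values=table / sums * 100.0, taxon=taxon_map)


def phylum_rollup(table: AbundanceTable) -> pd.DataFrame:
    """Sum species percent abundances within each phylum (stacked-bar input)."""
    labels = {}
    for cid in table.values.index:
        lab = table.taxon.get(cid)
        if not lab:
            warnings.warn(f"{cid}: missing phylum label, assigned 'Unclassified'", stacklevel=2)
            lab = "Unclassified"
        labels[cid] = lab
    return table.values.groupby(pd.Series(labels)).sum().rename_axis("phylum")


def bray_curtis_matrix(table) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    ``d(a, b) = sum|a_i - b_i| / sum(a_i + b_i)`` over species abundances;
    a pair of all-zero samples has distance 0 (with a warning).
    """
    values = table.values if isinstance(table, AbundanceTable) else table
    x = np.asarray(values, dtype=float).T  # samples x species
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                warnings.warn(
                    "two all-zero samples: Bray-Curtis distance defined as 0",
                    stacklevel=2,
                )
                dij = 0.0
            else:
                dij = np.abs(x[i] - x[j]).sum() / denom
            d[i, j] = d[j, i] = dij
    samples = list(values.columns) if hasattr(values, "columns") else list(range(n))
    return pd.DataFrame(d, index=samples, columns=samples)


def pcoa(distances, k: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    The Gower matrix ``-0.5 * J D^2 J`` (J the centering projector) is
    eigendecomposed; coordinates are eigenvectors scaled by the square roots
    of the top ``k`` positive eigenvalues. Negative eigenvalues — possible
    because Bray-Curtis is a semimetric — are dropped and reported.
    Proportions explained are relative to the positive eigenvalue total.
    """
    dvals = distances
    d = np.asarray(dvals, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(evals[0]), 1.0))
    pos = evals > tol
    neg = evals[evals < -tol]
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    lam = evals[:k]
    coords = evecs[:, :k] * np.sqrt(lam)[None, :]
    total_pos = evals[pos].sum() if n_pos else 1.0
    labels = (
        list(dvals.index) if hasattr(dvals, "index") else [str(i) for i in range(n)]
    )
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=labels, columns=[f"PCo{i + 1}" for i in range(k)]
        ),
        eigenvalues=evals[pos],
        proportion_explained=lam / total_pos if k else np.array([]),
        negative_eigenvalues=neg,
    )
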