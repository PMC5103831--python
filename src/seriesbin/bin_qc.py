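"""Bin quality control against single-copy marker gene sets.

Completeness of a genome bin is the fraction of the domain's universal
single-copy genes (51 for bacteria, 38 for archaea) recovered on its member
scaffolds; markers found in two or more copies indicate contamination or
scaffolding artifacts. A bin is "draft quality" when it holds at least 70%
of the requisite single-copy genes with minimal duplication — duplication
is capped as a configurable fraction of the marker set rather than a hard
zero, because genes split across scaffold gaps legitimately appear twice.

Contaminant scaffolds are flagged by robust outlier tests on GC content and
mean normalized coverage (median absolute deviation rule) and by taxonomic
votes conflicting with the bin's majority taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .esom import UNBINNED, BinAssignment
from .features import CoverageTable
from .synthetic_community import ARCHAEAL_MARKER_IDS, BACTERIAL_MARKER_IDS

__all__ = [
    "MarkerSet",
    "is_draft_quality",
    "BACTERIAL_MARKERS",
    "ARCHAEAL_MARKERS",
    "BinQuality",
    "ContaminantFlag",
    "assess_bin",
    "flag_contaminants",
    "refine_bins",
]


@dataclass(frozen=True)
class MarkerSet:
    domain: str
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = {"bacteria": 51, "archaea": 38}.get(self.domain)
        if expected is None:
            raise ValueError(f"unknown domain {self.domain!r}")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        if len(self.marker_ids) != expected:
            raise ValueError(
                f"{self.domain} marker set must hold {expected} ids, "
                f"got {len(self.marker_ids)}"
            )


#: default marker sets; ids are placeholders with the canonical cardinalities
#: and can be swapped for a concrete universal single-copy gene catalogue
BACTERIAL_MARKERS = MarkerSet("bacteria", BACTERIAL_MARKER_IDS)
ARCHAEAL_MARKERS = MarkerSet("archaea", ARCHAEAL_MARKER_IDS)


@dataclass
class BinQuality:
    bin_id: str
    domain: str
    completeness: float
    duplicated_marker_count: int
    duplication_fraction: float
    draft_quality: bool
    marker_copy_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ContaminantFlag:
    scaffold_id: str
    reasons: tuple[str, ...]


def is_draft_quality(
    completeness: float, duplication_fraction: float, duplication_cap: float = 0.10
) -> bool:
    """Draft-quality rule: >=70% of the single-copy set with minimal duplication."""
    return completeness >= 0.70 and duplication_fraction <= duplication_cap


def _marker_counts(
    members: Iterable[str],
    markers: pd.DataFrame,
    marker_set: MarkerSet,
    known_ids: set[str],
) -> dict[str, int]:
    members = set(members)
    sub = markers[markers["scaffold_id"].isin(members)]
    unknown = set(sub["marker_id"]) - known_ids
    if unknown:
        raise ValueError(f"marker id(s) not in any marker set: {sorted(unknown)[:5]}")
    counts = {m: 0 for m in marker_set.marker_ids}
    for m in sub["marker_id"]:
        if m in counts:
            counts[m] += 1
    return counts


def assess_bin(
    members: Iterable[str],
    markers: pd.DataFrame,
    domain: str | None = None,
    duplication_cap: float = 0.10,
    bin_id: str = "",
    marker_sets: Mapping[str, MarkerSet] | None = None,
) -> BinQuality:
    """Score one bin's completeness and duplication.

    ``markers`` is the annotation table (columns ``scaffold_id`` and
    ``marker_id`` at minimum); only annotations on member scaffolds count.
    If ``domain`` is None both marker sets are scored and the higher
    completeness wins (ties go to bacteria, the larger set). Draft quality
    requires completeness >= 0.70 and a duplication fraction at or under
    ``duplication_cap``.
    """
    sets = dict(marker_sets or {"bacteria": BACTERIAL_MARKERS, "archaea": ARCHAEAL_MARKERS})
    members = list(members)
    if domain is not None:
        if domain not in sets:
            raise ValueError(f"unknown domain {domain!r}")
        candidates = [domain]
    else:
        candidates = ["bacteria", "archaea"]

    known_ids = {m for ms in sets.values() for m in ms.marker_ids}
    best: BinQuality | None = None
    for dom in candidates:
        ms = sets[dom]
        counts = _marker_counts(members, markers, ms, known_ids)
        present = sum(1 for c in counts.values() if c >= 1)
        dup = sum(1 for c in counts.values() if c >= 2)
        completeness = present / len(ms.marker_ids)
        dup_frac = dup / len(ms.marker_ids)
        q = BinQuality(
            bin_id=bin_id,
            domain=dom,
            completeness=completeness,
            duplicated_marker_count=dup,
            duplication_fraction=dup_frac,
            draft_quality=is_draft_quality(completeness, dup_frac, duplication_cap),
            marker_copy_counts=counts,
        )
        if best is None or q.completeness > best.completeness:
            best = q
    assert best is not None
    return best


def _mad_outliers(values: np.ndarray, mad_cutoff: float) -> np.ndarray:
    """Boolean mask of |v - median| > cutoff * MAD; all False when MAD == 0."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros(len(values), dtype=bool)
    return np.abs(values - med) > mad_cutoff * mad


def flag_contaminants(
    members: Sequence[str],
    gc: Mapping[str, float],
    coverage: CoverageTable,
    taxon: Mapping[str, str] | None = None,
    mad_cutoff: float = 3.5,
) -> list[ContaminantFlag]:
    """Flag bin members with aberrant GC, aberrant coverage, or conflicting taxonomy.

    A scaffold is flagged when its GC or its mean normalized coverage lies
    more than ``mad_cutoff`` MADs from the bin median (dimensions whose MAD
    is zero are skipped), or when its taxon vote conflicts with a strict
    majority (>50% of voting members) taxon of the bin. Bins with fewer than
    4 members yield no flags — too few points for robust statistics.
    """
    members = list(members)
    if len(members) < 4:
        return []
    missing = [s for s in members if s not in gc]
    if missing:
        raise ValueError(f"missing GC for member scaffold(s): {missing[:5]}")
    missing = [s for s in members if s not in coverage.values.index]
    if missing:
        raise ValueError(f"missing coverage for member scaffold(s): {missing[:5]}")

    reasons: dict[str, list[str]] = {s: [] for s in members}
    gc_vals = np.array([gc[s] for s in members], dtype=float)
    for s, bad in zip(members, _mad_outliers(gc_vals, mad_cutoff)):
        if bad:
            reasons[s].append("gc")
    mean_cov = coverage.values.loc[members].mean(axis=1).to_numpy(dtype=float)
    for s, bad in zip(members, _mad_outliers(mean_cov, mad_cutoff)):
        if bad:
            reasons[s].append("coverage")

    if taxon is not None:
        votes = [taxon[s] for s in members if taxon.get(s)]
        if votes:
            tally: dict[str, int] = {}
            for t in votes:
                tally[t] = tally.get(t, 0) + 1
            top, top_n = max(tally.items(), key=lambda kv: kv[1])
            if top_n * 2 > len(votes):  # strict majority
                for s in members:
                    t = taxon.get(s)
                    if t and t != top:
                        reasons[s].append("taxonomy")

    return [
        ContaminantFlag(scaffold_id=s, reasons=tuple(r))
        for s, r in reasons.items()
        if r
    ]


def refine_bins(
    assignment: BinAssignment, flags: Iterable[ContaminantFlag]
) -> BinAssignment:
    """Move flagged scaffolds to UNBINNED, preserving the partition."""
    labels = dict(assignment.labels)
    for flag in flags:
        if flag.scaffold_id not in labels:
            raise ValueError(f"flag references unassigned scaffold {flag.scaffold_id!r}")
        labels[flag.scaffold_id] = UNBINNED
    return BinAssignment(labels=labels)
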