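"""Feature construction for differential-coverage + composition binning.

Each binnable scaffold is described by the concatenation of two blocks:

* a *coverage block* — its size-normalized fold-coverage series across all
  samples, rescaled to unit sum per scaffold so that only the shape of the
  series (which samples the organism is abundant in) matters, and
* a *tetra block* — its tetranucleotide frequency vector, the 256
  overlapping 4-mer frequencies counted on the given strand (4-mers are not
  collapsed with their reverse complements, hence 256 rather than 136
  columns).

Scaffolds from the same genome share both the coverage pattern and the
compositional signature, which is what the downstream self-organizing map
exploits to delineate genome bins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "KMERS",
    "CoverageTable",
    "FeatureMatrix",
    "tetranucleotide_frequencies",
    "normalize_coverage",
    "build_feature_matrix",
]

_BASES = "ACGT"
#: all 256 tetranucleotides in lexicographic order AAAA..TTTT
KMERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(_BASES, repeat=4)
)

# base -> 0..3; anything else (N, IUPAC ambiguity, lowercase is upcased first) -> -1
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass
class CoverageTable:
    """Per-scaffold, per-sample fold coverage.

    Parameters
    ----------
    values
        DataFrame indexed by scaffold id with one column per sample;
        entries are non-negative fold coverages.
    normalized
        Whether sample-size normalization (:func:`normalize_coverage`) has
        been applied.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate scaffold ids in coverage table: {list(dups)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("coverage table contains negative entries")

    @property
    def scaffold_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FeatureMatrix:
    """Row-per-scaffold matrix fed to the self-organizing map.

    Columns are partitioned into the coverage block (one column per sample,
    in sample order) followed by the tetra block (256 columns in
    lexicographic 4-mer order).
    """

    values: np.ndarray
    scaffold_ids: list[str]
    sample_ids: list[str]
    block_weights: tuple[float, float] = (1.0, 1.0)
    kmers: tuple[str, ...] = field(default=KMERS, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def coverage_block(self) -> np.ndarray:
        return self.values[:, : self.n_samples]

    @property
    def tetra_block(self) -> np.ndarray:
        return self.values[:, self.n_samples :]

    @property
    def column_names(self) -> list[str]:
        return list(self.sample_ids) + list(self.kmers)

    @property
    def column_blocks(self) -> list[str]:
        return ["coverage"] * self.n_samples + ["tetra"] * len(self.kmers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.scaffold_ids, columns=self.column_names)


def tetranucleotide_frequencies(sequence: str) -> np.ndarray:
    """Overlapping 4-mer frequencies of ``sequence`` on the given strand.

    Windows containing a non-ACGT symbol are skipped; remaining counts are
    divided by the number of valid windows, so the result sums to 1.

    Returns a length-256 vector in lexicographic 4-mer order.

    Raises
    ------
    ValueError
        If the sequence has no valid (fully unambiguous) 4-mer window.
    """
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < 4:
        raise ValueError("sequence too short/ambiguous: no valid 4-mer window")
    c0 = codes[:-3]
    c1 = codes[1:-2]
    c2 = codes[2:-1]
    c3 = codes[3:]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("sequence too short/ambiguous: no valid 4-mer window")
    idx = ((c0[valid] * 4 + c1[valid]) * 4 + c2[valid]) * 4 + c3[valid]
    counts = np.bincount(idx, minlength=256).astype(float)
    return counts / n_valid


def normalize_coverage(table: CoverageTable) -> CoverageTable:
    """Equalize per-sample totals to correct for sequencing-depth differences.

    Each sample column is divided by its column sum and multiplied by the
    mean column sum, so every normalized column totals the same amount while
    values stay on a fold-coverage-like scale.
    """
    sums = table.values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample column(s) sum to zero: {list(zero.index)}")
    out = table.values / sums * sums.mean()
    return CoverageTable(out, normalized=True)


def build_feature_matrix(
    scaffolds,
    coverage: CoverageTable,
    min_length: int = 8000,
    block_weights: tuple[float, float] = (1.0, 1.0),
    zscore_columns: bool = False,
) -> FeatureMatrix:
    """Assemble the combined coverage-series + tetranucleotide matrix.

    Parameters
    ----------
    scaffolds
        Mapping of scaffold id to DNA sequence (an object with a
        ``sequences`` attribute holding such a mapping is also accepted).
    coverage
        Size-normalized coverage table covering every retained scaffold.
    min_length
        Strict length gate: only scaffolds longer than this (default
        8000 bp, i.e. >8 kb) are binnable.
    block_weights
        ``(coverage_weight, tetra_weight)`` multipliers applied after each
        block is scaled to unit row sum, controlling how the two signals mix
        in the map's Euclidean metric.
    zscore_columns
        Optionally standardize each column after block scaling (off by
        default).
    """
    seqs = getattr(scaffolds, "sequences", scaffolds)
    if not coverage.normalized:
        raise ValueError("coverage table must be normalized (see normalize_coverage)")
    kept = [sid for sid, seq in seqs.items() if len(seq) > min_length]
    missing = [sid for sid in kept if sid not in coverage.values.index]
    if missing:
        raise ValueError(f"scaffolds missing from coverage table: {missing[:10]}")
    w_cov, w_tet = block_weights

    cov = coverage.values.loc[kept].to_numpy(dtype=float)
    row_sums = cov.sum(axis=1, keepdims=True)
    # all-zero coverage rows stay zero rather than dividing by zero
    cov_block = np.divide(cov, row_sums, out=np.zeros_like(cov), where=row_sums > 0) * w_cov

    tet_block = np.empty((len(kept), 256))
    for i, sid in enumerate(kept):
        tet_block[i] = tetranucleotide_frequencies(seqs[sid])
    tet_block *= w_tet

    values = np.hstack([cov_block, tet_block])
    if zscore_columns:
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd
    return FeatureMatrix(
        values=values,
        scaffold_ids=kept,
        sample_ids=coverage.sample_ids,
        block_weights=(w_cov, w_tet),
    )
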