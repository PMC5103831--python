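"""Seeded synthetic soil-community generator.

Emulates the statistical structure that the binning and profiling stages
assume, without simulating reads or assembly:

* genomes are order-3 Markov chains over ACGT with genome-specific,
  seeded transition matrices, so tetranucleotide frequencies carry genome
  identity while per-row GC is pinned exactly to each genome's GC target;
* abundances follow a log-normal series across samples taken at two soil
  depths, with a genome-specific depth loading so that communities from the
  same depth resemble each other more than communities across depths;
* genomes are fragmented into scaffolds with log-normally distributed
  lengths, and per-scaffold per-sample coverage is drawn as overdispersed
  (negative-binomial) read counts converted to fold coverage;
* each genome carries the full domain set of single-copy markers (51 for
  bacteria, 38 for archaea) planted as coordinate annotations, plus one
  ribosomal protein S3 (rpS3) locus whose amino-acid sequence diverges from
  a per-taxon base sequence.

Everything is deterministic given the design seed; a truth table links
scaffolds back to genomes for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .features import CoverageTable

__all__ = [
    "GenomeSpec",
    "SampleLabel",
    "CommunityDesign",
    "ScaffoldSet",
    "TruthTable",
    "design_community",
    "generate_genome_sequences",
    "fragment_and_cover",
]

_BASES = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"
RPS3_LENGTH = 220

#: single-copy marker ids; cardinalities follow the bacterial (51) and
#: archaeal (38) universal single-copy gene sets used for bin completeness
BACTERIAL_MARKER_IDS: tuple[str, ...] = tuple(f"BSCG_{i:02d}" for i in range(1, 52))
ARCHAEAL_MARKER_IDS: tuple[str, ...] = tuple(f"ASCG_{i:02d}" for i in range(1, 39))

_BACTERIAL_TAXA = (
    "Gemmatimonadetes",
    "Rokubacteria",
    "Acidobacteria",
    "Verrucomicrobia",
    "Chloroflexi",
    "Nitrospirae",
    "Actinobacteria",
    "Proteobacteria",
    "Armatimonadetes",
    "Bacteroidetes",
)
_ARCHAEAL_TAXA = ("Bathyarchaeota", "Thaumarchaeota", "Thermoplasmatales")


@dataclass
class GenomeSpec:
    genome_id: str
    domain: Literal["bacteria", "archaea"]
    taxon: str
    length_bp: int
    gc_target: float
    markov_order: int = 3
    transition_seed: int = 0
    abundance_profile: np.ndarray = field(default_factory=lambda: np.array([]))
    rps3_divergence: float = 0.05

    def validate(self, n_samples: int) -> None:
        if self.domain not in ("bacteria", "archaea"):
            raise ValueError(f"{self.genome_id}: unknown domain {self.domain!r}")
        if self.length_bp < 50_000:
            raise ValueError(f"{self.genome_id}: length_bp must be >= 50,000")
        if not 0.2 < self.gc_target < 0.8:
            raise ValueError(f"{self.genome_id}: gc_target must lie in (0.2, 0.8)")
        if len(self.abundance_profile) != n_samples:
            raise ValueError(
                f"{self.genome_id}: abundance_profile length "
                f"{len(self.abundance_profile)} != n_samples {n_samples}"
            )
        if np.any(np.asarray(self.abundance_profile) < 0):
            raise ValueError(f"{self.genome_id}: negative abundance")


@dataclass(frozen=True)
class SampleLabel:
    depth: Literal["shallow", "deep"]
    timepoint: str

    @property
    def sample_id(self) -> str:
        return f"{self.timepoint}_{self.depth}"


@dataclass
class CommunityDesign:
    n_genomes: int
    n_samples: int
    sample_labels: list[SampleLabel]
    depth_effect: float
    seed: int
    genome_specs: list[GenomeSpec]
    read_length: int = 250
    sample_depth_factors: np.ndarray = field(default_factory=lambda: np.array([]))

    def validate(self) -> None:
        if len(self.sample_labels) != self.n_samples:
            raise ValueError("sample_labels length must equal n_samples")
        if len(self.genome_specs) != self.n_genomes:
            raise ValueError("genome_specs length must equal n_genomes")
        if len(self.sample_depth_factors) != self.n_samples or np.any(
            np.asarray(self.sample_depth_factors) <= 0
        ):
            raise ValueError("sample_depth_factors must be positive, one per sample")
        for spec in self.genome_specs:
            spec.validate(self.n_samples)

    @property
    def sample_ids(self) -> list[str]:
        return [lab.sample_id for lab in self.sample_labels]

    @property
    def depths(self) -> np.ndarray:
        return np.array([lab.depth for lab in self.sample_labels])


@dataclass
class ScaffoldSet:
    """Emitted scaffolds plus their per-scaffold annotations.

    ``markers`` and ``rps3_loci`` use 1-based inclusive coordinates.
    """

    sequences: dict[str, str]
    table: pd.DataFrame  # scaffold_id index; genome_id, taxon, length, gc
    markers: pd.DataFrame  # scaffold_id, start, end, marker_id, genome_id
    rps3_loci: pd.DataFrame  # scaffold_id, start, end, rps3_id, genome_id

    @property
    def scaffold_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def gc(self) -> pd.Series:
        return self.table["gc"]

    @property
    def taxon_of(self) -> dict[str, str]:
        return self.table["taxon"].to_dict()


@dataclass
class TruthTable:
    scaffold_to_genome: dict[str, str]
    genome_domain: dict[str, str]
    genome_taxon: dict[str, str]
    genome_markers: dict[str, list[str]]
    genome_rps3: dict[str, str]
    abundance: pd.DataFrame  # genome_id x sample_id true mean fold coverage

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scaffold_id": sid,
                "genome_id": gid,
                "domain": self.genome_domain[gid],
                "taxon": self.genome_taxon[gid],
            }
            for sid, gid in self.scaffold_to_genome.items()
        ]
        return pd.DataFrame(rows).set_index("scaffold_id")


def _default_sample_labels(n_samples: int) -> list[SampleLabel]:
    # the ten-sample layout mirrors the study: four sampling days at two
    # depths plus two plot replicates -> six shallow (10-20 cm) and four
    # deep (30-40 cm) samples
    if n_samples == 10:
        return [
            SampleLabel("shallow", "pre_rain_p1"),
            SampleLabel("deep", "pre_rain_p1"),
            SampleLabel("shallow", "rain1_d4_p1"),
            SampleLabel("deep", "rain1_d4_p1"),
            SampleLabel("shallow", "rain1_d6_p1"),
            SampleLabel("deep", "rain1_d6_p1"),
            SampleLabel("shallow", "rain1_d6_p2"),
            SampleLabel("shallow", "rain2_d2_p1"),
            SampleLabel("deep", "rain2_d2_p1"),
            SampleLabel("shallow", "rain2_d2_p2"),
        ]
    labels = []
    for i in range(n_samples):
        depth = "shallow" if i % 2 == 0 or n_samples == 1 else "deep"
        labels.append(SampleLabel(depth, f"t{i // 2 + 1}_s{i + 1}"))
    return labels


def design_community(
    n_genomes: int,
    n_samples: int,
    seed: int,
    overrides: Mapping | None = None,
) -> CommunityDesign:
    """Draw a fully-populated community design, deterministically from ``seed``.

    ``overrides`` may set: ``genome_length`` (default 1,500,000 bp),
    ``depth_effect`` (default 1.0, natural-log abundance shift between depth
    groups), ``abundance_scale`` (default 20, mean fold coverage),
    ``archaea_fraction`` (default 0.2), ``series_log_sd`` (default 0.8,
    per-genome per-sample log-abundance variation),
    ``rps3_divergence`` (default 0.05), ``read_length`` (default 250),
    ``gc_range`` (default (0.35, 0.65)), ``sample_labels``.
    """
    if n_genomes < 1 or n_samples < 1:
        raise ValueError("n_genomes and n_samples must be positive")
    ov = dict(overrides or {})
    genome_length = int(ov.pop("genome_length", 1_500_000))
    depth_effect = float(ov.pop("depth_effect", 1.0))
    abundance_scale = float(ov.pop("abundance_scale", 20.0))
    archaea_fraction = float(ov.pop("archaea_fraction", 0.2))
    series_log_sd = float(ov.pop("series_log_sd", 0.8))
    rps3_divergence = float(ov.pop("rps3_divergence", 0.05))
    read_length = int(ov.pop("read_length", 250))
    gc_lo, gc_hi = ov.pop("gc_range", (0.35, 0.65))
    sample_labels = ov.pop("sample_labels", None) or _default_sample_labels(n_samples)
    if ov:
        raise ValueError(f"unknown design overrides: {sorted(ov)}")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    depth_sign = np.array(
        [0.5 if lab.depth == "shallow" else -0.5 for lab in sample_labels]
    )
    # per-sample data-size factors (sequencing yield differences)
    depth_factors = np.exp(rng.normal(0.0, 0.15, size=n_samples))

    n_arch = int(round(archaea_fraction * n_genomes))
    domains = ["archaea"] * n_arch + ["bacteria"] * (n_genomes - n_arch)
    rng.shuffle(domains)

    specs: list[GenomeSpec] = []
    bact_i = arch_i = 0
    for g in range(n_genomes):
        domain = domains[g]
        if domain == "archaea":
            taxon = _ARCHAEAL_TAXA[arch_i % len(_ARCHAEAL_TAXA)]
            arch_i += 1
        else:
            taxon = _BACTERIAL_TAXA[bact_i % len(_BACTERIAL_TAXA)]
            bact_i += 1
        mu = rng.normal(0.0, 0.6)
        depth_loading = rng.normal(0.0, 1.0)
        eps = rng.normal(0.0, series_log_sd, size=n_samples)
        log_ab = mu + depth_loading * depth_effect * depth_sign + eps
        profile = abundance_scale * np.exp(log_ab - 0.18)  # centre around the scale
        specs.append(
            GenomeSpec(
                genome_id=f"g{g + 1:03d}",
                domain=domain,
                taxon=taxon,
                length_bp=genome_length,
                gc_target=float(rng.uniform(gc_lo, gc_hi)),
                markov_order=3,
                transition_seed=int(rng.integers(0, 2**31 - 1)),
                abundance_profile=profile,
                rps3_divergence=rps3_divergence,
            )
        )

    design = CommunityDesign(
        n_genomes=n_genomes,
        n_samples=n_samples,
        sample_labels=list(sample_labels),
        depth_effect=depth_effect,
        seed=seed,
        genome_specs=specs,
        read_length=read_length,
        sample_depth_factors=depth_factors,
    )
    design.validate()
    return design


def _transition_cdfs(spec: GenomeSpec, perturbation: float = 0.6) -> np.ndarray:
    """Per-context cumulative transition probabilities (4**order x 4).

    Row logits are genome-seeded Gaussian perturbations; each row is then
    rescaled so its G+C mass equals the genome's GC target exactly, pinning
    genome GC while leaving the A/T and G/C splits (and hence the 4-mer
    signature) genome specific.
    """
    rng = np.random.default_rng(spec.transition_seed)
    n_ctx = 4**spec.markov_order
    logits = rng.normal(0.0, perturbation, size=(n_ctx, 4))
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    at = p[:, 0] + p[:, 3]
    gc = p[:, 1] + p[:, 2]
    p[:, 0] *= (1 - spec.gc_target) / at
    p[:, 3] *= (1 - spec.gc_target) / at
    p[:, 1] *= spec.gc_target / gc
    p[:, 2] *= spec.gc_target / gc
    return np.cumsum(p, axis=1)


def _markov_sequence(spec: GenomeSpec, rng: np.random.Generator) -> str:
    cdf = _transition_cdfs(spec)
    order = spec.markov_order
    n_ctx = 4**order
    mask = n_ctx - 1
    length = spec.length_bp
    us = rng.random(length)
    state = int(rng.integers(0, n_ctx))
    cdf_rows = [tuple(row) for row in cdf]
    out = [0] * length
    for i in range(length):
        row = cdf_rows[state]
        u = us[i]
        b = 0 if u < row[0] else (1 if u < row[1] else (2 if u < row[2] else 3))
        out[i] = b
        state = ((state << 2) | b) & mask
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    return lut[np.array(out, dtype=np.int64)].tobytes().decode("ascii")


def generate_genome_sequences(design: CommunityDesign) -> dict[str, str]:
    """Generate one DNA sequence per genome from its seeded Markov chain."""
    design.validate()
    seqs: dict[str, str] = {}
    for spec in design.genome_specs:
        rng = np.random.default_rng(
            np.random.SeedSequence((design.seed, spec.transition_seed, 1))
        )
        seqs[spec.genome_id] = _markov_sequence(spec, rng)
    return seqs


def _fragment_lengths(
    total: int,
    rng: np.random.Generator,
    median: float,
    sigma: float,
    min_len: int,
) -> list[int]:
    lengths: list[int] = []
    remaining = total
    while remaining >= min_len:
        L = int(rng.lognormal(np.log(median), sigma))
        L = max(min_len, min(L, remaining))
        lengths.append(L)
        remaining -= L
    return lengths


def _taxon_base_rps3(taxon: str, seed: int) -> str:
    # per-taxon base sequence shared by same-taxon genomes; stable digest so
    # results do not depend on interpreter hash randomization
    import hashlib

    digest = int.from_bytes(hashlib.sha256(taxon.encode()).digest()[:4], "big")
    rng = np.random.default_rng(np.random.SeedSequence((seed, digest, 7)))
    return "".join(rng.choice(list(_AA), size=RPS3_LENGTH))


def _mutate_aa(base: str, divergence: float, rng: np.random.Generator) -> str:
    seq = list(base)
    hits = np.flatnonzero(rng.random(len(seq)) < divergence)
    for i in hits:
        choices = [a for a in _AA if a != seq[i]]
        seq[i] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def fragment_and_cover(
    design: CommunityDesign,
    genomes: Mapping[str, str],
    min_scaffold_len: int = 1000,
    scaffold_len_median: float = 12_000.0,
    scaffold_len_sigma: float = 0.45,
    dispersion: float = 0.2,
    marker_len: int = 900,
) -> tuple[ScaffoldSet, CoverageTable, TruthTable, dict[str, str]]:
    """Fragment genomes into scaffolds, simulate coverage, plant annotations.

    Scaffold lengths are log-normal (median ``scaffold_len_median``,
    ``scaffold_len_sigma`` on the log scale) truncated below at
    ``min_scaffold_len``; a trailing remainder shorter than the minimum is
    dropped. Per-scaffold, per-sample read counts are negative binomial with
    mean ``abundance * depth_factor * length / read_length`` and variance
    ``mean + dispersion * mean**2``, converted back to fold coverage.
    Single-copy markers (51 bacterial / 38 archaeal) and one rpS3 locus per
    genome are placed on uniformly random scaffolds with 1-based inclusive
    coordinates.

    Returns ``(scaffolds, coverage, truth, rps3_sequences)``.
    """
    design.validate()
    missing = [s.genome_id for s in design.genome_specs if s.genome_id not in genomes]
    if missing:
        raise ValueError(f"genomes not generated for design: {missing}")

    sequences: dict[str, str] = {}
    rows = []
    marker_rows = []
    rps3_rows = []
    scaffold_to_genome: dict[str, str] = {}
    genome_markers: dict[str, list[str]] = {}
    genome_rps3: dict[str, str] = {}
    rps3_seqs: dict[str, str] = {}
    cov_blocks = []
    cov_index: list[str] = []

    depth_factors = np.asarray(design.sample_depth_factors, dtype=float)

    for spec in design.genome_specs:
        gid = spec.genome_id
        seq = genomes[gid]
        rng = np.random.default_rng(np.random.SeedSequence((design.seed, spec.transition_seed, 2)))
        lengths = _fragment_lengths(
            len(seq), rng, scaffold_len_median, scaffold_len_sigma, min_scaffold_len
        )
        if not lengths:
            raise ValueError(
                f"genome {gid} (length {len(seq)}) too short to yield a scaffold "
                f">= {min_scaffold_len} bp"
            )
        sids = []
        pos = 0
        for k, L in enumerate(lengths):
            sid = f"{gid}_s{k + 1:04d}"
            frag = seq[pos : pos + L]
            pos += L
            sequences[sid] = frag
            gc = (frag.count("G") + frag.count("C")) / L
            rows.append(
                {"scaffold_id": sid, "genome_id": gid, "taxon": spec.taxon,
                 "length": L, "gc": gc}
            )
            scaffold_to_genome[sid] = gid
            sids.append(sid)

        # negative-binomial read counts -> fold coverage
        L_arr = np.array(lengths, dtype=float)
        mean_cov = np.outer(np.ones(len(sids)), spec.abundance_profile * depth_factors)
        mean_reads = mean_cov * (L_arr[:, None] / design.read_length)
        if dispersion > 0:
            n_param = 1.0 / dispersion
            p_param = n_param / (n_param + mean_reads)
            reads = rng.negative_binomial(n_param, p_param)
        else:
            reads = rng.poisson(mean_reads)
        cov_blocks.append(reads * design.read_length / L_arr[:, None])
        cov_index.extend(sids)

        # plant single-copy markers on uniformly random scaffolds
        marker_ids = (
            BACTERIAL_MARKER_IDS if spec.domain == "bacteria" else ARCHAEAL_MARKER_IDS
        )
        homes = rng.integers(0, len(sids), size=len(marker_ids))
        for mid, h in zip(marker_ids, homes):
            sL = lengths[h]
            mL = min(marker_len, sL)
            start = int(rng.integers(1, sL - mL + 2))
            marker_rows.append(
                {"scaffold_id": sids[h], "start": start, "end": start + mL - 1,
                 "marker_id": mid, "genome_id": gid}
            )
        genome_markers[gid] = list(marker_ids)

        # one rpS3 locus per genome
        rid = f"{gid}|rps3"
        h = int(rng.integers(0, len(sids)))
        sL = lengths[h]
        rL = min(3 * RPS3_LENGTH, sL)
        start = int(rng.integers(1, sL - rL + 2))
        rps3_rows.append(
            {"scaffold_id": sids[h], "start": start, "end": start + rL - 1,
             "rps3_id": rid, "genome_id": gid}
        )
        genome_rps3[gid] = rid
        base = _taxon_base_rps3(spec.taxon, design.seed)
        rps3_seqs[rid] = _mutate_aa(base, spec.rps3_divergence, rng)

    table = pd.DataFrame(rows).set_index("scaffold_id")
    coverage = CoverageTable(
        pd.DataFrame(np.vstack(cov_blocks), index=cov_index, columns=design.sample_ids),
        normalized=False,
    )
    truth = TruthTable(
        scaffold_to_genome=scaffold_to_genome,
        genome_domain={s.genome_id: s.domain for s in design.genome_specs},
        genome_taxon={s.genome_id: s.taxon for s in design.genome_specs},
        genome_markers=genome_markers,
        genome_rps3=genome_rps3,
        abundance=pd.DataFrame(
            np.vstack([s.abundance_profile for s in design.genome_specs]),
            index=[s.genome_id for s in design.genome_specs],
            columns=design.sample_ids,
        ),
    )
    scaffolds = ScaffoldSet(
        sequences=sequences,
        table=table,
        markers=pd.DataFrame(
            marker_rows, columns=["scaffold_id", "start", "end", "marker_id", "genome_id"]
        ),
        rps3_loci=pd.DataFrame(
            rps3_rows, columns=["scaffold_id", "start", "end", "rps3_id", "genome_id"]
        ),
    )
    return scaffolds, coverage, truth, rps3_seqs
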