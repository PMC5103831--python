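"""Seeded end-to-end evaluation studies on synthetic communities.

These drive both the test suite and the reproduction script: parameter
recovery of the ESOM binning against the generator's truth table, recovery
of the two-depth community structure in Bray-Curtis PCoA space, and the
empirical false-discovery rate of the BH-corrected ANOVA screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import community_profile as cp
from . import esom, features, group_stats
from . import synthetic_community as sc

__all__ = [
    "BinningRun",
    "binning_recovery",
    "binning_recovery_study",
    "depth_separation_study",
    "fdr_simulation",
]


@dataclass
class BinningRun:
    seed: int
    ari: float
    n_bins: int
    unbinned_fraction: float
    n_scaffolds: int
    draft_quality_fraction: float


def binning_recovery(
    seed: int,
    n_genomes: int = 20,
    n_samples: int = 10,
    overrides: dict | None = None,
    block_weights: tuple[float, float] = (0.1, 1.0),
    epochs: int = 20,
    u_threshold_quantile: float = 0.6,
    min_bin_scaffolds: int = 5,
) -> BinningRun:
    """Generate one community, bin it with default settings, score vs truth."""
    design = sc.design_community(n_genomes, n_samples, seed, overrides=overrides)
    genomes = sc.generate_genome_sequences(design)
    scaffolds, coverage, truth, _ = sc.fragment_and_cover(design, genomes)
    normalized = features.normalize_coverage(coverage)
    fm = features.build_feature_matrix(
        scaffolds.sequences, normalized, block_weights=block_weights
    )
    model = esom.train_esom(fm, epochs=epochs, seed=seed)
    umatrix = esom.compute_umatrix(model)
    assignment = esom.delineate_bins(
        model, umatrix, u_threshold_quantile, min_bin_scaffolds
    )
    metrics = esom.evaluate_binning(assignment, truth.scaffold_to_genome)

    from . import bin_qc

    n_draft = 0
    bins = assignment.bins
    for members in bins.values():
        q = bin_qc.assess_bin(members, scaffolds.markers)
        n_draft += q.draft_quality
    return BinningRun(
        seed=seed,
        ari=metrics.ari,
        n_bins=len(bins),
        unbinned_fraction=metrics.unbinned_fraction,
        n_scaffolds=len(fm.scaffold_ids),
        draft_quality_fraction=n_draft / len(bins) if bins else 0.0,
    )


def binning_recovery_study(base_seed: int, n_seeds: int = 5, **kwargs) -> list[BinningRun]:
    return [binning_recovery(base_seed + i, **kwargs) for i in range(n_seeds)]


def depth_separation_study(
    base_seed: int,
    n_seeds: int = 50,
    n_genomes: int = 20,
    n_samples: int = 10,
    genome_length: int = 60_000,
) -> float:
    """Fraction of seeds where mean within-depth PCoA distance < between-depth.

    Runs the full profiling chain per seed — genome generation, rpS3
    clustering, percent abundances, Bray-Curtis, 2-axis PCoA — on short
    genomes (binning is not involved, so only the rpS3-bearing scaffolds'
    coverage matters).
    """
    hits = 0
    for i in range(n_seeds):
        design = sc.design_community(
            n_genomes, n_samples, base_seed + i, overrides={"genome_length": genome_length}
        )
        genomes = sc.generate_genome_sequences(design)
        scaffolds, coverage, _, rps3 = sc.fragment_and_cover(
            design, genomes, scaffold_len_median=8000
        )
        normalized = features.normalize_coverage(coverage)
        mapping = dict(
            zip(scaffolds.rps3_loci["rps3_id"], scaffolds.rps3_loci["scaffold_id"])
        )
        clusters, _ = cp.cluster_species(rps3)
        table = cp.abundance_table(clusters, normalized, mapping)
        ordination = cp.pcoa(cp.bray_curtis_matrix(table), k=2)
        xy = ordination.coordinates.to_numpy()
        depths = design.depths
        within, between = [], []
        for a in range(n_samples):
            for b in range(a + 1, n_samples):
                d = float(np.linalg.norm(xy[a] - xy[b]))
                (within if depths[a] == depths[b] else between).append(d)
        hits += np.mean(within) < np.mean(between)
    return hits / n_seeds


def fdr_simulation(
    base_seed: int,
    n_seeds: int = 50,
    n_analytes: int = 1000,
    alt_fraction: float = 0.10,
    effect_sd: float = 3.0,
    n_groups: int = 3,
    n_replicates: int = 3,
    q_threshold: float = 0.05,
) -> dict:
    """Empirical FDR of the BH-corrected ANOVA screen.

    Per seed: ``n_analytes`` analytes with ``n_groups`` groups of
    ``n_replicates`` (triplicate) measurements; a fraction carry a true
    shift of ``effect_sd`` standard deviations in one group. Returns the
    mean realized FDR at q <= ``q_threshold`` and the mean power.
    """
    fdrs, powers = [], []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        n_alt = int(round(alt_fraction * n_analytes))
        is_alt = np.zeros(n_analytes, dtype=bool)
        is_alt[rng.choice(n_analytes, size=n_alt, replace=False)] = True
        pvals = np.empty(n_analytes)
        for a in range(n_analytes):
            groups = rng.normal(0.0, 1.0, size=(n_groups, n_replicates))
            if is_alt[a]:
                groups[0] += effect_sd
            pvals[a] = group_stats.one_way_anova(list(groups)).p_value
        q = group_stats.bh_adjust(pvals)
        called = q <= q_threshold
        n_called = called.sum()
        fdrs.append((called & ~is_alt).sum() / n_called if n_called else 0.0)
        powers.append((called & is_alt).sum() / max(n_alt, 1))
    return {
        "fdr": float(np.mean(fdrs)),
        "power": float(np.mean(powers)),
        "n_seeds": n_seeds,
        "n_analytes": n_analytes,
    }
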