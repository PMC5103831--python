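"""Toroidal emergent self-organizing map (ESOM) binning.

A large SOM is trained on the combined coverage + tetranucleotide feature
matrix; the map's U-matrix (per-neuron mean distance to its eight toroidal
grid neighbors) forms a topography in which genome bins appear as low
"valleys" separated by high "ridges". Bins are delineated automatically as
connected components of valley neurons, replacing interactive polygon
curation around U-matrix structure.

Training is batch SOM: each epoch assigns every row to its best matching
unit (BMU) and then moves each neuron to the Gaussian-neighborhood-weighted
mean of all rows, with the neighborhood radius decaying linearly between
epochs. With radius 0 the update degenerates to one Lloyd k-means step with
neurons as centroids, which anchors the implementation to an independent
oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .features import FeatureMatrix

__all__ = [
    "UNBINNED",
    "SomConfig",
    "SomModel",
    "BinAssignment",
    "BinningMetrics",
    "default_grid",
    "train_esom",
    "compute_umatrix",
    "delineate_bins",
    "evaluate_binning",
]

UNBINNED = "UNBINNED"


@dataclass(frozen=True)
class SomConfig:
    rows: int
    cols: int
    epochs: int
    radius_start: float
    radius_end: float
    seed: int


@dataclass
class SomModel:
    """A trained toroidal SOM.

    ``weights`` has shape (rows, cols, n_features); ``bmu`` maps each
    training row id to its best-matching grid cell.
    """

    config: SomConfig
    weights: np.ndarray
    bmu: dict[str, tuple[int, int]]
    feature_names: list[str] = field(default_factory=list)
    quantization_error: float = float("nan")
    initial_quantization_error: float = float("nan")

    @property
    def rows(self) -> int:
        return self.config.rows

    @property
    def cols(self) -> int:
        return self.config.cols

    @property
    def flat_weights(self) -> np.ndarray:
        return self.weights.reshape(self.rows * self.cols, -1)


@dataclass
class BinAssignment:
    """Partition of scaffolds into named bins plus UNBINNED."""

    labels: dict[str, str]

    @property
    def bins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, lab in self.labels.items():
            if lab != UNBINNED:
                out.setdefault(lab, []).append(sid)
        return out

    @property
    def unbinned(self) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == UNBINNED]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scaffold_id": list(self.labels), "bin": list(self.labels.values())}
        ).set_index("scaffold_id")


@dataclass
class BinningMetrics:
    ari: float
    per_bin: pd.DataFrame  # bin, best_genome, precision, recall, size
    unbinned_fraction: float


def default_grid(n_rows: int, aspect: float = 1.6) -> tuple[int, int]:
    """Emergent-scale grid: ~2 neurons per training row, aspect 1:1.6.

    Emergent maps need many more neurons than clusters so that every cluster
    territory spans dozens of cells and territories are separated by
    interpolation zones whose high U-matrix values form closed ridges; with
    too few neurons per territory the valleys merge. Neuron count is clamped
    to [100, 4096].
    """
    neurons = min(max(2.0 * n_rows, 100.0), 4096.0)
    rows = max(2, int(round(np.sqrt(neurons / aspect))))
    cols = max(2, int(round(neurons / rows)))
    return rows, cols


def _toroidal_sq_grid_distances(rows: int, cols: int) -> np.ndarray:
    """(rows*cols, rows*cols) squared Euclidean grid distances with wraparound."""
    r = np.arange(rows)
    c = np.arange(cols)
    dr = np.abs(r[:, None] - r[None, :])
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(c[:, None] - c[None, :])
    dc = np.minimum(dc, cols - dc)
    d2 = (dr[:, None, :, None] ** 2 + dc[None, :, None, :] ** 2).astype(float)
    return d2.reshape(rows * cols, rows * cols)


def _bmu_indices(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flat BMU index and squared distance for every row of ``x``."""
    # ||x-w||^2 = ||x||^2 - 2 x.w + ||w||^2 ; argmin only needs the last two terms
    cross = x @ w.T
    wn = (w**2).sum(axis=1)
    d2 = wn[None, :] - 2.0 * cross
    idx = np.argmin(d2, axis=1)
    best = d2[np.arange(len(x)), idx] + (x**2).sum(axis=1)
    return idx, np.maximum(best, 0.0)


def train_esom(
    matrix: FeatureMatrix,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 20,
    radius_start: float | None = None,
    radius_end: float = 1.0,
    seed: int = 0,
) -> SomModel:
    """Train a batch SOM on the feature matrix.

    Weights are initialized by seeded sampling of training rows. Each epoch
    computes all BMUs, then replaces every neuron by the neighborhood-kernel
    weighted mean of the data, ``w_k = sum_i h(bmu_i, k) x_i / sum_i h``,
    with a Gaussian kernel ``h = exp(-d_grid^2 / (2 sigma^2))`` on toroidal
    grid distance and sigma decaying linearly from ``radius_start`` (default
    half the larger grid dimension) to ``radius_end``. ``sigma = 0`` reduces
    the kernel to an indicator, i.e. a Lloyd k-means step.
    """
    x = np.asarray(matrix.values, dtype=float)
    if x.size == 0:
        raise ValueError("empty feature matrix")
    if not np.isfinite(x).all():
        raise ValueError("NaN or infinite values in feature matrix")
    n = x.shape[0]
    if rows is None or cols is None:
        rows, cols = default_grid(n)
    if rows * cols < 4:
        raise ValueError("grid must have at least 4 neurons")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if rows * cols > 50 * n:
        warnings.warn(
            f"grid of {rows * cols} neurons is very large for {n} rows",
            stacklevel=2,
        )
    if radius_start is None:
        radius_start = max(rows, cols) / 2.0

    rng = np.random.default_rng(seed)
    n_neurons = rows * cols
    init_idx = rng.choice(n, size=n_neurons, replace=n < n_neurons)
    w = x[init_idx].astype(float).copy()

    d2_grid = _toroidal_sq_grid_distances(rows, cols)
    _, d0 = _bmu_indices(x, w)
    init_qe = float(np.sqrt(d0).mean())

    bmu_flat = np.zeros(n, dtype=int)
    for epoch in range(epochs):
        frac = epoch / (epochs - 1) if epochs > 1 else 1.0
        sigma = radius_start + (radius_end - radius_start) * frac
        bmu_flat, _ = _bmu_indices(x, w)
        if sigma <= 0:
            h = np.eye(n_neurons)
        else:
            h = np.exp(-d2_grid / (2.0 * sigma**2))
        # per-neuron sums of assigned rows, then kernel smoothing
        counts = np.bincount(bmu_flat, minlength=n_neurons).astype(float)
        sums = np.zeros((n_neurons, x.shape[1]))
        np.add.at(sums, bmu_flat, x)
        numer = h @ sums
        denom = h @ counts
        upd = denom > 0
        w[upd] = numer[upd] / denom[upd, None]

    bmu_flat, d_final = _bmu_indices(x, w)
    qe = float(np.sqrt(d_final).mean())
    bmu = {
        sid: (int(b // cols), int(b % cols))
        for sid, b in zip(matrix.scaffold_ids, bmu_flat)
    }
    return SomModel(
        config=SomConfig(rows, cols, epochs, float(radius_start), float(radius_end), seed),
        weights=w.reshape(rows, cols, -1),
        bmu=bmu,
        feature_names=matrix.column_names,
        quantization_error=qe,
        initial_quantization_error=init_qe,
    )


_NEIGH = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def compute_umatrix(model: SomModel) -> np.ndarray:
    """Mean Euclidean distance from each neuron to its 8 toroidal neighbors."""
    w = model.weights
    rows, cols = model.rows, model.cols
    u = np.zeros((rows, cols))
    for dr, dc in _NEIGH:
        shifted = np.roll(np.roll(w, -dr, axis=0), -dc, axis=1)
        u += np.sqrt(((w - shifted) ** 2).sum(axis=2))
    return u / len(_NEIGH)


def _valley_components(valley: np.ndarray) -> np.ndarray:
    """Label 8-connected components of True cells on a toroidal grid.

    Returns an int grid: -1 for ridge cells, component id >= 0 otherwise.
    """
    rows, cols = valley.shape
    labels = np.full((rows, cols), -1, dtype=int)
    next_label = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if not valley[r0, c0] or labels[r0, c0] != -1:
                continue
            stack = [(r0, c0)]
            labels[r0, c0] = next_label
            while stack:
                r, c = stack.pop()
                for dr, dc in _NEIGH:
                    rr, cc = (r + dr) % rows, (c + dc) % cols
                    if valley[rr, cc] and labels[rr, cc] == -1:
                        labels[rr, cc] = next_label
                        stack.append((rr, cc))
            next_label += 1
    return labels


def delineate_bins(
    model: SomModel,
    umatrix: np.ndarray,
    u_threshold_quantile: float = 0.6,
    min_bin_scaffolds: int = 5,
) -> BinAssignment:
    """Cut the U-matrix topography into genome bins.

    Neurons whose U-matrix value falls below the given quantile of all U
    values are valley cells; toroidal 8-connected components of valley cells
    are candidate bins, and every scaffold inherits its BMU's component.
    Scaffolds whose BMU is a ridge cell, or whose component holds fewer than
    ``min_bin_scaffolds`` scaffolds, are left UNBINNED.
    """
    if not 0 < u_threshold_quantile < 1:
        raise ValueError("u_threshold_quantile must lie in (0, 1)")
    umatrix = np.asarray(umatrix)
    if umatrix.shape != (model.rows, model.cols):
        raise ValueError("U-matrix shape does not match model grid")
    threshold = np.quantile(umatrix, u_threshold_quantile)
    valley = umatrix < threshold
    comp = _valley_components(valley)

    comp_members: dict[int, list[str]] = {}
    for sid, (r, c) in model.bmu.items():
        comp_members.setdefault(int(comp[r, c]), []).append(sid)

    kept = sorted(
        c for c, members in comp_members.items()
        if c >= 0 and len(members) >= min_bin_scaffolds
    )
    names = {c: f"bin_{i + 1:03d}" for i, c in enumerate(kept)}
    labels = {
        sid: names.get(int(comp[r, c]), UNBINNED) for sid, (r, c) in model.bmu.items()
    }
    return BinAssignment(labels=labels)


def plot_umatrix(umatrix: np.ndarray, path, assignment: BinAssignment | None = None) -> None:
    """Save a U-matrix heat map (optionally annotated with bin count) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(np.asarray(umatrix), cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="mean distance to toroidal neighbors")
    title = "U-matrix"
    if assignment is not None:
        title += f" ({len(assignment.bins)} bins)"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def evaluate_binning(assignment: BinAssignment, truth: dict[str, str]) -> BinningMetrics:
    """Score an assignment against genome truth labels.

    ARI is computed over binned scaffolds only; per-bin precision/recall are
    against each bin's best-matching genome. The unbinned fraction is
    reported separately.
    """
    missing = [s for s in assignment.labels if s not in truth]
    if missing:
        raise ValueError(f"scaffolds without truth label: {missing[:10]}")
    binned = [(s, lab) for s, lab in assignment.labels.items() if lab != UNBINNED]
    if binned:
        pred = [lab for _, lab in binned]
        true = [truth[s] for s, _ in binned]
        ari = float(adjusted_rand_score(true, pred))
    else:
        ari = float("nan")

    genome_sizes: dict[str, int] = {}
    for g in truth.values():
        genome_sizes[g] = genome_sizes.get(g, 0) + 1
    rows = []
    for bin_id, members in assignment.bins.items():
        votes: dict[str, int] = {}
        for s in members:
            votes[truth[s]] = votes.get(truth[s], 0) + 1
        best = max(votes, key=lambda g: votes[g])
        rows.append(
            {
                "bin": bin_id,
                "best_genome": best,
                "precision": votes[best] / len(members),
                "recall": votes[best] / genome_sizes[best],
                "size": len(members),
            }
        )
    per_bin = pd.DataFrame(rows, columns=["bin", "best_genome", "precision", "recall", "size"])
    unb = len(assignment.unbinned) / len(assignment.labels) if assignment.labels else 0.0
    return BinningMetrics(ari=ari, per_bin=per_bin, unbinned_fraction=unb)
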