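"""Anatomical network (connectome) handling.

The model couples neural ensembles through a weighted multigraph with two
edge attributes: fiber density ``weights`` (dimensionless, symmetric,
nonnegative) and Euclidean ``distances`` between region barycenters (mm).
Distances are converted into interaction delays given a spike-propagation
velocity.  A synthetic generator provides hemispherically symmetric
connectomes for offline testing in place of tractography-derived ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Connectome",
    "load_connectome",
    "save_connectome",
    "load_matrix",
    "save_matrix",
    "normalize_weights",
    "synthesize_connectome",
    "compute_delays",
]

#: velocity value meaning "no interaction delays" (instantaneous coupling)
INFINITE_SPEED = np.inf


@dataclass
class Connectome:
    """Weighted multigraph of neural fibers between brain regions.

    Attributes
    ----------
    n_regions
        Number of regions (ensembles) ``E``.
    weights
        ``E x E`` symmetric nonnegative fiber-density matrix, zero diagonal.
    distances
        ``E x E`` symmetric Euclidean distance matrix in millimeters.
    labels
        Region names, length ``E``.
    homotopic_pairs
        Optional perfect matching of region indices into left/right
        mirror pairs, used to tie local couplings across hemispheres.
    """

    n_regions: int
    weights: np.ndarray
    distances: np.ndarray
    labels: list[str] = field(default_factory=list)
    homotopic_pairs: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if not self.labels:
            self.labels = [f"region_{i:03d}" for i in range(self.n_regions)]
        self.validate()

    def validate(self) -> None:
        E = self.n_regions
        for name, m in (("weights", self.weights), ("distances", self.distances)):
            if m.shape != (E, E):
                raise ValueError(f"{name} must be {E}x{E}, got {m.shape}")
            bad = np.argwhere(~np.isfinite(m))
            if bad.size:
                i, j = bad[0]
                raise ValueError(f"{name} has non-finite entry at ({i}, {j})")
            bad = np.argwhere(m < 0)
            if bad.size:
                i, j = bad[0]
                raise ValueError(f"{name} has negative entry at ({i}, {j})")
            if not np.allclose(m, m.T, rtol=0, atol=1e-12 * max(1.0, m.max(initial=0.0))):
                raise ValueError(f"{name} is not symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} has nonzero diagonal")
        if len(self.labels) != E:
            raise ValueError(f"expected {E} labels, got {len(self.labels)}")
        if self.homotopic_pairs is not None:
            flat = [i for pair in self.homotopic_pairs for i in pair]
            if sorted(flat) != list(range(E)):
                raise ValueError("homotopic_pairs is not a perfect matching over regions")


def load_matrix(path: str | Path) -> np.ndarray:
    """Read a delimited-text square matrix (whitespace or comma separated)."""
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        m = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse as a numeric matrix ({exc})") from exc
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is not square, shape {m.shape}")
    return m


def save_matrix(m: np.ndarray, path: str | Path) -> None:
    """Write a matrix as whitespace-delimited text with 9 significant digits."""
    np.savetxt(path, np.asarray(m, dtype=float), fmt="%.9g")


def _check_entries(name: str, m: np.ndarray) -> None:
    bad = np.argwhere(~np.isfinite(m))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{name} has non-finite entry at ({i}, {j})")
    bad = np.argwhere(m < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{name} has negative entry at ({i}, {j}): {m[i, j]}")


def load_connectome(
    weights_path: str | Path,
    distances_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> Connectome:
    """Load a connectome from two delimited-text matrix files.

    The weight matrix is made symmetric by averaging with its transpose and
    its diagonal is zeroed.  An optional JSON sidecar supplies region labels
    and homotopic pairing.
    """
    W = load_matrix(weights_path)
    D = load_matrix(distances_path)
    if W.shape != D.shape:
        raise ValueError(
            f"weights {W.shape} and distances {D.shape} have different sizes"
        )
    _check_entries("weights", W)
    _check_entries("distances", D)
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    labels: list[str] = []
    pairs = None
    if sidecar_path is not None:
        meta = json.loads(Path(sidecar_path).read_text())
        labels = list(meta.get("labels", []))
        if meta.get("homotopic_pairs") is not None:
            pairs = [tuple(p) for p in meta["homotopic_pairs"]]
    return Connectome(W.shape[0], W, D, labels=labels, homotopic_pairs=pairs)


def save_connectome(c: Connectome, weights_path, distances_path, sidecar_path=None) -> None:
    save_matrix(c.weights, weights_path)
    save_matrix(c.distances, distances_path)
    if sidecar_path is not None:
        meta = {
            "labels": c.labels,
            "homotopic_pairs": [list(p) for p in c.homotopic_pairs]
            if c.homotopic_pairs is not None
            else None,
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def normalize_weights(c: Connectome, mode: str = "mean_edge") -> Connectome:
    """Rescale fiber densities to a unit-mean convention.

    ``mode="mean_edge"`` (default) divides by the mean of the nonzero
    strict-upper-triangle weights so the average existing edge weight is 1.
    ``mode="mean_degree"`` divides by the average row sum (node strength)
    instead.  Both preserve the zero pattern and symmetry, and both are
    idempotent.
    """
    W = c.weights
    iu = np.triu_indices(c.n_regions, k=1)
    edges = W[iu]
    nz = edges[edges > 0]
    if nz.size == 0:
        raise ValueError("cannot normalize an all-zero weight matrix")
    if mode == "mean_edge":
        scale = nz.mean()
    elif mode == "mean_degree":
        scale = W.sum(axis=1).mean()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(c, weights=W / scale)


def synthesize_connectome(n_regions: int, seed: int) -> Connectome:
    """Generate a random hemispherically symmetric connectome.

    ``n_regions/2`` barycenters are drawn uniformly in one half of a
    140 x 180 x 120 mm bounding box (MNI-like extents) and mirrored across
    the midsagittal plane, producing homotopic pairs.  Fiber densities
    follow the well-documented exponential decay of connection strength
    with distance (length scale 40 mm) with multiplicative lognormal
    jitter; the weakest 20% of edges are removed and the result is
    rescaled to unit mean edge weight.  Deterministic for a given seed.
    """
    if n_regions < 4 or n_regions % 2:
        raise ValueError("n_regions must be an even integer >= 4")
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    # left hemisphere occupies x in [5, 65]; mirror across x = 70
    pts_left = rng.uniform([5.0, 0.0, 0.0], [65.0, 180.0, 120.0], size=(half, 3))
    pts_right = pts_left.copy()
    pts_right[:, 0] = 140.0 - pts_right[:, 0]
    pts = np.vstack([pts_left, pts_right])
    diff = pts[:, None, :] - pts[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    W = np.exp(-D / 40.0)
    jitter = rng.lognormal(mean=0.0, sigma=0.5, size=(n_regions, n_regions))
    W = W * jitter
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    # prune the weakest fifth of the edges
    iu = np.triu_indices(n_regions, k=1)
    edges = W[iu]
    cutoff = np.quantile(edges, 0.2)
    W[W <= cutoff] = 0.0
    W = 0.5 * (W + W.T)  # pruning preserved symmetry; re-assert exactly
    labels = [f"L{i:02d}" for i in range(half)] + [f"R{i:02d}" for i in range(half)]
    pairs = [(i, i + half) for i in range(half)]
    c = Connectome(n_regions, W, D, labels=labels, homotopic_pairs=pairs)
    return normalize_weights(c)


def compute_delays(c: Connectome, v: float) -> np.ndarray:
    """Interaction delays tau = D / v in seconds (distances are mm).

    ``v`` is the spike-propagation velocity in m/s; ``np.inf`` (the
    infinite-speed sentinel) yields all-zero delays.
    """
    if np.isinf(v):
        return np.zeros_like(c.distances)
    if not v > 0:
        raise ValueError(f"velocity must be positive or infinite, got {v}")
    return c.distances * 1e-3 / v
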