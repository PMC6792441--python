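"""A small self-organizing map over tetranucleotide profiles.

Stands in for the "ESOM" style of composition binning: contig 4-mer
frequency vectors are projected onto a rectangular, optionally toroidal
node grid trained with the classic online Kohonen update (Gaussian
neighbourhood, linearly decaying learning rate and radius).  No installed
package provides a SOM, so the update rule is implemented here directly;
it is deliberately plain and fully deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SOMGrid", "train_som"]


@dataclass
class SOMGrid:
    width: int
    height: int
    weights: np.ndarray = field(repr=False)  # (width*height, dim)
    toroidal: bool = True
    epochs: int = 0
    seed: int = 0
    lr_start: float = 0.5
    lr_end: float = 0.01

    @property
    def n_nodes(self) -> int:
        return self.width * self.height

    def node_xy(self, node: int) -> tuple[int, int]:
        return node % self.width, node // self.width

    def _grid_dist2(self) -> np.ndarray:
        """Pairwise squared grid distances between nodes (toroidal aware)."""
        xs = np.arange(self.n_nodes) % self.width
        ys = np.arange(self.n_nodes) // self.width
        dx = np.abs(xs[:, None] - xs[None, :])
        dy = np.abs(ys[:, None] - ys[None, :])
        if self.toroidal:
            dx = np.minimum(dx, self.width - dx)
            dy = np.minimum(dy, self.height - dy)
        return (dx**2 + dy**2).astype(float)

    def best_matching_units(self, profiles) -> list[int]:
        X = _as_matrix(profiles)
        d = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return [int(i) for i in d.argmin(axis=1)]

    def quantization_error(self, profiles) -> float:
        """Mean Euclidean distance of each profile to its best node."""
        X = _as_matrix(profiles)
        d = np.sqrt(((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2))
        return float(d.min(axis=1).mean())

    def u_matrix(self) -> np.ndarray:
        """Mean distance of each node's weights to its grid neighbours."""
        out = np.zeros((self.height, self.width))
        for node in range(self.n_nodes):
            x, y = self.node_xy(node)
            dists = []
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nx, ny = x + dx, y + dy
                if self.toroidal:
                    nx, ny = nx % self.width, ny % self.height
                elif not (0 <= nx < self.width and 0 <= ny < self.height):
                    continue
                other = ny * self.width + nx
                dists.append(
                    np.linalg.norm(self.weights[node] - self.weights[other])
                )
            out[y, x] = np.mean(dists)
        return out


def _as_matrix(profiles) -> np.ndarray:
    rows = [getattr(p, "freqs", p) for p in profiles]
    return np.asarray(rows, dtype=float)


def train_som(
    profiles,
    width: int = 20,
    height: int = 12,
    epochs: int = 10,
    seed: int = 0,
    toroidal: bool = True,
    lr_start: float = 0.5,
    lr_end: float = 0.01,
) -> SOMGrid:
    """Train a SOM on tetranucleotide profiles.

    Weights are initialized from randomly drawn data points plus small
    jitter; samples are revisited in a fresh random order each epoch.
    Deterministic for a fixed seed.
    """
    X = _as_matrix(profiles)
    if X.size == 0:
        raise ValueError("train_som: empty profile list")
    n, dim = X.shape
    if n < width * height:
        warnings.warn(
            f"training a {width}x{height} SOM on only {n} profiles; "
            "consider a smaller grid",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    init_idx = rng.integers(0, n, size=width * height)
    weights = X[init_idx] + rng.normal(0, 1e-4, size=(width * height, dim))
    grid = SOMGrid(width, height, weights, toroidal, epochs, seed,
                   lr_start, lr_end)
    dist2 = grid._grid_dist2()
    radius_start = max(width, height) / 2.0
    radius_end = 1.0
    total_steps = max(1, epochs * n)
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            t = step / total_steps
            lr = lr_start + (lr_end - lr_start) * t
            radius = radius_start + (radius_end - radius_start) * t
            x = X[i]
            bmu = int(((weights - x) ** 2).sum(axis=1).argmin())
            h = np.exp(-dist2[bmu] / (2 * radius * radius))
            weights += (lr * h)[:, None] * (x - weights)
            step += 1
    grid.weights = weights
    return grid


def plot_u_matrix(grid: SOMGrid, path) -> None:
    """Write a U-matrix heat map (distance structure of the trained map)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(grid.u_matrix(), cmap="viridis")
    fig.colorbar(im, ax=ax, label="mean neighbour distance")
    ax.set_title(f"{grid.width}x{grid.height} SOM U-matrix")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
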