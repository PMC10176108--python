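"""Consensus co-clustering of peptide trajectories with self-organizing maps.

A single SOM run assigns each peptide trajectory to its best-matching unit
on a small (default 5x5) hexagonal grid.  Because the unit layout depends on
the random initialization, the map is retrained many times (default 1,000)
from random starting weights, and the fraction of restarts in which two
peptides share a best-matching unit is recorded in a symmetric co-clustering
frequency matrix.  Hierarchical clustering of that matrix (Euclidean
distance, average linkage) yields consensus peptide clusters.

Training is batch-mode with a Gaussian neighborhood whose radius decays
linearly over epochs; batch updates are deterministic given the
initialization, so the restart ensemble is the only randomness source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist
from scipy import stats

from .types import ConfigError, PhosphoMatrix, PtyrlinkError
from .temporal import line_trajectories


@dataclass(frozen=True)
class SomConfig:
    grid_rows: int = 5
    grid_cols: int = 5
    lattice: str = "hexagonal"
    metric: str = "euclidean"
    n_restarts: int = 1000
    epochs: int = 100
    # The final neighborhood stays at ~the inter-unit spacing: shrinking it
    # further lets the map quantize within-cluster noise, which fragments
    # coherent trajectory clusters across adjacent units and destroys the
    # consensus co-clustering signal.
    radius_initial: float | None = None  # default: max(grid)/2
    radius_final: float | None = None  # default: min(2, initial radius)
    # Learning rates apply to the online variant only; batch training (the
    # default and sole implementation here) ignores them.
    learning_rate_initial: float = 0.5
    learning_rate_final: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 2:
            raise ConfigError("grid must have at least 2 units")
        if self.lattice not in ("hexagonal", "rectangular"):
            raise ConfigError(f"lattice: unknown value {self.lattice!r}")
        if self.metric != "euclidean":
            raise ConfigError(f"metric: only 'euclidean' is supported")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        r0 = self.effective_radius_initial
        rf = self.effective_radius_final
        if not (r0 > 0 and rf > 0):
            raise ConfigError("radii must be positive")
        if r0 < rf:
            raise ConfigError("radius_initial must be >= radius_final")
        if self.learning_rate_initial < self.learning_rate_final:
            raise ConfigError(
                "learning_rate_initial must be >= learning_rate_final"
            )
        if not (self.learning_rate_final > 0):
            raise ConfigError("learning rates must be positive")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def effective_radius_initial(self) -> float:
        if self.radius_initial is not None:
            return self.radius_initial
        return max(self.grid_rows, self.grid_cols) / 2.0

    @property
    def effective_radius_final(self) -> float:
        if self.radius_final is not None:
            return self.radius_final
        return min(2.0, self.effective_radius_initial)


def grid_positions(config: SomConfig) -> np.ndarray:
    """Planar unit coordinates; hexagonal lattices use offset rows."""
    rows = np.repeat(np.arange(config.grid_rows), config.grid_cols)
    cols = np.tile(np.arange(config.grid_cols), config.grid_rows)
    if config.lattice == "hexagonal":
        x = cols + 0.5 * (rows % 2)
        y = rows * (np.sqrt(3.0) / 2.0)
    else:
        x = cols.astype(float)
        y = rows.astype(float)
    return np.column_stack([x, y])


def _grid_distances(config: SomConfig) -> np.ndarray:
    pos = grid_positions(config)
    return cdist(pos, pos)


def _init_weights(X: np.ndarray, config: SomConfig, rng: np.random.Generator
                  ) -> np.ndarray:
    """Random unit weights sampled in the data's principal-plane bounding box."""
    mean = X.mean(axis=0)
    Xc = X - mean
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, Vt.shape[0])
    basis = Vt[:k]
    scores = Xc @ basis.T
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    pts = rng.uniform(lo, hi, size=(config.n_units, k))
    return mean + pts @ basis


@dataclass
class SomFit:
    assignments: pd.Series  # peptide -> unit index
    weights: np.ndarray  # units x features
    quantization_error: float


def train_som(
    data: pd.DataFrame,
    config: SomConfig,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> SomFit:
    """Batch-train one SOM and assign each row to its best-matching unit."""
    if data.isna().any().any():
        raise PtyrlinkError("SOM input has missing cells")
    X = data.to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    W = _init_weights(X, config, rng)
    gd2 = _grid_distances(config) ** 2
    radii = np.linspace(config.effective_radius_initial,
                        config.effective_radius_final, config.epochs)
    bmu = np.zeros(X.shape[0], dtype=int)
    for sigma in radii:
        D = cdist(X, W, metric="sqeuclidean")
        bmu = np.argmin(D, axis=1)
        H = np.exp(-gd2 / (2.0 * sigma**2))
        counts = np.bincount(bmu, minlength=config.n_units).astype(float)
        sums = np.zeros_like(W)
        np.add.at(sums, bmu, X)
        numer = H @ sums
        denom = H @ counts
        ok = denom > 1e-12
        W[ok] = numer[ok] / denom[ok, None]
    D = cdist(X, W, metric="sqeuclidean")
    bmu = np.argmin(D, axis=1)
    qe = float(np.sqrt(D[np.arange(len(bmu)), bmu]).mean())
    return SomFit(
        assignments=pd.Series(bmu, index=data.index, name="unit"),
        weights=W,
        quantization_error=qe,
    )


@dataclass
class CoclusterMap:
    """Symmetric peptide x peptide co-assignment frequency matrix."""

    freq: pd.DataFrame
    n_restarts: int

    def __post_init__(self) -> None:
        arr = self.freq.to_numpy()
        if arr.shape[0] != arr.shape[1] or not np.array_equal(arr, arr.T):
            raise ValueError("co-clustering map must be symmetric")
        if not np.allclose(np.diag(arr), 1.0):
            raise ValueError("co-clustering map diagonal must be 1")
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("co-clustering frequencies must lie in [0, 1]")


def cocluster(data: pd.DataFrame, config: SomConfig) -> CoclusterMap:
    """Retrain the SOM ``n_restarts`` times and tally co-assignments.

    Restart r uses a child seed spawned deterministically from
    ``config.seed``, so the whole ensemble is reproducible.
    """
    n = data.shape[0]
    counts = np.zeros((n, n), dtype=np.int64)
    children = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    for child in children:
        fit = train_som(data, config, seed=child)
        bmu = fit.assignments.to_numpy()
        same = bmu[:, None] == bmu[None, :]
        counts += same
    freq = counts / float(config.n_restarts)
    np.fill_diagonal(freq, 1.0)
    return CoclusterMap(
        freq=pd.DataFrame(freq, index=data.index, columns=data.index),
        n_restarts=config.n_restarts,
    )


def cut_cocluster(
    cmap: CoclusterMap,
    n_clusters: int | None = None,
    height: float | None = None,
    linkage: str = "average",
) -> pd.Series:
    """Hierarchically cluster the rows of the frequency map (Euclidean
    distance) and cut into flat consensus clusters."""
    if (n_clusters is None) == (height is None):
        raise ValueError("specify exactly one of n_clusters or height")
    arr = cmap.freq.to_numpy(dtype=float)
    Z = hierarchy.linkage(pdist(arr, metric="euclidean"), method=linkage)
    if n_clusters is not None:
        if not 1 <= n_clusters <= arr.shape[0]:
            raise ValueError(f"n_clusters must be in [1, {arr.shape[0]}]")
        flat = hierarchy.fcluster(Z, n_clusters, criterion="maxclust")
    else:
        flat = hierarchy.fcluster(Z, height, criterion="distance")
    return pd.Series(flat, index=cmap.freq.index, name="cluster")


def cluster_band(
    cluster_peptides: Sequence[str],
    matrix: PhosphoMatrix,
    line: str,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-timepoint mean and t-based confidence band across a cluster.

    The band summarizes the cluster's replicate-mean log2FC trajectories in
    one cell line; the CI uses df = n_peptides - 1 and is undefined (NaN,
    flagged) for singleton clusters.
    """
    peptides = list(cluster_peptides)
    if not peptides:
        raise PtyrlinkError("cluster_band: empty cluster")
    if matrix.stage == "log2fc":
        from .preprocess import replicate_mean

        matrix = replicate_mean(matrix)
    matrix.require_stage("replicate_mean")
    traj = line_trajectories(matrix, line).loc[peptides]
    n = traj.notna().sum(axis=0)
    mean = traj.mean(axis=0)
    sd = traj.std(axis=0, ddof=1)
    half = pd.Series(np.nan, index=mean.index)
    ok = n > 1
    if ok.any():
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n[ok] - 1)
        half[ok] = tcrit * sd[ok] / np.sqrt(n[ok])
    out = pd.DataFrame(
        {
            "timepoint_s": mean.index,
            "mean_log2fc": mean.to_numpy(),
            "ci_lower": (mean - half).to_numpy(),
            "ci_upper": (mean + half).to_numpy(),
            "n_peptides": n.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def differential_som_input(
    line_a: str,
    line_b: str,
    matrix: PhosphoMatrix,
    include_basal: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Concatenate two lines' trajectories per peptide for differential SOMs.

    Feature rows capture the joint A/B shape so that "up in A, down in B"
    peptides form their own units.  The identically-zero 0 s columns are
    excluded by default to avoid degenerate dimensions.  Peptides missing
    either trajectory are dropped and returned in the audit list.
    """
    matrix.require_stage("replicate_mean")
    ts = matrix.timepoints_s if include_basal else [
        t for t in matrix.timepoints_s if t != 0
    ]
    blocks = []
    for line in (line_a, line_b):
        traj = line_trajectories(matrix, line)[ts]
        traj.columns = [f"{line}@{t}" for t in ts]
        blocks.append(traj)
    joined = pd.concat(blocks, axis=1, join="outer")
    complete = joined.notna().all(axis=1)
    dropped = sorted(joined.index[~complete].astype(str))
    return joined.loc[complete], dropped
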