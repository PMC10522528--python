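"""Distance-correlation connectomics over resting-state network ROIs.

Each subject contributes a BOLD matrix partitioned into 15 named network
blocks (voxels as columns, frames as rows).  Functional connectivity between
two networks is the distance correlation (Székely's dCor, the biased
V-statistic) between the two multivariate samples formed by their voxel
blocks; within-network connectivity is the average, over voxels, of the
distance correlation between one voxel's time course and the remaining
voxels of the same network taken as a single multivariate sample.  Over the
15 canonical networks this yields 15·16/2 = 120 labeled similarity measures
per subject, the "connectome vector" fed to the downstream classifier.

dCor is preferred over Pearson correlation here because it measures
dependence between random vectors of arbitrary (and unequal) dimension in a
single calculation, and the population quantity is zero exactly under
independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateDataError, SchemaError, ShapeError

#: Canonical resting-state network order; fixed so that connectome vectors
#: from different subjects are comparable element by element.
CANONICAL_NETWORKS: tuple[str, ...] = (
    "SMD", "SMI", "CON", "AUD", "DMN", "PMN", "VIS", "FPN",
    "SAL", "VAN", "DAN", "MET", "REW", "THA", "BGA",
)


def pair_labels(networks: Sequence[str] = CANONICAL_NETWORKS) -> list[str]:
    """Upper-triangle row-major pair labels, self-pairs included.

    For the 15 canonical networks this is the 120-element ordering
    SMDxSMD, SMDxSMI, ..., THAxBGA, BGAxBGA.
    """
    n = len(networks)
    return [f"{networks[i]}x{networks[j]}" for i in range(n) for j in range(i, n)]


@dataclass(frozen=True)
class ProbabilityMap:
    """Voxelwise membership probabilities of one network on a common grid."""

    network: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise DataError(f"probability map {self.network}: non-finite entries")
        if v.min() < 0.0 or v.max() > 1.0:
            raise DataError(f"probability map {self.network}: entries outside [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class NetworkROI:
    """The ordered voxel indices defining one network's region of interest."""

    network: str
    voxel_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.voxel_indices)) != len(self.voxel_indices):
            raise DataError(f"ROI {self.network}: duplicate voxel indices")


@dataclass
class TimeSeriesSet:
    """One subject's BOLD data as named network blocks of shape (T, voxels)."""

    blocks: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        frames = {b.shape[0] for b in self.blocks.values()}
        if len(frames) > 1:
            raise ShapeError(f"network blocks disagree on frame count: {sorted(frames)}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.blocks.values())).shape[0]

    @property
    def networks(self) -> tuple[str, ...]:
        return tuple(self.blocks)

    def to_matrix(self) -> np.ndarray:
        """Concatenate blocks column-wise in their stored order."""
        return np.hstack([self.blocks[n] for n in self.blocks])


@dataclass(frozen=True)
class ConnectomeVector:
    """Labeled within/between-network similarities in canonical pair order."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ShapeError("connectome values and labels differ in length")

    def as_series(self) -> pd.Series:
        return pd.Series(np.asarray(self.values), index=list(self.labels))


def select_roi(prob_map: ProbabilityMap, k: int) -> NetworkROI:
    """Pick the ``k`` voxels with largest membership probability.

    Ties are broken by ascending voxel index so the selection is
    deterministic.  Requires at least ``k`` strictly positive entries.
    """
    v = prob_map.values
    n_positive = int(np.count_nonzero(v > 0))
    if n_positive < k:
        raise DegenerateDataError(
            f"map {prob_map.network}: only {n_positive} positive voxels, need {k}"
        )
    # stable sort on (-probability, index): mergesort keeps index order on ties
    order = np.argsort(-v, kind="stable")[:k]
    return NetworkROI(network=prob_map.network, voxel_indices=tuple(int(i) for i in order))


def _check_sample(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.ndim != 2:
        raise ShapeError(f"{name}: expected a 2-D sample matrix, got ndim={M.ndim}")
    if not np.all(np.isfinite(M)):
        raise DataError(f"{name}: non-finite entries")
    return M


def _distance_matrix(M: np.ndarray) -> np.ndarray:
    """Euclidean distances between rows; (T, T)."""
    sq = np.sum(M * M, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (M @ M.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def _double_center(D: np.ndarray) -> np.ndarray:
    row = D.mean(axis=1, keepdims=True)
    col = D.mean(axis=0, keepdims=True)
    return D - row - col + D.mean()


def _dcor_from_centered(A: np.ndarray, B: np.ndarray) -> float:
    """dCor from already double-centered distance matrices (V-statistic)."""
    n2 = A.shape[0] ** 2
    dcov2 = float(np.sum(A * B)) / n2
    dvar2_a = float(np.sum(A * A)) / n2
    dvar2_b = float(np.sum(B * B)) / n2
    denom = dvar2_a * dvar2_b
    if denom <= 0.0:
        warnings.warn(
            "zero distance variance; returning dCor = 0 for a constant sample",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    # dcov2 can dip a hair below 0 from cancellation; the V-statistic is >= 0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(denom)))


def distance_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    r"""Székely's distance correlation between two samples (V-statistic).

    With :math:`a_{jk} = \lVert X_j - X_k \rVert` and the double-centered
    :math:`A_{jk} = a_{jk} - \bar a_{j\cdot} - \bar a_{\cdot k} + \bar a`,
    the squared distance covariance is
    :math:`\mathrm{dCov}^2 = n^{-2}\sum_{jk} A_{jk} B_{jk}`, distance
    variances analogously, and

    .. math:: \mathrm{dCor} = \sqrt{\mathrm{dCov}^2 /
              \sqrt{\mathrm{dVar}^2_X\, \mathrm{dVar}^2_Y}}.

    Returns a value in [0, 1]; returns 0 (with a warning) when either sample
    is constant, since dependence on a constant is undefined.
    """
    X = _check_sample(X, "X")
    Y = _check_sample(Y, "Y")
    if X.shape[0] != Y.shape[0]:
        raise ShapeError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    if X.shape[0] < 2:
        raise ShapeError("need at least 2 observations")
    A = _double_center(_distance_matrix(X))
    B = _double_center(_distance_matrix(Y))
    return _dcor_from_centered(A, B)


def between_network_similarity(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """dCor between two network blocks, each treated as one multivariate sample."""
    return distance_correlation(block_a, block_b)


def within_network_similarity(block: np.ndarray, method: str = "set") -> float:
    """Average voxel-to-rest similarity inside one network block.

    ``method="set"`` (default): for each voxel i, compute dCor between that
    voxel's time course and the remaining k-1 voxels taken as a single
    multivariate sample, then average over i.  ``method="pairwise"``
    averages dCor over all unordered voxel pairs instead; it is exposed
    because the set-based reading of "each voxel against the other voxels"
    is a modeling choice, not forced.
    """
    block = _check_sample(block, "block")
    T, k = block.shape
    if k < 2:
        raise DegenerateDataError("within-network similarity needs at least 2 voxels")
    if method == "pairwise":
        vals = [
            distance_correlation(block[:, i], block[:, j])
            for i in range(k)
            for j in range(i + 1, k)
        ]
        return float(np.mean(vals))
    if method != "set":
        raise ValueError(f"unknown within-network method {method!r}")

    # Squared Euclidean row distances decompose over columns, so the distance
    # matrix of the block minus voxel i is sqrt(D2_full - d_i^2) — no need to
    # recompute a k-1 dimensional distance matrix per voxel.
    sq = np.sum(block * block, axis=1)
    D2_full = sq[:, None] + sq[None, :] - 2.0 * (block @ block.T)
    np.maximum(D2_full, 0.0, out=D2_full)
    np.fill_diagonal(D2_full, 0.0)

    total = 0.0
    for i in range(k):
        di = np.abs(block[:, i][:, None] - block[:, i][None, :])
        rest2 = D2_full - di * di
        np.maximum(rest2, 0.0, out=rest2)
        A = _double_center(di)
        B = _double_center(np.sqrt(rest2))
        total += _dcor_from_centered(A, B)
    return total / k


def build_connectome(
    ts: TimeSeriesSet,
    networks: Sequence[str] = CANONICAL_NETWORKS,
    within_method: str = "set",
) -> ConnectomeVector:
    """Assemble the labeled similarity vector for one subject.

    Traverses the upper triangle of the network-by-network grid row-major:
    diagonal entries come from :func:`within_network_similarity`, off-diagonal
    entries from :func:`between_network_similarity`.  For the canonical 15
    networks the result has 120 entries.
    """
    missing = [n for n in networks if n not in ts.blocks]
    if missing:
        raise SchemaError(f"time series missing network blocks: {missing}")

    # Between-network dCor only needs each block's centered distance matrix
    # once; cache them.
    centered = {n: _double_center(_distance_matrix(np.asarray(ts.blocks[n], float)))
                for n in networks}

    labels = pair_labels(networks)
    values = np.empty(len(labels))
    idx = 0
    for i, a in enumerate(networks):
        for b in networks[i:]:
            if a == b:
                values[idx] = within_network_similarity(
                    np.asarray(ts.blocks[a], float), method=within_method
                )
            else:
                values[idx] = _dcor_from_centered(centered[a], centered[b])
            idx += 1
    return ConnectomeVector(values=values, labels=tuple(labels))


def connectome_table(
    timeseries: Mapping[str, TimeSeriesSet],
    networks: Sequence[str] = CANONICAL_NETWORKS,
    within_method: str = "set",
) -> pd.DataFrame:
    """Connectome vectors for a whole cohort, one row per subject."""
    rows = {}
    for sid, ts in timeseries.items():
        rows[sid] = build_connectome(ts, networks=networks, within_method=within_method).as_series()
    df = pd.DataFrame(rows).T
    df.index.name = "subject_id"
    return df


def read_timeseries_csv(path) -> TimeSeriesSet:
    """Read one subject's matrix file written by the synthetic module.

    The header names each column's network block (``NET:index``); rows are
    frames.
    """
    df = pd.read_csv(path)
    blocks: dict[str, list[str]] = {}
    for col in df.columns:
        net = col.split(":", 1)[0]
        blocks.setdefault(net, []).append(col)
    return TimeSeriesSet(blocks={n: df[cols].to_numpy(float) for n, cols in blocks.items()})
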