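"""Ensemble comparison statistics.

Quantifies the difference between two schemes' final-position clouds:

* ``average_net_distance`` — mean Euclidean displacement d over an ensemble,
  and ``signed_relative_difference`` E = (d2 - d1)/d1 between two schemes;
* uniform binning of final positions along the x1-axis and the J2
  separability criterion J2 = |S_w + S_b| / S_w built from within- and
  between-bin scatter of the x2 samples (larger J2: better-separated data);
* the bin-size sweep of the signed relative J2 error between two schemes
  and its average;
* convex hulls of final positions;
* an L1 mismatch between an ensemble histogram and a PDE density on the
  solver grid (quantifying Fokker--Planck consistency).

J2 convention: classes are x1-bins, samples are the x2 values within each
bin, so all scatters are scalars.  The per-bin scatter S_i is taken about
the *overall* mean mu_0 by default (with ``scatter_about='bin_mean'`` for
the classical within-class variant about mu_i).  Bins are left-closed,
right-open, anchored at the minimum x1 of the data — or at a caller-given
anchor, which the two-scheme sweep sets from the pooled data so both
schemes share identical bin edges.  Empty bins are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .pde import DensityField

__all__ = [
    "BinSummary",
    "J2Sweep",
    "average_net_distance",
    "signed_relative_difference",
    "bin_positions",
    "j2_criterion",
    "j2_error_sweep",
    "convex_hull_of_finals",
    "density_mismatch",
]


def average_net_distance(initials: np.ndarray, finals: np.ndarray) -> float:
    """Mean Euclidean distance between paired initial and final positions."""
    I = np.asarray(initials, dtype=float)
    F = np.asarray(finals, dtype=float)
    if I.shape != F.shape or I.ndim != 2 or I.shape[0] < 1:
        raise ValueError("initials and finals must be equal-shape K x d arrays")
    return float(np.mean(np.linalg.norm(F - I, axis=1)))


def signed_relative_difference(d1: float, d2: float) -> float:
    """E = (d2 - d1) / d1; positive when the second scheme travels further."""
    if d1 <= 0:
        raise ValueError("reference distance d1 must be positive")
    return (d2 - d1) / d1


# ---------------------------------------------------------------------------
# binning and the J2 criterion
# ---------------------------------------------------------------------------


def _bin_indices(x1: np.ndarray, r: float, anchor: Optional[float]):
    if r <= 0:
        raise ValueError("bin size r must be positive")
    if anchor is None:
        anchor = float(x1.min())
    # the small offset keeps points that sit on a bin edge up to roundoff
    # in the bin exact arithmetic would give (left-closed, right-open)
    ids = np.floor((x1 - anchor) / r + 1e-9).astype(np.int64)
    ids[ids < 0] = 0
    return ids, anchor


@dataclass
class BinSummary:
    """Occupied x1-bins of a final-position cloud."""

    r: float
    anchor: float
    bin_ids: np.ndarray      # occupied bin indices (sorted)
    edges: np.ndarray        # left edges of the occupied bins
    counts: np.ndarray       # n_i
    sums: np.ndarray         # U_i = sum of x2 values per bin
    means: np.ndarray        # mu_i
    x2_values: Optional[list] = None  # per-bin x2 sample arrays

    @property
    def m(self) -> int:
        """Number of occupied bins."""
        return len(self.bin_ids)


def bin_positions(
    finals: np.ndarray, r: float, anchor: Optional[float] = None,
    store_samples: bool = True,
) -> BinSummary:
    """Partition final positions into x1-bins of fixed size r."""
    F = np.asarray(finals, dtype=float)
    if F.ndim != 2 or F.shape[1] != 2 or F.shape[0] < 1:
        raise ValueError("finals must be a nonempty K x 2 array")
    x1, x2 = F[:, 0], F[:, 1]
    ids, anchor = _bin_indices(x1, r, anchor)
    uniq, inv, counts = np.unique(ids, return_inverse=True, return_counts=True)
    sums = np.bincount(inv, weights=x2)
    means = sums / counts
    samples = None
    if store_samples:
        order = np.argsort(inv, kind="stable")
        split = np.cumsum(counts)[:-1]
        samples = list(np.split(x2[order], split))
    return BinSummary(
        r=float(r), anchor=anchor, bin_ids=uniq,
        edges=anchor + uniq * float(r),
        counts=counts, sums=sums, means=means, x2_values=samples,
    )


def j2_criterion(
    finals: np.ndarray, r: float, anchor: Optional[float] = None,
    scatter_about: str = "overall_mean",
) -> float:
    """J2 = |S_w + S_b| / S_w over x1-bins of size r.

    With P_i = n_i / K, mu_i the per-bin x2 mean and mu_0 = sum_i P_i mu_i:
    S_b = sum_i P_i (mu_i - mu_0)^2 and S_w = sum_i P_i S_i, where S_i is
    the per-bin mean squared deviation of x2 about mu_0 (default) or about
    mu_i (``scatter_about='bin_mean'``).

    Raises on degenerate input: fewer than 2 occupied bins, or S_w = 0.
    """
    if scatter_about not in ("overall_mean", "bin_mean"):
        raise ValueError("scatter_about must be 'overall_mean' or 'bin_mean'")
    F = np.asarray(finals, dtype=float)
    if F.ndim != 2 or F.shape[1] != 2 or F.shape[0] < 1:
        raise ValueError("finals must be a nonempty K x 2 array")
    x1, x2 = F[:, 0], F[:, 1]
    K = len(x1)
    ids, anchor = _bin_indices(x1, r, anchor)
    uniq, inv, counts = np.unique(ids, return_inverse=True, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("J2 needs at least 2 occupied bins")
    P = counts / K
    means = np.bincount(inv, weights=x2) / counts
    mu0 = float(P @ means)
    if scatter_about == "overall_mean":
        dev2 = (x2 - mu0) ** 2
    else:
        dev2 = (x2 - means[inv]) ** 2
    S_i = np.bincount(inv, weights=dev2) / counts
    S_w = float(P @ S_i)
    S_b = float(P @ (means - mu0) ** 2)
    if S_w <= 0:
        raise ValueError("degenerate input: within-bin scatter S_w is zero")
    return abs(S_w + S_b) / S_w


@dataclass
class J2Sweep:
    """Bin-size sweep of the signed relative J2 error between two schemes."""

    r_values: np.ndarray
    j2_first: np.ndarray     # reference scheme (denominator)
    j2_second: np.ndarray
    errors: np.ndarray       # (J2_second - J2_first) / J2_first, per r

    @property
    def mean_error(self) -> float:
        return float(self.errors.mean())

    @property
    def all_positive(self) -> bool:
        return bool(np.all(self.errors > 0))


def j2_error_sweep(
    finals_first: np.ndarray,
    finals_second: np.ndarray,
    r0: float = 0.01,
    h: float = 0.001,
    k_max: int = 60,
    scatter_about: str = "overall_mean",
) -> J2Sweep:
    """Sweep r = r0 + k h for k = 1..k_max and compare J2 of two final-
    position sets.  Both sets use identical bin edges anchored at the
    pooled minimum x1 so their J2 values are comparable."""
    A = np.asarray(finals_first, dtype=float)
    B = np.asarray(finals_second, dtype=float)
    if A.size == 0 or B.size == 0:
        raise ValueError("both final-position sets must be nonempty")
    anchor = float(min(A[:, 0].min(), B[:, 0].min()))
    rs = r0 + h * np.arange(1, k_max + 1)
    j2a = np.empty(k_max)
    j2b = np.empty(k_max)
    for i, r in enumerate(rs):
        try:
            j2a[i] = j2_criterion(A, r, anchor=anchor, scatter_about=scatter_about)
            j2b[i] = j2_criterion(B, r, anchor=anchor, scatter_about=scatter_about)
        except ValueError as exc:
            raise ValueError(f"J2 failed at bin size r = {r:g}: {exc}") from exc
    return J2Sweep(r_values=rs, j2_first=j2a, j2_second=j2b,
                   errors=(j2b - j2a) / j2a)


# ---------------------------------------------------------------------------
# hulls and density mismatch
# ---------------------------------------------------------------------------


def convex_hull_of_finals(finals: np.ndarray) -> np.ndarray:
    """Counter-clockwise convex-hull vertices of a 2-D point cloud.

    Degenerate clouds (fewer than 3 points, or collinear) return the
    degenerate hull: the extreme points along the principal direction.
    """
    P = np.unique(np.asarray(finals, dtype=float), axis=0)
    if P.ndim != 2 or P.shape[1] != 2 or P.shape[0] < 1:
        raise ValueError("finals must be a nonempty K x 2 array")
    if len(P) >= 3:
        try:
            hull = ConvexHull(P)
            return P[hull.vertices]  # qhull orders 2-D vertices CCW
        except QhullError:
            pass
    if len(P) == 1:
        return P
    centred = P - P.mean(axis=0)
    direction = centred[np.argmax(np.linalg.norm(centred, axis=1))]
    proj = centred @ direction
    return np.array([P[np.argmin(proj)], P[np.argmax(proj)]])


def density_mismatch(finals: np.ndarray, u_final: DensityField) -> float:
    """L1 distance between the mass-normalised PDE density and the
    normalised final-position histogram on the PDE grid.

    Both are treated as probability mass per grid cell, so the value lies
    in [0, 2] (2 = disjoint supports).  Ensemble points outside the PDE
    domain are counted as mass the histogram places off-grid.
    """
    F = np.asarray(finals, dtype=float)
    if F.ndim != 2 or F.shape[1] != 2 or F.shape[0] < 1:
        raise ValueError("finals must be a nonempty K x 2 array")
    mass = u_final.mass()
    if mass <= 0:
        raise ValueError("PDE field has nonpositive mass")
    p = u_final.u * (u_final.grid.h**2 / mass)
    edges = u_final.grid.edges
    counts, _, _ = np.histogram2d(F[:, 0], F[:, 1], bins=(edges, edges))
    q = counts / len(F)
    inside = q.sum()
    return float(np.abs(p - q).sum() + (1.0 - inside))
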