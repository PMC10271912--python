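"""Advection/diffusion coefficient fields.

A macroscopic cell-density model of the advection--diffusion form

    du/dt + div(A u) - div(D grad u) = 0

is characterised entirely by the pair of coefficient fields (A, D): an
advection velocity ``A(x)`` in R^d and a symmetric positive-semidefinite
diffusion matrix ``D(x)`` in R^{d x d}.  The same pair also parameterises the
Euler--Maruyama schemes for the single-cell stochastic equation, where the
consistent drift is ``A + div D`` and the noise amplitude is a matrix square
root ``V`` with ``V V^T = D``.

This module defines the :class:`CoefficientField` container shared by the PDE
solver and the SDE simulator, the two built-in coefficient families used in
the numerical experiments (a power-law family and an environment-driven
family), numeric differentiation fallbacks, and the matrix square root.

Conventions
-----------
* ``div D`` is the *column-wise* divergence: component ``i`` is the scalar
  divergence of the ``i``-th column of ``D``.  For the symmetric matrices
  used here the row/column distinction is immaterial, but the column
  convention is fixed.
* All field callables are vectorised: they accept an ``(n, d)`` array of
  positions and return ``(n, d)`` (vectors) or ``(n, d, d)`` (matrices).
  The public ``*_at`` helpers additionally accept a single ``(d,)`` point.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "CoefficientField",
    "ScalarField",
    "power_law_field",
    "environment_field",
    "builtin_environment_v",
    "constant_field",
    "div_diffusion_numeric",
    "diffusion_factor",
    "make_field",
    "register_family",
    "FIELD_FAMILIES",
]

#: tolerance for symmetry checks on diffusion matrices
SYMMETRY_TOL = 1e-12
#: most negative eigenvalue accepted before a diffusion matrix is rejected;
#: eigenvalues in (EIGENVALUE_FLOOR, 0) are clamped to zero (roundoff guard
#: at diffusivity zeros such as the v = 1 contours of the environment field)
EIGENVALUE_FLOOR = -1e-12
#: default step for numeric divergence of the diffusion matrix
DIV_DIFFUSION_H = 1e-4


def _as_points(x: np.ndarray, dim: int) -> tuple[np.ndarray, bool]:
    """Promote a single point to a batch of one; return (points, was_single)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    if pts.shape[-1] != dim:
        raise ValueError(f"expected points in R^{dim}, got shape {x.shape}")
    return pts, single


@dataclass
class CoefficientField:
    """The coefficient pair (A, D) consumed by both the PDE and SDE sides.

    Parameters
    ----------
    dim
        Spatial dimension d (the experiments use d = 2).
    advection
        Vectorised map ``(n, d) -> (n, d)`` giving A(x).
    diffusion
        Vectorised map ``(n, d) -> (n, d, d)`` giving the symmetric PSD
        matrix D(x).
    div_diffusion
        Optional analytic column-wise divergence ``(n, d) -> (n, d)``.
        When absent a central-difference approximation is used.
    diffusion_diag
        Optional fast path for diagonal D: ``(n, d) -> (n, d)`` returning
        the diagonal entries.  Lets the simulator take elementwise square
        roots instead of factorising full matrices.
    metadata
        Free-form provenance record (family name, parameters).
    """

    dim: int
    advection: Callable[[np.ndarray], np.ndarray]
    diffusion: Callable[[np.ndarray], np.ndarray]
    div_diffusion: Optional[Callable[[np.ndarray], np.ndarray]] = None
    diffusion_diag: Optional[Callable[[np.ndarray], np.ndarray]] = None
    metadata: dict = _dc_field(default_factory=dict)

    # -- evaluation helpers -------------------------------------------------

    @property
    def is_diagonal(self) -> bool:
        return self.diffusion_diag is not None

    def advection_at(self, x: np.ndarray) -> np.ndarray:
        pts, single = _as_points(x, self.dim)
        out = np.asarray(self.advection(pts), dtype=float)
        return out[0] if single else out

    def diffusion_at(self, x: np.ndarray) -> np.ndarray:
        pts, single = _as_points(x, self.dim)
        out = np.asarray(self.diffusion(pts), dtype=float)
        return out[0] if single else out

    def div_diffusion_at(self, x: np.ndarray, h: float = DIV_DIFFUSION_H) -> np.ndarray:
        """Column-wise divergence of D, analytic when available."""
        if self.div_diffusion is not None:
            pts, single = _as_points(x, self.dim)
            out = np.asarray(self.div_diffusion(pts), dtype=float)
            return out[0] if single else out
        return div_diffusion_numeric(self, x, h)

    def validate_at(self, x: np.ndarray) -> None:
        """Check the symmetry/PSD invariants of D at the given point(s)."""
        pts, _ = _as_points(x, self.dim)
        Dm = np.asarray(self.diffusion(pts), dtype=float)
        scale = max(1.0, float(np.max(np.abs(Dm))))
        asym = np.max(np.abs(Dm - np.swapaxes(Dm, -1, -2)))
        if asym > SYMMETRY_TOL * scale:
            raise ValueError(f"diffusion matrix asymmetric: |D - D^T| = {asym:g}")
        eigs = np.linalg.eigvalsh(0.5 * (Dm + np.swapaxes(Dm, -1, -2)))
        if eigs.min() < EIGENVALUE_FLOOR * scale:
            raise ValueError(f"diffusion matrix has eigenvalue {eigs.min():g} < floor")


# ---------------------------------------------------------------------------
# built-in families
# ---------------------------------------------------------------------------


def _pow7(x: np.ndarray) -> np.ndarray:
    x2 = x * x
    x4 = x2 * x2
    return x4 * x2 * x


def _pow6(x: np.ndarray) -> np.ndarray:
    x2 = x * x
    return x2 * x2 * x2


def power_law_field(a: float, b: float) -> CoefficientField:
    """Power-law coefficient family in 2-D.

        A(x) = (a x1^7, a x2^7)^T,   D(x) = diag(b x1^7, b x2^7),

    with analytic divergence ``div D = (7 b x1^6, 7 b x2^6)^T``.  The
    diffusion entries are real square roots only for nonnegative
    coordinates; the simulator clamps (and counts) negative excursions.

    ``b`` must be nonnegative so that D is PSD where trajectories live.
    """
    a = float(a)
    b = float(b)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("power_law_field parameters must be finite")
    if b < 0:
        raise ValueError("power_law_field requires b >= 0 (nonnegative diffusion)")

    def advection(X: np.ndarray) -> np.ndarray:
        return a * _pow7(X)

    def diffusion_diag(X: np.ndarray) -> np.ndarray:
        return b * _pow7(X)

    def diffusion(X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        out = np.zeros((n, 2, 2))
        dd = b * _pow7(X)
        out[:, 0, 0] = dd[:, 0]
        out[:, 1, 1] = dd[:, 1]
        return out

    def div_diffusion(X: np.ndarray) -> np.ndarray:
        return 7.0 * b * _pow6(X)

    return CoefficientField(
        dim=2,
        advection=advection,
        diffusion=diffusion,
        div_diffusion=div_diffusion,
        diffusion_diag=diffusion_diag,
        metadata={"family": "power_law", "a": a, "b": b},
    )


@dataclass
class ScalarField:
    """A scalar field v(x) with an analytic gradient, both vectorised."""

    dim: int
    value: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    metadata: dict = _dc_field(default_factory=dict)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        pts, single = _as_points(x, self.dim)
        out = np.asarray(self.value(pts), dtype=float)
        return out[0] if single else out

    def gradient_at(self, x: np.ndarray) -> np.ndarray:
        pts, single = _as_points(x, self.dim)
        out = np.asarray(self.gradient(pts), dtype=float)
        return out[0] if single else out


def builtin_environment_v() -> ScalarField:
    """The built-in extracellular environment

        v(x1, x2) = 1 + 0.5 (sin^2 x1 + cos^2 x2),

    a fixed, space-periodic cue whose "valleys" (minima, v = 1 at
    x1 = k*pi, x2 = pi/2 + k*pi) attract the cell density.  Its analytic
    gradient is (0.5 sin 2x1, -0.5 sin 2x2).
    """

    def value(X: np.ndarray) -> np.ndarray:
        return 1.0 + 0.5 * (np.sin(X[:, 0]) ** 2 + np.cos(X[:, 1]) ** 2)

    def gradient(X: np.ndarray) -> np.ndarray:
        return np.stack(
            [0.5 * np.sin(2.0 * X[:, 0]), -0.5 * np.sin(2.0 * X[:, 1])], axis=-1
        )

    return ScalarField(dim=2, value=value, gradient=gradient,
                       metadata={"family": "builtin_environment"})


def environment_field(v: Optional[ScalarField] = None) -> CoefficientField:
    """Environment-driven coefficient family.

    For a scalar environment v with v(x) >= 1,

        A(x) = -grad v(x),   D(x) = (v(x) - 1) I,

    so that ``div D = grad v`` and the corrected drift ``A + div D``
    vanishes identically: the consistent single-cell scheme is drift-free.

    Evaluation raises if v(x) < 1 beyond a 1e-12 tolerance, since the
    diffusivity v - 1 must be nonnegative.
    """
    if v is None:
        v = builtin_environment_v()
    dim = v.dim

    def _diffusivity(X: np.ndarray) -> np.ndarray:
        w = np.asarray(v.value(X), dtype=float) - 1.0
        if w.min(initial=0.0) < -1e-12:
            raise ValueError(
                f"environment value below 1 (min diffusivity {w.min():g}); "
                "the diffusivity v - 1 must be nonnegative"
            )
        return np.clip(w, 0.0, None)

    def advection(X: np.ndarray) -> np.ndarray:
        return -np.asarray(v.gradient(X), dtype=float)

    def diffusion_diag(X: np.ndarray) -> np.ndarray:
        w = _diffusivity(X)
        return np.repeat(w[:, None], dim, axis=1)

    def diffusion(X: np.ndarray) -> np.ndarray:
        w = _diffusivity(X)
        return w[:, None, None] * np.eye(dim)

    def div_diffusion(X: np.ndarray) -> np.ndarray:
        # div((v - 1) I) = grad v, columnwise
        return np.asarray(v.gradient(X), dtype=float)

    return CoefficientField(
        dim=dim,
        advection=advection,
        diffusion=diffusion,
        div_diffusion=div_diffusion,
        diffusion_diag=diffusion_diag,
        metadata={"family": "environment", "v": v.metadata},
    )


def constant_field(advection, diffusion) -> CoefficientField:
    """A field with constant A and D (useful reference: div D = 0, so the
    naive and corrected schemes coincide)."""
    A0 = np.asarray(advection, dtype=float)
    D0 = np.asarray(diffusion, dtype=float)
    dim = A0.shape[0]
    if D0.shape != (dim, dim):
        raise ValueError("diffusion must be a (d, d) matrix")
    if np.max(np.abs(D0 - D0.T)) > SYMMETRY_TOL * max(1.0, np.max(np.abs(D0))):
        raise ValueError("constant diffusion matrix must be symmetric")
    diag = np.allclose(D0, np.diag(np.diag(D0)), atol=0.0)

    def advection_f(X):
        return np.broadcast_to(A0, X.shape).copy()

    def diffusion_f(X):
        return np.broadcast_to(D0, (X.shape[0], dim, dim)).copy()

    def div_diffusion_f(X):
        return np.zeros_like(X)

    diffusion_diag_f = None
    if diag:
        d0 = np.diag(D0).copy()

        def diffusion_diag_f(X):  # noqa: F811 - intentional conditional def
            return np.broadcast_to(d0, X.shape).copy()

    return CoefficientField(
        dim=dim,
        advection=advection_f,
        diffusion=diffusion_f,
        div_diffusion=div_diffusion_f,
        diffusion_diag=diffusion_diag_f,
        metadata={"family": "constant", "A": A0.tolist(), "D": D0.tolist()},
    )


# ---------------------------------------------------------------------------
# numeric divergence and the matrix square root
# ---------------------------------------------------------------------------


def div_diffusion_numeric(
    field: CoefficientField, x: np.ndarray, h: float = DIV_DIFFUSION_H
) -> np.ndarray:
    """Central-difference column-wise divergence of D.

    Component i is  sum_j [D_ji(x + h e_j) - D_ji(x - h e_j)] / (2 h),
    an O(h^2) approximation on smooth fields.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    pts, single = _as_points(x, field.dim)
    n, d = pts.shape
    out = np.zeros((n, d))
    for j in range(d):
        ej = np.zeros(d)
        ej[j] = h
        Dp = np.asarray(field.diffusion(pts + ej), dtype=float)
        Dm = np.asarray(field.diffusion(pts - ej), dtype=float)
        if not (np.all(np.isfinite(Dp)) and np.all(np.isfinite(Dm))):
            raise FloatingPointError(
                "non-finite diffusion evaluation on the divergence stencil"
            )
        # row j of the column-i entries: D_{ji}
        out += (Dp[:, j, :] - Dm[:, j, :]) / (2.0 * h)
    return out[0] if single else out


def diffusion_factor(Dmat: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root V of a PSD matrix, V V^T = D.

    Accepts a single (d, d) matrix or a batch (n, d, d).  Diagonal input
    short-circuits to ``diag(sqrt(D_ii))``.  Eigenvalues in
    (EIGENVALUE_FLOOR, 0) are clamped to zero; anything more negative, or
    any asymmetry beyond tolerance, is rejected.  The spectral root is
    used so that V is itself symmetric PSD (any factor with V V^T = D
    induces the same law; callers must only rely on the identity).
    """
    D = np.asarray(Dmat, dtype=float)
    single = D.ndim == 2
    Db = D[None] if single else D
    scale = max(1.0, float(np.max(np.abs(Db))) if Db.size else 1.0)
    asym = np.max(np.abs(Db - np.swapaxes(Db, -1, -2)))
    if asym > SYMMETRY_TOL * scale:
        raise ValueError(f"diffusion matrix asymmetric by {asym:g}")

    d = Db.shape[-1]
    offdiag = Db * (1.0 - np.eye(d))
    if not np.any(offdiag):
        diag = np.diagonal(Db, axis1=-2, axis2=-1)
        if diag.min() < EIGENVALUE_FLOOR * scale:
            raise ValueError(f"diagonal entry {diag.min():g} below eigenvalue floor")
        V = np.zeros_like(Db)
        idx = np.arange(d)
        V[..., idx, idx] = np.sqrt(np.clip(diag, 0.0, None))
        return V[0] if single else V

    w, Q = np.linalg.eigh(Db)
    if w.min() < EIGENVALUE_FLOOR * scale:
        raise ValueError(f"eigenvalue {w.min():g} below floor {EIGENVALUE_FLOOR}")
    w = np.clip(w, 0.0, None)
    V = (Q * np.sqrt(w)[..., None, :]) @ np.swapaxes(Q, -1, -2)
    return V[0] if single else V


# ---------------------------------------------------------------------------
# family registry (name-based selection from run configs)
# ---------------------------------------------------------------------------

FIELD_FAMILIES: dict[str, Callable[..., CoefficientField]] = {
    "power_law": power_law_field,
    "environment": environment_field,
    "constant": constant_field,
}


def register_family(name: str, factory: Callable[..., CoefficientField]) -> None:
    """Register a user-defined coefficient-field family under ``name``."""
    FIELD_FAMILIES[name] = factory


def make_field(name: str, **params) -> CoefficientField:
    """Instantiate a registered coefficient family by name."""
    try:
        factory = FIELD_FAMILIES[name]
    except KeyError:
        raise KeyError(
            f"unknown field family {name!r}; known: {sorted(FIELD_FAMILIES)}"
        ) from None
    return factory(**params)
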