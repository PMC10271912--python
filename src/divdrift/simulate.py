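"""Euler--Maruyama simulation of solitary-cell migration.

Two explicit schemes advance a cell position x_t under a coefficient field
(A, D):

* naive:      x <- x + A(x) dt + sqrt(2 dt) V(x) xi
* corrected:  x <- x + (A(x) + div D(x)) dt + sqrt(2 dt) V(x) xi

with V V^T = D and xi a vector of independent standard normals.  The
corrected drift ``A + div D`` is the one consistent (in the Fokker--Planck
sense) with the advection--diffusion PDE governed by the same (A, D); the
naive drift uses A alone and agrees with the corrected scheme only where
``div D = 0``.  Both are Ito-type schemes: the correction is *not* a
Stratonovich conversion.

Ensembles are simulated in vectorised chunks.  Each chunk of realisations
consumes its own RNG substream (``SeedSequence(entropy=seed,
spawn_key=(stream, chunk))`` driving an SFC64 generator), so runs are
bitwise reproducible for a given (seed, K, n_steps) and the shared-noise
mode can feed bitwise-identical Gaussian increments to both schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace
from typing import Optional, Sequence

import numpy as np

from .fields import CoefficientField, diffusion_factor

__all__ = [
    "SimulationConfig",
    "TrajectoryEnsemble",
    "GuardCounter",
    "em_step_naive",
    "em_step_corrected",
    "simulate_ensemble",
    "simulate_paired",
]

#: realisations per simulation chunk; a fixed constant so that results do not
#: depend on memory configuration
CHUNK = 32768

SCHEMES = ("naive", "corrected")


@dataclass
class GuardCounter:
    """Counts clamps of negative diffusion entries (e.g. power-law fields
    evaluated at negative coordinates, where sqrt(b x^7) would be imaginary).
    Acceptance runs of the power-law experiments require this to stay 0."""

    clamped: int = 0
    aborted: int = 0  # realisations frozen after a non-finite state

    def merge(self, other: "GuardCounter") -> None:
        self.clamped += other.clamped
        self.aborted += other.aborted


@dataclass
class SimulationConfig:
    """Configuration of one ensemble run.

    Defaults follow the power-law experiments: start (1, 1), time horizon
    [0, 1] in 1000 equal steps.
    """

    x0: Sequence[float] = (1.0, 1.0)
    t0: float = 0.0
    T: float = 1.0
    n_steps: int = 1000
    n_realisations: int = 100
    scheme: str = "corrected"
    seed: int = 0
    noise_mode: str = "independent"  # "independent" | "shared"
    domain_box: Optional[tuple[float, float]] = None  # reflecting box per axis
    record: str = "full"  # "full" | "final"

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.T <= self.t0:
            raise ValueError("need T > t0")
        if self.n_steps < 1 or self.n_realisations < 1:
            raise ValueError("need n_steps >= 1 and n_realisations >= 1")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.noise_mode not in ("independent", "shared"):
            raise ValueError("noise_mode must be 'independent' or 'shared'")
        if self.record not in ("full", "final"):
            raise ValueError("record must be 'full' or 'final'")
        if self.domain_box is not None:
            lo, hi = self.domain_box
            if not hi > lo:
                raise ValueError("domain_box must satisfy hi > lo")

    @property
    def dt(self) -> float:
        return (self.T - self.t0) / self.n_steps


@dataclass
class TrajectoryEnsemble:
    """K sample paths on a common time grid.

    ``positions`` has shape (K, n_saved, d); with ``record='final'`` only
    the initial and final times are kept.
    """

    times: np.ndarray
    positions: np.ndarray
    scheme: str
    seed: int
    config: SimulationConfig
    guard: GuardCounter = _dc_field(default_factory=GuardCounter)

    @property
    def n_realisations(self) -> int:
        return self.positions.shape[0]

    @property
    def initials(self) -> np.ndarray:
        return self.positions[:, 0, :]

    @property
    def finals(self) -> np.ndarray:
        return self.positions[:, -1, :]

    def write_tracks(self, path) -> None:
        """Delimited text export: one row per (realisation, time sample)."""
        K, n, d = self.positions.shape
        with open(path, "w") as fh:
            fh.write("realisation\tt\t" + "\t".join(f"x{i+1}" for i in range(d)) + "\n")
            for i in range(K):
                for k in range(n):
                    coords = "\t".join(f"{v:.17g}" for v in self.positions[i, k])
                    fh.write(f"{i}\t{self.times[k]:.17g}\t{coords}\n")

    def write_finals(self, path) -> None:
        header = "\t".join(f"x{i+1}" for i in range(self.positions.shape[2]))
        np.savetxt(path, self.finals, delimiter="\t", header=header, comments="")


# ---------------------------------------------------------------------------
# single steps
# ---------------------------------------------------------------------------


def _noise_amplitude(
    field: CoefficientField, X: np.ndarray, guard: Optional[GuardCounter]
):
    """Return (diag_amp, full_V): one of the two is None.

    diag_amp has shape (n, d) (diagonal V entries); full_V has shape
    (n, d, d).  Negative diagonal entries are clamped to zero and counted.
    """
    if field.diffusion_diag is not None:
        dd = np.asarray(field.diffusion_diag(X), dtype=float)
        neg = dd < 0.0
        if neg.any():
            if guard is not None:
                guard.clamped += int(neg.sum())
            dd = np.where(neg, 0.0, dd)
        return np.sqrt(dd), None
    D = np.asarray(field.diffusion(X), dtype=float)
    return None, diffusion_factor(D)


def _em_step(
    x: np.ndarray,
    field: CoefficientField,
    dt: float,
    xi: np.ndarray,
    corrected: bool,
    guard: Optional[GuardCounter] = None,
) -> np.ndarray:
    if dt <= 0:
        raise ValueError("dt must be positive")
    X = np.atleast_2d(np.asarray(x, dtype=float))
    Xi = np.atleast_2d(np.asarray(xi, dtype=float))
    drift = np.asarray(field.advection(X), dtype=float)
    if corrected:
        drift = drift + field.div_diffusion_at(X)
    amp, V = _noise_amplitude(field, X, guard)
    root = np.sqrt(2.0 * dt)
    if V is None:
        noise = amp * Xi
    else:
        noise = np.einsum("nij,nj->ni", V, Xi)
    out = X + drift * dt + root * noise
    return out[0] if np.asarray(x).ndim == 1 else out


def em_step_naive(x, field: CoefficientField, dt: float, xi,
                  guard: Optional[GuardCounter] = None) -> np.ndarray:
    """One naive Euler--Maruyama step: drift A only."""
    return _em_step(x, field, dt, xi, corrected=False, guard=guard)


def em_step_corrected(x, field: CoefficientField, dt: float, xi,
                      guard: Optional[GuardCounter] = None) -> np.ndarray:
    """One divergence-corrected step: drift A + div D."""
    return _em_step(x, field, dt, xi, corrected=True, guard=guard)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


def _reflect_into(X: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect positions into [lo, hi]^d (specular / billiard reflection)."""
    span = hi - lo
    z = np.mod(X - lo, 2.0 * span)
    return lo + np.minimum(z, 2.0 * span - z)


def _chunk_noise(seed: int, stream: int, chunk_index: int,
                 n_steps: int, k: int, d: int) -> np.ndarray:
    """Gaussian increments for one chunk: shape (n_steps, k, d)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream, chunk_index))
    gen = np.random.Generator(np.random.SFC64(ss))
    return gen.standard_normal((n_steps, k, d))


def _simulate(
    config: SimulationConfig,
    field: CoefficientField,
    schemes: Sequence[str],
    stream: int = 0,
) -> list[TrajectoryEnsemble]:
    """Run the ensemble for one or several schemes over the same noise."""
    K, N, d = config.n_realisations, config.n_steps, field.dim
    if config.x0.shape != (d,):
        raise ValueError(f"x0 has shape {config.x0.shape}, field dim is {d}")
    dt = config.dt
    full = config.record == "full"
    n_saved = N + 1 if full else 2
    times = (config.t0 + dt * np.arange(N + 1)) if full else np.array([config.t0, config.T])

    out_pos = [np.empty((K, n_saved, d)) for _ in schemes]
    guards = [GuardCounter() for _ in schemes]
    corrected_flags = [s == "corrected" for s in schemes]

    for c0 in range(0, K, CHUNK):
        c1 = min(c0 + CHUNK, K)
        k = c1 - c0
        noise = _chunk_noise(config.seed, stream, c0 // CHUNK, N, k, d)
        states = [np.broadcast_to(config.x0, (k, d)).copy() for _ in schemes]
        for pos in out_pos:
            pos[c0:c1, 0, :] = config.x0
        for n in range(N):
            xi = noise[n]
            for s, (X, corr, guard) in enumerate(zip(states, corrected_flags, guards)):
                Xn = _em_step(X, field, dt, xi, corrected=corr, guard=guard)
                if config.domain_box is not None:
                    lo, hi = config.domain_box
                    Xn = _reflect_into(Xn, lo, hi)
                bad = ~np.isfinite(Xn).all(axis=1)
                if bad.any():
                    # freeze non-finite realisations at their last finite state
                    guard.aborted += int(bad.sum())
                    Xn[bad] = X[bad]
                states[s] = Xn
                if full:
                    out_pos[s][c0:c1, n + 1, :] = Xn
        if not full:
            for s in range(len(schemes)):
                out_pos[s][c0:c1, 1, :] = states[s]

    return [
        TrajectoryEnsemble(
            times=times,
            positions=out_pos[s],
            scheme=schemes[s],
            seed=config.seed,
            config=replace(config, scheme=schemes[s]),
            guard=guards[s],
        )
        for s in range(len(schemes))
    ]


def simulate_ensemble(
    config: SimulationConfig, field: CoefficientField
) -> TrajectoryEnsemble:
    """Simulate K realisations of the configured scheme.

    Deterministic: the same (config, field) yields a bitwise-identical
    ensemble.
    """
    return _simulate(config, field, (config.scheme,))[0]


def simulate_paired(
    config: SimulationConfig, field: CoefficientField
) -> tuple[TrajectoryEnsemble, TrajectoryEnsemble]:
    """Simulate the naive and corrected schemes with shared noise.

    Requires ``noise_mode='shared'``.  Realisation i of both ensembles
    consumes bitwise-identical Gaussian increments, so after one step from
    a common start the position difference is exactly ``div D(x0) * dt``.
    """
    if config.noise_mode != "shared":
        raise ValueError("simulate_paired requires noise_mode='shared'")
    naive, corrected = _simulate(config, field, ("naive", "corrected"))
    return naive, corrected
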