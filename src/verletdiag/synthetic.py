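"""Synthetic-data generators for every diagnostic in the toolkit.

These generators ship in the package (not only in the test suite) so that
users can calibrate detector thresholds against inputs with known ground
truth: pressure series with an injected rebuild-phase pattern and optional
inner-list sawtooth, free-flight ideal gases for validating the
missed-interaction model, Lennard-Jones fluid configurations for the
simulator, and height fields with closed-form curvature and bending energy.

Every generator takes an explicit integer seed and is bit-reproducible for
a fixed seed (NumPy Generator contract).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import UnitSystem, GROMACS_UNITS, REDUCED_UNITS
from .curvature import HeightField
from .ljsim import SimState
from .pressurediag import PressureSeries

__all__ = [
    "SyntheticPressureSpec",
    "gen_pressure_series",
    "expected_phase_means",
    "gen_freeflight_gas",
    "gen_lj_fluid",
    "gen_height_field",
    "maxwell_boltzmann_velocities",
]


# ---------------------------------------------------------------------------
# pressure series


@dataclass
class SyntheticPressureSpec:
    """Recipe for a synthetic scalar pressure series.

    The deterministic part is ``mean`` plus a periodic additive
    ``phase_pattern`` of length ``nstlist`` (the per-phase offsets, phase 0
    first) plus, optionally, a zero-mean sawtooth of period
    ``inner_period`` and peak-to-peak amplitude ``2*inner_amplitude``
    modelling the faster inner-list pruning cadence of a dual pair list
    (the superposition of the two periods produces the characteristic
    zigzag).  Gaussian white noise with sd ``noise_sd`` is added on top.
    """

    n_steps: int
    dt: float
    nstlist: int
    noise_sd: float = 0.0
    phase_pattern: Optional[np.ndarray] = None
    inner_period: Optional[int] = None
    inner_amplitude: float = 0.0
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 2 or self.nstlist < 1 or self.dt <= 0:
            raise ValueError("need n_steps >= 2, nstlist >= 1, dt > 0")
        if self.phase_pattern is not None:
            self.phase_pattern = np.asarray(self.phase_pattern, dtype=float)
            if len(self.phase_pattern) != self.nstlist:
                raise ValueError("phase_pattern length must equal nstlist")
        if self.inner_period is not None and self.inner_period < 2:
            raise ValueError("inner_period must be >= 2")


def _deterministic_part(spec: SyntheticPressureSpec, idx: np.ndarray) -> np.ndarray:
    out = np.full(len(idx), spec.mean)
    if spec.phase_pattern is not None:
        out = out + spec.phase_pattern[idx % spec.nstlist]
    if spec.inner_period is not None and spec.inner_amplitude != 0.0:
        p = spec.inner_period
        phase = idx % p
        # zero-mean sawtooth ramp over [-A, A]
        out = out + spec.inner_amplitude * (2.0 * phase / (p - 1) - 1.0)
    return out


def gen_pressure_series(spec: SyntheticPressureSpec) -> PressureSeries:
    """Generate the synthetic series; see :class:`SyntheticPressureSpec`.

    The per-phase means of the deterministic part are available in closed
    form from :func:`expected_phase_means` for oracle checks.
    """
    rng = np.random.default_rng(spec.seed)
    idx = np.arange(spec.n_steps)
    values = _deterministic_part(spec, idx)
    if spec.noise_sd > 0:
        values = values + rng.normal(scale=spec.noise_sd, size=spec.n_steps)
    return PressureSeries(
        values=values,
        dt=spec.dt,
        start_step=0,
        nstlist=spec.nstlist,
        provenance=f"synthetic(seed={spec.seed})",
    )


def expected_phase_means(spec: SyntheticPressureSpec) -> np.ndarray:
    """Exact per-phase means of the deterministic part of the generator,
    averaged over one full joint cycle of the outer and inner periods."""
    cycle = spec.nstlist
    if spec.inner_period is not None:
        cycle = math.lcm(spec.nstlist, spec.inner_period)
    idx = np.arange(cycle)
    det = _deterministic_part(spec, idx)
    return det.reshape(cycle // spec.nstlist, spec.nstlist).mean(axis=0)


# ---------------------------------------------------------------------------
# particle systems


def maxwell_boltzmann_velocities(
    n: int,
    temperature: float,
    masses: np.ndarray,
    rng: np.random.Generator,
    units: UnitSystem = GROMACS_UNITS,
    remove_com: bool = True,
) -> np.ndarray:
    """Sample velocities with per-component variance kB T / m; optionally
    remove the center-of-mass drift (mass-weighted)."""
    masses = np.broadcast_to(np.atleast_1d(np.asarray(masses, float)), (n,))
    sigma = np.sqrt(units.kB * temperature / masses)
    v = rng.normal(size=(n, 3)) * sigma[:, None]
    if remove_com:
        v -= np.average(v, axis=0, weights=masses)
    return v


def gen_freeflight_gas(
    rho: float,
    temperature: float,
    mass: float,
    box: np.ndarray | float,
    seed: int = 0,
    units: UnitSystem = GROMACS_UNITS,
) -> SimState:
    """Uniformly distributed ideal-gas particles with Maxwell-Boltzmann
    velocities; run with ``potential=None`` for free flight.

    ``box`` may be a scalar (cubic box) or three lengths; the particle
    count is ``round(rho * V)``.  Velocities are rescaled so the kinetic
    temperature matches ``temperature`` exactly: in free flight velocities
    are never resampled, so a one-shot thermal fluctuation of the sampled
    kinetic energy would otherwise persist for the whole run.
    """
    box = np.broadcast_to(np.atleast_1d(np.asarray(box, float)), (3,)).copy()
    n = int(round(rho * float(np.prod(box))))
    if n < 2:
        raise ValueError("box too small for the requested density")
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 3)) * box
    vel = maxwell_boltzmann_velocities(n, temperature, mass, rng, units)
    state = SimState(positions=pos, velocities=vel, box=box, masses=np.full(n, mass))
    t_now = state.temperature(units)
    if t_now > 0 and temperature > 0:
        state.velocities *= math.sqrt(temperature / t_now)
    return state


def gen_lj_fluid(
    n: int,
    rho: float,
    temperature: float,
    seed: int = 0,
    mass: float = 1.0,
    units: UnitSystem = REDUCED_UNITS,
) -> SimState:
    """Cubic-lattice LJ fluid start at number density ``rho`` (reduced
    units by default): n particles on a simple cubic lattice (vacancies if
    n is not a cube) with Maxwell-Boltzmann velocities rescaled to the
    exact target temperature.  Equilibrate before production.
    """
    if n < 2 or rho <= 0:
        raise ValueError("need n >= 2 and rho > 0")
    box = np.full(3, (n / rho) ** (1.0 / 3.0))
    side = int(math.ceil(n ** (1.0 / 3.0)))
    rng = np.random.default_rng(seed)
    coords = np.stack(
        np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    take = rng.permutation(len(coords))[:n]
    pos = (coords[take] + 0.5) * (box / side)
    vel = maxwell_boltzmann_velocities(n, temperature, mass, rng, units)
    state = SimState(positions=pos, velocities=vel, box=box, masses=np.full(n, mass))
    t_now = state.temperature(units)
    if t_now > 0 and temperature > 0:
        state.velocities *= math.sqrt(temperature / t_now)
    return state


# ---------------------------------------------------------------------------
# height fields


def gen_height_field(
    mode: str,
    shape: tuple[int, int] = (64, 64),
    box: tuple[float, float] = (50.0, 50.0),
    amplitude: float = 0.25,
    wave: int = 1,
    amplitude2: float = 0.0,
    wave2: int = 1,
    offset: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[HeightField, dict]:
    """Height fields with closed-form small-slope curvature and energy.

    Modes: ``flat`` (constant ``offset``); ``sinusoid``
    (``a sin(2 pi k x / L_x)``); ``superposition`` (adds
    ``a2 sin(2 pi k2 y / L_y)``).  Returns the field and an ``info`` dict
    with the analytic mean-curvature grid ``H`` and the analytic
    ``integral_h2`` (small-slope limit), so that
    ``E = 2 kappa * integral_h2``.  For one sinusoid
    ``integral_h2 = a^2 k^4 L_x L_y / 8`` with ``k = 2 pi wave / L_x``;
    superposed orthogonal modes add their integrals (cross terms vanish).
    """
    nx, ny = shape
    lx, ly = box
    dx, dy = lx / nx, ly / ny
    x = (np.arange(nx) + 0.0) * dx
    y = (np.arange(ny) + 0.0) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    kx = 2.0 * math.pi * wave / lx
    ky = 2.0 * math.pi * wave2 / ly
    if mode == "flat":
        h = np.full((nx, ny), offset)
        h_analytic = np.zeros((nx, ny))
        integral = 0.0
    elif mode == "sinusoid":
        h = offset + amplitude * np.sin(kx * xx)
        h_analytic = -(amplitude / 2.0) * kx**2 * np.sin(kx * xx)
        integral = amplitude**2 * kx**4 * lx * ly / 8.0
    elif mode == "superposition":
        h = offset + amplitude * np.sin(kx * xx) + amplitude2 * np.sin(ky * yy)
        h_analytic = (
            -(amplitude / 2.0) * kx**2 * np.sin(kx * xx)
            - (amplitude2 / 2.0) * ky**2 * np.sin(ky * yy)
        )
        integral = (
            amplitude**2 * kx**4 * lx * ly / 8.0
            + amplitude2**2 * ky**4 * lx * ly / 8.0
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    field = HeightField(h=h, dx=dx, dy=dy)
    info = {"H": h_analytic, "integral_h2": integral}
    return field, info
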