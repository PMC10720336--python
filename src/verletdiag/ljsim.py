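"""Minimal instrumented Lennard-Jones fluid simulator.

A velocity-Verlet NVE/NVT/NPT simulator for truncated-and-shifted LJ
particles in a periodic orthorhombic box, built to *reproduce* neighbor-list
artifacts at desk scale rather than for production work.  The neighbor list
is rebuilt every ``nstlist`` steps with outer cutoff r_l; between rebuilds
the (possibly stale) list is reused, so pairs that cross from r > r_l to
r < r_c are genuinely missed by the force loop — exactly the mechanism that
biases the virial pressure in large production simulations.  A dual-list
mode prunes an inner list (cutoff r_inner) from the outer list at a faster
cadence, mimicking dual pair-list engines.

Instrumentation: per-step diagonal pressure-tensor samples (kinetic and
virial parts kept separable), box dimensions, energies, and an optional
missed-interaction log (unique new misses and miss events per step,
obtained from an exact all-pair scan at the interaction cutoff).

Thermostat: velocity rescaling to the target temperature every
``nsttcouple`` steps.  Barostat: Berendsen-type first-order box relaxation
every ``nstpcouple`` steps with isotropic, semi-isotropic (xy vs z), or
fully anisotropic coupling.  Neither scheme samples a rigorous ensemble;
both suffice to expose pressure-artifact phenomenology, which is
barostat-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import CutoffScheme, ScheduleConfig, UnitSystem, REDUCED_UNITS

__all__ = [
    "SimState",
    "LJPotential",
    "NeighborList",
    "PressureSample",
    "BarostatConfig",
    "ThermostatConfig",
    "RunResult",
    "build_neighbor_list",
    "brute_force_pairs",
    "forces_energy_virial",
    "instantaneous_pressure",
    "count_missed",
    "run",
]


@dataclass
class SimState:
    """Positions/velocities of N particles in a periodic orthorhombic box.

    Positions are wrapped into ``[0, box)`` on construction (required by the
    periodic neighbor search).  Units follow the chosen
    :class:`~verletdiag.core.UnitSystem` (nm/ps/amu or reduced LJ).
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    masses: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        self.positions = np.array(self.positions, dtype=float)
        self.velocities = np.array(self.velocities, dtype=float)
        self.box = np.array(self.box, dtype=float)
        self.masses = np.atleast_1d(np.array(self.masses, dtype=float))
        n = len(self.positions)
        if n < 2:
            raise ValueError("need at least 2 particles")
        if self.masses.size == 1:
            self.masses = np.full(n, float(self.masses[0]))
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions and velocities must be (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive lengths")
        self.wrap()

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def wrap(self) -> None:
        self.positions -= self.box * np.floor(self.positions / self.box)
        # guard against positions == box after floating-point wrap
        np.minimum(self.positions, np.nextafter(self.box, 0.0), out=self.positions)

    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.masses[:, None] * self.velocities**2))

    def temperature(self, units: UnitSystem, n_dof: Optional[int] = None) -> float:
        if n_dof is None:
            n_dof = 3 * self.n - 3  # COM momentum removed
        return 2.0 * self.kinetic_energy() / (n_dof * units.kB)

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(),
            self.velocities.copy(),
            self.box.copy(),
            self.masses.copy(),
            self.step,
        )


@dataclass
class LJPotential:
    """Truncated-and-shifted Lennard-Jones potential.

    ``u(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] + shift`` for r < r_c and 0
    beyond, with ``shift`` chosen so that u(r_c) = 0.  The force is
    continuous for r < r_c (a discontinuity of magnitude |u'(r_c)| remains
    at the cutoff itself); ``force_shift=True`` additionally subtracts
    u'(r_c) (r - r_c), making the force continuous at r_c as well — useful
    for strict energy-conservation checks.
    """

    epsilon: float
    sigma: float
    r_c: float
    force_shift: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0 or self.r_c <= 0:
            raise ValueError("epsilon, sigma, r_c must be positive")
        sr6 = (self.sigma / self.r_c) ** 6
        self.shift = -4.0 * self.epsilon * (sr6**2 - sr6)
        # u'(r_c), used by the force-shifted variant
        self._dudr_rc = (
            -24.0 * self.epsilon * (2.0 * sr6**2 - sr6) / self.r_c
        )

    def energy(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        sr6 = (self.sigma / r) ** 6
        u = 4.0 * self.epsilon * (sr6**2 - sr6) + self.shift
        if self.force_shift:
            u = u - self._dudr_rc * (r - self.r_c)
        return np.where(r < self.r_c, u, 0.0)


@dataclass
class NeighborList:
    """Pair list (i < j) built at ``built_at_step`` with cutoff ``r_l``.

    In dual mode ``inner_pairs`` holds the subset used for forces, pruned at
    ``inner_built_at`` with cutoff ``r_inner``.
    """

    pairs: np.ndarray
    built_at_step: int
    r_l: float
    inner_pairs: Optional[np.ndarray] = None
    inner_built_at: Optional[int] = None
    r_inner: Optional[float] = None

    @property
    def force_pairs(self) -> np.ndarray:
        return self.pairs if self.inner_pairs is None else self.inner_pairs


@dataclass
class PressureSample:
    """Instantaneous pressure tensor (pressure units of the unit system),
    with separable kinetic and virial parts (energy-density units)."""

    step: int
    tensor: np.ndarray
    kinetic: np.ndarray
    virial: np.ndarray

    @property
    def scalar(self) -> float:
        return float(np.trace(self.tensor) / 3.0)

    @property
    def parallel(self) -> float:
        """In-plane pressure (P_xx + P_yy)/2."""
        return float((self.tensor[0, 0] + self.tensor[1, 1]) / 2.0)

    @property
    def normal(self) -> float:
        """Normal pressure P_zz."""
        return float(self.tensor[2, 2])


@dataclass
class BarostatConfig:
    """Berendsen-type box rescaling toward ``target`` pressure.

    Every ``nstpcouple`` steps each coupled dimension group is scaled by
    ``mu = (1 - dt_couple * compressibility * (target - P) / tau_p)^(1/3)``.
    Modes: ``isotropic`` (scalar P drives all axes), ``semi-isotropic``
    ((P_xx+P_yy)/2 drives x,y and P_zz drives z), ``anisotropic`` (each axis
    driven by its own diagonal component).
    """

    mode: str = "isotropic"
    tau_p: float = 12.0
    target: float = 1.0
    compressibility: float = 4.5e-5

    def __post_init__(self) -> None:
        if self.mode not in ("isotropic", "semi-isotropic", "anisotropic"):
            raise ValueError(f"unknown barostat mode {self.mode!r}")
        if self.tau_p <= 0 or self.compressibility <= 0:
            raise ValueError("tau_p and compressibility must be positive")


@dataclass
class ThermostatConfig:
    """Velocity rescaling to ``target`` temperature every ``nsttcouple``."""

    target: float


# ---------------------------------------------------------------------------
# neighbor search


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.rint(d / box)


def brute_force_pairs(state: SimState, cutoff: float) -> np.ndarray:
    """O(N^2) minimum-image pair search; the oracle for the fast search."""
    pos, box = state.positions, state.box
    i, j = np.triu_indices(state.n, k=1)
    d = _min_image(pos[i] - pos[j], box)
    mask = np.einsum("ij,ij->i", d, d) < cutoff * cutoff
    return np.column_stack([i[mask], j[mask]]).astype(np.int64)


def _periodic_pairs(state: SimState, cutoff: float) -> np.ndarray:
    """Exact periodic fixed-radius pair search (grid/tree based)."""
    tree = cKDTree(state.positions, boxsize=state.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order].astype(np.int64)


def build_neighbor_list(state: SimState, cutoffs: CutoffScheme) -> NeighborList:
    """Build the pair list within r_l under the minimum-image convention.

    The pair set is exactly the brute-force O(N^2) set (grid-accelerated
    search, no clustering — a 1x1 pair list, isotropic by construction).
    Requires every box length > 2 r_l so that the minimum image is unique.
    """
    if np.any(state.box <= 2.0 * cutoffs.r_l):
        raise ValueError(
            f"box {state.box} too small: every length must exceed "
            f"2*r_l = {2.0 * cutoffs.r_l} for minimum-image validity"
        )
    pairs = _periodic_pairs(state, cutoffs.r_l)
    nlist = NeighborList(pairs=pairs, built_at_step=state.step, r_l=cutoffs.r_l)
    if cutoffs.dual:
        nlist.r_inner = cutoffs.r_inner
        prune_inner_list(nlist, state)
    return nlist


def prune_inner_list(nlist: NeighborList, state: SimState) -> None:
    """Refresh the inner list: outer pairs currently within r_inner.

    When ``r_inner >= r_l`` no pruning is applied (the inner list is the
    whole outer list), making the dual scheme exactly degenerate to the
    single-list scheme.
    """
    if nlist.r_inner is None:
        raise ValueError("neighbor list has no inner cutoff")
    if nlist.r_inner >= nlist.r_l:
        nlist.inner_pairs = nlist.pairs
    else:
        pos, box = state.positions, state.box
        d = _min_image(pos[nlist.pairs[:, 0]] - pos[nlist.pairs[:, 1]], box)
        mask = np.einsum("ij,ij->i", d, d) < nlist.r_inner**2
        nlist.inner_pairs = nlist.pairs[mask]
    nlist.inner_built_at = state.step


# ---------------------------------------------------------------------------
# forces, pressure, miss counting


def forces_energy_virial(
    state: SimState, potential: LJPotential, nlist: NeighborList
) -> tuple[np.ndarray, float, np.ndarray]:
    """Pair forces, shifted potential energy, and virial tensor from the
    listed pairs (the list may be stale; only pairs with *current* r < r_c
    contribute).

    virial_ab = sum_pairs d_a f_b with d = r_i - r_j and f the force on i.
    """
    n = state.n
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    pairs = nlist.force_pairs
    if len(pairs) == 0:
        return forces, 0.0, virial
    i, j = pairs[:, 0], pairs[:, 1]
    d = _min_image(state.positions[i] - state.positions[j], state.box)
    r2 = np.einsum("ij,ij->i", d, d)
    mask = r2 < potential.r_c**2
    if not mask.any():
        return forces, 0.0, virial
    i, j, d, r2 = i[mask], j[mask], d[mask], r2[mask]
    # overflow here only happens after a divergence, which run() reports
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        sr2 = potential.sigma**2 / r2
        sr6 = sr2**3
        # f_vec = w * d ; w = -(1/r) du/dr
        w = 24.0 * potential.epsilon * (2.0 * sr6**2 - sr6) / r2
        u = 4.0 * potential.epsilon * (sr6**2 - sr6) + potential.shift
        if potential.force_shift:
            r = np.sqrt(r2)
            u = u - potential._dudr_rc * (r - potential.r_c)
            w = w + potential._dudr_rc / r
    fvec = w[:, None] * d
    for c in range(3):
        forces[:, c] = np.bincount(i, weights=fvec[:, c], minlength=n)
        forces[:, c] -= np.bincount(j, weights=fvec[:, c], minlength=n)
    virial = d.T @ fvec
    return forces, float(u.sum()), virial


def instantaneous_pressure(
    state: SimState, virial: np.ndarray, units: UnitSystem = REDUCED_UNITS
) -> PressureSample:
    """Virial pressure tensor ``P_ab = (sum_i m v_a v_b + W_ab)/V`` times
    the unit system's pressure conversion factor."""
    kinetic = np.einsum(
        "i,ia,ib->ab", state.masses, state.velocities, state.velocities
    )
    tensor = (kinetic + virial) / state.volume * units.pressure_factor
    return PressureSample(
        step=state.step, tensor=tensor, kinetic=kinetic, virial=virial
    )


def _encode(pairs: np.ndarray, n: int) -> np.ndarray:
    if pairs.size == 0:
        return np.empty(0, dtype=np.int64)
    return pairs[:, 0].astype(np.int64) * n + pairs[:, 1].astype(np.int64)


def count_missed(
    state: SimState,
    r_c: float,
    nlist: NeighborList,
    seen: Optional[set] = None,
) -> tuple[int, int]:
    """Count pair interactions missed by the active force list right now.

    A missed pair has current minimum-image distance < r_c but is absent
    from the list used for forces.  ``seen`` (a set of encoded pairs,
    maintained by the caller per list lifetime) deduplicates pairs already
    missed at an earlier step of the same lifetime.

    Returns ``(n_unique_new, n_events)`` where ``n_events`` is the number of
    currently missed pairs and ``n_unique_new`` those not seen before.
    """
    within = _encode(_periodic_pairs(state, r_c), state.n)
    active = np.sort(_encode(nlist.force_pairs, state.n))
    idx = np.searchsorted(active, within)
    idx = np.minimum(idx, max(len(active) - 1, 0))
    if len(active):
        missing = within[active[idx] != within]
    else:
        missing = within
    n_events = len(missing)
    if seen is None:
        return n_events, n_events
    new = [p for p in missing.tolist() if p not in seen]
    seen.update(new)
    return len(new), n_events


# ---------------------------------------------------------------------------
# the integrator


@dataclass
class RunResult:
    """Per-step trajectory diagnostics from :func:`run`.

    Sample 0 is the initial configuration with a freshly built list (phase
    0); sample s corresponds to the state after s completed steps.  All
    pressures are in the unit system's pressure unit.
    """

    steps: np.ndarray
    p_diag: np.ndarray
    p_scalar: np.ndarray
    e_pot: np.ndarray
    e_kin: np.ndarray
    box: np.ndarray
    miss_unique: np.ndarray
    miss_events: np.ndarray
    state: SimState
    schedule: ScheduleConfig
    cutoffs: CutoffScheme
    units: UnitSystem

    @property
    def e_total(self) -> np.ndarray:
        return self.e_pot + self.e_kin

    def pressure_series(self):
        """Export as a :class:`~verletdiag.pressurediag.PressureSeries`."""
        from .pressurediag import PressureSeries

        return PressureSeries(
            values=self.p_diag,
            dt=self.schedule.dt,
            start_step=int(self.steps[0]),
            nstlist=self.schedule.nstlist,
            provenance="ljsim.run",
        )


def run(
    state: SimState,
    potential: Optional[LJPotential],
    cutoffs: CutoffScheme,
    schedule: ScheduleConfig,
    n_steps: int,
    thermostat: Optional[ThermostatConfig] = None,
    barostat: Optional[BarostatConfig] = None,
    units: UnitSystem = REDUCED_UNITS,
    count_misses: bool = False,
) -> RunResult:
    """Velocity-Verlet propagation with scheduled list rebuilds.

    The outer list is rebuilt whenever ``step % nstlist == 0`` (before the
    force evaluation of that step, so samples at those steps are phase 0);
    in dual mode the inner list is pruned whenever
    ``step % nstlist_inner == 0``.  ``potential=None`` runs free flight
    (ideal gas) — useful for validating the missed-interaction model.

    The caller is responsible for a stable time step (guideline:
    ``dt <~ 0.005 tau_LJ`` for dense reduced-unit fluids).  Non-finite
    positions/velocities/forces abort with the offending step number.
    """
    cutoffs.validate_against(schedule.nstlist)
    state = state.copy()
    n = state.n
    inv_m = 1.0 / state.masses[:, None]
    r_c = potential.r_c if potential is not None else cutoffs.r_c

    n_samp = n_steps + 1
    out = {
        "steps": np.arange(n_samp),
        "p_diag": np.empty((n_samp, 3)),
        "p_scalar": np.empty(n_samp),
        "e_pot": np.empty(n_samp),
        "e_kin": np.empty(n_samp),
        "box": np.empty((n_samp, 3)),
        "miss_unique": np.zeros(n_samp, dtype=np.int64),
        "miss_events": np.zeros(n_samp, dtype=np.int64),
    }

    def eval_forces(nlist):
        if potential is None:
            return np.zeros((n, 3)), 0.0, np.zeros((3, 3))
        return forces_energy_virial(state, potential, nlist)

    def record(s, e_pot, virial):
        ps = instantaneous_pressure(state, virial, units)
        out["p_diag"][s] = np.diag(ps.tensor)
        out["p_scalar"][s] = ps.scalar
        out["e_pot"][s] = e_pot
        out["e_kin"][s] = state.kinetic_energy()
        out["box"][s] = state.box

    state.step = 0
    nlist = build_neighbor_list(state, cutoffs)
    seen: set = set()
    forces, e_pot, virial = eval_forces(nlist)
    record(0, e_pot, virial)

    dt = schedule.dt
    for s in range(1, n_steps + 1):
        state.velocities += 0.5 * dt * forces * inv_m
        state.positions += dt * state.velocities
        state.wrap()
        state.step = s
        if s % schedule.nstlist == 0:
            nlist = build_neighbor_list(state, cutoffs)
            seen = set()
        elif cutoffs.dual and s % cutoffs.nstlist_inner == 0:
            prune_inner_list(nlist, state)
        forces, e_pot, virial = eval_forces(nlist)
        state.velocities += 0.5 * dt * forces * inv_m
        if not (np.isfinite(forces).all() and np.isfinite(state.velocities).all()):
            raise RuntimeError(f"simulation diverged at step {s}")
        if count_misses:
            nu, ne = count_missed(state, r_c, nlist, seen)
            out["miss_unique"][s] = nu
            out["miss_events"][s] = ne
        record(s, e_pot, virial)
        if thermostat is not None and s % schedule.nsttcouple == 0:
            t_inst = state.temperature(units)
            if t_inst > 0:
                state.velocities *= math.sqrt(thermostat.target / t_inst)
        if barostat is not None and s % schedule.nstpcouple == 0:
            _apply_berendsen(state, out["p_diag"][s], barostat, schedule, units)

    return RunResult(state=state, schedule=schedule, cutoffs=cutoffs, units=units, **out)


def _apply_berendsen(
    state: SimState,
    p_diag: np.ndarray,
    cfg: BarostatConfig,
    schedule: ScheduleConfig,
    units: UnitSystem,
) -> None:
    dt_c = schedule.nstpcouple * schedule.dt
    if cfg.mode == "isotropic":
        drive = np.full(3, p_diag.mean())
    elif cfg.mode == "semi-isotropic":
        p_par = 0.5 * (p_diag[0] + p_diag[1])
        drive = np.array([p_par, p_par, p_diag[2]])
    else:
        drive = p_diag.copy()
    mu = np.cbrt(1.0 - dt_c * cfg.compressibility * (cfg.target - drive) / cfg.tau_p)
    state.box *= mu
    state.positions *= mu
    state.wrap()
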