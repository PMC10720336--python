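"""Unit conventions, MD schedule configuration, and schedule sanity checks.

The toolkit adopts GROMACS-style molecular units throughout: lengths in nm,
times in ps, masses in amu (g/mol), energies in kJ/mol, temperatures in K,
and pressures in bar.  With these units the Boltzmann constant is
``0.0083144621 kJ/(mol K)`` and an energy density of 1 (kJ/mol)/nm^3
corresponds to ``16.6054`` bar.  A reduced Lennard-Jones unit system
(``epsilon = sigma = m = kB = 1``) is provided for desk-scale simulator
experiments; there the pressure conversion factor is 1.

The central configuration object is :class:`ScheduleConfig`, which holds the
step intervals at which a simulation engine rebuilds neighbor lists
(``nstlist``), samples and evaluates energies (``nstenergy``,
``nstcalcenergy``), and applies barostat and thermostat actions
(``nstpcouple``, ``nsttcouple``).  :func:`check_schedule` flags interval
combinations known to produce or hide pressure artifacts: couplers firing
out of phase with neighbor-list rebuilds act on pressures computed from
stale (possibly incomplete) pair lists, while an energy-evaluation interval
that is an exact multiple of the rebuild interval only ever samples the
pressure right after a rebuild and can mask the problem entirely.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

__all__ = [
    "UnitSystem",
    "GROMACS_UNITS",
    "REDUCED_UNITS",
    "KB_KJMOL",
    "PRESSURE_FACTOR_BAR",
    "ScheduleConfig",
    "CutoffScheme",
    "ScheduleDiagnostic",
    "check_schedule",
    "read_mdp",
    "schedule_from_mdp",
    "cutoffs_from_mdp",
]

#: Boltzmann constant in kJ/(mol K).
KB_KJMOL = 0.0083144621

#: Conversion from (kJ/mol)/nm^3 to bar.
PRESSURE_FACTOR_BAR = 16.6054


@dataclass(frozen=True)
class UnitSystem:
    """A named unit convention: Boltzmann constant and pressure conversion.

    ``pressure_factor`` converts an energy density (energy unit per
    length-unit cubed) into the pressure unit, and must be applied exactly
    once in any pressure computation.
    """

    name: str
    length: str
    time: str
    mass: str
    energy: str
    temperature: str
    pressure: str
    kB: float
    pressure_factor: float

    def __post_init__(self) -> None:
        if self.kB <= 0 or self.pressure_factor <= 0:
            raise ValueError("kB and pressure_factor must be positive")


GROMACS_UNITS = UnitSystem(
    name="gromacs",
    length="nm",
    time="ps",
    mass="amu",
    energy="kJ/mol",
    temperature="K",
    pressure="bar",
    kB=KB_KJMOL,
    pressure_factor=PRESSURE_FACTOR_BAR,
)

REDUCED_UNITS = UnitSystem(
    name="reduced-lj",
    length="sigma",
    time="tau",
    mass="m",
    energy="epsilon",
    temperature="epsilon/kB",
    pressure="epsilon/sigma^3",
    kB=1.0,
    pressure_factor=1.0,
)


def _check_interval(name: str, value: int) -> int:
    if int(value) != value or value < 1:
        raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
    return int(value)


@dataclass
class ScheduleConfig:
    """Step intervals of an MD engine's bookkeeping actions.

    Parameters
    ----------
    dt : float
        Integration time step (ps).
    nstlist : int
        Steps between neighbor-list rebuilds.
    nstenergy, nstcalcenergy : int
        Steps between energy/pressure *sampling* and *evaluation*.
    nstpcouple, nsttcouple : int, optional
        Steps between barostat / thermostat actions.  ``None`` defaults to
        ``nstlist`` (couplers in phase with list rebuilds).
    vbt : float, optional
        Tolerance on the missed-interaction energy drift per particle
        (kJ/mol/ps), the analog of GROMACS's verlet-buffer-tolerance.
        ``None`` disables tolerance-driven adjustment.
    """

    dt: float
    nstlist: int
    nstenergy: int = 1000
    nstcalcenergy: int = 100
    nstpcouple: Optional[int] = None
    nsttcouple: Optional[int] = None
    vbt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        self.nstlist = _check_interval("nstlist", self.nstlist)
        self.nstenergy = _check_interval("nstenergy", self.nstenergy)
        self.nstcalcenergy = _check_interval("nstcalcenergy", self.nstcalcenergy)
        if self.nstpcouple is None:
            self.nstpcouple = self.nstlist
        if self.nsttcouple is None:
            self.nsttcouple = self.nstlist
        self.nstpcouple = _check_interval("nstpcouple", self.nstpcouple)
        self.nsttcouple = _check_interval("nsttcouple", self.nsttcouple)

    @property
    def commensurate(self) -> bool:
        """True iff both coupler intervals are integer multiples of nstlist."""
        return (self.nstpcouple % self.nstlist == 0) and (
            self.nsttcouple % self.nstlist == 0
        )

    @property
    def interval(self) -> float:
        """Length of one neighbor-list lifetime, ``nstlist * dt`` (ps)."""
        return self.nstlist * self.dt


@dataclass
class CutoffScheme:
    """Interaction cutoff r_c and neighbor-list (outer) cutoff r_l, in nm.

    The shell ``r_l - r_c`` is the Verlet buffer that keeps the pair list
    valid between rebuilds.  In dual-list mode an inner list with cutoff
    ``r_inner`` is pruned from the outer list every ``nstlist_inner`` steps
    and used for the force evaluation.
    """

    r_c: float
    r_l: float
    dual: bool = False
    r_inner: Optional[float] = None
    nstlist_inner: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.r_c > 0:
            raise ValueError("r_c must be positive")
        if self.r_l < self.r_c:
            raise ValueError(f"r_l ({self.r_l}) must be >= r_c ({self.r_c})")
        if self.dual:
            if self.r_inner is None or self.nstlist_inner is None:
                raise ValueError("dual mode requires r_inner and nstlist_inner")
            if not (self.r_c <= self.r_inner <= self.r_l):
                raise ValueError("dual mode requires r_c <= r_inner <= r_l")
            self.nstlist_inner = _check_interval("nstlist_inner", self.nstlist_inner)

    def validate_against(self, nstlist: int) -> None:
        """Check the inner-list interval divides the outer one."""
        if self.dual:
            if not (1 <= self.nstlist_inner <= nstlist):
                raise ValueError("nstlist_inner must lie in [1, nstlist]")
            if nstlist % self.nstlist_inner != 0:
                raise ValueError("nstlist must be a multiple of nstlist_inner")

    @property
    def buffer(self) -> float:
        return self.r_l - self.r_c


@dataclass(frozen=True)
class ScheduleDiagnostic:
    """A machine-readable warning about a schedule configuration."""

    code: str
    message: str


def check_schedule(cfg: ScheduleConfig) -> list[ScheduleDiagnostic]:
    """Flag schedule interval combinations that cause or mask artifacts.

    Pure and deterministic: the warning set depends only on the divisibility
    relations among the intervals.

    Returns warnings for

    * ``nstpcouple`` not an integer multiple of ``nstlist`` — the barostat
      periodically acts on pressures computed from a stale pair list;
    * ``nsttcouple`` not an integer multiple of ``nstlist`` — same for the
      thermostat;
    * ``nstcalcenergy`` an integer multiple of ``nstlist`` — pressure is then
      only ever evaluated immediately after a rebuild, which can mask
      missed-interaction deviations (not reported when ``nstlist == 1``,
      where no stale-list steps exist).
    """
    out: list[ScheduleDiagnostic] = []
    if cfg.nstpcouple % cfg.nstlist != 0:
        out.append(
            ScheduleDiagnostic(
                code="nstpcouple-incommensurate",
                message=(
                    f"nstpcouple={cfg.nstpcouple} is not a multiple of "
                    f"nstlist={cfg.nstlist}: the barostat will periodically "
                    "act on pressures computed with a stale neighbor list."
                ),
            )
        )
    if cfg.nsttcouple % cfg.nstlist != 0:
        out.append(
            ScheduleDiagnostic(
                code="nsttcouple-incommensurate",
                message=(
                    f"nsttcouple={cfg.nsttcouple} is not a multiple of "
                    f"nstlist={cfg.nstlist}: the thermostat will periodically "
                    "act on kinetic energies biased by missed interactions."
                ),
            )
        )
    if cfg.nstlist > 1 and cfg.nstcalcenergy % cfg.nstlist == 0:
        out.append(
            ScheduleDiagnostic(
                code="nstcalcenergy-masks-misses",
                message=(
                    f"nstcalcenergy={cfg.nstcalcenergy} is a multiple of "
                    f"nstlist={cfg.nstlist}: energies/pressures are only "
                    "evaluated right after neighbor-list rebuilds, which can "
                    "mask missed-interaction deviations.  Consider "
                    "nstcalcenergy=1 for diagnosis."
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# mdp-style key-value configuration files


def read_mdp(path: str | Path) -> dict[str, str]:
    """Parse a GROMACS-mdp-style ``key = value`` text file into a dict.

    Lines starting with ``;`` (or ``#``) and inline ``;`` comments are
    ignored.  Keys are normalized to lower case with ``_`` mapped to ``-``
    so that values can be pasted directly from an mdp or log file.  This is
    a plain key-value reader, not a full mdp parser.
    """
    params: dict[str, str] = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        key = re.sub(r"[_\s]", "-", key.strip().lower()).replace("--", "-")
        params[key] = value.strip()
    return params


def _get_float(params: dict[str, str], *names: str) -> Optional[float]:
    for n in names:
        if n in params:
            return float(params[n])
    return None


def _get_int(params: dict[str, str], *names: str) -> Optional[int]:
    v = _get_float(params, *names)
    return None if v is None else int(v)


def schedule_from_mdp(params: dict[str, str]) -> ScheduleConfig:
    """Build a :class:`ScheduleConfig` from mdp-style parameters.

    Recognized keys: ``dt``, ``nstlist``, ``nstenergy``, ``nstcalcenergy``,
    ``nstpcouple``, ``nsttcouple``, ``verlet-buffer-tolerance`` (negative
    values disable the tolerance, as in GROMACS).
    """
    dt = _get_float(params, "dt")
    nstlist = _get_int(params, "nstlist")
    if dt is None or nstlist is None:
        raise ValueError("config must define at least 'dt' and 'nstlist'")
    vbt = _get_float(params, "verlet-buffer-tolerance", "vbt")
    if vbt is not None and vbt < 0:
        vbt = None
    return ScheduleConfig(
        dt=dt,
        nstlist=nstlist,
        nstenergy=_get_int(params, "nstenergy") or 1000,
        nstcalcenergy=_get_int(params, "nstcalcenergy") or 100,
        nstpcouple=_get_int(params, "nstpcouple"),
        nsttcouple=_get_int(params, "nsttcouple"),
        vbt=vbt,
    )


def cutoffs_from_mdp(params: dict[str, str]) -> CutoffScheme:
    """Build a :class:`CutoffScheme` from mdp-style parameters.

    ``r_c`` is taken as the larger of ``rvdw``/``rcoulomb`` (or an explicit
    ``r-c`` key); ``r_l`` from ``rlist`` (or ``r-l``), defaulting to r_c.
    """
    rvdw = _get_float(params, "rvdw")
    rcoul = _get_float(params, "rcoulomb")
    r_c = _get_float(params, "r-c", "rc")
    if r_c is None:
        cands = [v for v in (rvdw, rcoul) if v is not None]
        if not cands:
            raise ValueError("config must define rvdw/rcoulomb or r_c")
        r_c = max(cands)
    r_l = _get_float(params, "rlist", "r-l", "rl")
    if r_l is None:
        r_l = r_c
    r_inner = _get_float(params, "r-inner", "rinner")
    nst_inner = _get_int(params, "nstlist-inner")
    dual = r_inner is not None and nst_inner is not None
    return CutoffScheme(
        r_c=r_c, r_l=r_l, dual=dual, r_inner=r_inner, nstlist_inner=nst_inner
    )
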