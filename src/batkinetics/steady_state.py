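"""Steady-state free-fatty-acid (palmitate) tracer kinetics.

During a constant [U-13C]palmitate infusion the plasma tracer-to-tracee
ratio (TTR) reaches a plateau once appearance and disposal are balanced.
The rate of appearance is then the tracer infusion rate divided by the
plateau TTR, and plasma clearance is the rate of appearance divided by the
plasma palmitate concentration.

Internal units are μmol, mL and min; outputs use the conventional reporting
units (Ra in μmol/min, clearance in L/h).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Analyte",
    "InfusionMode",
    "Pool",
    "TracerProtocol",
    "EnrichmentSeries",
    "SteadyStateResult",
    "plateau_ttr",
    "palmitate_ra",
    "ffa_clearance",
    "steady_state_analysis",
    "DEFAULT_PLATEAU_WINDOW",
    "DEFAULT_CV_TOLERANCE",
]

#: Plateau window in minutes relative to the start of the glycerol bolus;
#: the palmitate infusion starts 4 h earlier, so [240, 360] min corresponds
#: to hours 8-10 of the infusion ("between 4 h and 6 h" of the plateau
#: assessment period in the protocol this emulates).
DEFAULT_PLATEAU_WINDOW: tuple[float, float] = (240.0, 360.0)

#: Coefficient-of-variation above which the plateau is flagged as unsteady.
DEFAULT_CV_TOLERANCE: float = 0.10


class Analyte(str, enum.Enum):
    PALMITATE = "palmitate"
    GLYCEROL = "glycerol"
    LEUCINE = "leucine"


class InfusionMode(str, enum.Enum):
    CONSTANT = "constant"
    BOLUS = "bolus"
    PRIMED_CONSTANT = "primed_constant"


class Pool(str, enum.Enum):
    PLASMA_FREE = "plasma_free"
    VLDL_BOUND = "vldl_bound"


@dataclass(frozen=True)
class TracerProtocol:
    """A stable-isotope tracer administration protocol.

    Parameters
    ----------
    analyte
        Traced analyte.
    mode
        ``constant`` infusion, single ``bolus``, or ``primed_constant``.
    body_weight
        Subject body weight in kg.
    infusion_rate
        Tracer infusion rate in nmol/kg/min (0 for a pure bolus).
    bolus_dose
        Bolus dose in μmol/kg; required iff ``mode == BOLUS``.
    prime_dose
        Priming dose in μmol/kg; required iff ``mode == PRIMED_CONSTANT``.
    """

    analyte: Analyte
    mode: InfusionMode
    body_weight: float
    infusion_rate: float = 0.0
    bolus_dose: float | None = None
    prime_dose: float | None = None

    def __post_init__(self) -> None:
        self_mode = InfusionMode(self.mode)
        object.__setattr__(self, "mode", self_mode)
        object.__setattr__(self, "analyte", Analyte(self.analyte))
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if self.infusion_rate < 0:
            raise ValueError("infusion_rate must be non-negative")
        if (self.bolus_dose is not None) != (self_mode is InfusionMode.BOLUS):
            raise ValueError("bolus_dose is required iff mode is 'bolus'")
        if (self.prime_dose is not None) != (
            self_mode is InfusionMode.PRIMED_CONSTANT
        ):
            raise ValueError(
                "prime_dose is required iff mode is 'primed_constant'"
            )


@dataclass
class EnrichmentSeries:
    """A TTR time course for one analyte/pool in one subject.

    Times are minutes relative to the glycerol bolus (negative values cover
    the palmitate-only run-in period) and must be strictly increasing.
    """

    subject_id: str
    analyte: Analyte
    pool: Pool
    times: np.ndarray
    ttr: np.ndarray
    concentration: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.analyte = Analyte(self.analyte)
        self.pool = Pool(self.pool)
        self.times = np.asarray(self.times, dtype=float)
        self.ttr = np.asarray(self.ttr, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.ttr.shape:
            raise ValueError("times and ttr must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ttr < 0):
            raise ValueError("ttr values must be non-negative")
        if self.concentration is not None:
            self.concentration = np.asarray(self.concentration, dtype=float)
            if self.concentration.shape != self.times.shape:
                raise ValueError("concentration length must match times")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SteadyStateResult:
    """Steady-state palmitate kinetics for one subject."""

    ra: float  # μmol/min
    clearance: float | None  # L/h; None if no concentration was supplied
    plateau_ttr: float
    plateau_window: tuple[float, float]
    plateau_cv: float
    steady: bool = True
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ra": self.ra,
            "clearance": self.clearance,
            "plateau_ttr": self.plateau_ttr,
            "plateau_cv": self.plateau_cv,
            "window": list(self.plateau_window),
            "steady": self.steady,
            "flags": list(self.flags),
        }


def plateau_ttr(
    series: EnrichmentSeries,
    window: Sequence[float] = DEFAULT_PLATEAU_WINDOW,
    cv_tolerance: float = DEFAULT_CV_TOLERANCE,
) -> tuple[float, float, bool]:
    """Average TTR inside a plateau window.

    Returns ``(mean, cv, steady)`` where *cv* is the sample coefficient of
    variation of the in-window samples and *steady* is False when *cv*
    exceeds ``cv_tolerance`` (a warning flag, not an error).

    Raises
    ------
    ValueError
        If fewer than two samples fall inside the window.
    """
    lo, hi = float(window[0]), float(window[1])
    in_win = (series.times >= lo) & (series.times <= hi)
    vals = series.ttr[in_win]
    if len(vals) < 2:
        raise ValueError(
            f"insufficient plateau samples: {len(vals)} in window [{lo}, {hi}]"
        )
    mean = float(np.mean(vals))
    if mean > 0:
        cv = float(np.std(vals, ddof=1) / mean)
    else:
        cv = 0.0 if np.allclose(vals, 0.0) else float("inf")
    return mean, cv, cv <= cv_tolerance


def palmitate_ra(protocol: TracerProtocol, plateau: float) -> float:
    """Palmitate rate of appearance in μmol/min.

    Ra = tracer infusion rate / plateau TTR; the infusion rate is given per
    kg so it is scaled by body weight and converted from nmol to μmol.
    """
    if InfusionMode(protocol.mode) is not InfusionMode.CONSTANT:
        raise ValueError("palmitate Ra requires a constant-infusion protocol")
    if plateau <= 0:
        raise ValueError("plateau TTR must be positive")
    rate_umol_min = protocol.infusion_rate * protocol.body_weight / 1000.0
    return rate_umol_min / plateau


def ffa_clearance(ra: float, concentration: float) -> float:
    """Plasma palmitate clearance in L/h.

    clearance = Ra / concentration; μmol/min divided by μmol/mL gives
    mL/min, converted to L/h (× 60 / 1000).
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if ra < 0:
        raise ValueError("ra must be non-negative")
    return ra / concentration * 60.0 / 1000.0


def steady_state_analysis(
    series: EnrichmentSeries,
    protocol: TracerProtocol,
    concentration: float | None = None,
    window: Sequence[float] = DEFAULT_PLATEAU_WINDOW,
    cv_tolerance: float = DEFAULT_CV_TOLERANCE,
) -> SteadyStateResult:
    """Full steady-state workup: plateau → Ra → clearance.

    ``concentration`` (μmol/mL) defaults to the mean of the series'
    concentration samples inside the plateau window when available.
    """
    mean, cv, steady = plateau_ttr(series, window, cv_tolerance)
    ra = palmitate_ra(protocol, mean)
    flags: list[str] = []
    if not steady:
        flags.append(f"plateau CV {cv:.3f} exceeds tolerance {cv_tolerance}")
    if concentration is None and series.concentration is not None:
        lo, hi = float(window[0]), float(window[1])
        sel = (series.times >= lo) & (series.times <= hi)
        conc = series.concentration[sel]
        conc = conc[np.isfinite(conc)]
        concentration = float(np.mean(conc)) if len(conc) else None
    clearance = (
        ffa_clearance(ra, concentration) if concentration is not None else None
    )
    return SteadyStateResult(
        ra=ra,
        clearance=clearance,
        plateau_ttr=mean,
        plateau_window=(float(window[0]), float(window[1])),
        plateau_cv=cv,
        steady=steady,
        flags=flags,
    )
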