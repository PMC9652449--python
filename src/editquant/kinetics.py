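"""In vitro cleavage kinetics: rate-constant and active-fraction estimation.

Cleavage time courses follow a one-phase exponential:

    cleaved(t) = P * (1 - exp(-t / tau)),    k = 1 / tau

fitted by bounded nonlinear least squares with multi-start initialisation.
Sampling grids come in three categories matching how single-turnover
plasmid-cleavage assays are run: fast (3-30 s), medium (3-300 s) and slow
(3-3600 s); a course is assigned the narrowest category whose span covers
about three time constants.

The active-enzyme titration assumes single (one-fold) turnover and random
partitioning of enzyme over plasmid molecules: a plasmid escapes cleavage
with Poisson probability exp(-a*r), where r is the nominal protein:plasmid
ratio and a the active fraction of the nominal protein, so

    intact(r) = exp(-a * r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

CATEGORIES = {"fast": (3.0, 30.0), "medium": (3.0, 300.0), "slow": (3.0, 3600.0)}

_CATEGORY_ORDER = ("fast", "medium", "slow")


class DataQualityError(ValueError):
    """The observations contradict the model beyond noise."""


@dataclass
class CleavageTimeCourse:
    times: np.ndarray
    fractions: np.ndarray
    replicate: str = "r1"
    category: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.shape != self.fractions.shape:
            raise ValueError("times and fractions must have equal length")
        if not (np.all(self.times > 0) and np.all(np.diff(self.times) > 0)):
            raise ValueError("times must be positive and strictly increasing")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("cleaved fractions must lie within [0, 1]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, replicate: str = "r1") -> "CleavageTimeCourse":
        return cls(df["time_s"].to_numpy(), df["cleaved_fraction"].to_numpy(), replicate)


@dataclass(frozen=True)
class KineticsFit:
    tau: float
    plateau: float
    sse: float
    converged: bool
    n_points: int
    flags: tuple[str, ...] = ()

    @property
    def k(self) -> float:
        """Rate constant 1/tau (0 for no-activity fits)."""
        return 0.0 if math.isinf(self.tau) else 1.0 / self.tau


@dataclass(frozen=True)
class TitrationResult:
    active_fraction: float
    sse: float
    converged: bool
    plasmid_conc: float
    flags: tuple[str, ...] = ()

    def active_concentration(self, nominal_conc: float) -> float:
        """Active protein concentration for a given nominal concentration,
        in the units of ``nominal_conc``."""
        return self.active_fraction * nominal_conc


def _one_phase(t: np.ndarray, plateau: float, tau: float) -> np.ndarray:
    return plateau * (1.0 - np.exp(-t / tau))


def fit_one_phase_decay(
    tc: CleavageTimeCourse, fix_plateau: bool = False, n_starts: int = 5
) -> KineticsFit:
    """Fit cleaved(t) = P*(1-exp(-t/tau)) and report tau, k = 1/tau.

    Requires >= 4 time points spanning at least one decade.  Multi-start
    initialisation: tau from the time of half-plateau plus log-spaced
    alternatives across the sampled range; P from the last observation.
    ``fix_plateau`` pins P = 1 (complete cleavage).  All-zero fractions
    return a no-activity fit with k = 0.
    """
    t, y = tc.times, tc.fractions
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if t.max() / t.min() < 10:
        raise ValueError("time points must span at least one decade")
    if np.all(y == 0):
        return KineticsFit(
            tau=math.inf, plateau=0.0, sse=0.0, converged=False,
            n_points=len(t), flags=("no_activity",),
        )
    p0 = max(float(y[-1]), 1e-3)
    half = p0 / 2.0
    above = np.nonzero(y >= half)[0]
    t_half = float(t[above[0]]) if len(above) else float(t[-1])
    tau_half = max(t_half / math.log(2.0), 1e-6)
    tau_starts = np.unique(
        np.concatenate([[tau_half], np.geomspace(t.min() / 3.0, t.max() * 3.0, n_starts - 1)])
    )

    best = None
    for tau0 in tau_starts:
        if fix_plateau:
            res = optimize.least_squares(
                lambda p: _one_phase(t, 1.0, p[0]) - y,
                x0=[tau0], bounds=([1e-9], [1e9]),
            )
            plateau, tau = 1.0, float(res.x[0])
        else:
            res = optimize.least_squares(
                lambda p: _one_phase(t, p[0], p[1]) - y,
                x0=[p0, tau0], bounds=([1e-9, 1e-9], [1.05, 1e9]),
            )
            plateau, tau = float(res.x[0]), float(res.x[1])
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, plateau, tau, bool(res.success))
    sse, plateau, tau, ok = best
    flags = []
    if 3.0 * tau > t.max():
        # the grid does not span ~3 time constants: category mismatch, the
        # rate is poorly constrained
        flags.append("undersampled")
    return KineticsFit(
        tau=tau, plateau=plateau, sse=sse, converged=ok,
        n_points=len(t), flags=tuple(flags),
    )


@dataclass(frozen=True)
class SamplingPlan:
    category: str
    times: np.ndarray
    flag: str = ""


def choose_sampling_category(pilot_k: float, n_points: int = 8) -> SamplingPlan:
    """Map a pilot rate to the narrowest sampling category whose span covers
    about three time constants, with a log-spaced grid inside its bounds."""
    if pilot_k < 0:
        raise ValueError("pilot_k must be non-negative")
    if pilot_k == 0:
        lo, hi = CATEGORIES["slow"]
        return SamplingPlan("slow", np.geomspace(lo, hi, n_points), flag="no_activity")
    tau = 1.0 / pilot_k
    for name in _CATEGORY_ORDER:
        lo, hi = CATEGORIES[name]
        if 3.0 * tau <= hi:
            return SamplingPlan(name, np.geomspace(lo, hi, n_points))
    lo, hi = CATEGORIES["slow"]
    return SamplingPlan("slow", np.geomspace(lo, hi, n_points), flag="slower_than_slow")


def estimate_active_fraction(
    titration: pd.DataFrame, plasmid_conc: float = 6.2
) -> TitrationResult:
    """Fit intact(r) = exp(-a*r) to a (ratio, intact_fraction) titration.

    Requires >= 4 ratios spanning both sides of 1:1.  A systematic increase
    of the intact fraction with ratio (beyond noise) is a data-quality
    error.  An all-intact titration returns a = 0 flagged as no activity.
    """
    r = np.asarray(titration["ratio"], dtype=float)
    y = np.asarray(titration["intact_fraction"], dtype=float)
    if len(r) < 4:
        raise ValueError("need at least 4 ratios")
    if not (r.min() < 1.0 < r.max()):
        raise ValueError("ratios must span below and above 1:1")
    reg = stats.linregress(r, y)
    if reg.slope > 0 and reg.pvalue < 0.05:
        raise DataQualityError(
            f"intact fraction increases with ratio (slope {reg.slope:.3g}, "
            f"p {reg.pvalue:.3g})"
        )
    with np.errstate(divide="ignore"):
        a0 = float(np.median(-np.log(np.clip(y, 1e-6, 1.0)) / r))
    a0 = min(max(a0, 1e-6), 10.0)
    res = optimize.least_squares(
        lambda p: np.exp(-p[0] * r) - y, x0=[a0], bounds=([0.0], [20.0])
    )
    a = float(res.x[0])
    sse = float(np.sum(res.fun**2))
    flags = ("no_activity",) if a <= 1e-5 else ()
    return TitrationResult(
        active_fraction=a, sse=sse, converged=bool(res.success),
        plasmid_conc=plasmid_conc, flags=flags,
    )


def threefold_excess_check(
    active_conc: float, plasmid_conc: float, target: float = 3.0, tol: float = 0.1
) -> bool:
    """Check the cleavage-assay setup ratio of active protein to target
    plasmid against the intended 1:3, within a +/-10% tolerance."""
    if active_conc <= 0 or plasmid_conc <= 0:
        raise ValueError("concentrations must be positive")
    ratio = active_conc / plasmid_conc
    return target * (1 - tol) <= ratio <= target * (1 + tol)
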