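"""FRET efficiency, donor-acceptor distance, and significance calling.

Lifetime-based FRET: the transfer efficiency follows from the donor lifetime
with (τ_DA) and without (τ_D) acceptor,

    E = 1 − τ_DA/τ_D = R₀⁶ / (R₀⁶ + r⁶),

whose right-hand form inverts to the donor-acceptor separation
r = R₀·((1−E)/E)^(1/6).  A sample is called FRET-positive only when its mean
lifetime falls more than three standard deviations below the mean of a
donor-only control distribution — a deliberately conservative threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .decay import MultiExpFit
from .errors import InvalidInputError, UndefinedDistanceError

__all__ = [
    "ControlDistribution",
    "FretResult",
    "ComponentClass",
    "fret_efficiency",
    "efficiency_percent",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "fret_call",
    "component_analysis",
]


@dataclass
class ControlDistribution:
    """Across-sample distribution of donor-only mean lifetimes."""

    mean_lifetime_ns: float
    sd_ns: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InvalidInputError("need >= 3 control samples")
        if self.sd_ns < 0:
            raise InvalidInputError("standard deviation must be >= 0")

    @classmethod
    def from_samples(cls, lifetimes_ns) -> "ControlDistribution":
        x = np.asarray(lifetimes_ns, dtype=float)
        return cls(float(x.mean()), float(x.std(ddof=1)), int(x.size))

    @classmethod
    def from_sem(cls, mean_ns: float, sem_ns: float, n: int) -> "ControlDistribution":
        """Reconstruct the across-sample s.d. from a reported SEM: sd = SEM·√n."""
        return cls(mean_ns, sem_ns * math.sqrt(n), n)

    @property
    def threshold_ns(self) -> float:
        return self.mean_lifetime_ns - 3.0 * self.sd_ns


@dataclass
class FretResult:
    efficiency: float
    tau_da_ns: float
    tau_d_ns: float
    r0_A: float | None = None
    distance_A: float | None = None
    significant: bool | None = None

    @property
    def efficiency_percent(self) -> int:
        return efficiency_percent(self.efficiency)


@dataclass
class ComponentClass:
    """Per-decay-component FRET interpretation."""

    lifetime_ns: float
    fraction: float
    efficiency: float
    label: str                    # "unquenched" | "low-FRET" | "high-FRET"
    distance_A: float | None


def fret_efficiency(tau_da: float, tau_d: float) -> float:
    """E = 1 − τ_DA/τ_D.  A donor lifetime that *grows* in presence of the
    acceptor yields a negative value, returned (not clipped) with a warning
    so environmental lifetime shifts stay visible."""
    if tau_d <= 0 or tau_da <= 0:
        raise InvalidInputError("lifetimes must be positive")
    e = 1.0 - tau_da / tau_d
    if e < 0:
        warnings.warn(f"tau_DA ({tau_da}) exceeds tau_D ({tau_d}); "
                      "negative efficiency — physically no FRET")
    return e


def efficiency_percent(efficiency: float) -> int:
    """Integer percent, rounding half away from zero."""
    x = efficiency * 100.0
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def efficiency_from_distance(distance_A: float, r0_A: float) -> float:
    """E(r) = R₀⁶ / (R₀⁶ + r⁶)."""
    if distance_A <= 0 or r0_A <= 0:
        raise InvalidInputError("distances must be positive")
    q = (distance_A / r0_A) ** 6
    return 1.0 / (1.0 + q)


def distance_from_efficiency(efficiency: float, r0_A: float) -> float:
    """r = R₀·((1−E)/E)^(1/6), defined for E strictly inside (0, 1)."""
    if r0_A <= 0:
        raise InvalidInputError("Förster radius must be positive")
    if not 0.0 < efficiency < 1.0:
        raise UndefinedDistanceError(
            f"distance undefined at efficiency {efficiency}")
    return r0_A * ((1.0 - efficiency) / efficiency) ** (1.0 / 6.0)


def fret_call(tau_sample_ns: float, control: ControlDistribution) -> bool:
    """True iff τ_sample < mean − 3·sd (strict)."""
    return tau_sample_ns < control.threshold_ns


def component_analysis(fit: MultiExpFit, tau_d_ns: float, r0_A: float | None = None,
                       unquenched_tol: float = 0.10) -> list[ComponentClass]:
    """Interpret each decay component of a fitted donor decay.

    A component within ``unquenched_tol`` (relative) of the donor-only
    lifetime is "unquenched"; the rest split at E = 0.5 into "low-FRET"
    (E < 0.5) and "high-FRET" (E >= 0.5 — the boundary belongs to high-FRET
    by convention).  Distances are attached where E ∈ (0, 1) and R₀ is given;
    fractional amplitudes pass through as population fractions.
    """
    if tau_d_ns <= 0:
        raise InvalidInputError("donor-only lifetime must be positive")
    out: list[ComponentClass] = []
    for frac, tau in zip(fit.model.amplitudes, fit.model.lifetimes_ns):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e = fret_efficiency(tau, tau_d_ns)
        if abs(tau - tau_d_ns) / tau_d_ns <= unquenched_tol:
            label = "unquenched"
        elif e >= 0.5:
            label = "high-FRET"
        else:
            label = "low-FRET"
        dist = None
        if label != "unquenched" and 0.0 < e < 1.0 and r0_A is not None:
            dist = distance_from_efficiency(e, r0_A)
        out.append(ComponentClass(lifetime_ns=float(tau), fraction=float(frac),
                                  efficiency=e, label=label, distance_A=dist))
    return out
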