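"""Two-component receptor–ligand equilibrium binding and engagement classification.

All concentrations are molar (mol/L) of epitope and paratope respectively;
avidity and multivalency are deliberately out of scope.  Affinity is the
equilibrium dissociation constant ``kd`` — lower means stronger binding.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "KD_WORKING_MIN",
    "KD_WORKING_MAX",
    "DomainError",
    "AffinityRangeWarning",
    "EquilibriumState",
    "EngagementBand",
    "EngagementClass",
    "occupancy",
    "solve_equilibrium",
    "classify_engagement",
    "log_engagement_ratio",
    "molarity_from_count",
]

AVOGADRO = 6.02214076e23

#: Working range for both free-antigen concentration and kd, in molar.
KD_WORKING_MIN = 1e-14
KD_WORKING_MAX = 1e-3


class DomainError(ValueError):
    """Raised when a numeric argument is outside its mathematical domain."""


class AffinityRangeWarning(UserWarning):
    """Emitted when a kd falls outside the simulator's working range."""


def _require_finite_nonneg(value: float, name: str) -> float:
    if not math.isfinite(value) or value < 0.0:
        raise DomainError(f"{name} must be finite and >= 0, got {value!r}")
    return float(value)


def check_affinity(kd: float) -> float:
    """Validate a dissociation constant; warn (not error) outside the working range."""
    if not math.isfinite(kd) or kd <= 0.0:
        raise DomainError(f"kd must be finite and > 0, got {kd!r}")
    if not (KD_WORKING_MIN <= kd <= KD_WORKING_MAX):
        warnings.warn(
            f"kd={kd:.3e} M outside working range "
            f"[{KD_WORKING_MIN:.0e}, {KD_WORKING_MAX:.0e}] M",
            AffinityRangeWarning,
            stacklevel=3,
        )
    return float(kd)


@dataclass(frozen=True)
class EquilibriumState:
    """Free and bound concentrations at mass-action equilibrium (molar)."""

    ag_free: float
    bcr_free: float
    complex: float

    @property
    def ag_total(self) -> float:
        return self.ag_free + self.complex

    @property
    def bcr_total(self) -> float:
        return self.bcr_free + self.complex


class EngagementClass(enum.IntEnum):
    """Receptor-engagement zones, ordered by increasing occupancy."""

    NEGLECT = 0
    UNDER = 1
    COMFORT = 2
    OVER = 3
    SATURATED = 4


@dataclass(frozen=True)
class EngagementBand:
    """Thresholds carving the occupancy axis into fate-relevant zones.

    ``delta_comfort`` is the half-width of the comfort band on
    log10(ag_free / kd); occupancy at the band edges is
    ``1 / (1 + 10**±delta_comfort)``.  ``theta_neglect`` and
    ``theta_saturated`` are occupancy fractions bracketing the responsive
    region; they must sit strictly outside the comfort band edges.
    """

    delta_comfort: float = 0.5
    theta_neglect: float = 0.01
    theta_saturated: float = 0.99

    def __post_init__(self) -> None:
        if not (self.delta_comfort > 0.0 and math.isfinite(self.delta_comfort)):
            raise DomainError("delta_comfort must be finite and > 0")
        lo_edge = 1.0 / (1.0 + 10.0 ** self.delta_comfort)  # occupancy at log-ratio -delta
        hi_edge = 1.0 / (1.0 + 10.0 ** -self.delta_comfort)
        if not (0.0 < self.theta_neglect < lo_edge):
            raise DomainError(
                f"theta_neglect={self.theta_neglect} must lie in (0, {lo_edge:.4f})"
            )
        if not (hi_edge < self.theta_saturated < 1.0):
            raise DomainError(
                f"theta_saturated={self.theta_saturated} must lie in ({hi_edge:.4f}, 1)"
            )


def occupancy(ag_free: float, kd: float) -> float:
    """Fraction of receptor bound at equilibrium: theta = ag / (ag + kd).

    Strictly increasing in ``ag_free`` and strictly decreasing in ``kd``;
    equals 0.5 exactly when ``ag_free == kd``.
    """
    ag = _require_finite_nonneg(ag_free, "ag_free")
    k = check_affinity(kd)
    return ag / (ag + k)


def solve_equilibrium(ag_total: float, bcr_total: float, kd: float) -> EquilibriumState:
    """Solve the single-species binding equilibrium for total concentrations.

    The complex concentration is the smaller root of
    ``x**2 - (A + B + K) x + A B = 0``, computed via the cancellation-free
    form ``x = 2AB / (S + sqrt(S**2 - 4AB))`` with ``S = A + B + K``, which
    stays accurate in the tight-binding limit ``K << A, B``.
    """
    a = _require_finite_nonneg(ag_total, "ag_total")
    b = _require_finite_nonneg(bcr_total, "bcr_total")
    k = check_affinity(kd)
    s = a + b + k
    prod = a * b
    if prod == 0.0:
        x = 0.0
    else:
        x = 2.0 * prod / (s + math.sqrt(s * s - 4.0 * prod))
    return EquilibriumState(ag_free=a - x, bcr_free=b - x, complex=x)


def log_engagement_ratio(ag_free: float, kd_apparent: float) -> float:
    """log10(ag_free / kd_apparent); -inf when no free antigen."""
    ag = _require_finite_nonneg(ag_free, "ag_free")
    k = check_affinity(kd_apparent)
    if ag == 0.0:
        return -math.inf
    return math.log10(ag / k)


def classify_engagement(
    ag_free: float,
    kd_apparent: float,
    band: EngagementBand = EngagementBand(),
) -> EngagementClass:
    """Assign one engagement zone to a (free antigen, apparent kd) pair.

    COMFORT wins whenever ``|log10(ag/kd)| <= delta_comfort``; otherwise the
    occupancy thresholds decide NEGLECT/SATURATED and the sign of the
    log-ratio decides UNDER/OVER.  ``ag_free == 0`` maps to NEGLECT by
    convention (the log-ratio is undefined there).
    """
    ratio = log_engagement_ratio(ag_free, kd_apparent)
    if ratio == -math.inf:
        return EngagementClass.NEGLECT
    if abs(ratio) <= band.delta_comfort:
        return EngagementClass.COMFORT
    theta = occupancy(ag_free, kd_apparent)
    if theta < band.theta_neglect:
        return EngagementClass.NEGLECT
    if theta > band.theta_saturated:
        return EngagementClass.SATURATED
    return EngagementClass.UNDER if ratio < 0.0 else EngagementClass.OVER


def molarity_from_count(n_molecules: float, volume: float) -> float:
    """Convert a molecule count in a volume (liters) to molar concentration."""
    n = _require_finite_nonneg(n_molecules, "n_molecules")
    if not math.isfinite(volume) or volume <= 0.0:
        raise DomainError(f"volume must be finite and > 0, got {volume!r}")
    return n / (AVOGADRO * volume)
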