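"""Hill dose-response curves and dose-dependent birth-death rates.

A clone's response to a cytotoxic drug is modelled through a three-parameter
Hill function ``H(d; b, E, m)`` acting on its death rate: the death rate at
dose ``d`` is ``nu - log H(d)``, so the drug leaves the division rate
untouched (cytotoxic, not cytostatic action) and shifts the net growth rate
by ``log H(d)``, from 0 at ``d = 0`` down to ``log b`` at saturating dose.

The GR50 of a clone is the dose at which the drug-induced increase of the
death rate reaches half its maximum ``-log b``; in closed form
``GR50 = E * b**(-1/(2m))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HillParams",
    "SubpopulationParams",
    "hill",
    "death_rate",
    "net_rate",
    "gr50",
]


@dataclass(frozen=True)
class HillParams:
    """Parameters of the Hill dose-response curve.

    Attributes
    ----------
    b : float
        Asymptotic response at infinite dose, dimensionless, in (0, 1).
    E : float
        Dose at which the curve is halfway between 1 and ``b`` (same
        concentration units as the doses), > 0.
    m : float
        Hill coefficient (steepness), > 0.
    """

    b: float
    E: float
    m: float

    def __post_init__(self) -> None:
        if not (0.0 < self.b < 1.0):
            raise ValueError(f"Hill asymptote b must lie in (0, 1), got {self.b}")
        if not self.E > 0.0:
            raise ValueError(f"Hill half-effect dose E must be > 0, got {self.E}")
        if not self.m > 0.0:
            raise ValueError(f"Hill steepness m must be > 0, got {self.m}")


@dataclass(frozen=True)
class SubpopulationParams:
    """Birth-death and dose-response parameters of one clone.

    ``beta`` is the division rate and ``nu`` the baseline (drug-free) death
    rate, both per unit time and nonnegative.  The drug-free net growth rate
    is ``alpha = beta - nu``.
    """

    beta: float
    nu: float
    hill: HillParams = field(default_factory=lambda: HillParams(0.5, 1.0, 1.0))

    def __post_init__(self) -> None:
        if self.beta < 0.0:
            raise ValueError(f"division rate beta must be >= 0, got {self.beta}")
        if self.nu < 0.0:
            raise ValueError(f"death rate nu must be >= 0, got {self.nu}")

    @property
    def alpha(self) -> float:
        """Drug-free net growth rate ``beta - nu``."""
        return self.beta - self.nu

    @property
    def gr50(self) -> float:
        return gr50(self.hill)


def hill(d, p: HillParams):
    """Evaluate the Hill curve ``b + (1 - b) / (1 + (d/E)^m)``.

    Strictly decreasing in ``d``; equals 1 at ``d = 0`` and tends to ``b``
    as ``d`` grows.  ``d`` may be a scalar or array of nonnegative doses.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("doses must be >= 0")
    # (d/E)^m with the convention 0^m = 0 for every m > 0 (no singularity
    # at d = 0 even when m < 1).
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0.0, np.power(d / p.E, p.m), 0.0)
    out = p.b + (1.0 - p.b) / (1.0 + ratio)
    return out if out.ndim else float(out)


def death_rate(d, sp: SubpopulationParams):
    """Dose-dependent death rate ``nu - log H(d)``.

    Equals ``nu`` without drug and increases monotonically with dose up to
    ``nu - log b``.
    """
    out = sp.nu - np.log(hill(d, sp.hill))
    return out if np.ndim(out) else float(out)


def net_rate(d, sp: SubpopulationParams):
    """Net growth rate ``lambda(d) = beta - nu + log H(d)``; may be negative."""
    out = sp.beta - np.asarray(death_rate(d, sp))
    return out if out.ndim else float(out)


def gr50(p: HillParams) -> float:
    """Dose at which the drug effect on the death rate is half-maximal.

    Solves ``log H(d) = log(b) / 2``; in closed form ``E * b**(-1/(2m))``.
    Always slightly above ``E`` and tends to ``E`` as ``b -> 1`` or
    ``m -> inf``; diverges to inf as ``m -> 0`` (a flat curve has no
    half-effect dose).
    """
    with np.errstate(over="ignore"):
        return float(p.E * np.exp(-np.log(p.b) / (2.0 * p.m)))
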