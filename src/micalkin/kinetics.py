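"""Rapid-equilibrium non-essential-activator rate law and derived quantities.

The model describes an enzyme E that oxidises a substrate S (NADPH, read out
at 340 nm) and is accelerated — but not strictly required to be bound — by an
activator A (filamentous actin).  Four enzyme species are assumed to be in
rapid equilibrium::

          K_M                K_act
    E + S <=> ES        E + A <=> EA
    EA + S <=> EAS  (alpha*K_M)
    ES + A <=> EAS  (alpha*K_act)

ES turns over with rate constant ``k_cat`` and the ternary complex EAS with
``beta * k_cat``.  The steady-state initial velocity is

    v = E_t * k_cat * (S/K_M) * (1 + beta*A/(alpha*K_act))
        -----------------------------------------------------
        1 + S/K_M + A/K_act + S*A/(alpha*K_M*K_act)

``alpha`` couples substrate and activator binding (alpha < 1: binding one
raises the affinity for the other); ``beta`` is the acceleration factor of the
ternary complex.  At alpha = beta = 1 the expression collapses exactly to
single-substrate Michaelis-Menten kinetics, independent of A.

At a fixed activator concentration the same velocity obeys an apparent
Michaelis-Menten law with

    k_cat_app(A) = k_cat * (1 + beta*A/(alpha*K_act)) / (1 + A/(alpha*K_act))
    K_M_app(A)   = K_M   * (1 + A/K_act)              / (1 + A/(alpha*K_act))

Concentrations are in µM throughout; catalytic power (k_cat/K_M) is reported
in s⁻¹ mM⁻¹ as is conventional for these enzymes.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GlobalKineticParams",
    "Condition",
    "ApparentParams",
    "velocity",
    "apparent_kcat",
    "apparent_km",
    "catalytic_power",
    "fold_change",
    "round_half_away",
]


class KineticsDomainError(ValueError):
    """Raised when kinetic parameters or concentrations are out of domain."""


@dataclass(frozen=True)
class GlobalKineticParams:
    """Global parameters of the non-essential-activator model.

    Parameters
    ----------
    k_cat : float
        Turnover number of the enzyme–substrate complex, s⁻¹.
    K_M : float
        Substrate (NADPH) half-saturation constant, µM.
    K_act : float
        Activator (F-actin) dissociation constant, µM.
    alpha : float
        Dimensionless coupling factor (> 0).  alpha < 1 means activator
        binding tightens substrate binding and vice versa.
    beta : float
        Dimensionless acceleration factor (>= 0): ratio of ternary-complex
        turnover to binary-complex turnover.
    """

    k_cat: float
    K_M: float
    K_act: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("k_cat", "K_M", "K_act", "alpha"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise KineticsDomainError(f"{name} must be finite and > 0, got {getattr(self, name)!r}")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise KineticsDomainError(f"beta must be finite and >= 0, got {self.beta!r}")

    def apparent(self, activator_conc: float) -> "ApparentParams":
        """Apparent Michaelis-Menten constants at a fixed activator level."""
        return ApparentParams(
            k_cat_app=apparent_kcat(self, activator_conc),
            K_M_app=apparent_km(self, activator_conc),
            activator_conc=float(activator_conc),
        )

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.k_cat, self.K_M, self.K_act, self.alpha, self.beta)


@dataclass(frozen=True)
class Condition:
    """One cuvette condition: [NADPH], [F-actin] and total enzyme, all µM."""

    substrate_conc: float
    activator_conc: float
    enzyme_conc: float

    def __post_init__(self) -> None:
        if self.substrate_conc < 0 or self.activator_conc < 0:
            raise KineticsDomainError("concentrations must be non-negative")
        if self.enzyme_conc <= 0:
            raise KineticsDomainError("enzyme_conc must be > 0 for velocity evaluation")


@dataclass(frozen=True)
class ApparentParams:
    """Michaelis-Menten constants observed at one activator concentration."""

    k_cat_app: float
    K_M_app: float
    activator_conc: float

    @property
    def catalytic_power(self) -> float:
        """k_cat_app / K_M_app in s⁻¹ mM⁻¹."""
        return catalytic_power(self.k_cat_app, self.K_M_app)


def _rate(S, A, E, k_cat, K_M, K_act, alpha, beta):
    """Vectorised rate law; no validation.  All concentrations µM, rate µM/s."""
    s = np.asarray(S, dtype=float) / K_M
    a = np.asarray(A, dtype=float) / K_act
    num = np.asarray(E, dtype=float) * k_cat * s * (1.0 + beta * a / alpha)
    den = 1.0 + s + a + s * a / alpha
    return num / den


def velocity(params: GlobalKineticParams, cond: Condition) -> float:
    """Initial NADPH-oxidation velocity, µM/s.

    Evaluates the rapid-equilibrium rate law at the given condition.  Equals
    ``E * k_cat_app * S / (K_M_app + S)`` built from :func:`apparent_kcat` and
    :func:`apparent_km` as an algebraic identity.
    """
    return float(
        _rate(
            cond.substrate_conc,
            cond.activator_conc,
            cond.enzyme_conc,
            *params.as_tuple(),
        )
    )


def apparent_kcat(params: GlobalKineticParams, activator_conc) -> float:
    """Apparent turnover number at a fixed activator concentration, s⁻¹.

    Interpolates between ``k_cat`` at A = 0 and ``beta * k_cat`` at saturating
    activator, with midpoint at A = alpha * K_act.
    """
    A = np.asarray(activator_conc, dtype=float)
    if np.any(A < 0):
        raise KineticsDomainError("activator_conc must be >= 0")
    a = A / (params.alpha * params.K_act)
    out = params.k_cat * (1.0 + params.beta * a) / (1.0 + a)
    return float(out) if np.isscalar(activator_conc) else out


def apparent_km(params: GlobalKineticParams, activator_conc) -> float:
    """Apparent substrate half-saturation constant at fixed activator, µM.

    Runs from ``K_M`` at A = 0 to ``alpha * K_M`` at saturating activator;
    constant in A exactly when alpha = 1 (no coupling).
    """
    A = np.asarray(activator_conc, dtype=float)
    if np.any(A < 0):
        raise KineticsDomainError("activator_conc must be >= 0")
    out = params.K_M * (1.0 + A / params.K_act) / (1.0 + A / (params.alpha * params.K_act))
    return float(out) if np.isscalar(activator_conc) else out


def catalytic_power(k_cat_app: float, K_M_app: float) -> float:
    """Catalytic power k_cat_app / K_M_app in s⁻¹ mM⁻¹.

    The µM half-saturation constant is converted to mM, i.e. the ratio is
    multiplied by 1000.  A zero turnover number gives zero power.
    """
    if K_M_app <= 0:
        raise KineticsDomainError(f"K_M_app must be > 0, got {K_M_app!r}")
    if k_cat_app < 0:
        raise KineticsDomainError(f"k_cat_app must be >= 0, got {k_cat_app!r}")
    return 1000.0 * k_cat_app / K_M_app


def fold_change(value_at: float, value_ref: float) -> float:
    """Ratio of a quantity to its reference value (e.g. the zero-actin row)."""
    if value_ref <= 0:
        raise KineticsDomainError(f"reference value must be > 0, got {value_ref!r}")
    return value_at / value_ref


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as printed report tables round (45.05 → 45.1)."""
    d = decimal.Decimal(repr(float(x)))
    exp = decimal.Decimal(1).scaleb(-ndigits)
    return float(d.quantize(exp, rounding=decimal.ROUND_HALF_UP))
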