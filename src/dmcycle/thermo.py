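"""Thermodynamic bookkeeping for 1:1 binding equilibria.

Everything downstream of the raw experiments — double mutant cycles,
affinity ladders, solvent comparisons — is linear algebra on free
energies, enthalpies and entropies with standard uncertainties.  This
module provides the value-with-uncertainty container, the K ↔ ΔG°
conversions and quadrature error propagation used by every stage.

Conventions
-----------
* Internal units are kJ mol⁻¹ for energies and M⁻¹ for association
  constants; conversion happens only at I/O boundaries.
* ``ΔG° = −RT ln K`` and ``TΔS° = ΔH° + RT ln K``, so
  ``ΔG° = ΔH° − TΔS°`` holds identically.
* Quoted ``±`` uncertainties are treated as independent Gaussian
  standard errors (1σ) and combined in quadrature.  Experimental
  reports rarely state whether a ``±`` is a standard error or a fit
  confidence interval; 1σ is the conservative reading and is what the
  propagation below assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

__all__ = [
    "R_KJ",
    "T_DEFAULT",
    "RT",
    "ThermoQuantity",
    "BindingMeasurement",
    "gibbs_from_K",
    "K_from_gibbs",
    "entropy_from",
    "combine_linear",
]

#: Gas constant in kJ mol⁻¹ K⁻¹.
R_KJ = 8.314e-3

#: All measurements modelled here were taken at 298 K.
T_DEFAULT = 298.0


def RT(T: float = T_DEFAULT) -> float:
    """R·T in kJ mol⁻¹ (≈ 2.478 kJ mol⁻¹ at 298 K)."""
    return R_KJ * T


class UnitMismatchError(ValueError):
    """Arithmetic attempted between quantities carrying different units."""


@dataclass(frozen=True)
class ThermoQuantity:
    """A scalar with a standard uncertainty and a unit tag.

    Parameters
    ----------
    value : float
        The central value.
    sigma : float
        Standard uncertainty (1σ), same unit as ``value``; must be ≥ 0.
    unit : str
        Unit symbol, e.g. ``"kJ/mol"``, ``"1/M"``, ``""`` (dimensionless).
    """

    value: float
    sigma: float = 0.0
    unit: str = "kJ/mol"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    def _check_unit(self, other: "ThermoQuantity") -> None:
        if self.unit != other.unit:
            raise UnitMismatchError(
                f"cannot combine {self.unit!r} with {other.unit!r}"
            )

    def __add__(self, other: "ThermoQuantity") -> "ThermoQuantity":
        self._check_unit(other)
        return ThermoQuantity(
            self.value + other.value,
            math.hypot(self.sigma, other.sigma),
            self.unit,
        )

    def __sub__(self, other: "ThermoQuantity") -> "ThermoQuantity":
        self._check_unit(other)
        return ThermoQuantity(
            self.value - other.value,
            math.hypot(self.sigma, other.sigma),
            self.unit,
        )

    def __neg__(self) -> "ThermoQuantity":
        return ThermoQuantity(-self.value, self.sigma, self.unit)

    def scaled(self, c: float) -> "ThermoQuantity":
        """Multiply by an exact scalar (sigma scales by |c|)."""
        return ThermoQuantity(c * self.value, abs(c) * self.sigma, self.unit)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.sigma:
            return f"{self.value:g} ± {self.sigma:g} {self.unit}".rstrip()
        return f"{self.value:g} {self.unit}".rstrip()


def gibbs_from_K(K: ThermoQuantity | float, T: float = T_DEFAULT) -> ThermoQuantity:
    """Standard free energy of association, ΔG° = −RT ln K.

    Parameters
    ----------
    K : ThermoQuantity or float
        Association constant in M⁻¹ (must be > 0).  A bare float is
        treated as exact.
    T : float
        Temperature in kelvin.

    Returns
    -------
    ThermoQuantity
        ΔG° in kJ mol⁻¹ with sigma propagated as RT·σ_K/K.
    """
    if not isinstance(K, ThermoQuantity):
        K = ThermoQuantity(float(K), 0.0, "1/M")
    if K.value <= 0:
        raise ValueError(f"association constant must be positive, got {K.value}")
    rt = RT(T)
    return ThermoQuantity(-rt * math.log(K.value), rt * K.sigma / K.value, "kJ/mol")


def K_from_gibbs(dG: ThermoQuantity | float, T: float = T_DEFAULT) -> ThermoQuantity:
    """Inverse of :func:`gibbs_from_K`: K = exp(−ΔG°/RT), σ_K = K·σ_G/RT."""
    if not isinstance(dG, ThermoQuantity):
        dG = ThermoQuantity(float(dG), 0.0, "kJ/mol")
    rt = RT(T)
    K = math.exp(-dG.value / rt)
    return ThermoQuantity(K, K * dG.sigma / rt, "1/M")


def entropy_from(
    dH: ThermoQuantity | float,
    K: ThermoQuantity | float,
    T: float = T_DEFAULT,
) -> ThermoQuantity:
    """Entropic term TΔS° = ΔH° + RT ln K (kJ mol⁻¹), sigma in quadrature."""
    if not isinstance(dH, ThermoQuantity):
        dH = ThermoQuantity(float(dH), 0.0, "kJ/mol")
    dG = gibbs_from_K(K, T)
    return ThermoQuantity(
        dH.value - dG.value, math.hypot(dH.sigma, dG.sigma), "kJ/mol"
    )


def combine_linear(
    terms: Iterable[Tuple[float, ThermoQuantity]]
) -> ThermoQuantity:
    """Signed linear combination Σ cᵢ·vᵢ with quadrature sigma.

    All quantities must share one unit.  This is the workhorse behind
    the double-mutant-cycle combination and solvent differences.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("combine_linear requires at least one term")
    unit = terms[0][1].unit
    value = 0.0
    var = 0.0
    for c, q in terms:
        if q.unit != unit:
            raise UnitMismatchError(f"cannot combine {unit!r} with {q.unit!r}")
        value += c * q.value
        var += (c * q.sigma) ** 2
    return ThermoQuantity(value, math.sqrt(var), unit)


@dataclass(frozen=True)
class BindingMeasurement:
    """One host·guest complex in one solvent: K and ΔH° with uncertainties.

    ΔG° and TΔS° are derived, never stored, so the thermodynamic
    identity ΔG° = ΔH° − TΔS° holds by construction.
    """

    host: str
    guest: str
    solvent: str
    K: ThermoQuantity
    dH: ThermoQuantity
    T: float = T_DEFAULT
    method: str = "ITC"  # ITC | NMR-competition | reference

    def __post_init__(self) -> None:
        if self.K.value <= 0:
            raise ValueError("association constant must be positive")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.K.unit != "1/M":
            raise UnitMismatchError("K must carry unit '1/M'")
        if self.dH.unit != "kJ/mol":
            raise UnitMismatchError("dH must carry unit 'kJ/mol'")
        if self.method not in ("ITC", "NMR-competition", "reference"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def complex_id(self) -> str:
        return f"{self.host}·{self.guest}[{self.solvent}]"

    @property
    def dG(self) -> ThermoQuantity:
        """ΔG° = −RT ln K."""
        return gibbs_from_K(self.K, self.T)

    @property
    def TdS(self) -> ThermoQuantity:
        """TΔS° = ΔH° + RT ln K."""
        return entropy_from(self.dH, self.K, self.T)
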