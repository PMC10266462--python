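"""Chemical double mutant cycles (DMC).

A DMC isolates the free-energy contribution of one functional-group
contact from the overall stability of a complex.  Four complexes are
measured: A carries both interaction partners, B and C each delete one
of them, and D deletes both.  The signed combination

    ΔΔG° = ΔG°(A) − ΔG°(B) − ΔG°(C) + ΔG°(D)

cancels every pairwise secondary effect (for instance a substituent's
influence on the anchoring H-bond strength, which appears equally in
the A−C and B−D differences) and leaves only the interaction of
interest.  The same combination applied to ΔH° or TΔS° decomposes the
interaction into enthalpic and entropic parts.  Uncertainties combine
in quadrature, so four ±σ measurements give a ±2σ cycle at worst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .thermo import BindingMeasurement, ThermoQuantity, combine_linear

__all__ = ["DMCQuad", "dmc_delta", "solvent_difference", "table_entry"]


@dataclass(frozen=True)
class DMCQuad:
    """The four complexes of one double mutant cycle.

    Mutation bookkeeping: A and C share the unmutated host, B and D the
    mutated host; A and B share the full guest, C and D the truncated
    guest.  All four must be measured in the same solvent at the same
    temperature.
    """

    A: BindingMeasurement
    B: BindingMeasurement
    C: BindingMeasurement
    D: BindingMeasurement
    label: str = ""

    def __post_init__(self) -> None:
        ms = (self.A, self.B, self.C, self.D)
        if len({m.solvent for m in ms}) != 1:
            raise ValueError("all four complexes must share one solvent")
        if len({m.T for m in ms}) != 1:
            raise ValueError("all four complexes must share one temperature")
        if self.A.host != self.C.host or self.B.host != self.D.host:
            raise ValueError(
                "host mismatch: A/C must share the unmutated host and B/D "
                "the mutated host"
            )
        if self.A.guest != self.B.guest or self.C.guest != self.D.guest:
            raise ValueError(
                "guest mismatch: A/B must share the full guest and C/D the "
                "truncated guest"
            )

    @property
    def solvent(self) -> str:
        return self.A.solvent


def dmc_delta(
    quad: DMCQuad, property: Literal["G", "H", "TS"] = "G"
) -> ThermoQuantity:
    """Interaction term ΔΔ = Δ_A − Δ_B − Δ_C + Δ_D for G, H or TS.

    For ``"G"`` the per-complex ΔG° values are derived from K, for
    ``"H"`` the calorimetric ΔH° is used directly and for ``"TS"`` the
    entropic term TΔS° = ΔH° + RT ln K; consequently
    ΔΔG° = ΔΔH° − TΔΔS° holds identically.
    """
    if property == "G":
        vals = [m.dG for m in (quad.A, quad.B, quad.C, quad.D)]
    elif property == "H":
        vals = [m.dH for m in (quad.A, quad.B, quad.C, quad.D)]
    elif property == "TS":
        vals = [m.TdS for m in (quad.A, quad.B, quad.C, quad.D)]
    else:
        raise ValueError(f"property must be G, H or TS, got {property!r}")
    return combine_linear(zip((1.0, -1.0, -1.0, 1.0), vals))


def solvent_difference(
    ddG_water: ThermoQuantity, ddG_chloroform: ThermoQuantity
) -> ThermoQuantity:
    """Water-minus-chloroform interaction energy (the aqueous solvation part)."""
    return ddG_water - ddG_chloroform


def table_entry(q: ThermoQuantity) -> str:
    """Render "value ± sigma" to integer kJ mol⁻¹, sigma rounded up."""
    return f"{round(q.value):d} ± {math.ceil(q.sigma - 1e-9):d}"
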