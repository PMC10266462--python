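"""Linear free-energy relationships and solvation decomposition.

The interpretive layer on top of the double-mutant-cycle results:

* **Hammett regression** — in a non-polar solvent the interaction
  energies track the meta Hammett constant of the guest substituent,
  ΔΔG°(CHCl₃)/kJ mol⁻¹ ≈ −7.4 − 11.7·σ_m, reflecting electrostatic
  control of both edge-to-face and stacking geometries.
* **Hydrophobic transfer line** — the water-minus-chloroform difference
  for non-polar substituents is linear (slope ≈ 1) in the water →
  n-hexadecane transfer free energy of the corresponding PhX compound:
  complexation fully desolvates a non-polar substituent.
* **Resolvation energies** — polar substituents fall below that line;
  the deviation measures the stabilisation gained by keeping H-bonds to
  water in the complex, and is well approximated by −α_S·β_X with
  α_S = 2.8 the H-bond donor parameter of water.
* **Composite aqueous predictor** — Hammett term + transfer-line term
  − α_S·β_X, assessed by its RMSE against measured values.
* A burial heuristic (≈ 0.15 kJ mol⁻¹ per Å² of hydrophobic surface)
  and entropy–enthalpy compensation diagnostics round out the toolkit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ALPHA_WATER",
    "HAMMETT_SLOPE_CHCL3",
    "HAMMETT_INTERCEPT_CHCL3",
    "NONPOLAR_LINE_SLOPE",
    "NONPOLAR_LINE_INTERCEPT",
    "BURIAL_COEFFICIENT",
    "NON_POLAR_SUBSTITUENTS",
    "POLAR_SUBSTITUENTS",
    "ProvenanceWarning",
    "SubstituentRecord",
    "LFERFit",
    "LinearFreeEnergyFit",
    "hammett_fit",
    "predict_chloroform_ddg",
    "nonpolar_transfer_fit",
    "resolvation_energy",
    "hbond_solvation_energy",
    "predict_water_ddg",
    "model_rmse",
    "buried_area_energy",
    "ee_compensation",
]

#: H-bond donor parameter of water on the Hunter α/β scale.
ALPHA_WATER = 2.8

#: Hammett description of the chloroform interaction energies (kJ/mol per σ_m).
HAMMETT_SLOPE_CHCL3 = -11.7
HAMMETT_INTERCEPT_CHCL3 = -7.4

#: Default non-polar transfer line: Δ(water−chloroform) = slope·ΔG_tr + intercept.
NONPOLAR_LINE_SLOPE = 1.1
NONPOLAR_LINE_INTERCEPT = 13.7

#: Free-energy cost of hydrating hydrophobic surface, kJ mol⁻¹ Å⁻².
BURIAL_COEFFICIENT = 0.15

NON_POLAR_SUBSTITUENTS = frozenset({"H", "Me", "Et", "iPr", "F", "Cl", "Br"})
POLAR_SUBSTITUENTS = frozenset({"CHO", "COMe", "NO2", "NMe2", "OMe"})


class ProvenanceWarning(UserWarning):
    """Emitted when literature-sourced parameters (σ, β, ΔG_transfer) are used."""


@dataclass(frozen=True)
class SubstituentRecord:
    """Per-substituent descriptors used by the LFER layer.

    dG_transfer is the water → n-hexadecane transfer free energy of the
    monosubstituted benzene PhX in kJ mol⁻¹ (more negative = more
    hydrophobic); ``None`` when no literature value is packaged.
    beta is the H-bond acceptor parameter β_X and must be 0 for the
    non-polar class.
    """

    X: str
    sigma_m: float
    sigma_p: float
    beta: float = 0.0
    dG_transfer: Optional[float] = None
    polarity_class: str = "non-polar"

    def __post_init__(self) -> None:
        if self.polarity_class not in ("non-polar", "polar"):
            raise ValueError(f"unknown polarity class {self.polarity_class!r}")
        if self.polarity_class == "polar" and self.beta == 0.0:
            raise ValueError(
                f"{self.X}: a polar substituent needs a nonzero H-bond "
                "acceptor parameter"
            )
        expected = (
            "non-polar" if self.X in NON_POLAR_SUBSTITUENTS
            else "polar" if self.X in POLAR_SUBSTITUENTS
            else None
        )
        if expected is not None and self.polarity_class != expected:
            raise ValueError(
                f"{self.X} must be classed {expected!r}, got "
                f"{self.polarity_class!r}"
            )


@dataclass(frozen=True)
class LFERFit:
    """An ordinary-least-squares line with standard errors and R²."""

    slope: float
    slope_sigma: float
    intercept: float
    intercept_sigma: float
    r_squared: float
    n_points: int
    residuals: Tuple[float, ...]
    labels: Tuple[str, ...] = ()

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


class LinearFreeEnergyFit:
    """Unweighted OLS of a free-energy response on one descriptor.

    Closed-form normal equations; standard errors from the residual
    variance with n−2 degrees of freedom.  Estimator-style: ``fit(x, y)``
    then read ``slope_``, ``intercept_``, ``r_squared_`` or ``fit_``.
    """

    def __init__(self) -> None:
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "LinearFreeEnergyFit":
        if params:
            raise ValueError(f"unknown parameter(s) {sorted(params)}")
        return self

    def fit(
        self,
        x: Sequence[float],
        y: Sequence[float],
        labels: Sequence[str] = (),
        weights: Optional[Sequence[float]] = None,
    ) -> "LinearFreeEnergyFit":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        n = len(x)
        if n < 3:
            raise ValueError("at least 3 points are required")
        # optional per-point weights (e.g. 1/σ²); default unweighted
        w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match x in length")
        sw = float(w.sum())
        xm, ym = float((w * x).sum() / sw), float((w * y).sum() / sw)
        sxx = float(np.sum(w * (x - xm) ** 2))
        if sxx == 0.0:
            raise ValueError("all descriptor values identical: singular design")
        sxy = float(np.sum(w * (x - xm) * (y - ym)))
        syy = float(np.sum(w * (y - ym) ** 2))
        slope = sxy / sxx
        intercept = float(ym - slope * xm)
        resid = y - (slope * x + intercept)
        ssr = float(np.sum(w * resid**2))
        r2 = 1.0 if syy == 0.0 else 1.0 - ssr / syy
        s2 = ssr / (n - 2) if n > 2 else 0.0
        slope_se = math.sqrt(s2 / sxx)
        intercept_se = math.sqrt(s2 * (1.0 / sw + xm**2 / sxx))
        self.slope_ = slope
        self.intercept_ = intercept
        self.r_squared_ = r2
        self.fit_ = LFERFit(
            slope=slope,
            slope_sigma=slope_se,
            intercept=intercept,
            intercept_sigma=intercept_se,
            r_squared=r2,
            n_points=n,
            residuals=tuple(float(r) for r in resid),
            labels=tuple(labels),
        )
        return self


def hammett_fit(pairs: Iterable[Tuple[float, float]], labels: Sequence[str] = ()) -> LFERFit:
    """OLS of a response (ΔΔG° or log K) on a Hammett constant."""
    pairs = list(pairs)
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    return LinearFreeEnergyFit().fit(x, y, labels).fit_


def predict_chloroform_ddg(
    sigma_m: float,
    slope: float = HAMMETT_SLOPE_CHCL3,
    intercept: float = HAMMETT_INTERCEPT_CHCL3,
) -> float:
    """Electrostatic (Hammett) estimate of the interaction energy in chloroform."""
    return intercept + slope * sigma_m


def nonpolar_transfer_fit(
    differences: Mapping[str, float],
    records: Mapping[str, SubstituentRecord],
    strict: bool = False,
) -> LFERFit:
    """Fit the water−chloroform difference against ΔG_transfer, non-polar only.

    Substituents classed non-polar but lacking a packaged transfer value
    are dropped with a by-name warning (``strict=True`` raises instead).
    """
    xs: List[float] = []
    ys: List[float] = []
    labels: List[str] = []
    missing: List[str] = []
    for X, diff in differences.items():
        rec = records.get(X)
        if rec is None or rec.polarity_class != "non-polar":
            continue
        if rec.dG_transfer is None or math.isnan(rec.dG_transfer):
            missing.append(X)
            continue
        xs.append(rec.dG_transfer)
        ys.append(diff)
        labels.append(X)
    if missing:
        msg = f"no transfer free energy packaged for: {', '.join(sorted(missing))}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, ProvenanceWarning, stacklevel=2)
    if len(xs) < 3:
        raise ValueError(
            f"need >= 3 non-polar substituents with transfer values, got {len(xs)}"
        )
    return LinearFreeEnergyFit().fit(xs, ys, labels).fit_


def resolvation_energy(
    X: str,
    differences: Mapping[str, float],
    records: Mapping[str, SubstituentRecord],
    nonpolar_fit: LFERFit,
) -> float:
    """Extra aqueous stabilisation of a polar substituent (kJ mol⁻¹, negative).

    The observed water−chloroform difference minus the non-polar line's
    prediction at the substituent's transfer free energy: what remains
    after complete-desolvation behaviour is accounted for, i.e. the
    benefit of retaining H-bonds to water in the complex.
    """
    rec = records[X]
    if rec.polarity_class != "polar":
        raise ValueError(f"{X} is non-polar; resolvation applies to polar groups")
    if rec.dG_transfer is None or math.isnan(rec.dG_transfer):
        raise ValueError(f"no transfer free energy packaged for {X}")
    return differences[X] - nonpolar_fit.predict(rec.dG_transfer)


def hbond_solvation_energy(beta: float, alpha_s: float = ALPHA_WATER) -> float:
    """Free energy of an X···water H-bond, −α_S·β_X (kJ mol⁻¹)."""
    return -alpha_s * beta


def predict_water_ddg(
    record: SubstituentRecord,
    nonpolar_line: Tuple[float, float] = (NONPOLAR_LINE_SLOPE, NONPOLAR_LINE_INTERCEPT),
    hammett: Tuple[float, float] = (HAMMETT_SLOPE_CHCL3, HAMMETT_INTERCEPT_CHCL3),
    alpha_s: float = ALPHA_WATER,
) -> float:
    """Composite aqueous interaction-energy predictor (kJ mol⁻¹).

    Electrostatic Hammett term (as in chloroform) + hydrophobic
    transfer-line term + H-bond resolvation term −α_S·β_X (zero for
    non-polar X).  The transfer line defaults to the fitted non-polar
    coefficients so the predictor is usable without refitting.
    """
    if record.dG_transfer is None or math.isnan(record.dG_transfer):
        raise ValueError(f"no transfer free energy packaged for {record.X}")
    if record.polarity_class == "polar" and record.beta == 0.0:
        raise ValueError(f"{record.X}: polar substituent with missing beta")
    slope, intercept = nonpolar_line
    h_slope, h_intercept = hammett
    return (
        h_intercept
        + h_slope * record.sigma_m
        + slope * record.dG_transfer
        + intercept
        - alpha_s * record.beta
    )


def model_rmse(predictions: Sequence[float], observations: Sequence[float]) -> float:
    """Root-mean-square deviation between paired predictions and measurements."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predictions and observations must have equal length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def buried_area_energy(area: float, coefficient: float = BURIAL_COEFFICIENT) -> float:
    """Hydrophobic stabilisation from burying ``area`` Å² of surface (≤ 0)."""
    if area < 0:
        raise ValueError("buried area must be non-negative")
    return -coefficient * area


def ee_compensation(
    dH_list: Sequence[float], TdS_list: Sequence[float]
) -> LFERFit:
    """Entropy–enthalpy compensation: OLS of TΔS° on ΔH° across a series."""
    return LinearFreeEnergyFit().fit(dH_list, TdS_list).fit_
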