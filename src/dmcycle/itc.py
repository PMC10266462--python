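"""Isothermal titration calorimetry: 1:1 isotherm simulation and fitting.

A titration injects guest (titrant) into a cell containing host.  For a
1:1 equilibrium the bound concentration after each injection is the
root of the mass-balance quadratic (the Wiseman isotherm)::

    [HG] = ((H + G + 1/K) − sqrt((H + G + 1/K)² − 4·H·G)) / 2

with H, G the running *total* concentrations in the active cell volume.
Each injection displaces an equal volume of cell liquid, so existing
concentrations are diluted by (1 − vᵢ/V₀) before the new titrant is
added — the perfusion convention used by commercial instruments.  The
heat of injection i is the enthalpy of the complex newly formed in the
active volume, normalised per mole of injected guest.

The shape of the isotherm is governed by the Wiseman c-value
c = n·K·[H]_cell.  For c ≲ 1 the curve is too shallow and for
c ≳ 10³–10⁴ too step-like to determine K, although a step-like curve
still yields an accurate ΔH° (its height) — the fit therefore reports a
``K_reliable`` flag alongside the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .thermo import ThermoQuantity

__all__ = [
    "InjectionSchedule",
    "ITCFitResult",
    "ITCFitError",
    "bound_concentration",
    "simulate_heats",
    "ITCIsothermFit",
    "fit_isotherm",
]


class ITCFitError(RuntimeError):
    """Isotherm fit failed or the input is degenerate; message carries diagnostics."""


@dataclass(frozen=True)
class InjectionSchedule:
    """Concentrations and injection programme of one ITC experiment.

    Parameters
    ----------
    cell_volume : float
        Active cell volume V₀ in litres.
    host_cell_concentration : float
        Initial host concentration in the cell, M.
    titrant_syringe_concentration : float
        Guest concentration in the syringe, M.
    injection_volumes : tuple of float
        Per-injection volumes in litres.
    """

    cell_volume: float
    host_cell_concentration: float
    titrant_syringe_concentration: float
    injection_volumes: tuple

    def __post_init__(self) -> None:
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be positive")
        if self.host_cell_concentration <= 0:
            raise ValueError("host concentration must be positive")
        if self.titrant_syringe_concentration <= 0:
            raise ValueError("syringe concentration must be positive")
        vols = tuple(float(v) for v in self.injection_volumes)
        object.__setattr__(self, "injection_volumes", vols)
        if not vols or any(v <= 0 for v in vols):
            raise ValueError("injection volumes must be positive")
        if sum(vols) >= self.cell_volume:
            raise ValueError(
                "cumulative injected volume must stay below the cell volume"
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @classmethod
    def default(
        cls,
        cell_mM: float = 0.04,
        syringe_mM: float = 0.28,
        n_injections: int = 30,
        injection_uL: float = 10.0,
        cell_volume_mL: float = 1.4,
    ) -> "InjectionSchedule":
        """Typical microcalorimeter programme (0.28 mM guest into 0.04 mM host)."""
        return cls(
            cell_volume=cell_volume_mL * 1e-3,
            host_cell_concentration=cell_mM * 1e-3,
            titrant_syringe_concentration=syringe_mM * 1e-3,
            injection_volumes=(injection_uL * 1e-6,) * n_injections,
        )


def bound_concentration(H: float, G: float, K: float) -> float:
    """Root of the 1:1 mass-balance quadratic; numerically safe form.

    Uses the (b − sqrt(d)) root rewritten as 2HG/(b + sqrt(d)) to avoid
    catastrophic cancellation when K·H ≫ 1.
    """
    if H <= 0 or G <= 0:
        return 0.0
    b = H + G + 1.0 / K
    disc = b * b - 4.0 * H * G
    if disc < 0:  # impossible for valid inputs; guard against rounding
        if disc < -1e-12 * b * b:
            raise ITCFitError(f"negative discriminant {disc} in mass balance")
        disc = 0.0
    return 2.0 * H * G / (b + math.sqrt(disc))


def _total_concentrations(schedule: InjectionSchedule) -> tuple:
    """Running total host/guest concentrations after each injection."""
    V0 = schedule.cell_volume
    H = schedule.host_cell_concentration
    G = 0.0
    Hs, Gs, dil = [], [], []
    for v in schedule.injection_volumes:
        d = v / V0
        H *= 1.0 - d
        G = G * (1.0 - d) + schedule.titrant_syringe_concentration * d
        Hs.append(H)
        Gs.append(G)
        dil.append(1.0 - d)
    return np.array(Hs), np.array(Gs), np.array(dil)


def _molar_heats(
    schedule: InjectionSchedule,
    K: float,
    dH: float,
    n_stoich: float = 1.0,
    baseline: float = 0.0,
) -> np.ndarray:
    """Noise-free molar heats (kJ per mol of injectant) for each injection.

    Stoichiometry n is absorbed as an effective active-host fraction
    n·[H]; the complex concentration is reported per binding site.
    """
    Hs, Gs, dil = _total_concentrations(schedule)
    V0 = schedule.cell_volume
    q = np.empty(len(Hs))
    hg_prev = 0.0
    for i, (H, G, d) in enumerate(zip(Hs, Gs, dil)):
        hg = bound_concentration(n_stoich * H, G, K)
        dq = dH * V0 * (hg - hg_prev * d)  # kJ released in injection i
        moles_injected = (
            schedule.titrant_syringe_concentration * schedule.injection_volumes[i]
        )
        q[i] = dq / moles_injected + baseline
        hg_prev = hg
    return q


def simulate_heats(
    schedule: InjectionSchedule,
    K: float,
    dH: float,
    n_stoich: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    baseline: float = 0.0,
) -> np.ndarray:
    """Simulate per-injection molar heats for a 1:1 titration.

    Parameters
    ----------
    K : float
        Association constant, M⁻¹ (> 0).
    dH : float
        Binding enthalpy ΔH°, kJ mol⁻¹.
    n_stoich : float
        Stoichiometry (active host fraction), dimensionless.
    noise_sd : float
        Standard deviation of additive Gaussian noise, kJ per mol of
        injectant.
    seed : int, optional
        Seed for the noise generator; required for reproducibility.
    baseline : float
        Constant dilution-heat offset, kJ per mol of injectant.
    """
    if K <= 0:
        raise ValueError("association constant must be positive")
    q = _molar_heats(schedule, K, dH, n_stoich, baseline)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd, size=q.shape)
    return q


@dataclass(frozen=True)
class ITCFitResult:
    """Fitted 1:1 isotherm parameters with curvature-based uncertainties."""

    K: ThermoQuantity
    dH: ThermoQuantity
    n_stoich: ThermoQuantity
    baseline: float
    c_value: float
    K_reliable: bool
    residuals: np.ndarray
    n_iter: int


class ITCIsothermFit:
    """Nonlinear least-squares fit of per-injection heats to a 1:1 isotherm.

    Estimator-style interface: construct with options, call
    :meth:`fit`, read trailing-underscore attributes.

    Parameters
    ----------
    constrain_n : bool, default False
        Fix the stoichiometry at 1.0 instead of fitting it.
    discard_first : bool, default False
        Drop injection 1 before fitting (common practice against the
        first-injection artefact; kept by default).
    c_min, c_max : float
        Reliability window for the Wiseman c-value; outside it the
        ``K_reliable_`` flag is False.  The default window [1, 10⁴] is
        deliberately stricter than the extreme step-like regime
        (c > 10⁶) where K is entirely unmeasurable.
    max_nfev : int
        Iteration budget for the optimiser.

    Attributes
    ----------
    K_, dH_, n_, baseline_ : fitted parameters (ThermoQuantity / float)
    c_value_ : float
    K_reliable_ : bool
    result_ : ITCFitResult
    """

    def __init__(
        self,
        constrain_n: bool = False,
        discard_first: bool = False,
        c_min: float = 1.0,
        c_max: float = 1e4,
        max_nfev: int = 400,
    ) -> None:
        self.constrain_n = constrain_n
        self.discard_first = discard_first
        self.c_min = c_min
        self.c_max = c_max
        self.max_nfev = max_nfev

    # -- minimal estimator plumbing -------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "constrain_n": self.constrain_n,
            "discard_first": self.discard_first,
            "c_min": self.c_min,
            "c_max": self.c_max,
            "max_nfev": self.max_nfev,
        }

    def set_params(self, **params) -> "ITCIsothermFit":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -------------------------------------------------------------------
    def _initial_guess(
        self, heats: np.ndarray, schedule: InjectionSchedule, keep: slice
    ) -> tuple:
        """Coarse grid on log10 K; (dH, baseline) are linear given K, n."""
        best = None
        for logK in np.arange(2.0, 11.0, 1.0):
            shape = _molar_heats(schedule, 10.0**logK, 1.0, 1.0, 0.0)[keep]
            A = np.column_stack([shape, np.ones_like(shape)])
            coef, res, *_ = np.linalg.lstsq(A, heats[keep], rcond=None)
            sse = float(np.sum((A @ coef - heats[keep]) ** 2))
            if best is None or sse < best[0]:
                best = (sse, logK, coef[0], coef[1])
        _, logK, dH0, base0 = best
        if abs(dH0) < 1e-12:
            dH0 = np.min(heats) if abs(np.min(heats)) > abs(np.max(heats)) else np.max(heats)
        return logK, dH0, base0

    def fit(
        self,
        schedule: InjectionSchedule,
        heats: Sequence[float],
        initial_guesses: Optional[dict] = None,
    ) -> "ITCIsothermFit":
        heats = np.asarray(heats, dtype=float)
        sched = schedule
        if len(heats) != sched.n_injections:
            raise ValueError("heats length must match the injection schedule")
        if len(heats) < 6:
            raise ITCFitError("at least 6 injections are required")
        if np.allclose(heats, 0.0):
            raise ITCFitError("all-zero heats: no signal to fit")
        # The full dilution history is always modelled; discarding the
        # first injection only removes its residual from the objective.
        keep = slice(1, None) if self.discard_first else slice(None)

        logK0, dH0, base0 = self._initial_guess(heats, sched, keep)
        if initial_guesses:
            if "K" in initial_guesses:
                logK0 = math.log10(initial_guesses["K"])
            dH0 = initial_guesses.get("dH", dH0)
            base0 = initial_guesses.get("baseline", base0)
        n0 = 1.0

        if self.constrain_n:
            x0 = np.array([logK0, dH0, base0])

            def unpack(x):
                return 10.0 ** x[0], x[1], 1.0, x[2]
        else:
            x0 = np.array([logK0, dH0, n0, base0])

            def unpack(x):
                return 10.0 ** x[0], x[1], x[2], x[3]

        def residual(x):
            K, dH, n, base = unpack(x)
            return (_molar_heats(sched, K, dH, n, base) - heats)[keep]

        sol = least_squares(residual, x0, max_nfev=self.max_nfev, method="lm")
        if not sol.success:
            raise ITCFitError(
                f"isotherm fit did not converge: {sol.message} "
                f"(nfev={sol.nfev}, cost={sol.cost:.3g})"
            )
        K, dH, n, base = unpack(sol.x)

        # Gauss-Newton covariance: (JᵀJ)⁻¹ · s² with s² = SSR/(N − p)
        dof = max(len(sol.fun) - len(sol.x), 1)
        s2 = 2.0 * sol.cost / dof
        JTJ = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(JTJ) * s2
            perr = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            perr = np.full(len(sol.x), np.inf)
        sigma_K = K * math.log(10.0) * perr[0]
        sigma_dH = perr[1]
        sigma_n = 0.0 if self.constrain_n else perr[2]

        c_value = n * K * sched.host_cell_concentration
        reliable = self.c_min <= c_value <= self.c_max

        self.K_ = ThermoQuantity(K, sigma_K, "1/M")
        self.dH_ = ThermoQuantity(dH, sigma_dH, "kJ/mol")
        self.n_ = ThermoQuantity(n, sigma_n, "")
        self.baseline_ = float(base)
        self.c_value_ = float(c_value)
        self.K_reliable_ = bool(reliable)
        self.result_ = ITCFitResult(
            K=self.K_,
            dH=self.dH_,
            n_stoich=self.n_,
            baseline=self.baseline_,
            c_value=self.c_value_,
            K_reliable=self.K_reliable_,
            residuals=residual(sol.x),
            n_iter=sol.nfev,
        )
        return self


def fit_isotherm(
    heats: Sequence[float],
    schedule: InjectionSchedule,
    initial_guesses: Optional[dict] = None,
    **options,
) -> ITCFitResult:
    """Thin functional wrapper over :class:`ITCIsothermFit`."""
    est = ITCIsothermFit(**options)
    est.fit(schedule, heats, initial_guesses=initial_guesses)
    return est.result_
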