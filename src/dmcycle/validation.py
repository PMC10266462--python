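"""Seeded recovery benchmarks for the whole pipeline.

Each benchmark generates synthetic data with known ground truth, runs
the corresponding analysis stage and summarises how well the truth is
recovered.  They power both the package's acceptance checks and the
reproduction script; all randomness flows from a single seed.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Tuple

import numpy as np
from scipy import stats

from .dmc import dmc_delta
from .itc import InjectionSchedule, ITCIsothermFit, simulate_heats
from .lfer import hammett_fit
from .nmr import (
    AffinityLadder,
    CompetitionObservation,
    LadderAnchor,
    LadderEdge,
    LadderGraph,
    dynamic_range_check,
    exchange_constant,
)
from .synthetic import (
    StudyScenario,
    child_rng,
    competitive_equilibrium_solve,
    generate_study,
)

__all__ = [
    "itc_recovery_benchmark",
    "tight_binder_benchmark",
    "ladder_recovery_benchmark",
    "end_to_end_benchmark",
]


def itc_recovery_benchmark(
    n_reps: int = 200,
    seed: int = 42,
    noise_frac: float = 0.01,
    c_range: Tuple[float, float] = (5.0, 500.0),
) -> Dict[str, float]:
    """Parameter recovery across the informative c-value window.

    Draws K so that c = K·[H]_cell is log-uniform over ``c_range``, ΔH°
    uniform in [−60, −20] kJ/mol, adds heat noise of ``noise_frac``·|ΔH|
    and refits.  Returns median relative errors of K and ΔH°.
    """
    rng = np.random.default_rng(seed)
    sched = InjectionSchedule.default()
    errK, errH = [], []
    for _ in range(n_reps):
        c = 10 ** rng.uniform(*np.log10(c_range))
        K = c / sched.host_cell_concentration
        dH = rng.uniform(-60.0, -20.0)
        heats = simulate_heats(
            sched, K, dH,
            noise_sd=noise_frac * abs(dH),
            seed=int(rng.integers(2**31 - 1)),
        )
        est = ITCIsothermFit(constrain_n=True).fit(sched, heats)
        errK.append(abs(est.K_.value - K) / K)
        errH.append(abs(est.dH_.value - dH) / abs(dH))
    return {
        "median_K_rel_err": float(np.median(errK)),
        "median_dH_rel_err": float(np.median(errH)),
        "n": n_reps,
    }


def tight_binder_benchmark(
    seed: int = 42, c_value: float = 4e6, noise_frac: float = 0.01
) -> Dict[str, float]:
    """The step-isotherm regime: K unmeasurable, ΔH° still accurate."""
    sched = InjectionSchedule.default()
    K = c_value / sched.host_cell_concentration
    dH = -40.0
    heats = simulate_heats(
        sched, K, dH, noise_sd=noise_frac * abs(dH), seed=seed
    )
    est = ITCIsothermFit(constrain_n=True).fit(sched, heats)
    return {
        "true_c": c_value,
        "fitted_c": est.c_value_,
        "K_reliable": est.K_reliable_,
        "dH_rel_err": abs(est.dH_.value - dH) / abs(dH),
    }


def _simulate_edge(
    rng: np.random.Generator,
    logK_lo: float,
    logK_hi: float,
    noise: float,
    n_spectra: int = 5,
    host_total: float = 3e-4,
) -> Tuple[float, float]:
    """One pairwise competition: mean and sd of per-spectrum log10 ratios."""
    Kw, Ks = 10.0**logK_lo, 10.0**logK_hi
    ratio = Ks / Kw
    logs = []
    lams = np.linspace(0.6, 1.4, n_spectra)
    for i, lam in enumerate(lams):
        Gs = 1.2 * host_total
        Gw = min(ratio, 1e9) * Gs * lam
        eq = competitive_equilibrium_solve(host_total, [Gw, Gs], [Kw, Ks])
        species = {
            "HG1": eq.bound[0],
            "HG2": eq.bound[1],
            "G1": eq.free_guests[0],
            "G2": eq.free_guests[1],
        }
        obs = CompetitionObservation(
            spectrum_id=str(i),
            species_integrals={
                sp: (c * 2 * math.exp(rng.normal(0.0, noise)) * 1e6, 2)
                for sp, c in species.items()
            },
        )
        if dynamic_range_check(obs)[0]:
            logs.append(math.log10(exchange_constant(obs)))
    if len(logs) < 2:
        raise RuntimeError("competition produced fewer than two usable spectra")
    return float(np.mean(logs)), float(np.std(logs, ddof=1))


def ladder_recovery_benchmark(
    n_reps: int = 500,
    seed: int = 77,
    integral_noise: float = 0.02,
    max_nodes: int = 8,
    anchor_sigma: float = 0.02,
) -> Dict[str, float]:
    """Random anchored ladders: fraction of replicates whose every node
    lands within 3 propagated sigmas of truth."""
    ok = 0
    for rep in range(n_reps):
        rng = child_rng(seed, "ladder", rep)
        n = int(rng.integers(4, max_nodes + 1))
        logK = np.sort(rng.uniform(5.0, 12.0, size=n))
        edges = []
        for i in range(1, n):
            j = int(rng.integers(0, i))
            lo, hi = (j, i) if logK[j] <= logK[i] else (i, j)
            m, s = _simulate_edge(rng, logK[lo], logK[hi], integral_noise)
            edges.append(LadderEdge(f"n{lo}", f"n{hi}", m, max(s, 1e-4)))
        anchor = LadderAnchor(
            "n0",
            float(logK[0] + rng.normal(0.0, anchor_sigma)),
            anchor_sigma,
        )
        est = AffinityLadder().fit(LadderGraph(edges=edges, anchors=[anchor]))
        ok += all(
            abs(est.log10K_[f"n{i}"].value - logK[i])
            <= 3.0 * est.log10K_[f"n{i}"].sigma
            for i in range(n)
        )
    return {"coverage_3sigma": ok / n_reps, "n": n_reps}


def end_to_end_benchmark(
    substituents,
    n_reps: int = 200,
    seed: int = 10_000,
    interaction_noise_sd: float = 0.5,
    slope_truth: float = -11.7,
) -> Dict[str, float]:
    """Full-route studies (ITC + NMR ladder → DMC → Hammett regression).

    For each replicate, the chloroform interaction energies are fit
    against σ_m and the 95 % confidence interval of the slope is
    checked against the injected value.  Returns the CI coverage and
    the pooled mean absolute DMC error.
    """
    hits = 0
    abs_err = []
    for rep in range(n_reps):
        scenario = StudyScenario(
            substituents=substituents,
            interaction_noise_sd=interaction_noise_sd,
            seed=seed + rep,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            study = generate_study(scenario, route="instrument")
        pairs = []
        for X, rec in substituents.items():
            dd = dmc_delta(study.quad(X, "chloroform"), "G")
            pairs.append((rec.sigma_m, dd.value))
            for solvent in ("water", "chloroform"):
                ddv = dmc_delta(study.quad(X, solvent), "G").value
                abs_err.append(abs(ddv - study.interaction_truth[(X, solvent)]))
        fit = hammett_fit(pairs)
        tcrit = stats.t.ppf(0.975, fit.n_points - 2)
        hits += abs(fit.slope - slope_truth) <= tcrit * fit.slope_sigma
    return {
        "slope_ci_coverage": hits / n_reps,
        "mean_abs_dmc_err": float(np.mean(abs_err)),
        "n": n_reps,
    }
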