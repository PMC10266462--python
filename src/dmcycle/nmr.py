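"""Guest-competition NMR: exchange constants and affinity ladders.

When two guests compete for one host and all species are in slow
exchange, the ¹H signal integrals report concentrations directly
(integral ∝ concentration × protons per signal).  The guest-exchange
equilibrium constant for  HG₁ + G₂ ⇌ HG₂ + G₁  is

    K_exch = [HG₂][G₁] / ([HG₁][G₂])        so  K(HG₂) = K_exch · K(HG₁)

i.e. K_exch > 1 means the second guest binds more strongly.  Because
K_exch is a ratio of ratios it is invariant to spectrometer gain and to
the absolute concentration scale.

A single competition can only bridge a limited affinity gap (both
complexes must be observable), but chaining pairwise competitions steps
up an *affinity ladder* from an absolutely calibrated reference complex
to affinities far beyond direct measurement.  The ladder is solved here
as a weighted least-squares problem on log₁₀ K over the measurement
graph, which reduces exactly to multiplying ratios along the chain when
the graph is a tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .thermo import ThermoQuantity

__all__ = [
    "CompetitionObservation",
    "DynamicRangeError",
    "MassBalanceError",
    "exchange_constant",
    "exchange_constant_series",
    "dynamic_range_check",
    "LadderEdge",
    "LadderAnchor",
    "LadderGraph",
    "AffinityLadder",
    "ladder_solve",
]

#: role keys a competition spectrum must resolve
ROLES = ("HG1", "HG2", "G1", "G2")


class DynamicRangeError(ValueError):
    """A required species is invisible: the K ratio exceeds the method's range."""


class MassBalanceError(ValueError):
    """Derived concentrations are inconsistent with the stated totals."""


@dataclass(frozen=True)
class CompetitionObservation:
    """Integrals from one competition spectrum.

    ``species_integrals`` maps the role keys ``HG1``/``HG2`` (the two
    host·guest complexes) and ``G1``/``G2`` (the free guests) to
    ``(integral, protons_per_signal)``.  ``host_total`` and
    ``guest_totals`` (role → M) are optional; when present they fix the
    absolute concentration scale and enable mass-balance validation.
    The host is assumed saturated (free host negligible), which is the
    regime in which competition experiments are run.
    """

    spectrum_id: str
    species_integrals: Mapping[str, Tuple[float, int]]
    host_total: Optional[float] = None
    guest_totals: Optional[Mapping[str, float]] = None
    mass_balance_tol: float = 0.05

    def __post_init__(self) -> None:
        for sp, (integral, protons) in self.species_integrals.items():
            if integral < 0:
                raise ValueError(f"negative integral for {sp}")
            if protons < 1:
                raise ValueError(f"protons_per_signal must be >= 1 for {sp}")

    def raw_concentrations(self) -> Dict[str, float]:
        """Concentrations up to one overall scale factor (integral/protons)."""
        return {
            sp: integral / protons
            for sp, (integral, protons) in self.species_integrals.items()
        }

    def concentrations(self) -> Dict[str, float]:
        """Concentrations in M, scaled to close the host mass balance.

        Requires ``host_total``; validates guest mass balances to
        ``mass_balance_tol`` (relative) when guest totals are given.
        """
        raw = self.raw_concentrations()
        if self.host_total is None:
            raise ValueError("host_total is required to fix the scale")
        bound = raw.get("HG1", 0.0) + raw.get("HG2", 0.0)
        if bound <= 0:
            raise DynamicRangeError("no host-bound species observed")
        scale = self.host_total / bound
        conc = {sp: v * scale for sp, v in raw.items()}
        if self.guest_totals:
            for g, free in (("1", "G1"), ("2", "G2")):
                key = f"G{g}"
                total = self.guest_totals.get(key)
                if total is None:
                    continue
                derived = conc.get(free, 0.0) + conc.get(f"HG{g}", 0.0)
                if abs(derived - total) > self.mass_balance_tol * total:
                    raise MassBalanceError(
                        f"{self.spectrum_id}: guest {key} mass balance off by "
                        f"{abs(derived - total) / total:.1%} (> "
                        f"{self.mass_balance_tol:.0%})"
                    )
        return conc


def exchange_constant(observation: CompetitionObservation) -> float:
    """Guest-exchange constant K_exch = [HG₂][G₁]/([HG₁][G₂]) from one spectrum.

    Scale-invariant: works directly on integral/proton ratios without
    absolute concentrations.  Raises :class:`DynamicRangeError` when any
    of the four required species has zero integral.
    """
    raw = observation.raw_concentrations()
    missing = [r for r in ROLES if raw.get(r, 0.0) <= 0.0]
    if missing:
        raise DynamicRangeError(
            f"{observation.spectrum_id}: species {missing} below detection; "
            "the association-constant ratio exceeds the measurable range"
        )
    return (raw["HG2"] * raw["G1"]) / (raw["HG1"] * raw["G2"])


def exchange_constant_series(
    observations: Sequence[CompetitionObservation],
) -> ThermoQuantity:
    """Mean K_exch over a titration series, sigma = sd of per-spectrum values."""
    values = [exchange_constant(o) for o in observations]
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return ThermoQuantity(mean, sd, "")


def dynamic_range_check(
    observation: CompetitionObservation, min_minor_fraction: float = 0.05
) -> Tuple[bool, str]:
    """Accept a spectrum only if both complexes are comfortably observable.

    The minor complex must hold at least ``min_minor_fraction`` of the
    total bound host; below that, integration error dominates and the
    exchange constant is unreliable.
    """
    raw = observation.raw_concentrations()
    b1, b2 = raw.get("HG1", 0.0), raw.get("HG2", 0.0)
    bound = b1 + b2
    if bound <= 0:
        return False, "no bound species observed"
    minor = min(b1, b2) / bound
    if minor < min_minor_fraction:
        return (
            False,
            f"minor complex fraction {minor:.3g} below "
            f"threshold {min_minor_fraction:g}",
        )
    return True, "ok"


# ---------------------------------------------------------------------------
# affinity ladder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LadderEdge:
    """One measured competition: log10 K(target) − log10 K(source) = ratio."""

    source: str
    target: str
    log10_ratio: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("edge sigma must be positive")


@dataclass(frozen=True)
class LadderAnchor:
    """A complex with an absolutely known log10 K (the ladder's reference)."""

    node: str
    log10_K: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("anchor sigma must be non-negative")


@dataclass
class LadderGraph:
    edges: List[LadderEdge]
    anchors: List[LadderAnchor]

    @property
    def nodes(self) -> List[str]:
        seen: Dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.source)
            seen.setdefault(e.target)
        for a in self.anchors:
            seen.setdefault(a.node)
        return list(seen)


class AffinityLadder:
    """Weighted least-squares fusion of a competition-measurement graph.

    Minimises Σ_e w_e (x_j − x_i − r_e)² + Σ_a w_a (x_a − v_a)² over the
    per-complex log₁₀ K values x, with w = 1/σ².  Anchors enter as
    strong priors; with a single anchor and a tree of edges the solution
    is exactly the chained product of ratios.

    Attributes (after :meth:`fit`)
    ------------------------------
    log10K_ : dict node → ThermoQuantity
        Absolute log₁₀ K with sigma from the inverse normal matrix
        (includes anchor uncertainty).
    log10K_relative_sigma_ : dict node → float
        Sigma with anchors treated as exact (measurement-only part),
        useful when the reference value's error should be kept separate.
    cycle_warnings_ : list of str
    """

    def __init__(self, anchor_weight_floor: float = 1e-12, cycle_nsigma: float = 3.0):
        self.anchor_weight_floor = anchor_weight_floor
        self.cycle_nsigma = cycle_nsigma

    def get_params(self, deep: bool = True) -> dict:
        return {
            "anchor_weight_floor": self.anchor_weight_floor,
            "cycle_nsigma": self.cycle_nsigma,
        }

    def set_params(self, **params) -> "AffinityLadder":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _check_connected(self, graph: LadderGraph) -> None:
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_edges_from((e.source, e.target) for e in graph.edges)
        anchored = {a.node for a in graph.anchors}
        if not anchored:
            raise ValueError("ladder needs at least one anchor")
        for comp in nx.connected_components(g):
            if not comp & anchored:
                orphan = sorted(comp)
                raise ValueError(
                    f"complex(es) {orphan} are not connected to any anchor"
                )

    def _check_cycles(self, graph: LadderGraph) -> List[str]:
        # Signed ratio sums around independent cycles should vanish;
        # a residual beyond cycle_nsigma·σ flags inconsistent data.
        msgs: List[str] = []
        # parallel edges: every pair of edges between the same nodes is a cycle
        simple = nx.Graph()
        for idx, e in enumerate(graph.edges):
            pair = tuple(sorted((e.source, e.target)))
            if simple.has_edge(*pair):
                other = graph.edges[simple.edges[pair]["idx"]]
                sgn = 1.0 if (other.source, other.target) == (e.source, e.target) else -1.0
                mis = e.log10_ratio - sgn * other.log10_ratio
                sig = math.hypot(e.sigma, other.sigma)
                if abs(mis) > self.cycle_nsigma * sig:
                    msgs.append(
                        f"replicate edges {e.source}->{e.target} disagree by "
                        f"{mis:.3g} (> {self.cycle_nsigma:g} sigma = {self.cycle_nsigma * sig:.3g})"
                    )
            else:
                simple.add_edge(*pair, idx=idx)
        for cycle in nx.cycle_basis(simple):
            total = 0.0
            var = 0.0
            ok = True
            for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                e = graph.edges[simple.edges[tuple(sorted((a, b)))]["idx"]]
                sgn = 1.0 if (e.source, e.target) == (a, b) else -1.0
                total += sgn * e.log10_ratio
                var += e.sigma**2
            if abs(total) > self.cycle_nsigma * math.sqrt(var):
                msgs.append(
                    f"cycle {' -> '.join(cycle + [cycle[0]])} closes with "
                    f"residual {total:.3g} (> {self.cycle_nsigma:g} sigma = "
                    f"{self.cycle_nsigma * math.sqrt(var):.3g})"
                )
        return msgs

    def fit(self, graph: LadderGraph) -> "AffinityLadder":
        self._check_connected(graph)
        self.cycle_warnings_ = self._check_cycles(graph)
        for msg in self.cycle_warnings_:
            warnings.warn(msg, stacklevel=2)

        nodes = graph.nodes
        index = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        rows = len(graph.edges) + len(graph.anchors)
        A = np.zeros((rows, n))
        b = np.zeros(rows)
        w = np.zeros(rows)
        for r, e in enumerate(graph.edges):
            A[r, index[e.target]] = 1.0
            A[r, index[e.source]] = -1.0
            b[r] = e.log10_ratio
            w[r] = 1.0 / e.sigma**2
        for r, a in enumerate(graph.anchors, start=len(graph.edges)):
            A[r, index[a.node]] = 1.0
            b[r] = a.log10_K
            w[r] = 1.0 / max(a.sigma**2, self.anchor_weight_floor)

        W = np.diag(w)
        N = A.T @ W @ A
        x = np.linalg.solve(N, A.T @ W @ b)
        cov = np.linalg.inv(N)
        sig = np.sqrt(np.diag(cov))

        # anchor-free sigmas: subtract the anchor variance propagated
        # through the (approximately rigid) ladder
        anchor_var = min(a.sigma**2 for a in graph.anchors)
        rel = np.sqrt(np.clip(np.diag(cov) - anchor_var, 0.0, np.inf))

        self.nodes_ = nodes
        self.log10K_ = {
            nd: ThermoQuantity(float(x[i]), float(sig[i]), "log10(1/M)")
            for nd, i in index.items()
        }
        self.log10K_relative_sigma_ = {nd: float(rel[index[nd]]) for nd in nodes}
        return self


def ladder_solve(graph: LadderGraph, **options) -> Dict[str, ThermoQuantity]:
    """Thin functional wrapper over :class:`AffinityLadder`."""
    return AffinityLadder(**options).fit(graph).log10K_
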