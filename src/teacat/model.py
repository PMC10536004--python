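"""Linear compartmental model of catechin trafficking.

The model describes the fate of an orally ingested catechin bolus as
first-order, donor-controlled transfers between named body pools
(upper GI tract, small and large intestine, liver, plasma, kidneys,
extravascular tissues) and irreversible losses into terminal sinks
(feces, urine, extravascular loss).  All state variables are expressed
as *fraction of the ingested dose*, so the system is dimensionless and
dose-independent; transfer coefficients L(I, J) carry units of
fraction·h⁻¹, with J the donor and I the recipient pool.

The system ``dx/dt = M x`` with constant generator ``M`` is solved
exactly by matrix exponentiation (eigendecomposition fast path) or,
as an independent cross-check, by stiff ODE integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.integrate import solve_ivp

Edge = tuple[str, str]

# -- final topology ----------------------------------------------------------

FINAL_COMPARTMENTS: tuple[str, ...] = (
    "upper_GI",
    "small_intestine",
    "large_intestine",
    "liver",
    "plasma",
    "kidneys",
    "extravascular",
)
FINAL_SINKS: tuple[str, ...] = ("feces", "urine", "extravascular_loss")

FINAL_EDGES: tuple[Edge, ...] = (
    ("upper_GI", "small_intestine"),
    ("small_intestine", "large_intestine"),
    ("small_intestine", "liver"),
    ("large_intestine", "feces"),
    ("liver", "plasma"),
    ("plasma", "kidneys"),
    ("plasma", "extravascular"),
    ("extravascular", "plasma"),
    ("extravascular", "extravascular_loss"),
    ("kidneys", "urine"),
)

#: small_intestine → liver: the absorption route (fraction absorbed per h).
ABSORPTION_EDGE: Edge = ("small_intestine", "liver")
#: small_intestine → large_intestine: the fecal route, fixed at 2× absorption.
FECAL_EDGE: Edge = ("small_intestine", "large_intestine")
#: large_intestine → feces: drains an unsampled pool into an unsampled sink.
COLONIC_EDGE: Edge = ("large_intestine", "feces")

VARIANTS = ("portal_vein", "biliary_excretion", "enterohepatic", "no_extravascular")


@dataclass(frozen=True)
class ModelStructure:
    """Directed compartment graph with dosing site, observation sites and sinks.

    Compartments are kinetically homogeneous pools; sinks are terminal
    (irreversible) destinations with no outgoing edges.  The bolus dose
    enters ``dose_compartment`` at t = 0.
    """

    compartments: tuple[str, ...]
    sinks: tuple[str, ...]
    edges: tuple[Edge, ...]
    dose_compartment: str = "upper_GI"
    plasma_compartment: str = "plasma"
    urine_sink: str = "urine"

    def __post_init__(self) -> None:
        nodes = set(self.compartments) | set(self.sinks)
        if set(self.compartments) & set(self.sinks):
            raise ValueError("compartments and sinks must be disjoint")
        for o, d in self.edges:
            if o not in self.compartments:
                raise ValueError(f"edge origin {o!r} is not a compartment")
            if d not in nodes:
                raise ValueError(f"edge destination {d!r} is not a known node")
        if self.dose_compartment not in self.compartments:
            raise ValueError("dose compartment missing from structure")
        if self.plasma_compartment not in self.compartments:
            raise ValueError("plasma compartment missing from structure")
        if self.urine_sink not in self.sinks:
            raise ValueError("urine sink missing from structure")
        # every compartment needs an exit; sinks must not have one
        origins = {o for o, _ in self.edges}
        for c in self.compartments:
            if c not in origins:
                raise ValueError(f"compartment {c!r} has no outgoing edge")
        # connectivity from the dosing site
        if self.reachable_from(self.dose_compartment) != nodes:
            unreachable = nodes - self.reachable_from(self.dose_compartment)
            raise ValueError(f"nodes unreachable from dose site: {sorted(unreachable)}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.compartments + self.sinks

    def reachable_from(self, start: str) -> set[str]:
        seen = {start}
        frontier = [start]
        succ: dict[str, list[str]] = {}
        for o, d in self.edges:
            succ.setdefault(o, []).append(d)
        while frontier:
            n = frontier.pop()
            for d in succ.get(n, ()):
                if d not in seen:
                    seen.add(d)
                    frontier.append(d)
        return seen

    def index(self, node: str) -> int:
        return self.nodes.index(node)


@dataclass(frozen=True)
class Linked:
    """Parameter tied to an anchor edge: value = multiplier × value(anchor)."""

    anchor: Edge
    multiplier: float


Status = str | Linked  # "fixed" | "adjustable" | Linked


@dataclass
class ParameterSet:
    """Fractional transfer coefficients L(I, J) with fit status and bounds.

    ``values`` maps (origin, destination) edges to coefficients in h⁻¹.
    Linked edges always satisfy value = multiplier × value(anchor); call
    :meth:`resolve` after mutating an anchor.
    """

    values: dict[Edge, float]
    status: dict[Edge, Status] = field(default_factory=dict)
    bounds: dict[Edge, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative coefficient on edge {e}: {v}")
        self.values = dict(self.values)
        for e in self.values:
            self.status.setdefault(e, "adjustable")
        self._apply_links()

    def _apply_links(self) -> None:
        for e, st in self.status.items():
            if isinstance(st, Linked):
                self.values[e] = st.multiplier * self.values[st.anchor]

    def resolve(self) -> "ParameterSet":
        """Return a copy with all linked values recomputed from their anchors."""
        out = ParameterSet(dict(self.values), dict(self.status), dict(self.bounds))
        out._apply_links()
        return out

    @property
    def adjustable_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.values if self.status.get(e) == "adjustable")

    def with_values(self, updates: Mapping[Edge, float]) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        out = ParameterSet(vals, dict(self.status), dict(self.bounds))
        return out

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.status), dict(self.bounds))


@dataclass(frozen=True)
class DoseRecord:
    """One catechin's dose and the structural attributes used as factors."""

    catechin: str
    mass_mg: float
    gallated: bool
    b_ring_hydroxyls: int

    def __post_init__(self) -> None:
        if self.mass_mg <= 0:
            raise ValueError("dose mass must be positive")
        if self.b_ring_hydroxyls not in (2, 3):
            raise ValueError("B-ring hydroxyl count must be 2 or 3")


#: The study's green-tea-extract dose: 445 mg total catechins per serving.
DOSES: dict[str, DoseRecord] = {
    "EGCG": DoseRecord("EGCG", 290.0, gallated=True, b_ring_hydroxyls=3),
    "EGC": DoseRecord("EGC", 87.0, gallated=False, b_ring_hydroxyls=3),
    "EC": DoseRecord("EC", 39.0, gallated=False, b_ring_hydroxyls=2),
    "ECG": DoseRecord("ECG", 28.0, gallated=True, b_ring_hydroxyls=2),
}

CATECHINS: tuple[str, ...] = ("EGCG", "EGC", "EC", "ECG")

#: Blood collection schedule (h post-ingestion).
PLASMA_TIMES: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 10.0, 12.0)
#: Ends of the timed urine pools (0–4, 4–8, 8–12, 12–24 h).
URINE_INTERVAL_ENDS: tuple[float, ...] = (4.0, 8.0, 12.0, 24.0)


@dataclass
class TrajectorySet:
    """Fraction-of-dose time courses for every compartment and sink."""

    times: np.ndarray  # (T,)
    labels: tuple[str, ...]  # compartments then sinks
    states: np.ndarray  # (T, n_nodes)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (time_h, compartment)."""
        recs = [
            (t, lab, self.states[i, j])
            for i, t in enumerate(self.times)
            for j, lab in enumerate(self.labels)
        ]
        return pd.DataFrame(recs, columns=["time_h", "compartment", "fraction_of_dose"])


# -- structure builders ------------------------------------------------------


def build_final_structure() -> ModelStructure:
    """The accepted 7-compartment topology (plus feces/urine/extravascular-loss sinks)."""
    return ModelStructure(FINAL_COMPARTMENTS, FINAL_SINKS, FINAL_EDGES)


def build_variant_structure(variant: str) -> ModelStructure:
    """Structural alternatives evaluated during model development.

    ``no_extravascular`` is the 6-compartment starting model; the other
    variants add a portal-vein pool on the absorption route, a biliary
    excretion edge, or enterohepatic recirculation to the final model.
    """
    base = build_final_structure()
    if variant == "no_extravascular":
        comps = tuple(c for c in base.compartments if c != "extravascular")
        sinks = tuple(s for s in base.sinks if s != "extravascular_loss")
        # plasma must still drain somewhere besides kidneys? it keeps kidneys only
        edges = tuple(
            e for e in base.edges if "extravascular" not in e and "extravascular_loss" not in e
        )
        return replace(base, compartments=comps, sinks=sinks, edges=edges)
    if variant == "portal_vein":
        comps = base.compartments + ("portal_vein",)
        edges = tuple(e for e in base.edges if e != ("small_intestine", "liver"))
        edges += (("small_intestine", "portal_vein"), ("portal_vein", "liver"))
        return replace(base, compartments=comps, edges=edges)
    if variant == "biliary_excretion":
        return replace(base, edges=base.edges + (("liver", "large_intestine"),))
    if variant == "enterohepatic":
        return replace(base, edges=base.edges + (("liver", "small_intestine"),))
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


# -- rate matrix and simulation ---------------------------------------------


def rate_matrix_array(structure: ModelStructure, params: ParameterSet) -> np.ndarray:
    """Generator matrix M over compartments ∪ sinks (columns are donors).

    M[i, j] = L(i, j) for i ≠ j; M[j, j] = −Σᵢ L(i, j).  Sink columns are
    zero (nothing leaves a sink), so every column sums to zero and total
    mass is conserved.
    """
    params = params.resolve()
    nodes = structure.nodes
    n = len(nodes)
    idx = {lab: k for k, lab in enumerate(nodes)}
    M = np.zeros((n, n))
    for e in structure.edges:
        if e not in params.values:
            raise KeyError(f"missing coefficient for edge {e}")
        k = params.values[e]
        if k < 0:
            raise ValueError(f"negative coefficient on edge {e}")
        o, d = e
        M[idx[d], idx[o]] += k
        M[idx[o], idx[o]] -= k
    return M


def rate_matrix(structure: ModelStructure, params: ParameterSet) -> pd.DataFrame:
    """Labelled generator matrix (rows = recipients, columns = donors)."""
    M = rate_matrix_array(structure, params)
    return pd.DataFrame(M, index=structure.nodes, columns=structure.nodes)


def compartment_matrix(structure: ModelStructure, params: ParameterSet) -> np.ndarray:
    """Compartment-only submatrix A of the generator (sinks removed)."""
    M = rate_matrix_array(structure, params)
    nc = len(structure.compartments)
    return M[:nc, :nc]


def _propagate_expm(M: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Solve x(t) = e^{Mt} x0 by stepping expm over the time increments.

    Sequential propagation keeps each Padé evaluation cheap (small M·Δt)
    and is smooth in the matrix entries, which matters for the
    finite-difference Jacobians used in fitting.  Equal consecutive
    times reuse the propagator.
    """
    X = np.empty((len(times), len(x0)))
    x = x0.copy()
    prev_t = 0.0
    prev_dt = None
    P = None
    for i, t in enumerate(times):
        dt = t - prev_t
        if dt > 0:
            if prev_dt is None or abs(dt - prev_dt) > 1e-15:
                P = scipy.linalg.expm(M * dt)
                prev_dt = dt
            x = P @ x
        X[i] = x
        prev_t = t
    return X


def simulate(
    structure: ModelStructure,
    params: ParameterSet,
    times: Iterable[float],
    backend: str = "expm",
) -> TrajectorySet:
    """Forward-simulate a unit bolus into the dose compartment at t = 0.

    ``backend='expm'`` solves the constant-coefficient linear system
    exactly by matrix exponentiation stepped over the time grid;
    ``backend='ode'`` integrates with a high-order Runge–Kutta method
    (DOP853) at tight tolerances and exists as an independent numerical
    cross-check of the default solver.
    """
    t = np.asarray(list(times), dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    if t[0] < 0:
        raise ValueError("times must be non-negative")

    M = rate_matrix_array(structure, params)
    x0 = np.zeros(len(structure.nodes))
    x0[structure.index(structure.dose_compartment)] = 1.0

    if backend == "expm":
        X = _propagate_expm(M, x0, t)
    elif backend == "ode":
        sol = solve_ivp(
            lambda _t, x: M @ x,
            (0.0, max(float(t[-1]), 1e-12)),
            x0,
            t_eval=t,
            method="DOP853",
            rtol=1e-13,
            atol=1e-18,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        X = sol.y.T
    else:
        raise ValueError(f"unknown backend {backend!r}")

    return TrajectorySet(times=t, labels=structure.nodes, states=X)


def observe(
    traj: TrajectorySet,
    structure: ModelStructure,
    plasma_times: Iterable[float],
    urine_interval_ends: Iterable[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the two sampled observables from a simulated trajectory.

    Plasma is sampled instantaneously (fraction of dose in the plasma
    pool); urine is a cumulative sink read at the end of each timed
    collection interval.  Requested times must lie on the simulation
    grid — no interpolation or extrapolation is performed.
    """

    def pick(ts: Iterable[float]) -> np.ndarray:
        out = []
        for ti in ts:
            hits = np.nonzero(np.isclose(traj.times, ti, rtol=0.0, atol=1e-9))[0]
            if len(hits) == 0:
                raise ValueError(f"time {ti} h is not on the simulation grid")
            out.append(hits[0])
        return np.asarray(out, dtype=int)

    plasma = traj[structure.plasma_compartment][pick(plasma_times)]
    urine = traj[structure.urine_sink][pick(urine_interval_ends)]
    return plasma, urine
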