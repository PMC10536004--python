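"""Raw-table conversion, tidy CSV serialization, and run configuration.

Raw inputs are plasma concentrations (with subject height/weight to
estimate plasma volume) and urine concentrations with interval volumes;
both convert to the model's dimensionless fraction-of-dose observable.

Tidy CSV dialect (comma-separated, UTF-8, mandatory header, times in
decimal hours):

    subject_id, catechin, observable, time_h, fraction_of_dose

with ``observable`` ∈ {plasma, urine_cum}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import DoseRecord
from .fitting import ObservationSeries

OBSERVABLES = ("plasma", "urine_cum")


@dataclass(frozen=True)
class SubjectBiometrics:
    subject_id: str
    height_m: float
    weight_kg: float
    sex: str = "M"

    def __post_init__(self) -> None:
        if self.height_m <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")


def total_blood_volume_l(b: SubjectBiometrics) -> float:
    """Nadler's height/weight formula for total blood volume (litres)."""
    h, w = b.height_m, b.weight_kg
    if b.sex.upper().startswith("F"):
        return 0.3561 * h**3 + 0.03308 * w + 0.1833
    return 0.3669 * h**3 + 0.03219 * w + 0.6041


def plasma_volume_l(b: SubjectBiometrics, hematocrit: float = 0.45) -> float:
    """Plasma volume = total blood volume × (1 − hematocrit)."""
    if not 0 < hematocrit < 1:
        raise ValueError("hematocrit must be in (0, 1)")
    return total_blood_volume_l(b) * (1.0 - hematocrit)


def to_fraction_of_dose(
    plasma_conc_mg_per_l: np.ndarray | float,
    biometrics: SubjectBiometrics,
    dose: DoseRecord,
    hematocrit: float = 0.45,
) -> np.ndarray:
    """Plasma fraction of dose = concentration × plasma volume / dose mass."""
    if biometrics is None:
        raise ValueError("subject biometrics are required")
    conc = np.asarray(plasma_conc_mg_per_l, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    return conc * plasma_volume_l(biometrics, hematocrit) / dose.mass_mg


def urine_fraction_of_dose(
    urine_conc_mg_per_l: np.ndarray,
    interval_volumes_l: np.ndarray,
    interval_ends_h: np.ndarray,
    dose: DoseRecord,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative urinary fraction of dose at each interval end.

    Per-interval excreted mass = concentration × collected volume; the
    cumulative sum over time-ordered intervals is divided by the dose.
    Input rows may arrive in any order; output is time-sorted (and hence
    monotone by construction).
    """
    conc = np.asarray(urine_conc_mg_per_l, dtype=float)
    vol = np.asarray(interval_volumes_l, dtype=float)
    ends = np.asarray(interval_ends_h, dtype=float)
    if np.any(vol < 0):
        raise ValueError("urine volumes must be non-negative")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    order = np.argsort(ends)
    cum = np.cumsum(conc[order] * vol[order]) / dose.mass_mg
    return ends[order], cum


# -- tidy CSV ----------------------------------------------------------------


def series_to_frame(series_list: list[ObservationSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for t, v in zip(s.plasma_times, s.plasma_fod):
            rows.append((s.subject_id, s.catechin, "plasma", t, v))
        for t, v in zip(s.urine_interval_ends, s.urine_cum_fod):
            rows.append((s.subject_id, s.catechin, "urine_cum", t, v))
    return pd.DataFrame(
        rows, columns=["subject_id", "catechin", "observable", "time_h", "fraction_of_dose"]
    )


def frame_to_series(df: pd.DataFrame) -> list[ObservationSeries]:
    required = {"subject_id", "catechin", "observable", "time_h", "fraction_of_dose"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = set(df["observable"].unique()) - set(OBSERVABLES)
    if bad:
        raise ValueError(f"unknown observables: {sorted(bad)}")
    out = []
    for (subject, cat), g in df.groupby(["subject_id", "catechin"], sort=True):
        p = g[g.observable == "plasma"].sort_values("time_h")
        u = g[g.observable == "urine_cum"].sort_values("time_h")
        out.append(
            ObservationSeries(
                subject_id=str(subject),
                catechin=str(cat),
                plasma_times=p.time_h.to_numpy(),
                plasma_fod=p.fraction_of_dose.to_numpy(),
                urine_interval_ends=u.time_h.to_numpy(),
                urine_cum_fod=u.fraction_of_dose.to_numpy(),
            )
        )
    return out


def write_series_csv(series_list: list[ObservationSeries], path: str | Path) -> None:
    series_to_frame(series_list).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> list[ObservationSeries]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return frame_to_series(pd.read_csv(path))


# -- declarative model configuration ----------------------------------------
#
# Schema (YAML/JSON):
#   structure:
#     compartments: [name, ...]
#     sinks: [name, ...]
#     edges: ["origin->destination", ...]
#     dose_compartment / plasma_compartment / urine_sink: name
#   parameters:
#     "origin->destination":
#       value: <h^-1>
#       status: fixed | adjustable | {linked: "origin->dest", multiplier: x}
#       bounds: [lo, hi]          # adjustable edges only


def _edge(key: str) -> tuple[str, str]:
    o, _, d = key.partition("->")
    if not d:
        raise ValueError(f"edge key {key!r} must look like 'origin->destination'")
    return (o, d)


def structure_to_dict(structure) -> dict:
    return {
        "compartments": list(structure.compartments),
        "sinks": list(structure.sinks),
        "edges": [f"{o}->{d}" for o, d in structure.edges],
        "dose_compartment": structure.dose_compartment,
        "plasma_compartment": structure.plasma_compartment,
        "urine_sink": structure.urine_sink,
    }


def structure_from_dict(d: dict):
    from .model import ModelStructure

    return ModelStructure(
        compartments=tuple(d["compartments"]),
        sinks=tuple(d["sinks"]),
        edges=tuple(_edge(e) for e in d["edges"]),
        dose_compartment=d.get("dose_compartment", "upper_GI"),
        plasma_compartment=d.get("plasma_compartment", "plasma"),
        urine_sink=d.get("urine_sink", "urine"),
    )


def params_to_dict(params) -> dict:
    from .model import Linked

    out = {}
    for e, v in params.values.items():
        st = params.status.get(e, "adjustable")
        rec: dict = {"value": float(v)}
        if isinstance(st, Linked):
            rec["status"] = {"linked": f"{st.anchor[0]}->{st.anchor[1]}",
                             "multiplier": st.multiplier}
        else:
            rec["status"] = st
        if e in params.bounds:
            rec["bounds"] = [float(b) for b in params.bounds[e]]
        out[f"{e[0]}->{e[1]}"] = rec
    return out


def params_from_dict(d: dict):
    from .model import Linked, ParameterSet

    values, status, bounds = {}, {}, {}
    for key, rec in d.items():
        e = _edge(key)
        values[e] = float(rec["value"])
        st = rec.get("status", "adjustable")
        if isinstance(st, dict):
            status[e] = Linked(_edge(st["linked"]), float(st["multiplier"]))
        elif st in ("fixed", "adjustable"):
            status[e] = st
        else:
            raise ValueError(f"unknown status {st!r} for edge {key}")
        if "bounds" in rec:
            bounds[e] = (float(rec["bounds"][0]), float(rec["bounds"][1]))
    return ParameterSet(values, status, bounds)


# -- run configuration -------------------------------------------------------


@dataclass
class RunConfig:
    """Settings for the end-to-end pipeline; defaults mirror the study criteria."""

    structure: str = "final"  # "final" or a variant name
    n_subjects: int = 19
    seed: int = 1
    inter_subject_cv: float = 0.30
    measurement_cv: float = 0.20
    weight_cv: float = 0.2
    ssr_threshold: float = 1e-5
    fsd_threshold: float = 0.5
    corr_threshold: float = 0.8
    input_csv: str | None = None  # load instead of generate when set
    output_dir: str = "teacat_run"
    init_overrides: dict = field(default_factory=dict)  # "origin->dest" -> h^-1

    def __post_init__(self) -> None:
        for name in ("ssr_threshold", "fsd_threshold", "corr_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.inter_subject_cv < 0 or self.measurement_cv < 0 or self.weight_cv <= 0:
            raise ValueError("invalid coefficient of variation")


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
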