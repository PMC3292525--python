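"""Incubation experiment descriptions.

An :class:`ExperimentSpec` states what went into the dish: initial medium
concentrations, which substrate carries the tracer and at what enrichment,
and how long the cells were incubated.  The three hepatocyte incubation
conditions are provided as builders:

* :func:`condition_a` — 20 mM glucose, 50% [1,2-13C2]glucose;
* :func:`condition_b` — 20 mM glucose (50% [1,2-13C2]) + 9 mM lactate;
* :func:`condition_c` — 20 mM glucose + 9 mM lactate (50% [U-13C3]).

Conditions b/c in the dish also contained 1 mM pyruvate (lactate/pyruvate
9:1); the model carries no separate medium-pyruvate pool, so only the 9 mM
lactate is represented (see the methods note).

Tracer isotopomers use the bitmask convention of :mod:`labeldyn.network`:
bit i-1 set means carbon i is 13C, so [1,2-13C2]glucose is isotopomer
``0b000011 = 3`` and [U-13C3]lactate is ``0b111 = 7``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "TracerSpec",
    "ExperimentSpec",
    "condition_a",
    "condition_b",
    "condition_c",
    "load_experiment",
    "save_experiment",
]


@dataclass(frozen=True)
class TracerSpec:
    """One tracer species: ``fraction`` of pool molecules start as
    ``isotopomer`` (bitmask), the remainder unlabeled."""

    pool: str
    isotopomer: int
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("tracer fraction must be in [0, 1]")
        if self.isotopomer < 0:
            raise ValueError("isotopomer bitmask must be >= 0")


@dataclass(frozen=True)
class ExperimentSpec:
    id: str
    duration: float = 120.0
    medium: dict[str, float] = field(default_factory=dict)
    tracers: tuple[TracerSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        total = {}
        for tr in self.tracers:
            total[tr.pool] = total.get(tr.pool, 0.0) + tr.fraction
        for pool, f in total.items():
            if f > 1.0 + 1e-12:
                raise ValueError(f"tracer fractions for {pool} exceed 1")


GLC_12_13C2 = 0b000011  # [1,2-13C2]glucose
LAC_U_13C3 = 0b111  # [U-13C3]lactate


def condition_a(enrichment: float = 0.5) -> ExperimentSpec:
    return ExperimentSpec(
        id="glucose_only",
        duration=120.0,
        medium={"glc_med": 20.0, "lac_med": 0.0},
        tracers=(TracerSpec("glc_med", GLC_12_13C2, enrichment),),
    )


def condition_b(enrichment: float = 0.5) -> ExperimentSpec:
    return ExperimentSpec(
        id="glucose_lactate_labelglc",
        duration=120.0,
        medium={"glc_med": 20.0, "lac_med": 9.0},
        tracers=(TracerSpec("glc_med", GLC_12_13C2, enrichment),),
    )


def condition_c(enrichment: float = 0.5) -> ExperimentSpec:
    return ExperimentSpec(
        id="glucose_lactate_labellac",
        duration=120.0,
        medium={"glc_med": 20.0, "lac_med": 9.0},
        tracers=(TracerSpec("lac_med", LAC_U_13C3, enrichment),),
    )


def save_experiment(exp: ExperimentSpec, path: str | Path) -> None:
    obj = {
        "id": exp.id,
        "duration": exp.duration,
        "medium": exp.medium,
        "tracers": [
            {"pool": t.pool, "isotopomer": t.isotopomer, "fraction": t.fraction}
            for t in exp.tracers
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def load_experiment(path: str | Path) -> ExperimentSpec:
    obj = json.loads(Path(path).read_text())
    return ExperimentSpec(
        id=obj["id"],
        duration=obj.get("duration", 120.0),
        medium=dict(obj.get("medium", {})),
        tracers=tuple(
            TracerSpec(t["pool"], t["isotopomer"], t["fraction"])
            for t in obj.get("tracers", [])
        ),
    )
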