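"""Access to the packaged hepatocyte measurement fixtures."""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .measurement import MeasurementTable

__all__ = [
    "glucose_only_measurements",
    "glucose_lactate_measurements",
    "printed_fit_glucose_only",
]


def _read(name: str) -> str:
    return resources.files("labeldyn.data").joinpath(name).read_text()


def glucose_only_measurements() -> MeasurementTable:
    """The 2-h 50% [1,2-13C2]glucose incubation (28 quantitative rows:
    22 whole-molecule/concentration points + 6 glycogen-fragment points)."""
    df = pd.read_csv(io.StringIO(_read("hepatocyte_glucose_only.csv")), comment="#")
    return MeasurementTable(df, experiment="glucose_only")


def glucose_lactate_measurements() -> MeasurementTable:
    """The paired glucose+lactate incubations (label in glucose / in lactate)."""
    df = pd.read_csv(io.StringIO(_read("hepatocyte_glucose_lactate.csv")), comment="#")
    return MeasurementTable(df)


def printed_fit_glucose_only() -> pd.DataFrame:
    """Measured rows plus the published best-fit simulated columns
    (``channeling`` = two hexose-phosphate pools, ``mixed`` = one pool)."""
    return pd.read_csv(io.StringIO(_read("printed_fit_glucose_only.csv")), comment="#")
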