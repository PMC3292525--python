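"""Measurement tables, natural-abundance correction and the χ² objective.

Measured mass-isotopologue fractions and total concentrations live in a
small CSV dialect with columns ``experiment, metabolite, fragment, quantity,
mean, sd, units`` where ``quantity`` is ``m0``..``m6`` (molar fraction) or
``conc`` and ``fragment`` is a carbon range such as ``C1-C6`` or ``C2-C5``.
Lines starting with ``#`` are comments; the packaged fixtures use them to
document row counts and known typographical corrections.

χ² is the sum over data points of squared (measured − simulated) deviations
normalized by the measurement standard deviation, grouped per metabolite
fragment exactly as the tables group their rows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementTable",
    "ChiSquareReport",
    "chi_square",
    "correct_natural_abundance",
    "add_natural_abundance",
    "load_measurements",
    "write_measurements",
    "P13C_NATURAL",
]

#: standard terrestrial 13C abundance
P13C_NATURAL = 0.0107

_COLUMNS = ["experiment", "metabolite", "fragment", "quantity", "mean", "sd", "units"]


@dataclass
class MeasurementTable:
    """Rows of measured quantities with standard deviations.

    ``data`` is a DataFrame with the dialect columns; a table may span
    several experiments (use :meth:`for_experiment` to slice one out).
    """

    data: pd.DataFrame
    experiment: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement table missing columns {missing}")
        bad_sd = self.data[self.data["sd"] <= 0]
        if len(bad_sd):
            raise ValueError(
                "rows with sd <= 0 cannot enter chi-square: "
                + ", ".join(
                    f"{r.metabolite}/{r.fragment}/{r.quantity}"
                    for r in bad_sd.itertuples()
                )
            )
        frac = self.data[self.data["quantity"].str.startswith("m")]
        if ((frac["mean"] < 0) | (frac["mean"] > 1)).any():
            raise ValueError("isotopologue fraction means must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_points(self) -> int:
        return len(self.data)

    def experiments(self) -> list[str]:
        return list(self.data["experiment"].unique())

    def for_experiment(self, experiment: str) -> "MeasurementTable":
        sub = self.data[self.data["experiment"] == experiment].reset_index(drop=True)
        if not len(sub):
            raise KeyError(f"no rows for experiment {experiment!r}")
        return MeasurementTable(sub, experiment=experiment)

    def keys(self) -> list[tuple[str, str, str]]:
        return [
            (r.metabolite, r.fragment, r.quantity) for r in self.data.itertuples()
        ]


@dataclass
class ChiSquareReport:
    """χ² grouped by (metabolite, fragment), as the study tables group rows."""

    groups: dict[tuple[str, str], float]
    total: float
    n: int
    per_point: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def group(self, metabolite: str, fragment: str) -> float:
        return self.groups[(metabolite, fragment)]


def chi_square(
    simulated: dict[tuple[str, str, str], float],
    table: MeasurementTable,
) -> ChiSquareReport:
    """χ² = Σ_i [(y_i − y_sim,i)/σ_i]² over every row of ``table``.

    Every row must have a matching simulated observable; unmatched rows raise
    with the offending keys listed.
    """
    missing = [k for k in table.keys() if k not in simulated]
    if missing:
        raise KeyError(f"no simulated observable for measurement rows: {missing}")
    groups: dict[tuple[str, str], float] = {}
    per_point: dict[tuple[str, str, str], float] = {}
    total = 0.0
    for r in table.data.itertuples():
        key = (r.metabolite, r.fragment, r.quantity)
        z = (r.mean - simulated[key]) / r.sd
        contrib = float(z * z)
        per_point[key] = contrib
        groups[(r.metabolite, r.fragment)] = (
            groups.get((r.metabolite, r.fragment), 0.0) + contrib
        )
        total += contrib
    return ChiSquareReport(groups=groups, total=total, n=len(table.data),
                           per_point=per_point)


# ---------------------------------------------------------------------------
# natural abundance


def _convolution_matrix(n_carbons: int, p13c: float) -> np.ndarray:
    """M[j, k] = C(n−k, j−k)·p^(j−k)·(1−p)^(n−j): raw_j = Σ_k M[j,k]·true_k.

    Each of the n−k unlabeled skeleton carbons of a true m_k species is 13C
    with probability p, shifting the observed mass upward binomially.
    """
    n = n_carbons
    M = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        for j in range(k, n + 1):
            M[j, k] = comb(n - k, j - k) * p13c ** (j - k) * (1 - p13c) ** (n - j)
    return M


def add_natural_abundance(
    fractions: np.ndarray, n_carbons: int, p13c: float = P13C_NATURAL
) -> np.ndarray:
    """Forward-convolve a tracer-only distribution with natural abundance."""
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != n_carbons + 1:
        raise ValueError("fractions must have length n_carbons + 1")
    return _convolution_matrix(n_carbons, p13c) @ fractions


def correct_natural_abundance(
    raw_fractions: np.ndarray, n_carbons: int, p13c: float = P13C_NATURAL
) -> np.ndarray:
    """Remove the natural-13C contribution from a measured distribution.

    Inverts the binomial skeleton-carbon convolution; small negative
    artifacts (< 1e-9) from measurement noise are clipped and the result
    renormalized to sum to 1.  Only skeleton carbons are corrected;
    derivatization atoms are assumed already removed upstream.
    """
    raw = np.asarray(raw_fractions, dtype=float)
    if len(raw) != n_carbons + 1:
        raise ValueError("raw_fractions must have length n_carbons + 1")
    if not (0.0 <= p13c < 0.5):
        raise ValueError("p13c must be in [0, 0.5)")
    if abs(raw.sum() - 1.0) > 1e-6:
        raise ValueError(f"raw fractions sum to {raw.sum()}, expected 1")
    M = _convolution_matrix(n_carbons, p13c)
    corrected = np.linalg.solve(M, raw)
    corrected = np.where(np.abs(corrected) < 1e-9, 0.0, corrected)
    corrected = np.clip(corrected, 0.0, None)
    total = corrected.sum()
    if total <= 0:
        raise ValueError("correction annihilated the distribution")
    return corrected / total


# ---------------------------------------------------------------------------
# I/O


def load_measurements(path: str | Path) -> MeasurementTable:
    """Read a measurement CSV; malformed rows are reported with line numbers."""
    path = Path(path)
    rows = []
    errors = []
    with path.open() as fh:
        lines = fh.readlines()
    header: list[str] | None = None
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        fields = next(iter(pd.read_csv(io.StringIO(text), header=None).itertuples(index=False)))
        if header is None:
            header = [str(f).strip() for f in fields]
            if header != _COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: header {header} != expected {_COLUMNS}"
                )
            continue
        if len(fields) != len(_COLUMNS):
            errors.append(f"{path}:{lineno}: expected {len(_COLUMNS)} fields")
            continue
        rec = dict(zip(_COLUMNS, fields))
        try:
            rec["mean"] = float(rec["mean"])
            rec["sd"] = float(rec["sd"])
        except (TypeError, ValueError):
            errors.append(f"{path}:{lineno}: mean/sd not numeric")
            continue
        rows.append(rec)
    if errors:
        raise ValueError("malformed measurement rows:\n" + "\n".join(errors))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return MeasurementTable(df)


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, columns=_COLUMNS)
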