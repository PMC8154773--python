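"""Reanalysis-precision statistics: RMS-SD and RMS-CV over replicate
analyses.

Each subject is analyzed r >= 2 times (by different operators or by one
operator repeatedly); the per-subject sample standard deviation (n-1
denominator) and coefficient of variation are pooled as root-mean-square
averages — the standard short-term precision-error convention for
quantitative imaging.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class PrecisionError(ValueError):
    pass


@dataclasses.dataclass
class ReplicateTable:
    """Replicate measurements per subject and parameter.

    ``values[param]`` is an (n_subjects, n_replicates) array; all parameters
    share the subject list and replicate count.
    """

    values: dict[str, np.ndarray]
    subjects: list[str] | None = None
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        shapes = {k: np.asarray(v, dtype=float).shape for k, v in self.values.items()}
        if not shapes:
            raise PrecisionError("no parameters")
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise PrecisionError(f"inconsistent replicate shapes: {shapes}")
        if len(first) != 2 or first[1] < 2:
            raise PrecisionError("need an (n_subjects, r>=2) array per parameter")
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        n = first[0]
        if self.subjects is None:
            self.subjects = [f"S{i+1}" for i in range(n)]
        if len(self.subjects) != n:
            raise PrecisionError("subject list length mismatch")
        if self.groups is not None and len(self.groups) != n:
            raise PrecisionError("group list length mismatch")

    @property
    def n_replicates(self) -> int:
        return next(iter(self.values.values())).shape[1]


def _as_array(table) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise PrecisionError("need an (n_subjects, r>=2) array of replicates")
    return x


def rms_sd(table: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Root-mean-square of per-subject replicate standard deviations, in
    units of the measured variable."""
    x = _as_array(table)
    sd = x.std(axis=1, ddof=1)
    return float(np.sqrt(np.mean(sd**2)))


def rms_cv(table: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Root-mean-square of per-subject coefficients of variation, percent."""
    x = _as_array(table)
    means = x.mean(axis=1)
    if np.any(means <= 0):
        raise PrecisionError("RMS-CV requires strictly positive subject means")
    cv = 100.0 * x.std(axis=1, ddof=1) / means
    return float(np.sqrt(np.mean(cv**2)))


def precision_report(
    table: ReplicateTable,
    groups: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Mean, RMS-SD and RMS-CV per parameter, overall ("All") and per group.

    Groups come either from ``table.groups`` or an explicit name->row-index
    mapping; empty groups are skipped with a warning row omitted.
    """
    import warnings

    if groups is None and table.groups is not None:
        groups = {
            g: [i for i, gi in enumerate(table.groups) if gi == g]
            for g in dict.fromkeys(table.groups)
        }
    rows = []
    strata: list[tuple[str, np.ndarray | None]] = [("All", None)]
    for name, idx in (groups or {}).items():
        idx = np.asarray(list(idx), dtype=int)
        if idx.size == 0:
            warnings.warn(f"empty group {name!r} omitted", UserWarning)
            continue
        strata.append((name, idx))
    for gname, idx in strata:
        for param, vals in table.values.items():
            sub = vals if idx is None else vals[idx]
            rows.append(
                {
                    "group": gname,
                    "parameter": param,
                    "mean": float(sub.mean()),
                    "rms_sd": rms_sd(sub),
                    "rms_cv_pct": rms_cv(sub),
                }
            )
    return pd.DataFrame(rows)
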