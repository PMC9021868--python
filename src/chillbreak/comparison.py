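"""Bland–Altman agreement analysis between break-estimation methods.

Two methods *agree* when at least 95 % of the per-cultivar differences fall
inside the limits of agreement, mean difference ± 1.96 · SD of the
differences (points exactly on a limit count as inside).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, NamedTuple, Sequence

import numpy as np

__all__ = ["AgreementReport", "bland_altman", "pairwise_agreement", "column_summary"]

#: standard-normal 97.5 % quantile used for the limits of agreement
LOA_MULTIPLIER = 1.96


@dataclass
class AgreementReport:
    """Pairwise Bland–Altman comparison of per-cultivar values."""

    method_pair: tuple[str, str]
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]
    inside_fraction: float
    agree: bool
    n: int


def bland_altman(
    values_a: Sequence[float],
    values_b: Sequence[float],
    labels: tuple[str, str] = ("A", "B"),
    agreement_level: float = 0.95,
) -> AgreementReport:
    """Bland–Altman difference analysis of paired per-cultivar values.

    Differences d_i = a_i − b_i; limits of agreement are
    mean(d) ± 1.96·SD(d) with the sample (n − 1) SD; the verdict is
    ``agree`` when the inclusive inside fraction reaches
    ``agreement_level``.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    lo = mean_diff - LOA_MULTIPLIER * sd_diff
    hi = mean_diff + LOA_MULTIPLIER * sd_diff
    inside = float(np.mean((d >= lo) & (d <= hi)))
    return AgreementReport(
        method_pair=labels,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa=(lo, hi),
        inside_fraction=inside,
        agree=inside >= agreement_level,
        n=len(a),
    )


def pairwise_agreement(
    values_by_method: Mapping[str, Sequence[float]],
    agreement_level: float = 0.95,
) -> list[AgreementReport]:
    """All unordered method-pair comparisons (6 pairs for 4 methods).

    Vectors must be aligned (same cultivar order in every method).
    """
    lengths = {m: len(v) for m, v in values_by_method.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"method vectors have unequal lengths: {lengths}")
    return [
        bland_altman(values_by_method[a], values_by_method[b], (a, b), agreement_level)
        for a, b in combinations(sorted(values_by_method), 2)
    ]


class ColumnSummary(NamedTuple):
    min: float
    max: float
    mean: float


def column_summary(values: Sequence[float]) -> ColumnSummary:
    """Exact min/max/mean of a per-cultivar column."""
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise ValueError("empty column")
    return ColumnSummary(float(v.min()), float(v.max()), float(v.mean()))
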