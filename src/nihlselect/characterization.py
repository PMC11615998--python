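"""Group summaries and hearing-loss growth slopes.

Summaries report median/IQR (linear-interpolation quartiles) per group;
growth slopes come from a zero-intercept least-squares line of pooled
(exposure time, threshold) points per group — pooled scatter fits, not
per-subject slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from nihlselect.synthetic_cohort import Cohort, Worker

__all__ = [
    "SlopeFit",
    "GroupSummary",
    "fit_zero_intercept_slope",
    "combined_pta",
    "summarize_group",
    "group_slopes",
]

#: Frequency combinations summarized alongside single frequencies.
DEFAULT_COMBINATIONS: tuple[tuple[float, ...], ...] = (
    (0.5, 1.0, 2.0),
    (4.0, 12.5),
)


@dataclass
class SlopeFit:
    freq_set: tuple[float, ...]
    group: str
    slope: float          # dB per year
    n: int

    def to_dict(self) -> dict:
        return {"freq_set": list(self.freq_set), "group": self.group,
                "slope": self.slope, "n": self.n}


@dataclass
class GroupSummary:
    group: str
    n: int
    sex_counts: dict[str, int]
    medians_iqr: dict[str, tuple[float, float, float]] = field(
        default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group": self.group, "n": self.n,
            "sex_counts": dict(self.sex_counts),
            "medians_iqr": {k: list(v) for k, v in self.medians_iqr.items()},
        }


def fit_zero_intercept_slope(pairs: Sequence[tuple[float, float]],
                             freq_set: Sequence[float] = (),
                             group: str = "") -> SlopeFit:
    """Least-squares line through the origin: slope = sum(t*h) / sum(t^2)."""
    if not pairs:
        raise ValueError("need at least one (time, threshold) pair")
    t = np.array([p[0] for p in pairs], dtype=float)
    h = np.array([p[1] for p in pairs], dtype=float)
    denom = float(np.sum(t * t))
    if denom == 0:
        raise ValueError("all exposure times are zero; slope undefined")
    slope = float(np.sum(t * h) / denom)
    return SlopeFit(tuple(freq_set), group, slope, len(pairs))


def combined_pta(worker: Worker, freq_set: Sequence[float],
                 ears: str = "bilateral") -> float:
    """Unweighted mean threshold over ``freq_set`` and the selected ear(s)."""
    for f in freq_set:
        if f not in worker.ht_left or f not in worker.ht_right:
            raise ValueError(f"frequency {f} missing from audiogram")
    return worker.pta(freq_set, ears)


def _med_iqr(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def summarize_group(cohort: Cohort, ids: Iterable[str], group: str = "",
                    combinations: Sequence[Sequence[float]] = DEFAULT_COMBINATIONS,
                    ears: str = "bilateral") -> GroupSummary:
    """Median/IQR of demographics, exposure and PTAs for a set of workers.

    PTAs cover every frequency on the grid plus the configured
    combinations.  Quartiles use linear interpolation.
    """
    ids = sorted(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    workers = [cohort.get(i) for i in ids]  # raises on unknown id

    med = {}
    med["age"] = _med_iqr(np.array([w.age for w in workers]))
    med["exposure_time"] = _med_iqr(
        np.array([w.exposure_time for w in workers]))
    med["cne"] = _med_iqr(np.array([w.cne for w in workers]))
    for f in cohort.frequencies:
        med[f"pta_{f:g}kHz"] = _med_iqr(
            np.array([w.pta((f,), ears) for w in workers]))
    for combo in combinations:
        key = "pta_" + "_".join(f"{f:g}" for f in combo) + "kHz"
        med[key] = _med_iqr(
            np.array([combined_pta(w, combo, ears) for w in workers]))

    sex_counts: dict[str, int] = {}
    for w in workers:
        sex_counts[w.sex] = sex_counts.get(w.sex, 0) + 1
    return GroupSummary(group, len(workers), sex_counts, med)


def group_slopes(cohort: Cohort, groups: dict[str, Iterable[str]],
                 freq_sets: Sequence[Sequence[float]] = ((4.0,), (12.5,),
                                                         (0.5, 1.0, 2.0),
                                                         (4.0, 12.5)),
                 ears: str = "bilateral") -> list[SlopeFit]:
    """Zero-intercept growth slope per group x frequency set."""
    fits = []
    for group in sorted(groups):
        workers = [cohort.get(i) for i in sorted(groups[group])]
        for fs in freq_sets:
            pairs = [(w.exposure_time, combined_pta(w, fs, ears))
                     for w in workers]
            fits.append(fit_zero_intercept_slope(pairs, tuple(fs), group))
    return fits
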