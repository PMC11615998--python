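"""Face-validity scoring of selection methods.

A credible susceptible group should be younger, shorter-exposed and
lower-dosed than its resistant counterpart while showing worse hearing.
Each method's groups are contrasted on those variables (rank-sum test for
continuous, Pearson chi-square for sex) and scored by how many contrasts
are significant in the expected direction.  Methods are then ranked by
that concordance count.

Two-sided tests throughout; no multiple-testing correction is applied, by
design.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata

from nihlselect.classical_selectors import SelectionResult
from nihlselect.synthetic_cohort import Cohort

__all__ = [
    "GroupComparison",
    "FaceValidityScore",
    "rank_sum_test",
    "chi_square_2x2",
    "assess_method",
    "rank_methods",
]

_EXACT_MAX_N = 8


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  ) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Returns ``(U, p)`` where ``U`` counts pairs with ``x > y`` (ties count
    one half).  Exact enumeration over all labelings is used when both
    samples have at most 8 observations and there are no ties; otherwise a
    normal approximation with tie correction is used (no continuity
    correction).  A zero-variance null (all values tied) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    has_ties = len(np.unique(combined)) < combined.size
    if nx <= _EXACT_MAX_N and ny <= _EXACT_MAX_N and not has_ties:
        # enumerate every split of the pooled sample into groups of size nx
        total = 0
        n_le = 0
        n_ge = 0
        for idx in itertools.combinations(range(nx + ny), nx):
            u_perm = float(ranks[list(idx)].sum() - nx * (nx + 1) / 2.0)
            total += 1
            if u_perm <= u:
                n_le += 1
            if u_perm >= u:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le / total, n_ge / total))
        return u, p

    n = nx + ny
    mean = nx * ny / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    z = (u - mean) / math.sqrt(var)
    return u, float(min(1.0, 2.0 * norm.sf(abs(z))))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table (no continuity correction).

    Table layout ``[[a, b], [c, d]]``; statistic is
    ``n (ad - bc)^2 / (r1 r2 c1 c2)`` with p from chi-square(1 df).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all margins must be positive")
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class GroupComparison:
    """One variable's SG-vs-RG contrast."""

    variable: str
    units: str
    sg_summary: dict
    rg_summary: dict
    statistic: float
    p_value: float
    expected_direction: str          # "sg_lower" | "sg_higher" | "none"
    concordant: Optional[bool]       # None when direction is "none" or
                                     # the comparison is indeterminate
    indeterminate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "variable", "units", "sg_summary", "rg_summary", "statistic",
            "p_value", "expected_direction", "concordant", "indeterminate")}


@dataclass
class FaceValidityScore:
    method_id: str
    n_expected: int
    n_concordant: int
    n_discordant_significant: int
    detail: list[GroupComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method_id": self.method_id,
            "n_expected": self.n_expected,
            "n_concordant": self.n_concordant,
            "n_discordant_significant": self.n_discordant_significant,
            "detail": [c.to_dict() for c in self.detail],
        }


def _median_iqr(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"n": int(values.size), "median": float(med),
            "q1": float(q1), "q3": float(q3)}


def assess_method(cohort: Cohort, selection: SelectionResult,
                  alpha: float = 0.05,
                  phenotype_freqs: Optional[Sequence[float]] = None,
                  ears: Optional[str] = None) -> FaceValidityScore:
    """Score one method's groups against the expected susceptibility
    pattern: SG younger, shorter-exposed, lower-CNE, higher-PTA.

    Sex is compared with the chi-square test but carries no expected
    direction.  A continuous comparison with fewer than two subjects in
    either group is marked indeterminate.
    """
    if not selection.sg_ids or not selection.rg_ids:
        raise ValueError("SG and RG must both be non-empty")
    if phenotype_freqs is None:
        phenotype_freqs = selection.metadata.get("phenotype_freqs",
                                                 [4.0, 12.5])
    if ears is None:
        ears = selection.metadata.get("ears", "bilateral")

    sg = [cohort.get(i) for i in sorted(selection.sg_ids)]
    rg = [cohort.get(i) for i in sorted(selection.rg_ids)]

    continuous = [
        ("age", "years", lambda w: w.age, "sg_lower"),
        ("exposure_time", "years", lambda w: w.exposure_time, "sg_lower"),
        ("cne", "dBA-years", lambda w: w.cne, "sg_lower"),
        (f"pta_{'_'.join(f'{f:g}' for f in phenotype_freqs)}kHz", "dB HL",
         lambda w: w.pta(phenotype_freqs, ears), "sg_higher"),
    ]
    detail: list[GroupComparison] = []
    n_conc = 0
    n_disc = 0
    for name, units, getter, direction in continuous:
        xs = np.array([getter(w) for w in sg])
        ys = np.array([getter(w) for w in rg])
        if xs.size < 2 or ys.size < 2:
            detail.append(GroupComparison(
                name, units, _median_iqr(xs), _median_iqr(ys),
                float("nan"), float("nan"), direction, None,
                indeterminate=True))
            continue
        stat, p = rank_sum_test(xs, ys)
        sg_med = float(np.median(xs))
        rg_med = float(np.median(ys))
        if direction == "sg_lower":
            right_way = sg_med < rg_med
        else:
            right_way = sg_med > rg_med
        significant = p < alpha
        conc = bool(significant and right_way)
        if conc:
            n_conc += 1
        elif significant and not right_way:
            n_disc += 1
        detail.append(GroupComparison(
            name, units, _median_iqr(xs), _median_iqr(ys), stat, p,
            direction, conc))

    sg_male = sum(1 for w in sg if w.sex == "male")
    rg_male = sum(1 for w in rg if w.sex == "male")
    try:
        stat, p = chi_square_2x2(sg_male, len(sg) - sg_male,
                                 rg_male, len(rg) - rg_male)
        indet = False
    except ValueError:
        stat, p, indet = float("nan"), float("nan"), True
    detail.append(GroupComparison(
        "sex", "proportion male",
        {"n": len(sg), "male": sg_male,
         "proportion_male": sg_male / len(sg)},
        {"n": len(rg), "male": rg_male,
         "proportion_male": rg_male / len(rg)},
        stat, p, "none", None, indeterminate=indet))

    return FaceValidityScore(selection.method_id, n_expected=4,
                             n_concordant=n_conc,
                             n_discordant_significant=n_disc,
                             detail=detail)


def rank_methods(scores: Sequence[FaceValidityScore],
                 ) -> list[FaceValidityScore]:
    """Order by concordance desc, then discordant-significant asc, then
    method id."""
    if not scores:
        raise ValueError("no scores to rank")
    return sorted(scores, key=lambda s: (-s.n_concordant,
                                         s.n_discordant_significant,
                                         s.method_id))
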