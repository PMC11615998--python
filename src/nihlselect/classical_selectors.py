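"""Non-ML extreme-group selectors (methods m1-m5).

Three families are implemented:

* stratified percentile selection (m1, m2): rank by a pure-tone average
  within covariate strata and take a fixed fraction from each tail;
* bidimensional cuts (m3): z-score two frequencies and cut the extremes of
  the diagonal projection;
* regression residuals (m4 linear, m5 quadratic): regress the bilateral
  pure-tone average on cumulative noise exposure and take residual tails.

Positive extremes (worse hearing than peers/prediction) form the
susceptible group (SG); negative extremes the resistant group (RG).  All
rankings break ties by worker id so results are invariant to input order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from nihlselect.synthetic_cohort import Cohort

__all__ = [
    "SelectionResult",
    "StratumSpec",
    "select_stratified_extremes",
    "select_bidimensional_extremes",
    "select_residual_extremes",
    "run_classical_method",
    "CLASSICAL_METHOD_CONFIGS",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """A method's susceptible/resistant membership with per-subject scores."""

    method_id: str
    sg_ids: set[str]
    rg_ids: set[str]
    score: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sg_ids & self.rg_ids:
            raise ValueError("SG and RG overlap")
        missing = (self.sg_ids | self.rg_ids) - set(self.score)
        if missing:
            raise ValueError(f"score missing for selected ids: "
                             f"{sorted(missing)[:5]}")

    def to_dict(self) -> dict:
        return {
            "method_id": self.method_id,
            "sg_ids": sorted(self.sg_ids),
            "rg_ids": sorted(self.rg_ids),
            "score": {k: self.score[k] for k in sorted(self.score)},
            "metadata": self.metadata,
        }


@dataclass(frozen=True)
class StratumSpec:
    """Two crossed axes; ``edges`` are interior cut points producing
    ``len(edges)+1`` left-closed bins per axis."""

    axis1: tuple[str, tuple[float, ...]]
    axis2: tuple[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for _, edges in (self.axis1, self.axis2):
            if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
                raise ValueError("bin edges must be strictly increasing")

    def assign(self, cohort: Cohort) -> list[tuple[int, int]]:
        out = []
        for w in cohort:
            b1 = int(np.searchsorted(self.axis1[1], getattr(w, self.axis1[0]),
                                     side="right"))
            b2 = int(np.searchsorted(self.axis2[1], getattr(w, self.axis2[0]),
                                     side="right"))
            out.append((b1, b2))
        return out


def _take_extremes(ids: Sequence[str], scores: Sequence[float],
                   k: int) -> tuple[set[str], set[str]]:
    """Top-k (SG) and bottom-k (RG) by (score, id); deterministic ties."""
    order = sorted(range(len(ids)), key=lambda i: (scores[i], ids[i]))
    rg = {ids[i] for i in order[:k]}
    sg = {ids[i] for i in order[len(order) - k:]}
    return sg, rg


def select_stratified_extremes(cohort: Cohort, strata: StratumSpec,
                               freqs: Sequence[float], ear: str,
                               fraction: float,
                               method_id: str = "stratified",
                               ) -> SelectionResult:
    """Percentile selection within covariate strata.

    Within each stratum, workers are ranked by the mean threshold over
    ``freqs`` for ``ear``; ``floor(fraction * n_stratum)`` workers go to
    each tail.  Strata with fewer than ``ceil(1/fraction)`` workers are
    skipped with a warning.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    bins = strata.assign(cohort)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, b in enumerate(bins):
        groups.setdefault(b, []).append(i)

    workers = cohort.workers
    scores = {w.id: w.pta(freqs, ear) for w in workers}
    sg: set[str] = set()
    rg: set[str] = set()
    min_n = math.ceil(1.0 / fraction)
    strata_used = {}
    for key in sorted(groups):
        idx = groups[key]
        if len(idx) < min_n:
            logger.warning("stratum %s has %d workers (< %d); skipped",
                           key, len(idx), min_n)
            strata_used[str(key)] = {"n": len(idx), "skipped": True}
            continue
        k = int(math.floor(fraction * len(idx)))
        g_ids = [workers[i].id for i in idx]
        g_sc = [scores[w] for w in g_ids]
        s_sg, s_rg = _take_extremes(g_ids, g_sc, k)
        sg |= s_sg
        rg |= s_rg
        strata_used[str(key)] = {"n": len(idx), "per_tail": k,
                                 "skipped": False}
    return SelectionResult(
        method_id, sg, rg, scores,
        metadata={"strata": strata_used, "fraction": fraction,
                  "phenotype_freqs": list(freqs), "ears": ear,
                  "axis1": [strata.axis1[0], list(strata.axis1[1])],
                  "axis2": [strata.axis2[0], list(strata.axis2[1])]})


def select_bidimensional_extremes(cohort: Cohort, fx: float, fy: float,
                                  fraction: float, ear: str = "left",
                                  method_id: str = "bidimensional",
                                  ) -> SelectionResult:
    """Cut the extremes of the diagonal projection of two z-scored axes.

    Each worker's thresholds at ``fx`` and ``fy`` are standardized over the
    cohort; the extremity score is ``(z_x + z_y) / 2``, i.e. the projection
    on the main diagonal — the unique symmetric linear combination.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    for f in (fx, fy):
        if f not in cohort.frequencies:
            raise ValueError(f"frequency {f} not on the cohort grid")
    ids = [w.id for w in cohort]
    x = np.array([w.pta((fx,), ear) for w in cohort])
    y = np.array([w.pta((fy,), ear) for w in cohort])
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on an axis; cannot standardize")
    score = ((x - x.mean()) / sx + (y - y.mean()) / sy) / 2.0
    k = int(math.floor(fraction * len(ids)))
    sg, rg = _take_extremes(ids, score.tolist(), k)
    return SelectionResult(
        method_id, sg, rg, dict(zip(ids, score.tolist())),
        metadata={"fx": fx, "fy": fy, "fraction": fraction,
                  "phenotype_freqs": [fx, fy], "ears": ear})


def select_residual_extremes(cohort: Cohort, freqs: Sequence[float] = (3.0, 4.0, 6.0),
                             model: str = "linear", fraction: float = 0.10,
                             ears: str = "bilateral",
                             method_id: Optional[str] = None,
                             ) -> SelectionResult:
    """Residual tails of a least-squares fit of bilateral PTA on CNE.

    ``model`` is ``"linear"`` (intercept + CNE) or ``"quadratic"``
    (+ CNE^2).  Residual = measured - predicted; the top residual fraction
    (hearing worse than the dose predicts) is the SG, the bottom the RG.
    """
    if model not in ("linear", "quadratic"):
        raise ValueError(f"unknown model {model!r}")
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if len(cohort) < 10:
        raise ValueError("need at least 10 workers for a residual fit")
    ids = [w.id for w in cohort]
    cne = np.array([w.cne for w in cohort])
    y = np.array([w.pta(freqs, ears) for w in cohort])
    degree = 1 if model == "linear" else 2
    if np.ptp(cne) == 0:
        raise ValueError("degenerate design: CNE is constant")
    X = np.vander(cne, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < degree + 1:
        raise ValueError("collinear design matrix in residual fit")
    pred = X @ coef
    resid = y - pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    k = int(math.floor(fraction * len(ids)))
    sg, rg = _take_extremes(ids, resid.tolist(), k)
    return SelectionResult(
        method_id or f"residual_{model}", sg, rg,
        dict(zip(ids, resid.tolist())),
        metadata={"model": model, "coefficients": coef.tolist(), "r2": r2,
                  "fraction": fraction, "phenotype_freqs": list(freqs),
                  "ears": ears})


#: Published configurations for methods m1-m5.
CLASSICAL_METHOD_CONFIGS: dict[str, dict] = {
    # 9 strata: exposure years {<15, 15-25, >25} x noise {<=85, 86-91, >=92}
    "m1": {"kind": "stratified",
           "strata": StratumSpec(("exposure_time", (15.0, 25.0)),
                                 ("leq_8h", (86.0, 92.0))),
           "freqs": (4.0, 6.0), "ear": "left", "fraction": 0.20},
    # 9 strata: age {<35, 35-50, >50} x noise {<85, 86-91, >92}
    "m2": {"kind": "stratified",
           "strata": StratumSpec(("age", (35.0, 50.0)),
                                 ("leq_8h", (86.0, 92.0))),
           "freqs": (3.0,), "ear": "left", "fraction": 0.10},
    "m3": {"kind": "bidimensional", "fx": 4.0, "fy": 6.0,
           "ear": "left", "fraction": 0.10},
    "m4": {"kind": "residual", "freqs": (3.0, 4.0, 6.0), "model": "linear",
           "fraction": 0.10},
    "m5": {"kind": "residual", "freqs": (3.0, 4.0, 6.0), "model": "quadratic",
           "fraction": 0.20},
}


def run_classical_method(cohort: Cohort, method_id: str) -> SelectionResult:
    """Run one of m1-m5 with its published configuration on an already
    method-filtered cohort."""
    try:
        cfg = dict(CLASSICAL_METHOD_CONFIGS[method_id])
    except KeyError:
        raise ValueError(f"unknown classical method {method_id!r}") from None
    kind = cfg.pop("kind")
    if kind == "stratified":
        return select_stratified_extremes(cohort, method_id=method_id, **cfg)
    if kind == "bidimensional":
        return select_bidimensional_extremes(cohort, method_id=method_id,
                                             **cfg)
    return select_residual_extremes(cohort, method_id=method_id, **cfg)
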