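"""Rank audiometric frequency sets by diagnostic-model performance.

For each candidate frequency set, the hearing outcome is binarized over
that set and the demographic/lifestyle classifiers are evaluated by
cross-validation; sets are then ranked by mean AUC.  The same seed (hence
fold construction) is shared across sets so ranking differences reflect
the label, not fold noise.

The thresholds define the *label*, never the features: feeding the set's
mean threshold back in as a predictor would make the task circular.  That
alternate reading is available behind ``ht_as_feature`` and is marked
experimental.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from nihlselect.ml_selector import (
    DiagnosticModelSpec,
    cross_validated_fit,
)
from nihlselect.synthetic_cohort import Cohort

__all__ = [
    "DEFAULT_FREQ_SETS",
    "FrequencyEvalResult",
    "evaluate_frequency_sets",
    "rank_frequency_sets",
]

#: Candidate sets evaluated by default (kHz).
DEFAULT_FREQ_SETS: tuple[tuple[float, ...], ...] = (
    (4.0,),
    (12.5,),
    (4.0, 12.5),
    (4.0, 6.0, 12.5),
    (4.0, 10.0, 12.5),
    (4.0, 6.0, 10.0, 12.5),
    (3.0, 4.0, 6.0, 10.0, 12.5),
)


@dataclass
class FrequencyEvalResult:
    """Pooled cross-validated metrics for one frequency set.

    Pooled means are unweighted over algorithms; pooled SDs are taken over
    all per-fold metrics of all algorithms.  ``failed`` marks sets whose
    label was degenerate (e.g. single-class).
    """

    freq_set: tuple[float, ...]
    mean_auc: float = float("nan")
    sd_auc: float = float("nan")
    mean_accuracy: float = float("nan")
    sd_accuracy: float = float("nan")
    per_algorithm: dict[str, dict[str, float]] = field(default_factory=dict)
    failed: bool = False
    failure_reason: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "freq_set": list(self.freq_set),
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "per_algorithm": self.per_algorithm,
            "failed": self.failed,
            "failure_reason": self.failure_reason,
        }


def evaluate_frequency_sets(cohort: Cohort,
                            freq_sets: Sequence[Sequence[float]] = DEFAULT_FREQ_SETS,
                            spec: Optional[DiagnosticModelSpec] = None,
                            ht_as_feature: bool = False,
                            ) -> list[FrequencyEvalResult]:
    """Evaluate each frequency set independently; results keep input order.

    A degenerate label for one set marks that set failed and leaves the
    others untouched.  ``ht_as_feature`` (experimental) appends the set's
    mean threshold to the classifier features — this makes the task partly
    circular (the label is a function of that feature) and is off by
    default.
    """
    if spec is None:
        spec = DiagnosticModelSpec()
    grid = set(cohort.frequencies)
    for fs in freq_sets:
        missing = set(float(f) for f in fs) - grid
        if missing:
            raise ValueError(f"frequencies {sorted(missing)} not on the grid")

    results: list[FrequencyEvalResult] = []
    for fs in freq_sets:
        fs = tuple(float(f) for f in fs)
        rule = replace(spec.label_rule, frequencies=fs)
        sub_spec = replace(spec, label_rule=rule)
        extra = None
        if ht_as_feature:
            extra = np.array([[w.pta(fs, rule.ears)] for w in cohort])
        try:
            ev = cross_validated_fit(cohort, sub_spec, extra_features=extra)
        except ValueError as exc:
            results.append(FrequencyEvalResult(fs, failed=True,
                                               failure_reason=str(exc)))
            continue
        fold_auc = np.concatenate(
            [ev.per_algorithm[a]["fold_auc"] for a in ev.algorithms])
        fold_acc = np.concatenate(
            [ev.per_algorithm[a]["fold_accuracy"] for a in ev.algorithms])
        per_alg = {a: {"accuracy": ev.per_algorithm[a]["mean_accuracy"],
                       "auc": ev.per_algorithm[a]["mean_auc"]}
                   for a in ev.algorithms}
        results.append(FrequencyEvalResult(
            fs,
            mean_auc=float(fold_auc.mean()),
            sd_auc=float(fold_auc.std(ddof=1)) if len(fold_auc) > 1 else 0.0,
            mean_accuracy=float(fold_acc.mean()),
            sd_accuracy=float(fold_acc.std(ddof=1)) if len(fold_acc) > 1 else 0.0,
            per_algorithm=per_alg,
        ))
    return results


def rank_frequency_sets(results: Sequence[FrequencyEvalResult],
                        ) -> list[FrequencyEvalResult]:
    """Order by mean AUC desc, then mean accuracy desc, then smaller set.

    Failed sets sort last (in input order)."""
    if not results:
        raise ValueError("no results to rank")
    indexed = list(enumerate(results))

    def key(item):
        i, r = item
        if r.failed:
            return (1, 0.0, 0.0, 0, i)
        return (0, -r.mean_auc, -r.mean_accuracy, len(r.freq_set), i)

    return [r for _, r in sorted(indexed, key=key)]
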