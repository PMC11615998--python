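"""Study-level and per-method inclusion/exclusion rules.

Rules run in declared order and the first matching rule claims the
removal, so report counts always reconcile:
``input_count == output_count + sum(removed_by_rule.values())``.

Two readings in the published criteria deserve a note.  The inter-aural
gap criterion is printed as an exclusion for a gap "<40 dB", which taken
literally would exclude nearly every worker; it is implemented reversed
(exclude if the gap is >= 40 dB, i.e. drop asymmetric losses).  History
criteria that cannot be verified from tabular data (meningitis, ototoxic
drugs, acoustic trauma, ...) are read from optional boolean flags that
default to "absent".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from nihlselect.synthetic_cohort import CONVENTIONAL_FREQS, Cohort, Worker

__all__ = [
    "FilterReport",
    "FilterRule",
    "apply_rules",
    "apply_study_exclusions",
    "apply_method_criteria",
    "study_rules",
    "method_rules",
    "METHOD_IDS",
]

METHOD_IDS = ("m1", "m2", "m3", "m4", "m5", "m6")

#: Pre-existing loss bound (dB HL) on the pre-employment audiogram.
PREEXISTING_LOSS_DB = 25.0

#: Inter-aural gap (dB) at/above which a worker is excluded (m1, m3).
EAR_GAP_DB = 40.0
_EAR_GAP_FREQS = (4.0, 6.0)


@dataclass
class FilterReport:
    input_count: int
    output_count: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    #: informational counts that do not remove anyone (e.g. workers
    #: retained despite a missing pre-employment audiogram)
    flagged: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_count != self.output_count + sum(
                self.removed_by_rule.values()):
            raise ValueError("filter report counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "output_count": self.output_count,
            "removed_by_rule": dict(self.removed_by_rule),
            "flagged": dict(self.flagged),
        }


@dataclass(frozen=True)
class FilterRule:
    """Named predicate; ``predicate(worker) is True`` removes the worker."""
    name: str
    predicate: Callable[[Worker], bool]


def _preexisting_loss(w: Worker) -> bool:
    if w.preemployment_ht is None:
        return False  # unscreenable: retained and flagged, never removed
    return any(w.preemployment_ht.get(f, float("-inf")) >= PREEXISTING_LOSS_DB
               for f in CONVENTIONAL_FREQS)


def _ear_gap(w: Worker) -> bool:
    return any(abs(w.ht_left[f] - w.ht_right[f]) >= EAR_GAP_DB
               for f in _EAR_GAP_FREQS)


def _flag(name: str) -> Callable[[Worker], bool]:
    return lambda w: bool(w.flags.get(name, False))


def study_rules() -> list[FilterRule]:
    """Cohort-wide exclusions applied before any selection method."""
    return [
        FilterRule("preexisting_loss_ge_25dB", _preexisting_loss),
        FilterRule("exposure_lt_1yr", lambda w: w.exposure_time < 1.0),
        FilterRule("otologic_disease", _flag("otologic_disease")),
        FilterRule("hereditary_deafness", _flag("hereditary_deafness")),
        FilterRule("abnormal_impedance", _flag("abnormal_impedance")),
        FilterRule("toxic_exposure", _flag("toxic_exposure")),
    ]


def method_rules(method_id: str) -> list[FilterRule]:
    """Method-specific rules (appended after the study-level rules)."""
    if method_id == "m1":
        return [
            FilterRule("history_meningitis", _flag("meningitis")),
            FilterRule("aminoglycoside_treatment", _flag("aminoglycoside")),
            FilterRule("acoustic_trauma", _flag("acoustic_trauma")),
            FilterRule("ear_gap_ge_40dB", _ear_gap),
            FilterRule("exposure_lt_5yr", lambda w: w.exposure_time < 5.0),
            FilterRule("female", lambda w: w.sex == "female"),
            FilterRule(
                "duration_over_age_cap",
                lambda w: w.exposure_time > 0.666 * w.age - 20.0),
        ]
    if method_id == "m2":
        return [
            FilterRule("head_injury", _flag("head_injury")),
            FilterRule("ototoxic_drugs", _flag("ototoxic_drugs")),
            FilterRule("prior_harmful_noise", _flag("prior_harmful_noise")),
            FilterRule("no_hearing_protection",
                       _flag("no_hearing_protection")),
        ]
    if method_id == "m3":
        return [
            FilterRule("middle_ear_disease", _flag("middle_ear_disease")),
            FilterRule("air_bone_gap", _flag("air_bone_gap")),
            FilterRule("ear_gap_ge_40dB", _ear_gap),
        ]
    if method_id == "m4":
        return [FilterRule("cne_le_80dBA", lambda w: w.cne <= 80.0)]
    if method_id == "m5":
        return [
            FilterRule("other_factory_noise", _flag("other_factory_noise")),
            FilterRule("exposure_le_1yr", lambda w: w.exposure_time <= 1.0),
        ]
    if method_id == "m6":
        return []
    raise ValueError(f"unknown method_id {method_id!r}; "
                     f"expected one of {METHOD_IDS}")


def apply_rules(cohort: Cohort,
                rules: Sequence[FilterRule]) -> tuple[Cohort, FilterReport]:
    """Apply ordered rules; the first matching rule claims each removal."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    removed: dict[str, int] = {}
    kept: list[Worker] = []
    unscreenable = 0
    for w in cohort:
        if w.preemployment_ht is None:
            unscreenable += 1
        for rule in rules:
            if rule.predicate(w):
                removed[rule.name] = removed.get(rule.name, 0) + 1
                break
        else:
            kept.append(w)
    out = Cohort(kept, list(cohort.frequencies), dict(cohort.provenance))
    flagged = {"unscreenable_no_preemployment": unscreenable} if unscreenable else {}
    report = FilterReport(len(cohort), len(out), removed, flagged)
    return out, report


def apply_study_exclusions(cohort: Cohort) -> tuple[Cohort, FilterReport]:
    """Remove workers with pre-existing loss (>=25 dB HL at 0.5-6 kHz on the
    pre-employment audiogram), under one year of exposure, or flagged
    histories.  Workers without a pre-employment audiogram are retained and
    counted under ``flagged``."""
    return apply_rules(cohort, study_rules())


def apply_method_criteria(cohort: Cohort,
                          method_id: str) -> tuple[Cohort, FilterReport]:
    """Study-level rules followed by ``method_id``'s own criteria; ``m6``
    adds nothing beyond the study-level screen."""
    rules = study_rules() + method_rules(method_id)
    return apply_rules(cohort, rules)
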