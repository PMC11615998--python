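"""Misclassification-based selection (method m6).

Risk-factor classifiers (AdaBoost, MLP, random forest, SVM) are trained to
predict a binarized hearing outcome from age, sex, cumulative noise
exposure, smoking and drinking.  Subjects misclassified by *all*
algorithms on out-of-fold predictions are the selection pool: hearing
worse than the risk factors predict marks susceptibility, better marks
resistance.  A second stage keeps the audiometric extremes of each group
and checks them against the correctly-classified controls (mean +/- k SD).

Out-of-fold predictions only: in-sample misclassification would conflate
model bias with subject extremity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from nihlselect.classical_selectors import SelectionResult
from nihlselect.synthetic_cohort import Cohort, Worker

__all__ = [
    "ALGORITHMS",
    "FEATURES",
    "LabelRule",
    "DiagnosticModelSpec",
    "ModelEvalResult",
    "build_classifier",
    "label_from_rule",
    "feature_matrix",
    "cross_validated_fit",
    "select_misclassified_extremes",
    "control_ids",
    "refine_by_sd",
]

ALGORITHMS = ("adaboost", "mlp", "random_forest", "svm")
FEATURES = ("age", "sex", "cne", "smoking", "drinking")
_CONTINUOUS = ("age", "cne")


@dataclass(frozen=True)
class LabelRule:
    """Binarization of the hearing outcome: case iff the mean threshold
    over ``frequencies`` for ``ears`` exceeds ``threshold`` (dB HL).

    The 25 dB HL default mirrors the normal-hearing bound used by the
    study-level screen.
    """

    frequencies: tuple[float, ...] = (4.0, 12.5)
    ears: str = "bilateral"
    threshold: float = 25.0

    def label(self, worker: Worker) -> int:
        return int(worker.pta(self.frequencies, self.ears) > self.threshold)


@dataclass(frozen=True)
class DiagnosticModelSpec:
    features: tuple[str, ...] = FEATURES
    label_rule: LabelRule = field(default_factory=LabelRule)
    algorithms: tuple[str, ...] = ALGORITHMS
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.algorithms:
            raise ValueError("algorithms must be non-empty")
        if not self.features:
            raise ValueError("features must be non-empty")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")
        unknown = set(self.features) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")


@dataclass
class ModelEvalResult:
    """Cross-validated metrics plus one out-of-fold prediction per subject.

    ``per_subject`` is indexed by worker id with columns ``true`` and, per
    algorithm, ``pred_<alg>`` (out-of-fold label), ``conf_<alg>``
    (confidence in the predicted class: a probability where the algorithm
    has one, otherwise a margin magnitude), and ``pos_<alg>``
    (positive-class score used for the AUC).
    """

    algorithms: tuple[str, ...]
    per_algorithm: dict[str, dict[str, float]]
    pooled: dict[str, float]
    per_subject: pd.DataFrame
    has_probability: dict[str, bool]
    spec: Optional[DiagnosticModelSpec] = None

    def to_dict(self) -> dict:
        return {
            "algorithms": list(self.algorithms),
            "per_algorithm": self.per_algorithm,
            "pooled": self.pooled,
            "has_probability": self.has_probability,
        }


def build_classifier(name: str, seed: int):
    """Fixed, documented hyperparameters; only the seed varies."""
    if name == "adaboost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed)
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=400,
                             random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, min_samples_leaf=5,
                                      random_state=seed, n_jobs=1)
    if name == "svm":
        # margin-based: scores come from decision_function, not probabilities
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    raise ValueError(f"unknown algorithm {name!r}")


def label_from_rule(cohort: Cohort, rule: LabelRule) -> np.ndarray:
    return np.array([rule.label(w) for w in cohort], dtype=int)


def feature_matrix(cohort: Cohort,
                   features: Sequence[str] = FEATURES) -> np.ndarray:
    """Encode features: sex/smoking/drinking as 0/1, age/cne as-is
    (standardization happens per training fold)."""
    cols = []
    for name in features:
        if name == "age":
            cols.append([w.age for w in cohort])
        elif name == "cne":
            cols.append([w.cne for w in cohort])
        elif name == "sex":
            cols.append([1.0 if w.sex == "male" else 0.0 for w in cohort])
        elif name == "smoking":
            cols.append([1.0 if w.smoking == "currently" else 0.0
                         for w in cohort])
        elif name == "drinking":
            cols.append([1.0 if w.drinking == "currently" else 0.0
                         for w in cohort])
        else:
            raise ValueError(f"unknown feature {name!r}")
    return np.column_stack(cols)


def _standardize(train: np.ndarray, test: np.ndarray,
                 cont_idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Scale continuous columns with training-fold statistics only."""
    train = train.copy()
    test = test.copy()
    for j in cont_idx:
        mu = train[:, j].mean()
        sd = train[:, j].std()
        if sd == 0:
            sd = 1.0
        train[:, j] = (train[:, j] - mu) / sd
        test[:, j] = (test[:, j] - mu) / sd
    return train, test


def cross_validated_fit(cohort: Cohort, spec: DiagnosticModelSpec,
                        extra_features: Optional[np.ndarray] = None,
                        ) -> ModelEvalResult:
    """Stratified k-fold evaluation; every subject is predicted exactly once
    out-of-fold by every algorithm.

    ``extra_features`` (n_workers x k), if given, are appended to the
    feature matrix and standardized per training fold like the continuous
    covariates.
    """
    ids = [w.id for w in cohort]
    X = feature_matrix(cohort, spec.features)
    n_base = X.shape[1]
    if extra_features is not None:
        extra = np.atleast_2d(np.asarray(extra_features, dtype=float))
        if extra.shape[0] != len(ids):
            extra = extra.T
        X = np.column_stack([X, extra])
    y = label_from_rule(cohort, spec.label_rule)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("label rule yields a single class")
    if counts.min() < spec.k_folds:
        raise ValueError(
            f"minority class has {counts.min()} members; needs >= k_folds "
            f"({spec.k_folds})")
    cont_idx = [i for i, f in enumerate(spec.features) if f in _CONTINUOUS]
    cont_idx += list(range(n_base, X.shape[1]))

    skf = StratifiedKFold(n_splits=spec.k_folds, shuffle=True,
                          random_state=spec.seed)
    folds = list(skf.split(X, y))

    n = len(ids)
    table: dict[str, np.ndarray] = {"true": y.astype(int)}
    per_algorithm: dict[str, dict[str, float]] = {}
    has_probability: dict[str, bool] = {}
    for alg in spec.algorithms:
        proto = build_classifier(alg, spec.seed)
        use_proba = hasattr(proto, "predict_proba")
        has_probability[alg] = use_proba
        pred = np.empty(n, dtype=int)
        conf = np.empty(n, dtype=float)
        pos = np.empty(n, dtype=float)
        accs, aucs = [], []
        for tr, te in folds:
            Xtr, Xte = _standardize(X[tr], X[te], cont_idx)
            clf = clone(proto)
            clf.fit(Xtr, y[tr])
            p = clf.predict(Xte)
            pred[te] = p
            if use_proba:
                proba = clf.predict_proba(Xte)
                pos_col = list(clf.classes_).index(1)
                pos[te] = proba[:, pos_col]
                conf[te] = proba[np.arange(len(te)), [
                    list(clf.classes_).index(c) for c in p]]
            else:
                d = clf.decision_function(Xte)
                pos[te] = d
                conf[te] = np.abs(d)
            accs.append(accuracy_score(y[te], p))
            aucs.append(roc_auc_score(y[te], pos[te]))
        per_algorithm[alg] = {
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "mean_auc": float(np.mean(aucs)),
            "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            "fold_accuracy": [float(a) for a in accs],
            "fold_auc": [float(a) for a in aucs],
        }
        table[f"pred_{alg}"] = pred
        table[f"conf_{alg}"] = conf
        table[f"pos_{alg}"] = pos

    pooled = {
        "mean_accuracy": float(np.mean(
            [per_algorithm[a]["mean_accuracy"] for a in spec.algorithms])),
        "mean_auc": float(np.mean(
            [per_algorithm[a]["mean_auc"] for a in spec.algorithms])),
    }
    per_subject = pd.DataFrame(table, index=pd.Index(ids, name="id"))
    return ModelEvalResult(tuple(spec.algorithms), per_algorithm, pooled,
                           per_subject, has_probability, spec)


def _rank_unit(values: np.ndarray) -> np.ndarray:
    """Map a monotone score to [0, 1] by rank (average ranks for ties)."""
    from scipy.stats import rankdata
    if len(values) == 1:
        return np.ones(1)
    r = rankdata(values)
    return (r - 1.0) / (len(values) - 1.0)


def select_misclassified_extremes(cohort: Cohort, eval_result: ModelEvalResult,
                                  n_per_group: int = 150,
                                  method_id: str = "m6") -> SelectionResult:
    """Select extremes among subjects misclassified by *all* algorithms.

    SG candidates are true cases predicted non-case by every algorithm
    (hearing worse than their risk factors predict); RG candidates the
    reverse.  Within each pool, subjects are ranked by the mean across
    algorithms of the confidence assigned to the wrong predicted class —
    probabilities where available, otherwise margins rank-normalized to
    [0, 1] within the pool — and the top ``n_per_group`` are kept.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    tab = eval_result.per_subject
    cohort_ids = {w.id for w in cohort}
    if not set(tab.index) >= cohort_ids:
        raise ValueError("evaluation does not cover the cohort")
    tab = tab.loc[[w.id for w in cohort]]

    algs = eval_result.algorithms
    preds = np.column_stack([tab[f"pred_{a}"].to_numpy() for a in algs])
    true = tab["true"].to_numpy()
    all_wrong = (preds != true[:, None]).all(axis=1)
    sg_pool = np.flatnonzero(all_wrong & (true == 1))
    rg_pool = np.flatnonzero(all_wrong & (true == 0))

    def pick(pool: np.ndarray) -> tuple[set[str], dict[str, float]]:
        if len(pool) == 0:
            return set(), {}
        parts = []
        for a in algs:
            conf = tab[f"conf_{a}"].to_numpy()[pool]
            if eval_result.has_probability.get(a, True):
                parts.append(conf)
            else:
                parts.append(_rank_unit(conf))
        score = np.mean(parts, axis=0)
        ids = tab.index.to_numpy()[pool]
        order = sorted(range(len(pool)), key=lambda i: (-score[i], ids[i]))
        keep = order[:min(n_per_group, len(pool))]
        return ({str(ids[i]) for i in keep},
                {str(ids[i]): float(score[i]) for i in range(len(pool))})

    sg, sg_scores = pick(sg_pool)
    rg, rg_scores = pick(rg_pool)
    scores = {**sg_scores, **rg_scores}
    rule = eval_result.spec.label_rule if eval_result.spec else LabelRule()
    return SelectionResult(
        method_id, sg, rg, scores,
        metadata={"n_per_group": n_per_group,
                  "sg_pool_size": int(len(sg_pool)),
                  "rg_pool_size": int(len(rg_pool)),
                  "phenotype_freqs": list(rule.frequencies),
                  "ears": rule.ears,
                  "algorithms": list(algs)})


def control_ids(eval_result: ModelEvalResult) -> set[str]:
    """Subjects correctly classified out-of-fold by every algorithm."""
    tab = eval_result.per_subject
    preds = np.column_stack([tab[f"pred_{a}"].to_numpy()
                             for a in eval_result.algorithms])
    ok = (preds == tab["true"].to_numpy()[:, None]).all(axis=1)
    return set(tab.index.to_numpy()[ok].astype(str))


def refine_by_sd(selection: SelectionResult, cohort: Cohort,
                 control: set[str], freqs: Sequence[float],
                 ears: str = "bilateral", top_frac: float = 0.15,
                 sd_multiple: float = 2.0) -> SelectionResult:
    """Keep the audiometric extremes of each group and require them to sit
    beyond ``sd_multiple`` control SDs.

    The top ``top_frac`` of the SG by phenotype PTA are kept if their PTA
    exceeds the control mean by more than ``sd_multiple`` SDs; symmetric
    rule for the bottom of the RG.  Refinement is contractive.
    """
    if not control:
        raise ValueError("control set is empty")
    if not 0.0 < top_frac <= 1.0:
        raise ValueError("top_frac must be in (0, 1]")
    ctrl_pta = np.array([cohort.get(i).pta(freqs, ears) for i in sorted(control)])
    mu = float(ctrl_pta.mean())
    sd = float(ctrl_pta.std(ddof=1)) if len(ctrl_pta) > 1 else 0.0

    def trim(ids: set[str], top: bool) -> tuple[set[str], list[dict]]:
        ranked = sorted(ids, key=lambda i: (-cohort.get(i).pta(freqs, ears)
                                            if top else
                                            cohort.get(i).pta(freqs, ears), i))
        k = int(math.floor(top_frac * len(ranked)))
        if top_frac >= 1.0:
            k = len(ranked)
        detail = []
        kept = set()
        for wid in ranked[:k]:
            pta = cohort.get(wid).pta(freqs, ears)
            passes = (pta > mu + sd_multiple * sd if top
                      else pta < mu - sd_multiple * sd)
            detail.append({"id": wid, "pta": float(pta), "kept": bool(passes)})
            if passes:
                kept.add(wid)
        return kept, detail

    sg, sg_detail = trim(selection.sg_ids, top=True)
    rg, rg_detail = trim(selection.rg_ids, top=False)
    meta = dict(selection.metadata)
    meta.update({
        "refined_from": selection.method_id,
        "control_n": int(len(ctrl_pta)),
        "control_mean": mu, "control_sd": sd,
        "top_frac": top_frac, "sd_multiple": sd_multiple,
        "phenotype_freqs": list(freqs), "ears": ears,
        "sd_check": {"sg": sg_detail, "rg": rg_detail},
    })
    score = {i: selection.score[i] for i in (sg | rg) if i in selection.score}
    # refined members keep their selection score; fall back to PTA if absent
    for i in (sg | rg) - set(score):
        score[i] = float(cohort.get(i).pta(freqs, ears))
    return SelectionResult(selection.method_id + "_refined", sg, rg, score,
                           metadata=meta)
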