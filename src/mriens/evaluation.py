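"""Nested cross-validation and AUC evaluation.

Every classification step — feature selection/extraction, hyperparameter
choice, model fitting — happens inside each outer training fold only; the
inner folds (delegated to the method builders) choose hyperparameters, and
out-of-fold scores over the outer loop give the AUC point estimate.  The
harness records exactly which subjects each fold's builder saw, so leakage
(a test subject entering any fitting call) is checkable after the fact.

AUC is computed by the Mann-Whitney equivalence: the probability that a
random positive outscores a random negative, ties counted half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .io_volumes import ValidationError, Volume, crop_inner

__all__ = [
    "auc",
    "CVPlan",
    "CVResult",
    "RegionComparison",
    "run_nested_cv",
    "compare_regions",
    "assert_no_leakage",
    "method1_builder",
    "method2_builder",
    "cnn3d_builder",
]


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve with the half-tie convention.

    Equals ``P(score+ > score-) + 0.5 * P(score+ = score-)`` over all
    positive/negative pairs, computed from midranks.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # midranks handle ties at exactly 1/2
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass(frozen=True)
class CVPlan:
    """Nested cross-validation plan.

    Defaults: 10 stratified outer folds (the validation protocol of the
    replicated MCI-conversion source study) and 5 inner folds for
    hyperparameter choice; fold assignment is seeded from ``seed``.
    """

    k_out: int = 10
    k_in: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k_out < 2 or self.k_in < 2:
            raise ValidationError("k_out and k_in must both be >= 2")


@dataclass
class CVResult:
    """Out-of-fold scores and per-fold bookkeeping of one nested-CV run."""

    subject_ids: list[str]
    labels: list[int]
    oof_scores: list[float]
    fold_of_subject: list[int]
    auc_value: float
    fold_aucs: list[float]
    chosen_params: list[dict]
    fitted_subjects: list[list[str]]
    test_subjects: list[list[str]]
    seed: int

    def to_dict(self) -> dict:
        return {
            "subject_ids": list(self.subject_ids),
            "labels": [int(v) for v in self.labels],
            "oof_scores": [float(v) for v in self.oof_scores],
            "fold_of_subject": [int(v) for v in self.fold_of_subject],
            "auc": self.auc_value,
            "fold_aucs": [float(v) for v in self.fold_aucs],
            "chosen_params": self.chosen_params,
            "fitted_subjects": self.fitted_subjects,
            "test_subjects": self.test_subjects,
            "seed": self.seed,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def scores_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "label": self.labels,
                "fold": self.fold_of_subject,
                "score": self.oof_scores,
            }
        )


MethodBuilder = Callable[[Sequence[Volume], np.ndarray, int, int], object]
"""Signature: builder(train_volumes, train_labels, k_in, seed) -> model
with a ``score_volumes(volumes) -> array`` method and an optional
``chosen_params`` attribute."""


def run_nested_cv(
    volumes: Sequence[Volume],
    y: Sequence[int],
    builder: MethodBuilder,
    plan: CVPlan,
) -> CVResult:
    """Run a method through nested CV and return out-of-fold results.

    Each subject is scored exactly once, by the model of the outer fold
    that held it out; fitting only ever sees the fold's training subjects
    (recorded in ``fitted_subjects`` for the leakage audit).
    """
    y = np.asarray(y, dtype=np.int64)
    if len(volumes) != len(y):
        raise ValidationError("one label per volume required")
    counts = np.bincount(y, minlength=2)
    if (counts < plan.k_out).any():
        raise ValidationError(
            f"need >= k_out={plan.k_out} subjects per class, got "
            f"{counts.tolist()}"
        )
    ids = [v.subject_id for v in volumes]
    splitter = StratifiedKFold(
        n_splits=plan.k_out, shuffle=True, random_state=plan.seed
    )
    oof = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    fold_aucs: list[float] = []
    chosen: list[dict] = []
    fitted_subjects: list[list[str]] = []
    test_subjects: list[list[str]] = []
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        fold_seed = (plan.seed * 10_000 + fold * 101) % (2**31)
        train_volumes = [volumes[i] for i in tr]
        model = builder(train_volumes, y[tr], plan.k_in, fold_seed)
        scores = np.asarray(model.score_volumes([volumes[i] for i in te]))
        oof[te] = scores
        fold_of[te] = fold
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(auc(scores, y[te]))
        chosen.append(dict(getattr(model, "chosen_params", {})))
        fitted_subjects.append([ids[i] for i in tr])
        test_subjects.append([ids[i] for i in te])
    assert not np.isnan(oof).any(), "every subject must be scored once"
    return CVResult(
        subject_ids=ids,
        labels=y.tolist(),
        oof_scores=oof.tolist(),
        fold_of_subject=fold_of.tolist(),
        auc_value=auc(oof, y),
        fold_aucs=fold_aucs,
        chosen_params=chosen,
        fitted_subjects=fitted_subjects,
        test_subjects=test_subjects,
        seed=plan.seed,
    )


def assert_no_leakage(result: CVResult) -> None:
    """Hard audit: no test subject of a fold appears in its fitting set."""
    for fold, (fit_ids, test_ids) in enumerate(
        zip(result.fitted_subjects, result.test_subjects)
    ):
        overlap = set(fit_ids) & set(test_ids)
        if overlap:
            raise AssertionError(
                f"fold {fold}: test subjects {sorted(overlap)} entered fitting"
            )


@dataclass
class RegionComparison:
    """Paired whole-volume vs inner-structures nested-CV results."""

    whole: CVResult
    inner: CVResult
    crop_k: int

    @property
    def auc_difference(self) -> float:
        """inner AUC minus whole-volume AUC."""
        return self.inner.auc_value - self.whole.auc_value


def compare_regions(
    volumes: Sequence[Volume],
    y: Sequence[int],
    builder: MethodBuilder,
    plan: CVPlan,
    crop_k: int,
) -> RegionComparison:
    """Run the same method on whole volumes and on the inner crop.

    The two runs share the plan (and hence identical fold assignments — a
    paired design), so the AUC difference isolates the effect of
    restricting the analysis to the inner cerebral structures.
    """
    whole = run_nested_cv(volumes, y, builder, plan)
    cropped = [crop_inner(v, crop_k) for v in volumes]
    inner = run_nested_cv(cropped, y, builder, plan)
    if whole.test_subjects != inner.test_subjects:
        raise AssertionError("paired design violated: fold splits differ")
    return RegionComparison(whole=whole, inner=inner, crop_k=crop_k)


# ---------------------------------------------------------------------------
# builder factories


def method1_builder(**kwargs) -> MethodBuilder:
    """Builder for Method #1 (fusion of AS+SVM and kPLS+SVM)."""
    from .ensemble import build_method1

    def build(volumes, y, k_in, seed):
        return build_method1(volumes, y, k_in=k_in, seed=seed, **kwargs)

    return build


def method2_builder(**kwargs) -> MethodBuilder:
    """Builder for Method #2 (per-slice ensemble over approaches/gaps)."""
    from .ensemble import build_method2

    def build(volumes, y, k_in, seed):
        return build_method2(volumes, y, seed=seed, **kwargs)

    return build


def cnn3d_builder(**kwargs) -> MethodBuilder:
    """Builder for the from-scratch 3-D patch CNN."""
    from .classifiers import train_patch_cnn

    def build(volumes, y, k_in, seed):
        return train_patch_cnn(volumes, y, seed=seed, **kwargs)

    return build
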