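"""Log-likelihood-ratio scores and the per-feature transformation.

The complete-matrix score of element *i* against classes A and B is

.. math::

    \\mathrm{score}_i = \\log P_W(\\Sigma_i \\mid n_i, \\hat\\Sigma_A)
        - \\log P_W(\\Sigma_i \\mid n_i, \\hat\\Sigma_B)

(positive favors A). The single-feature score of feature *j* for class
C is the change in class log-likelihood caused by deleting row/column
*j* from both the element matrix and the class scale matrix:

.. math::

    \\Delta\\log P_W^{\\,j}(C) = \\log P_W(\\Sigma, n \\mid \\hat\\Sigma_C)
        - \\log P_W(\\Sigma_j, n \\mid \\hat\\Sigma_{C_j})

and the two-class ratio vector
``Ratio_j = dlogP_j(C1) - dlogP_j(C2)`` is the element's transformed
feature representation. Deleting a whole group of features at once is
the same construction on a larger principal submatrix.

Scale convention
----------------
The class density is evaluated, by default, directly at the element's
covariance/correlation matrix (``mode="literal"``), although a Wishart
matrix with scale :math:`\\hat\\Sigma_C` has expectation
:math:`n_i \\hat\\Sigma_C`. The alternative ``mode="scatter"``
evaluates the density at the scatter matrix :math:`n_i \\Sigma_i`,
whose expectation matches the scale convention. The choice shifts
absolute log-likelihoods but the comparative (ratio) structure is what
drives classification; literal is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .class_model import ClassModel, ElementSample, Scheme, Weighting, fit_with_exclusion
from .exceptions import (
    DimensionMismatchError,
    EmptyResultError,
    MoreThanTwoClassesError,
)
from .wishart import SPDMatrix, WishartParams, validate_spd, wishart_log_pdf

__all__ = [
    "ScoreVector",
    "complete_score",
    "principal_submatrix",
    "single_feature_scores",
    "score_ratio_vector",
    "group_feature_score",
    "transform_dataset",
    "scores_to_frame",
]

ScoreMode = Literal["literal", "scatter"]


@dataclass(frozen=True)
class ScoreVector:
    """Per-feature log-likelihood-ratio deltas for one element."""

    element_id: str
    label: Hashable | None
    complete_score: float
    per_feature: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.per_feature) != len(self.feature_names):
            raise DimensionMismatchError(
                "per_feature and feature_names must have equal length"
            )


def _argument_matrix(element: ElementSample, mode: ScoreMode) -> SPDMatrix:
    if mode == "literal":
        return element.matrix
    if mode == "scatter":
        return validate_spd(element.dof * element.matrix.values)
    raise ValueError(f"unknown score mode {mode!r}")


def _check_dims(element: ElementSample, *models: ClassModel) -> int:
    p = element.matrix.p
    for m in models:
        if m.scale.p != p:
            raise DimensionMismatchError(
                f"class {m.label!r} scale is {m.scale.p}x{m.scale.p}, element is {p}x{p}"
            )
    return p


def complete_score(
    element: ElementSample,
    model_a: ClassModel,
    model_b: ClassModel,
    mode: ScoreMode = "literal",
) -> float:
    """Two-class log-likelihood ratio of the full matrix; positive
    values favor ``model_a``'s class."""
    _check_dims(element, model_a, model_b)
    m = _argument_matrix(element, mode)
    la = wishart_log_pdf(m, WishartParams(scale=model_a.scale, dof=element.dof))
    lb = wishart_log_pdf(m, WishartParams(scale=model_b.scale, dof=element.dof))
    return la - lb


def principal_submatrix(M: SPDMatrix, delete: Iterable[int]) -> SPDMatrix:
    """Delete the listed rows *and* identically indexed columns.

    Principal submatrices of an SPD matrix are SPD, so the result is
    revalidated and returned as an :class:`SPDMatrix`. Indices are
    0-based.
    """
    delete = set(delete)
    p = M.p
    for j in delete:
        if not 0 <= j < p:
            raise IndexError(f"feature index {j} out of range for p={p}")
    if len(delete) == p:
        raise EmptyResultError("cannot delete every feature")
    if not delete:
        return M
    keep = [i for i in range(p) if i not in delete]
    return validate_spd(M.values[np.ix_(keep, keep)])


def group_feature_score(
    element: ElementSample,
    model: ClassModel,
    delete: Iterable[int],
    mode: ScoreMode = "literal",
    full_log_pdf: float | None = None,
) -> float:
    """Change in class log-likelihood when a whole feature group is
    deleted from both the element and the class scale matrix.

    ``full_log_pdf`` lets callers reuse the full-matrix density (the
    shared first term) across many deletions. ``delete`` empty gives 0
    by construction; a singleton reduces to the single-feature score.
    """
    _check_dims(element, model)
    delete = set(delete)
    if full_log_pdf is None:
        m_full = _argument_matrix(element, mode)
        full_log_pdf = wishart_log_pdf(
            m_full, WishartParams(scale=model.scale, dof=element.dof)
        )
    if not delete:
        return 0.0
    sub_el = principal_submatrix(_argument_matrix(element, mode), delete)
    sub_cl = principal_submatrix(model.scale, delete)
    sub_log = wishart_log_pdf(sub_el, WishartParams(scale=sub_cl, dof=element.dof))
    return full_log_pdf - sub_log


def single_feature_scores(
    element: ElementSample,
    model: ClassModel,
    mode: ScoreMode = "literal",
) -> np.ndarray:
    """All p single-feature deletion scores against one class model.

    Costs p + 1 density evaluations: the full-matrix term is computed
    once and shared across the p deletions.
    """
    p = _check_dims(element, model)
    m_full = _argument_matrix(element, mode)
    full = wishart_log_pdf(m_full, WishartParams(scale=model.scale, dof=element.dof))
    return np.array(
        [
            group_feature_score(element, model, {j}, mode=mode, full_log_pdf=full)
            for j in range(p)
        ]
    )


def score_ratio_vector(
    element: ElementSample,
    model_a: ClassModel,
    model_b: ClassModel,
    mode: ScoreMode = "literal",
    feature_names: Sequence[str] | None = None,
) -> ScoreVector:
    """Two-class score vector: ``Ratio_j`` per feature plus the
    complete-matrix score. Swapping the class models negates every
    entry."""
    p = _check_dims(element, model_a, model_b)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{j}" for j in range(p)
    )
    if len(names) != p:
        raise DimensionMismatchError(f"expected {p} feature names, got {len(names)}")
    da = single_feature_scores(element, model_a, mode=mode)
    db = single_feature_scores(element, model_b, mode=mode)
    return ScoreVector(
        element_id=element.element_id,
        label=element.label,
        complete_score=complete_score(element, model_a, model_b, mode=mode),
        per_feature=da - db,
        feature_names=names,
    )


def transform_dataset(
    elements: Sequence[ElementSample],
    exclusion: Scheme = "leave_one_out",
    k: int = 10,
    shuffle_seed: int = 0,
    weighting: Weighting = "dof_weighted",
    mode: ScoreMode = "literal",
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score every element with class models it was excluded from.

    The two class labels are ordered by ``sorted()``; the first plays
    the role of class A (positive scores favor it). Output is an
    N x (p + 1) feature table: one ``ratio_<feature>`` column per
    feature plus ``complete_score``, indexed by element id, with the
    label carried alongside — ready for any downstream classifier.
    """
    labels = sorted({e.label for e in elements}, key=repr)
    if len(labels) != 2:
        raise MoreThanTwoClassesError(
            f"two-class transform requires exactly 2 labels, found {labels!r}"
        )
    label_a, label_b = labels
    models = fit_with_exclusion(
        elements, scheme=exclusion, k=k, shuffle_seed=shuffle_seed, weighting=weighting
    )
    vectors = [
        score_ratio_vector(
            e,
            models[e.element_id][label_a],
            models[e.element_id][label_b],
            mode=mode,
            feature_names=feature_names,
        )
        for e in elements
    ]
    return scores_to_frame(vectors)


def transform_dataset_per_class(
    elements: Sequence[ElementSample],
    exclusion: Scheme = "leave_one_out",
    k: int = 10,
    shuffle_seed: int = 0,
    weighting: Weighting = "dof_weighted",
    mode: ScoreMode = "literal",
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Multiclass variant: one deletion-delta column per (class, feature)
    plus one complete log-likelihood column per class, no ratios.

    Useful beyond two classes, where no single reference class exists;
    with exactly two classes the ratio transform
    (:func:`transform_dataset`) is the standard representation.
    """
    labels = sorted({e.label for e in elements}, key=repr)
    models = fit_with_exclusion(
        elements, scheme=exclusion, k=k, shuffle_seed=shuffle_seed, weighting=weighting
    )
    p = elements[0].matrix.p
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{j}" for j in range(p)
    )
    rows = []
    for e in elements:
        row: dict = {"label": e.label}
        for lbl in labels:
            model = models[e.element_id][lbl]
            m = _argument_matrix(e, mode)
            row[f"loglik_{lbl}"] = wishart_log_pdf(
                m, WishartParams(scale=model.scale, dof=e.dof)
            )
            deltas = single_feature_scores(e, model, mode=mode)
            row.update({f"delta_{lbl}_{n}": d for n, d in zip(names, deltas)})
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index([e.element_id for e in elements], name="element_id"))


def scores_to_frame(vectors: Sequence[ScoreVector]) -> pd.DataFrame:
    """Assemble score vectors into the delimited-text-ready table:
    element_id (index), label, complete_score, ratio_<feature> ..."""
    if not vectors:
        raise EmptyResultError("no score vectors to assemble")
    names = vectors[0].feature_names
    rows = []
    for v in vectors:
        if v.feature_names != names:
            raise DimensionMismatchError("inconsistent feature names across vectors")
        row = {"label": v.label, "complete_score": v.complete_score}
        row.update({f"ratio_{n}": x for n, x in zip(names, v.per_feature)})
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index([v.element_id for v in vectors], name="element_id"))
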