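"""Class-wise Wishart scale estimation with leakage-free exclusion.

Each classification unit (an *element*) is an SPD matrix — the
covariance or correlation matrix of one subject or one time-series
batch — together with the number of observations ``n_i`` behind it.
A class model is the (optionally length-weighted) average of its
member matrices,

.. math::

    \\hat\\Sigma_C = \\sum_{i \\in C} w_i \\Sigma_i, \\qquad
    w_i = 1/N_C \\text{ (uniform)} \\quad\\text{or}\\quad
    w_i = n_i \\big/ \\textstyle\\sum_j n_j \\text{ (dof-weighted)},

which is itself SPD because a convex combination of SPD matrices is
SPD. Exclusion protocols (leave-one-out, stratified k-fold) guarantee
that an element's own matrix never contributes to the scale matrix
used to score it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Literal, Sequence

import numpy as np

from .exceptions import (
    ClassTooSmallError,
    DegreesOfFreedomError,
    DimensionMismatchError,
    EmptyClassError,
    UnlabeledElementError,
)
from .wishart import SPDMatrix, validate_spd

__all__ = [
    "ElementSample",
    "ClassModel",
    "estimate_scale_matrix",
    "fit_with_exclusion",
]

Weighting = Literal["uniform", "dof_weighted"]
Scheme = Literal["leave_one_out", "k_fold"]


@dataclass(frozen=True)
class ElementSample:
    """One classification unit: an SPD matrix, its degrees of freedom,
    and an optional class label.

    ``dof`` is the number of observation vectors behind the matrix
    (for a time-series batch, its length in time points) and must be at
    least the matrix dimension, else the element cannot be scored.
    """

    matrix: SPDMatrix
    dof: int
    label: Hashable | None = None
    element_id: str = ""

    def __post_init__(self) -> None:
        if not float(self.dof).is_integer():
            raise DegreesOfFreedomError(f"dof must be an integer, got {self.dof!r}")
        object.__setattr__(self, "dof", int(self.dof))
        if self.dof < self.matrix.p:
            raise DegreesOfFreedomError(
                f"element {self.element_id!r}: dof={self.dof} < p={self.matrix.p}"
            )


@dataclass(frozen=True)
class ClassModel:
    """A fitted class: scale matrix, member count, estimation settings."""

    scale: SPDMatrix
    n_members: int
    weighting: Weighting
    label: Hashable


def estimate_scale_matrix(
    members: Sequence[ElementSample],
    weighting: Weighting = "dof_weighted",
    label: Hashable = None,
) -> ClassModel:
    """Average member matrices into a class scale matrix.

    ``uniform`` weights every member equally; ``dof_weighted`` weights
    by observation count, the right choice when members come from
    batches of very different length (it reduces to uniform when all
    lengths are equal). The result is re-validated as SPD.
    """
    if len(members) == 0:
        raise EmptyClassError("cannot estimate a scale matrix from zero members")
    p = members[0].matrix.p
    for m in members:
        if m.matrix.p != p:
            raise DimensionMismatchError(
                f"member {m.element_id!r} has p={m.matrix.p}, expected {p}"
            )

    if weighting == "uniform":
        weights = np.full(len(members), 1.0 / len(members))
    elif weighting == "dof_weighted":
        dofs = np.array([m.dof for m in members], dtype=float)
        weights = dofs / dofs.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    acc = np.zeros((p, p))
    for w, m in zip(weights, members):
        acc += w * m.matrix.values
    return ClassModel(
        scale=validate_spd(acc),
        n_members=len(members),
        weighting=weighting,
        label=label if label is not None else members[0].label,
    )


def _class_index(elements: Sequence[ElementSample]) -> dict[Hashable, list[int]]:
    by_class: dict[Hashable, list[int]] = {}
    for i, e in enumerate(elements):
        if e.label is None:
            raise UnlabeledElementError(f"element {e.element_id!r} has no label")
        by_class.setdefault(e.label, []).append(i)
    for lbl, idx in by_class.items():
        if len(idx) < 2:
            raise ClassTooSmallError(
                f"class {lbl!r} has {len(idx)} member(s); need >= 2 so exclusion "
                "leaves a non-empty class"
            )
    return by_class


def assign_folds(
    elements: Sequence[ElementSample],
    scheme: Scheme,
    k: int = 10,
    shuffle_seed: int = 0,
) -> np.ndarray:
    """Fold index per element. Leave-one-out puts each element in its
    own fold; k-fold shuffles within each class (seeded) and deals
    members round-robin, i.e. the folds are stratified by label."""
    by_class = _class_index(elements)
    folds = np.zeros(len(elements), dtype=int)
    if scheme == "leave_one_out":
        folds[:] = np.arange(len(elements))
        return folds
    if scheme != "k_fold":
        raise ValueError(f"unknown exclusion scheme {scheme!r}")
    if k < 2:
        raise ClassTooSmallError(f"k_fold requires k >= 2, got k={k}")
    smallest = min(len(idx) for idx in by_class.values())
    if k > smallest:
        raise ClassTooSmallError(
            f"k={k} exceeds the smallest class size {smallest}"
        )
    rng = np.random.default_rng(shuffle_seed)
    for idx in by_class.values():
        order = rng.permutation(idx)
        for j, el in enumerate(order):
            folds[el] = j % k
    return folds


def fit_with_exclusion(
    elements: Sequence[ElementSample],
    scheme: Scheme = "leave_one_out",
    k: int = 10,
    shuffle_seed: int = 0,
    weighting: Weighting = "dof_weighted",
) -> dict[str, dict[Hashable, ClassModel]]:
    """Fit per-element class models such that no element's matrix enters
    the scale matrix used to score it.

    For ``leave_one_out`` the element's own class is re-averaged
    without it; for ``k_fold`` every class model is estimated from the
    complement of the element's fold. Other classes also exclude the
    held-out fold (they lose nothing under leave-one-out, where the
    fold is a single element of one class).

    Returns
    -------
    dict
        ``element_id -> {class label -> ClassModel}``.
    """
    ids = [e.element_id for e in elements]
    if len(set(ids)) != len(ids):
        raise ValueError("element_id values must be unique")
    by_class = _class_index(elements)
    folds = assign_folds(elements, scheme, k=k, shuffle_seed=shuffle_seed)

    # One model set per fold, shared by the fold's members.
    fold_models: dict[int, dict[Hashable, ClassModel]] = {}
    for f in np.unique(folds):
        models: dict[Hashable, ClassModel] = {}
        for lbl, idx in by_class.items():
            train = [elements[i] for i in idx if folds[i] != f]
            if not train:
                raise ClassTooSmallError(
                    f"fold {f} removes every member of class {lbl!r}"
                )
            models[lbl] = estimate_scale_matrix(train, weighting=weighting, label=lbl)
        fold_models[int(f)] = models

    return {e.element_id: fold_models[int(folds[i])] for i, e in enumerate(elements)}
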