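"""Turn labeled multivariate time series into scoreable elements.

A labeled series (rows = time points, columns = channels, plus a
per-point class label) is split at every label change into maximal
constant-label *batches*. Each batch long enough (T >= p, the hard
invertibility constraint) yields one element: its p x p sample
covariance or Pearson correlation matrix with degrees of freedom equal
to the batch length. Uneven batch lengths are the whole point — the
Wishart degrees of freedom absorb them, so no clipping or padding is
ever applied.

Batches are mean-centered per channel before the covariance /
correlation is computed (the generative model assumes mean-zero
observation vectors; raw signals such as EEG carry large offsets).
The covariance divisor is the batch length T, matching the scatter
convention ``(1/n) sum X X'``; ``T - 1`` is available as an option.
Indices are 0-based and intervals half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Hashable, Literal, Sequence

import numpy as np
import pandas as pd

from .class_model import ElementSample
from .exceptions import (
    BatchTooShortError,
    DegenerateChannelError,
    LengthMismatchError,
)
from .wishart import validate_spd

__all__ = [
    "BatchSeries",
    "split_batches",
    "batch_to_element",
    "batches_to_elements",
    "read_series_csv",
    "read_series_arff",
]


@dataclass(frozen=True)
class BatchSeries:
    """A maximal run of time points sharing one label.

    ``data`` is T x p; ``t_start``/``t_end`` index the source series,
    0-based, half-open.
    """

    data: np.ndarray
    label: Hashable
    t_start: int
    t_end: int
    channel_names: tuple[str, ...] = field(default=())

    @property
    def length(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]


def split_batches(
    series: np.ndarray,
    labels: Sequence[Hashable],
    channel_names: Sequence[str] | None = None,
) -> list[BatchSeries]:
    """Split a series into maximal constant-label runs, in order.

    The batches partition the series exactly: concatenating their data
    reproduces the input.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise LengthMismatchError(f"series must be 2-D (T x p), got shape {series.shape}")
    t = series.shape[0]
    if len(labels) != t:
        raise LengthMismatchError(
            f"series has {t} time points but {len(labels)} labels"
        )
    if t == 0:
        return []
    names = tuple(channel_names) if channel_names is not None else tuple(
        f"ch{j}" for j in range(series.shape[1])
    )

    batches: list[BatchSeries] = []
    start = 0
    for i in range(1, t + 1):
        if i == t or labels[i] != labels[start]:
            batches.append(
                BatchSeries(
                    data=series[start:i],
                    label=labels[start],
                    t_start=start,
                    t_end=i,
                    channel_names=names,
                )
            )
            start = i
    return batches


def batch_to_element(
    batch: BatchSeries,
    statistic: Literal["covariance", "correlation"] = "correlation",
    min_length_policy: Literal["drop", "error"] = "drop",
    center: bool = True,
    ddof: int = 0,
    element_id: str | None = None,
    ridge: float = 0.0,
) -> ElementSample | None:
    """Extract one element (matrix + dof + label) from a batch.

    Returns ``None`` for batches shorter than the channel count when
    ``min_length_policy="drop"``; raises :class:`BatchTooShortError`
    under ``"error"``. ``ddof=0`` divides the covariance by T (scatter
    convention); ``ddof=1`` gives the unbiased T-1 divisor. A constant
    channel makes the correlation undefined and raises
    :class:`DegenerateChannelError`.
    """
    t, p = batch.data.shape
    if t < p:
        if min_length_policy == "drop":
            return None
        raise BatchTooShortError(
            f"batch [{batch.t_start}, {batch.t_end}) has length {t} < p={p}"
        )
    x = batch.data - batch.data.mean(axis=0) if center else batch.data.copy()

    if statistic == "covariance":
        mat = (x.T @ x) / (t - ddof)
    elif statistic == "correlation":
        sd = x.std(axis=0)
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            names = [batch.channel_names[j] if batch.channel_names else str(j) for j in bad]
            raise DegenerateChannelError(
                f"zero-variance channel(s) {names} in batch "
                f"[{batch.t_start}, {batch.t_end})"
            )
        xs = (x - x.mean(axis=0)) / sd
        mat = (xs.T @ xs) / t
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    return ElementSample(
        matrix=validate_spd(mat, ridge=ridge),
        dof=t,
        label=batch.label,
        element_id=element_id if element_id is not None else f"batch_{batch.t_start}_{batch.t_end}",
    )


def batches_to_elements(
    batches: Sequence[BatchSeries],
    statistic: Literal["covariance", "correlation"] = "correlation",
    min_length_policy: Literal["drop", "error"] = "drop",
    center: bool = True,
    ddof: int = 0,
    ridge: float = 0.0,
    preprocess: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[list[ElementSample], int]:
    """Convert a batch list, counting (never hiding) dropped batches.

    ``preprocess`` is an optional hook applied to each batch's T x p
    data before matrix extraction (e.g. a user-supplied detrender).

    Returns ``(elements, n_dropped)``.
    """
    elements: list[ElementSample] = []
    dropped = 0
    for i, b in enumerate(batches):
        if preprocess is not None:
            data = np.asarray(preprocess(b.data), dtype=float)
            b = BatchSeries(data=data, label=b.label, t_start=b.t_start,
                            t_end=b.t_end, channel_names=b.channel_names)
        el = batch_to_element(
            b,
            statistic=statistic,
            min_length_policy=min_length_policy,
            center=center,
            ddof=ddof,
            element_id=f"b{i:04d}_{b.t_start}_{b.t_end}",
            ridge=ridge,
        )
        if el is None:
            dropped += 1
        else:
            elements.append(el)
    return elements, dropped


def read_series_csv(
    path: str | Path,
    label_column: str,
    sep: str = ",",
) -> tuple[np.ndarray, list, list[str]]:
    """Read a delimited series: one row per time point, named channel
    columns plus a label column.

    Returns ``(series T x p, labels, channel names)``.
    """
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise LengthMismatchError(f"label column {label_column!r} not in {list(df.columns)}")
    labels = df[label_column].tolist()
    channels = [c for c in df.columns if c != label_column]
    return df[channels].to_numpy(dtype=float), labels, channels


def read_series_arff(
    path: str | Path,
    label_column: str | None = None,
) -> tuple[np.ndarray, list, list[str]]:
    """Read an ARFF series file (the UCI EEG eye-state native format).

    The label column defaults to the last attribute. Nominal labels are
    decoded from bytes to str.
    """
    from scipy.io import arff

    data, meta = arff.loadarff(str(path))
    names = list(meta.names())
    if label_column is None:
        label_column = names[-1]
    if label_column not in names:
        raise LengthMismatchError(f"label column {label_column!r} not in {names}")
    channels = [n for n in names if n != label_column]
    series = np.column_stack([np.asarray(data[c], dtype=float) for c in channels])
    raw = data[label_column]
    labels = [v.decode() if isinstance(v, bytes) else v for v in raw]
    return series, labels, channels
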