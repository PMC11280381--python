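"""Descriptor pruning and correlation-based subset selection.

The selection strategy mirrors classical correlation-matrix analysis:
constant and duplicate columns are dropped first, then descriptors are
accepted greedily by decreasing absolute Pearson correlation with the
activity, skipping any descriptor that is too collinear with one already
accepted or too weakly related to the response.  All correlations are
computed on training records only, so held-out data never influences the
choice of model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import Dataset
from .errors import PruneError, SelectionError, SizeError

__all__ = ["SelectionConfig", "RemovalLogEntry", "prune_descriptors", "select_descriptors"]


@dataclass
class SelectionConfig:
    """Thresholds for pruning and greedy selection.

    variance_floor
        Columns with variance at or below this are treated as constant.
    pairwise_r_max
        Maximum allowed |Pearson r| between two accepted descriptors.
    activity_r_min
        Minimum required |Pearson r| between a descriptor and the activity.
    max_descriptors
        Hard cap on the selected subset size.
    """

    variance_floor: float = 1e-10
    pairwise_r_max: float = 0.9
    activity_r_min: float = 0.1
    max_descriptors: int = 3

    def __post_init__(self):
        if self.variance_floor < 0 or not np.isfinite(self.variance_floor):
            raise ValueError("variance_floor must be finite and >= 0")
        if not (0 < self.pairwise_r_max <= 1):
            raise ValueError("pairwise_r_max must lie in (0, 1]")
        if not (0 <= self.activity_r_min < 1):
            raise ValueError("activity_r_min must lie in [0, 1)")
        if self.max_descriptors < 1:
            raise ValueError("max_descriptors must be >= 1")


@dataclass
class RemovalLogEntry:
    descriptor: str
    rule: str  # "zero variance" | "duplicate"
    detail: str = ""


def _training_matrix(ds: Dataset):
    role = "train" if "train" in ds.role_labels else None
    if role is None:
        # unsplit dataset: use every record with an observed activity
        X = ds.X()
        y = ds.y()
        mask = ~np.isnan(y.to_numpy())
        return X.loc[mask], y[mask]
    return ds.X(role), ds.y(role)


def prune_descriptors(
    ds: Dataset, cfg: SelectionConfig | None = None
) -> tuple[Dataset, list[RemovalLogEntry]]:
    """Drop constant and exactly duplicated descriptor columns.

    Duplicates keep the first column in file order.  Returns the reduced
    dataset and a removal log with one entry per dropped column.
    """
    cfg = cfg or SelectionConfig()
    if not ds.descriptor_names:
        raise PruneError("dataset has no descriptors")
    X, _ = _training_matrix(ds)
    if X.shape[0] < 3:
        raise SizeError(f"pruning needs at least 3 training records, have {X.shape[0]}")

    log: list[RemovalLogEntry] = []
    kept: list[str] = []
    kept_arrays: dict[str, np.ndarray] = {}
    for name in ds.descriptor_names:
        col = X[name].to_numpy()
        if float(np.var(col)) <= cfg.variance_floor:
            log.append(RemovalLogEntry(name, "zero variance"))
            continue
        dup_of = next(
            (k for k in kept if np.array_equal(kept_arrays[k], col)), None
        )
        if dup_of is not None:
            log.append(RemovalLogEntry(name, "duplicate", f"identical to {dup_of!r}"))
            continue
        kept.append(name)
        kept_arrays[name] = col

    if not kept:
        raise PruneError("all descriptors removed during pruning", removal_log=log)
    return ds.with_descriptors(kept), log


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def select_descriptors(ds: Dataset, cfg: SelectionConfig | None = None) -> list[str]:
    """Greedy correlation-ranked descriptor subset.

    Descriptors are ranked by |r| with the training activity (ties broken
    by column order) and accepted in rank order unless they fall below
    ``activity_r_min`` or exceed ``pairwise_r_max`` against an already
    accepted descriptor; acceptance stops at ``max_descriptors``.
    """
    cfg = cfg or SelectionConfig()
    X, y = _training_matrix(ds)
    yv = y.to_numpy()
    if np.isnan(yv).any():
        raise SelectionError("training activities missing; cannot rank descriptors")

    scored = []
    for order, name in enumerate(ds.descriptor_names):
        r = _pearson(X[name].to_numpy(), yv)
        scored.append((-abs(r), order, name, r))
    scored.sort()

    selected: list[str] = []
    for neg_abs_r, _, name, _r in scored:
        if len(selected) >= cfg.max_descriptors:
            break
        if -neg_abs_r < cfg.activity_r_min:
            continue
        col = X[name].to_numpy()
        if any(
            abs(_pearson(col, X[prev].to_numpy())) > cfg.pairwise_r_max
            for prev in selected
        ):
            continue
        selected.append(name)

    if not selected:
        raise SelectionError(
            f"no descriptor reached |r| >= {cfg.activity_r_min} with the activity"
        )
    return selected
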