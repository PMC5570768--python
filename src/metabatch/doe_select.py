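"""Design-of-experiments subset selection on a PCA score plane.

A cohort described by many clinical/personal descriptors is summarized by a
two-component PCA score map (multivariate characterization).  A full
two-level factorial design -- a virtual square with four corners plus a
center point -- is then fitted into that plane, and the samples nearest each
design point are selected.  The same mechanism, applied repeatedly to the
remaining samples, divides a selected set into representative analytical
batches so that every batch spans the cohort's variability.

The square's half-widths set the trade-off discussed for pilot versus
comprehensive studies: a smaller square avoids outliers, a wider square
covers more of the observed variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "SelectionDesign",
    "SelectionWarning",
    "build_design",
    "select_representative",
    "allocate_batches",
    "characterize",
]

#: Fixed processing order of the design points.
CORNER_ORDER = ((-1, -1), (-1, +1), (+1, -1), (+1, +1))


class SelectionWarning(UserWarning):
    """Emitted when a group cannot supply the full requested subset."""


@dataclass
class DescriptorTable:
    """Samples x descriptors with a per-sample group label.

    Categorical descriptor columns are one-hot encoded on access so that the
    PCA sees a numeric matrix; missing values are tolerated downstream by
    NIPALS' missing-data support.
    """

    data: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_ids: {dup}")
        self.group = pd.Series(self.group).reindex(self.data.index)
        if self.group.isna().any():
            bad = self.group.index[self.group.isna()].tolist()
            raise ValueError(f"group label missing for samples: {bad}")

    def numeric(self) -> pd.DataFrame:
        """Descriptor matrix with categoricals one-hot encoded."""
        cat = self.data.select_dtypes(exclude=[np.number]).columns
        if len(cat) == 0:
            return self.data.astype(float)
        return pd.get_dummies(self.data, columns=list(cat), dtype=float)

    @property
    def groups(self) -> list:
        return sorted(self.group.unique().tolist())


@dataclass
class SelectionDesign:
    """A fitted two-level factorial design (square plus center point)."""

    design_points: list[tuple[float, float]]
    per_point: list[int]
    width_mode: str
    width_parameter: float
    point_labels: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(sum(self.per_point))


def build_design(scores, width_mode: str = "quantile",
                 width_parameter: float = 0.95,
                 per_corner: int = 5, per_center: int = 3,
                 allow_short: bool = False) -> SelectionDesign:
    """Fit the factorial square into a 2-D score cloud.

    The corner coordinates are ``(+-w1, +-w2)`` where ``w_j`` is the
    ``width_parameter`` quantile of ``|t_j|`` (``quantile`` mode) or
    ``width_parameter * sd(t_j)`` (``sd`` mode); the center sits at the
    score-space origin.  When fewer samples than design slots are available
    the call fails, unless ``allow_short`` is set, in which case a
    :class:`SelectionWarning` is emitted and selection will simply take
    every sample (small subgroups are analyzed in full rather than dropped).
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("scores must be an n x 2 matrix")
    n = S.shape[0]
    need = 4 * per_corner + per_center
    if n < need:
        if not allow_short:
            raise ValueError(
                f"insufficient samples: design requires {need}, only {n} available")
        warnings.warn(
            f"design requires {need} samples but only {n} are available; "
            "all will be selected", SelectionWarning, stacklevel=2)
    if width_parameter <= 0:
        raise ValueError("width_parameter must be positive")
    if width_mode == "quantile":
        if width_parameter > 1:
            raise ValueError("quantile width_parameter must be in (0, 1]")
        w = np.quantile(np.abs(S), width_parameter, axis=0)
    elif width_mode == "sd":
        w = width_parameter * S.std(axis=0, ddof=1)
    else:
        raise ValueError("width_mode must be 'quantile' or 'sd'")
    points = [(sx * w[0], sy * w[1]) for sx, sy in CORNER_ORDER] + [(0.0, 0.0)]
    labels = ["corner(-,-)", "corner(-,+)", "corner(+,-)", "corner(+,+)", "center"]
    return SelectionDesign(design_points=points,
                           per_point=[per_corner] * 4 + [per_center],
                           width_mode=width_mode, width_parameter=width_parameter,
                           point_labels=labels)


def _nearest_assignment(scores: pd.DataFrame, points, counts, labels):
    """Greedy without-replacement nearest-sample assignment to design points.

    Points are visited in fixed order; distance ties are broken by sample_id
    lexicographic order so the selection is platform independent.
    """
    S = scores.to_numpy(dtype=float)
    ids = list(scores.index)
    order_key = np.argsort(np.argsort([str(i) for i in ids]))  # lexicographic rank
    available = np.ones(len(ids), dtype=bool)
    rows = []
    for (px, py), count, label in zip(points, counts, labels):
        d = np.hypot(S[:, 0] - px, S[:, 1] - py)
        for _ in range(count):
            if not available.any():
                break
            cand = np.flatnonzero(available)
            # sort by (distance, lexicographic sample id)
            best = cand[np.lexsort((order_key[cand], d[cand]))][0]
            available[best] = False
            rows.append((ids[best], label, float(d[best])))
    return pd.DataFrame(rows, columns=["sample_id", "design_point", "distance"]).set_index("sample_id")


def select_representative(scores, design: SelectionDesign) -> pd.DataFrame:
    """Select the samples nearest each design point, without replacement.

    Returns a frame indexed by sample_id with the assigned design point and
    score-space distance.  If fewer samples than requested are available,
    all are selected and a :class:`SelectionWarning` is emitted (small
    subgroups are kept in full rather than dropped).
    """
    Sf = scores if isinstance(scores, pd.DataFrame) else pd.DataFrame(
        np.asarray(scores, dtype=float))
    if Sf.shape[1] != 2:
        raise ValueError("scores must have exactly 2 columns")
    if Sf.shape[0] < design.total:
        warnings.warn(
            f"only {Sf.shape[0]} samples available for a {design.total}-sample design; "
            "selecting all", SelectionWarning, stacklevel=2)
    return _nearest_assignment(Sf, design.design_points, design.per_point,
                               design.point_labels)


def _batch_targets(n: int, n_batches: int) -> list[int]:
    base, rem = divmod(n, n_batches)
    return [base + 1] * rem + [base] * (n_batches - rem)


def _peel(scores: pd.DataFrame, design: SelectionDesign, target: int) -> list:
    """Pick ``target`` samples by cycling the design points, nearest first."""
    S = scores.to_numpy(dtype=float)
    ids = list(scores.index)
    order_key = np.argsort(np.argsort([str(i) for i in ids]))
    available = np.ones(len(ids), dtype=bool)
    picked: list = []
    dists = [np.hypot(S[:, 0] - px, S[:, 1] - py) for px, py in design.design_points]
    pt = 0
    while len(picked) < target and available.any():
        d = dists[pt % len(dists)]
        cand = np.flatnonzero(available)
        best = cand[np.lexsort((order_key[cand], d[cand]))][0]
        available[best] = False
        picked.append(ids[best])
        pt += 1
    return picked


def allocate_batches(scores, group: pd.Series, n_batches: int,
                     design: SelectionDesign) -> pd.Series:
    """Divide a selected set into representative analytical batches.

    Batches are built by iterative peeling: within every group, batch 1
    takes a miniature representative selection (design points visited in
    round-robin, nearest remaining sample each time) of its target size from
    the remaining members, then batch 2 from what is left, and so on; the
    last batch receives the remainder.  Every group contributes
    ``floor(n_g / n_batches)`` or ``ceil(n_g / n_batches)`` samples to each
    batch, so each batch mirrors the group composition of the whole set.

    Returns a per-sample integer batch label (1-based) aligned to ``scores``.
    """
    Sf = scores if isinstance(scores, pd.DataFrame) else pd.DataFrame(
        np.asarray(scores, dtype=float))
    group = pd.Series(group).reindex(Sf.index)
    if group.isna().any():
        raise ValueError("group label missing for some samples")
    if n_batches < 2:
        raise ValueError("n_batches must be at least 2")
    sizes = group.value_counts()
    too_small = sizes[sizes < n_batches]
    if len(too_small) > 0:
        raise ValueError(
            f"group(s) smaller than n_batches={n_batches}: {too_small.to_dict()}")
    batch = pd.Series(index=Sf.index, dtype=int, name="batch")
    for g in sorted(group.unique(), key=str):
        members = Sf.index[group == g]
        remaining = list(members)
        targets = _batch_targets(len(members), n_batches)
        for b, target in enumerate(targets[:-1], start=1):
            picked = _peel(Sf.loc[remaining], design, target)
            batch.loc[picked] = b
            remaining = [i for i in remaining if i not in set(picked)]
        batch.loc[remaining] = n_batches
    return batch


def characterize(table: DescriptorTable, group, n_components: int = 2,
                 scaling="UV", select: str = "fixed",
                 max_components: int = 2, seed: int | None = None):
    """PCA score map of one group's descriptor sub-table.

    Convenience wrapper: subsets the table to ``group``, one-hot encodes,
    fits NIPALS PCA (two components by default, optionally Q2-gated with a
    hard cap) and returns the fitted model.
    """
    from .pca import fit_pca

    idx = table.group.index[table.group == group]
    if len(idx) == 0:
        raise ValueError(f"no samples in group {group!r}")
    X = table.numeric().loc[idx]
    # drop constant columns within the subgroup: carry no selection information
    sds = X.std(axis=0, ddof=1, skipna=True)
    X = X.loc[:, sds.fillna(0.0) > 0]
    n_comp = min(n_components, max_components)
    return fit_pca(X, n_components=n_comp, scaling=scaling, select=select, seed=seed)
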