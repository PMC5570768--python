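"""Column scaling and internal-standard (IS) normalization of peak-area matrices.

Relative quantification by GC-MS reports arbitrary-unit peak areas whose
per-sample magnitude depends on injection volume and instrument sensitivity.
Spiked internal standards track that multiplicative variability, so dividing
each sample by a summary of its IS signal removes it.  The summary used here
is the first principal-component score (t1) of the IS sub-matrix, computed
on unit-variance-scaled but *uncentered* data (``UVN`` scaling), so that t1
is proportional to the per-sample injection factor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScalingMode",
    "ScalingSpec",
    "PeakAreaMatrix",
    "fit_scaling",
    "scale_matrix",
    "is_normalize",
]


class ScalingMode(str, enum.Enum):
    """Column pretreatment applied before latent-variable modelling.

    UV
        Unit variance: subtract the column mean, divide by the sample
        standard deviation (``ddof=1``).
    UVN
        Unit variance, no centering: divide by the standard deviation only.
        Column means are preserved (rescaled), which keeps nonnegative data
        nonnegative -- required for the IS normalization step.
    CENTER
        Mean centering only.
    NONE
        Identity.
    """

    UV = "UV"
    UVN = "UVN"
    CENTER = "CENTER"
    NONE = "NONE"


def _as_mode(mode: "ScalingMode | str") -> ScalingMode:
    if isinstance(mode, ScalingMode):
        return mode
    return ScalingMode(str(mode).upper())


@dataclass
class ScalingSpec:
    """A (possibly fitted) column-scaling recipe.

    Once fitted, ``means`` and ``sds`` are stored so that exactly the same
    transform can be replayed on new rows (e.g. when projecting held-out
    samples onto a trained model).
    """

    mode: ScalingMode = ScalingMode.UV
    means: pd.Series | None = field(default=None, repr=False)
    sds: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mode = _as_mode(self.mode)

    @property
    def fitted(self) -> bool:
        if self.mode in (ScalingMode.UV, ScalingMode.UVN):
            return self.sds is not None
        if self.mode is ScalingMode.CENTER:
            return self.means is not None
        return True

    def copy(self) -> "ScalingSpec":
        return replace(self)


def _to_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return pd.DataFrame(arr)

def fit_scaling(X, mode: "ScalingMode | str" = ScalingMode.UV) -> ScalingSpec:
    """Fit a :class:`ScalingSpec` (column means and sds) on a matrix.

    Standard deviations use the sample (``ddof=1``) denominator.  Missing
    cells are ignored in the moment estimates.
    """
    Xf = _to_frame(X)
    mode = _as_mode(mode)
    if Xf.size == 0:
        raise ValueError("cannot fit scaling on an empty matrix")
    means = Xf.mean(axis=0, skipna=True)
    sds = Xf.std(axis=0, ddof=1, skipna=True)
    if mode in (ScalingMode.UV, ScalingMode.UVN):
        bad = sds.index[(~np.isfinite(sds.to_numpy())) | (sds.to_numpy() <= 0)]
        if len(bad) > 0:
            raise ValueError(
                f"zero-variance column(s) cannot be scaled to unit variance: {list(bad)}"
            )
    return ScalingSpec(mode=mode, means=means, sds=sds)


def scale_matrix(X, spec: "ScalingSpec | ScalingMode | str" = ScalingMode.UV):
    """Scale the columns of ``X`` according to ``spec``.

    If ``spec`` is unfitted (or just a mode), means/sds are estimated from
    ``X`` first.  Returns ``(X_scaled, fitted_spec)``; replaying the fitted
    spec on the same matrix reproduces the output exactly.
    """
    if isinstance(spec, (ScalingMode, str)):
        spec = ScalingSpec(mode=_as_mode(spec))
    Xf = _to_frame(X)
    if Xf.size == 0:
        raise ValueError("cannot scale an empty matrix")
    if not spec.fitted:
        spec = fit_scaling(Xf, spec.mode)
    mode = spec.mode
    if mode is ScalingMode.NONE:
        return Xf.copy(), spec
    if mode is ScalingMode.CENTER:
        return Xf - spec.means, spec
    if spec.sds is None:
        raise ValueError("fitted spec lacks standard deviations")
    sds = spec.sds
    if not sds.index.equals(Xf.columns):
        try:
            sds = sds.loc[Xf.columns]
        except KeyError as exc:
            raise ValueError("scaling spec does not cover all columns") from exc
    if mode is ScalingMode.UV:
        means = spec.means.loc[Xf.columns]
        return (Xf - means) / sds, spec
    # UVN: divide by sd, keep the mean (no centering)
    return Xf / sds, spec


# ---------------------------------------------------------------------------
# Peak-area container


@dataclass
class PeakAreaMatrix:
    """Samples x metabolites peak areas with per-sample metadata.

    Parameters
    ----------
    data
        Nonnegative peak areas, one row per sample, one column per channel
        (identified metabolites and internal standards alike).
    is_columns
        Column names designated as internal standards.  Must be strictly
        positive in every sample when IS normalization is requested.
    group, batch, run_order
        Per-sample class label, analytical batch label and injection
        position.  Run order must be unique within each batch.
    """

    data: pd.DataFrame
    is_columns: list[str] = field(default_factory=list)
    group: pd.Series | None = None
    batch: pd.Series | None = None
    run_order: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_ids: {dup}")
        missing_is = [c for c in self.is_columns if c not in self.data.columns]
        if missing_is:
            raise ValueError(f"IS columns not present in matrix: {missing_is}")
        for name in ("group", "batch", "run_order"):
            s = getattr(self, name)
            if s is not None:
                s = pd.Series(s) if not isinstance(s, pd.Series) else s
                s = s.reindex(self.data.index)
                if s.isna().any():
                    bad = s.index[s.isna()].tolist()
                    raise ValueError(f"metadata '{name}' missing for samples: {bad}")
                setattr(self, name, s)
        if self.run_order is not None and self.batch is not None:
            for b, idx in self.data.index.groupby(self.batch).items():
                ro = self.run_order.loc[idx]
                if ro.duplicated().any():
                    raise ValueError(f"run_order not unique within batch {b!r}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.is_columns]

    @property
    def metabolites(self) -> pd.DataFrame:
        """The non-IS part of the matrix."""
        return self.data[self.metabolite_ids]

    @property
    def internal_standards(self) -> pd.DataFrame:
        return self.data[list(self.is_columns)]

    def copy(self) -> "PeakAreaMatrix":
        return PeakAreaMatrix(
            data=self.data.copy(),
            is_columns=list(self.is_columns),
            group=None if self.group is None else self.group.copy(),
            batch=None if self.batch is None else self.batch.copy(),
            run_order=None if self.run_order is None else self.run_order.copy(),
        )

    def subset(self, sample_ids) -> "PeakAreaMatrix":
        ids = list(sample_ids)
        return PeakAreaMatrix(
            data=self.data.loc[ids].copy(),
            is_columns=list(self.is_columns),
            group=None if self.group is None else self.group.loc[ids].copy(),
            batch=None if self.batch is None else self.batch.loc[ids].copy(),
            run_order=None if self.run_order is None else self.run_order.loc[ids].copy(),
        )


def _is_t1(is_block: pd.DataFrame) -> pd.Series:
    """First-component score of the UVN-scaled (uncentered) IS block.

    Oriented so that mean(t1) > 0; IS areas are strictly positive so the
    dominant singular direction is single-signed and the orientation makes
    sample-wise division well defined.
    """
    from .pca import fit_pca  # local import: pca depends on this module's scaling

    vals = is_block.to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = is_block.index[np.isnan(vals).any(axis=1)].tolist()
        raise ValueError(f"missing IS areas for samples: {bad}")
    if (vals <= 0).any():
        rows = is_block.index[(vals <= 0).any(axis=1)].tolist()
        raise ValueError(f"non-positive IS areas for samples: {rows}")
    model = fit_pca(is_block, n_components=1, scaling=ScalingMode.UVN, select="fixed")
    t1 = model.scores.iloc[:, 0]
    if t1.mean() < 0:
        t1 = -t1
    near_zero = t1.index[np.abs(t1.to_numpy()) < 1e-12].tolist()
    if near_zero:
        raise ValueError(f"t1 score is zero for samples: {near_zero}")
    return t1


def is_normalize(pam: PeakAreaMatrix, per_batch: bool = True) -> PeakAreaMatrix:
    """Normalize every channel of each sample by its IS t1 score.

    A one-component PCA is fitted to the UVN-scaled internal-standard
    sub-matrix; each sample's entire row (IS and metabolite channels) is then
    divided by its t1 score.  Because t1 is a linear projection of uncentered
    data, a per-sample multiplicative factor applied to all channels is
    removed exactly.

    With ``per_batch=True`` (default) the PCA is fitted separately inside
    each analytical batch, mirroring a per-day workflow; set it to ``False``
    to fit one model across all samples.

    Missing values in non-IS columns pass through as missing.  Returns a new
    :class:`PeakAreaMatrix`; the input is untouched.
    """
    if not pam.is_columns:
        raise ValueError("is_normalize requires a nonempty set of IS columns")
    out = pam.copy()
    if per_batch and pam.batch is not None:
        t1 = pd.Series(index=pam.data.index, dtype=float)
        for _, idx in pam.data.index.groupby(pam.batch).items():
            t1.loc[idx] = _is_t1(pam.data.loc[idx, list(pam.is_columns)])
    else:
        t1 = _is_t1(pam.data[list(pam.is_columns)])
    out.data = out.data.div(t1, axis=0)
    return out
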