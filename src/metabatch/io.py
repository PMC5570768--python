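"""Delimited-text readers/writers and run configuration.

All matrices travel as delimited text with a header row; sample metadata
(group, batch, run_order) live either inline under reserved column names or
in a sidecar table keyed by sample_id.  Output is always UTF-8 CSV with dot
decimals, whatever the input dialect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .doe_select import DescriptorTable
from .preprocess import PeakAreaMatrix

__all__ = [
    "RunConfig",
    "read_matrix",
    "read_descriptors",
    "read_peak_areas",
    "write_table",
]

RESERVED = ("sample_id", "group", "batch", "run_order")


def _read_table(path, sep=None, decimal=".") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", decimal=decimal)
    else:
        df = pd.read_csv(path, sep=sep, decimal=decimal)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'sample_id' column")
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample_id(s): {dup}")
    return df.set_index("sample_id")


def _check_numeric(df: pd.DataFrame, path, missing_codes=("", "NA", "NaN")) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = df.notna() & out.isna() & ~df.astype(str).isin(missing_codes)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}")
    return out


def read_matrix(path, kind: str = "peak_areas", is_columns=(),
                metadata_path=None, sep=None, decimal="."):
    """Read a sample-by-variable matrix with metadata.

    ``kind`` is ``"peak_areas"`` (returns :class:`PeakAreaMatrix`; requires
    group/batch/run_order metadata and an IS column list) or
    ``"descriptors"`` (returns :class:`DescriptorTable`; requires group).
    """
    df = _read_table(path, sep=sep, decimal=decimal)
    if metadata_path is not None:
        meta = _read_table(metadata_path, sep=sep, decimal=decimal)
        missing = df.index.difference(meta.index).tolist()
        if missing:
            raise ValueError(f"{metadata_path}: no metadata for samples {missing}")
        for col in RESERVED[1:]:
            if col in meta.columns:
                df[col] = meta.loc[df.index, col]
    meta_cols = [c for c in RESERVED[1:] if c in df.columns]
    meta = df[meta_cols]
    values = _check_numeric(df.drop(columns=meta_cols), path)
    if kind == "descriptors":
        if "group" not in meta.columns:
            raise ValueError(f"{path}: descriptor tables need a 'group' column")
        return DescriptorTable(data=values, group=meta["group"])
    if kind == "peak_areas":
        for col in ("group", "batch", "run_order"):
            if col not in meta.columns:
                raise ValueError(f"{path}: peak-area tables need a '{col}' column")
        missing_is = [c for c in is_columns if c not in values.columns]
        if missing_is:
            raise ValueError(f"{path}: declared IS columns absent: {missing_is}")
        return PeakAreaMatrix(data=values, is_columns=list(is_columns),
                              group=meta["group"], batch=meta["batch"],
                              run_order=meta["run_order"].astype(int))
    raise ValueError(f"unknown kind {kind!r}")


def read_descriptors(path, **kw) -> DescriptorTable:
    return read_matrix(path, kind="descriptors", **kw)


def read_peak_areas(path, is_columns, **kw) -> PeakAreaMatrix:
    return read_matrix(path, kind="peak_areas", is_columns=is_columns, **kw)


def write_table(df: pd.DataFrame, path, index_label="sample_id",
                float_format="%.6g") -> Path:
    """Write a table as UTF-8 CSV with dot decimals, 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index_label=index_label, float_format=float_format,
              encoding="utf-8")
    return path


@dataclass
class RunConfig:
    """Validated configuration of the end-to-end pipeline."""

    out_dir: str = "metabatch_out"
    descriptors_path: str | None = None
    peak_areas_path: str | None = None
    is_columns: list[str] = field(default_factory=list)
    scaling: str = "UV"
    per_corner: int = 5
    per_center: int = 3
    width_mode: str = "quantile"
    width_parameter: float = 0.95
    max_components: int = 2
    n_batches: int = 4
    folds: int = 7
    n_orth: int = 1
    alpha: float = 0.05
    positive_class: str | None = None
    control_group: str = "control"
    is_normalize_per_batch: bool = True
    refit_pca_per_batch: bool = False
    seed: int = 0
    simulate: bool = True           # no input paths -> synthetic study

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_batches < 2:
            raise ValueError("n_batches must be at least 2")
        if self.width_parameter <= 0:
            raise ValueError("width_parameter must be positive")
        if self.peak_areas_path or self.descriptors_path:
            self.simulate = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
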