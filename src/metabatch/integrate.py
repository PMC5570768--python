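"""Combine per-batch OPLS-DA profiles into one metabolic profile.

Instead of concatenating batch data and correcting batch effects, each
analytical batch is modelled separately and only the batch-invariant summary
-- the p(corr) vector -- is combined:

1. keep metabolites whose p(corr) has the same strict sign in every batch
   (sign consistency; an exact zero has no sign and fails the filter);
2. average the per-batch p(corr) values of the retained metabolites;
3. combine the per-batch jackknife standard errors as a root mean square,
   ``SE_avg = sqrt(sum_b SE_b^2 / B)``;
4. form the combined confidence interval ``t(1 - alpha/2, N - B) * SE_avg``
   where N is the total number of cross-validation groups over all batches;
5. call a metabolite significant when ``|avg p(corr)| > CI``.

With three batches of sevenfold cross-validation this is the t-quantile at
18 degrees of freedom applied to ``sqrt((SE_1^2 + SE_2^2 + SE_3^2) / 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .opls import BatchResult

__all__ = [
    "CombinedProfile",
    "SusPlotData",
    "sign_consistency",
    "average_pcorr",
    "combined_se",
    "combined_ci",
    "call_significant",
    "sus_data",
    "integrate_batches",
]


@dataclass
class SusPlotData:
    """Paired p(corr) values of two models over their shared metabolites."""

    pairs: pd.DataFrame                # columns: pcorr_a, pcorr_b
    r_squared: float
    same_direction: pd.Series


@dataclass
class CombinedProfile:
    """The combined multi-batch metabolic profile."""

    pcorr_by_batch: pd.DataFrame       # K x B, columns are batch ids
    sign_consistent: pd.Series
    avg_pcorr: pd.Series               # NaN where not sign-consistent
    se_avg: pd.Series | None
    avg_ci: pd.Series | None
    significant: pd.Series | None
    n_total_cv_groups: int | None
    alpha: float = 0.05

    @property
    def n_batches(self) -> int:
        return self.pcorr_by_batch.shape[1]

    @property
    def metabolite_ids(self) -> list:
        return list(self.pcorr_by_batch.index)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-metabolite table, sorted by |average p(corr)| descending."""
        out = self.pcorr_by_batch.copy()
        out.columns = [f"pcorr_{b}" for b in out.columns]
        out["sign_consistent"] = self.sign_consistent
        out["avg_pcorr"] = self.avg_pcorr
        if self.se_avg is not None:
            out["se_avg"] = self.se_avg
        if self.avg_ci is not None:
            out["avg_ci"] = self.avg_ci
        if self.significant is not None:
            out["significant"] = self.significant
        return out.sort_values("avg_pcorr", key=lambda s: s.abs().fillna(-1.0),
                               ascending=False, kind="mergesort")

    def summary(self) -> dict:
        return {
            "n_metabolites": int(self.pcorr_by_batch.shape[0]),
            "n_batches": int(self.n_batches),
            "n_sign_consistent": int(self.sign_consistent.sum()),
            "n_significant": (None if self.significant is None
                              else int(self.significant.sum())),
            "alpha": self.alpha,
            "n_total_cv_groups": self.n_total_cv_groups,
        }


def _as_matrix(pcorr_matrix) -> pd.DataFrame:
    """Coerce to a K x B frame (metabolites as rows, batches as columns)."""
    if isinstance(pcorr_matrix, pd.DataFrame):
        return pcorr_matrix
    arr = np.asarray(pcorr_matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D p(corr) matrix")
    # convention used by the operation-level API: rows are batches
    return pd.DataFrame(arr.T)


def sign_consistency(pcorr_matrix) -> pd.Series:
    """True where all batches agree on a strict sign.

    ``pcorr_matrix`` is B x K (rows = batches) for array input, or a K x B
    DataFrame.  Missing entries are not allowed; an exact zero in any batch
    makes the metabolite inconsistent.
    """
    M = _as_matrix(pcorr_matrix)
    if M.shape[1] < 2:
        raise ValueError("sign consistency needs at least 2 batches")
    vals = M.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing p(corr) entries are not allowed")
    return pd.Series((vals > 0).all(axis=1) | (vals < 0).all(axis=1),
                     index=M.index, name="sign_consistent")


def average_pcorr(pcorr_matrix, mask: pd.Series) -> pd.Series:
    """Arithmetic mean across batches where the mask is true, NaN elsewhere."""
    M = _as_matrix(pcorr_matrix)
    mask = pd.Series(mask)
    mask.index = M.index
    avg = M.mean(axis=1)
    return avg.where(mask.astype(bool)).rename("avg_pcorr")


def combined_se(se_matrix) -> pd.Series:
    """Root-mean-square of per-batch standard errors, per metabolite."""
    M = _as_matrix(se_matrix)
    vals = M.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("standard errors must be nonnegative")
    return pd.Series(np.sqrt((vals ** 2).mean(axis=1)), index=M.index,
                     name="se_avg")


def combined_ci(se_avg, n_total: int, n_batches: int, alpha: float = 0.05):
    """Combined CI half-width: t(1 - alpha/2, N - B) * SE_avg.

    ``n_total`` counts the cross-validation groups pooled over all batches;
    one degree of freedom is spent per batch.
    """
    if n_total <= n_batches:
        raise ValueError(
            f"need more total CV groups ({n_total}) than batches ({n_batches})")
    mult = float(stats.t.ppf(1.0 - alpha / 2.0, n_total - n_batches))
    out = mult * np.asarray(se_avg, dtype=float)
    if isinstance(se_avg, pd.Series):
        return pd.Series(out, index=se_avg.index, name="avg_ci")
    if np.isscalar(se_avg) or out.ndim == 0:
        return float(out)
    return out


def call_significant(avg_pcorr, avg_ci) -> pd.Series:
    """Significant iff |average p(corr)| strictly exceeds the combined CI."""
    avg = pd.Series(avg_pcorr, dtype=float)
    ci = pd.Series(avg_ci, dtype=float)
    if len(avg) != len(ci):
        raise ValueError("avg_pcorr and avg_ci are not aligned")
    ci.index = avg.index
    sig = (avg.abs() > ci) & avg.notna() & ci.notna()
    return sig.rename("significant")


def sus_data(pcorr_a, pcorr_b) -> SusPlotData:
    """Shared-and-unique-structure (SUS) comparison of two p(corr) vectors.

    Restricted to metabolites present in both models; ``r_squared`` is the
    squared Pearson correlation (the coefficient of determination of the
    simple regression line drawn in a SUS plot).  Identical profiles fall on
    the diagonal with R^2 = 1.
    """
    a = pd.Series(pcorr_a, dtype=float)
    b = pd.Series(pcorr_b, dtype=float)
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("SUS comparison needs at least 3 shared metabolites")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("correlation undefined for a zero-variance p(corr) vector")
    r = float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
    pairs = pd.DataFrame({"pcorr_a": a, "pcorr_b": b})
    same = ((a > 0) & (b > 0)) | ((a < 0) & (b < 0))
    return SusPlotData(pairs=pairs, r_squared=r * r,
                       same_direction=same.rename("same_direction"))


def integrate_batches(batch_results, alpha: float = 0.05) -> CombinedProfile:
    """Full integration of two or more per-batch OPLS-DA results.

    All batches must cover the identical metabolite set (profiles are only
    comparable when the same variables entered every model).  Standard
    errors are optional; without them the profile carries sign-consistency
    flags and averages but no significance calls.
    """
    results = list(batch_results)
    if len(results) < 2:
        raise ValueError("integration needs at least 2 batches")
    ref = list(results[0].pcorr.index)
    for r in results[1:]:
        if list(r.pcorr.index) != ref:
            a, b = set(ref), set(r.pcorr.index)
            diff = sorted(a.symmetric_difference(b), key=str)
            raise ValueError(f"metabolite sets differ between batches: {diff}")
    batch_ids = [r.batch_id if r.batch_id is not None else i + 1
                 for i, r in enumerate(results)]
    P = pd.DataFrame({bid: r.pcorr for bid, r in zip(batch_ids, results)})
    mask = sign_consistency(P)
    avg = average_pcorr(P, mask)
    have_se = all(r.jackknife_se is not None and r.n_cv_groups is not None
                  for r in results)
    se_avg = ci = sig = None
    n_total = None
    if have_se:
        S = pd.DataFrame({bid: r.jackknife_se for bid, r in zip(batch_ids, results)})
        se_avg = combined_se(S)
        n_total = int(sum(r.n_cv_groups for r in results))
        ci = combined_ci(se_avg, n_total, len(results), alpha=alpha)
        sig = call_significant(avg, ci) & mask
        se_avg = se_avg.where(mask)
        ci = ci.where(mask)
    return CombinedProfile(pcorr_by_batch=P, sign_consistent=mask,
                           avg_pcorr=avg, se_avg=se_avg, avg_ci=ci,
                           significant=sig, n_total_cv_groups=n_total,
                           alpha=alpha)


def batch_results_from_frames(frames: dict, pcorr_col: str = "pcorr",
                              se_col: str = "jackknife_se",
                              n_col: str = "n_cv_groups") -> list[BatchResult]:
    """Build :class:`BatchResult` objects from per-batch result tables.

    ``frames`` maps batch id -> DataFrame indexed by metabolite with a
    p(corr) column and, optionally, jackknife SE and CV-group-count columns
    (the format written by the per-batch fit step).
    """
    out = []
    for bid, df in frames.items():
        se = df[se_col] if se_col in df.columns else None
        n = None
        if n_col in df.columns and df[n_col].notna().any():
            n = int(df[n_col].dropna().iloc[0])
        out.append(BatchResult(batch_id=bid, pcorr=df[pcorr_col],
                               jackknife_se=se, n_cv_groups=n))
    return out
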