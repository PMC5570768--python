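"""OPLS and OPLS-DA with correlation-scaled loadings and jackknife errors.

Orthogonal projections to latent structures (OPLS) splits the systematic
variation of a metabolite matrix X into a part predictive of a single
response y and a part orthogonal to it.  For two-class discriminant analysis
(OPLS-DA) the response is a centered 0/1 class dummy.

The quantity carried forward to multi-batch integration is p(corr): the
Pearson correlation between the predictive score t and each (scaled)
metabolite column.  It is bounded in [-1, 1] and invariant to positive
rescaling of individual columns, which makes profiles comparable across
models fitted to different batches as long as the same variables are used.

Precision of each p(corr) is estimated by a delete-one-group jackknife over
the sevenfold cross-validation groups:

    SE_k = sqrt( (N-1)/N * sum_i (theta_ik - mean_k)^2 )

with N the number of cross-validation groups, and the per-batch confidence
interval is t(1 - alpha/2, N - 1) * SE_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ScalingMode, ScalingSpec, scale_matrix

__all__ = [
    "OplsModel",
    "BatchResult",
    "fit_opls",
    "fit_oplsda",
    "crossvalidate_jackknife",
    "ci_from_se",
    "run_order_effect",
    "fit_batch",
]


@dataclass
class OplsModel:
    """A fitted single-response OPLS model (1 predictive + A_o orthogonal)."""

    t: pd.Series                       # predictive score
    p: pd.Series                       # predictive loading
    w: pd.Series                       # predictive weight, unit norm
    c: float                           # inner relation y ~ t
    t_orth: pd.DataFrame               # n x A_o orthogonal scores
    p_orth: pd.DataFrame
    w_orth: pd.DataFrame
    pcorr: pd.Series                   # corr(t, scaled original column k)
    r2x_pred: float                    # fraction of X SS in the predictive component
    r2x_orth: np.ndarray
    r2y_cum: float
    scaling: ScalingSpec
    y_mean: float
    y_scale: float
    n_orth: int
    classes: tuple | None = None       # (negative_class, positive_class) for DA
    q2: float | None = None
    cv: "CvResult | None" = field(default=None, repr=False)

    @property
    def r2x_pred_percent(self) -> float:
        """Percent of X variation captured by the predictive component."""
        return 100.0 * self.r2x_pred

    @property
    def r2x_total(self) -> float:
        return float(self.r2x_pred + self.r2x_orth.sum())

    @property
    def component_label(self) -> str:
        """SIMCA-style component count: predictive + X-orthogonal + Y-orthogonal."""
        return f"1 + {self.n_orth} + 0"


@dataclass
class CvResult:
    q2: float
    submodel_pcorr: pd.DataFrame       # N x K
    jackknife_se: pd.Series
    n_groups: int


@dataclass
class BatchResult:
    """Per-batch OPLS-DA summary used by the integration step."""

    batch_id: object
    pcorr: pd.Series
    jackknife_se: pd.Series | None = None
    n_cv_groups: int | None = None
    model: OplsModel | None = None
    alpha: float = 0.05

    @property
    def ci(self) -> pd.Series | None:
        """Jackknife CI half-widths: t(1-alpha/2, N-1) * SE."""
        if self.jackknife_se is None or self.n_cv_groups is None:
            return None
        return ci_from_se(self.jackknife_se, self.n_cv_groups, self.alpha)

    @property
    def significant(self) -> pd.Series | None:
        ci = self.ci
        if ci is None:
            return None
        return self.pcorr.abs() > ci


def _encode_y(y, classes=None) -> tuple[np.ndarray, tuple | None]:
    """Continuous y passes through; two-class labels become a 0/1 dummy."""
    ya = np.asarray(y)
    if classes is not None:
        neg, pos = classes
        dummy = np.where(ya == pos, 1.0, 0.0)
        return dummy, (neg, pos)
    return ya.astype(float), None


def _fit_opls_core(Xs: np.ndarray, y: np.ndarray, n_orth: int):
    """OPLS on an already scaled X and centered/scaled y.

    Per orthogonal component: w from the y-covariance, the orthogonal weight
    is the part of the loading p not aligned with w; X is deflated by the
    orthogonal component.  The final predictive component is computed on the
    deflated matrix.
    """
    E = Xs.copy()
    t_orth, p_orth, w_orth = [], [], []
    for _ in range(n_orth):
        w = E.T @ y / float(y @ y)
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("predictive weight degenerated to zero (y orthogonal to X)")
        w /= nw
        t = E @ w
        p = E.T @ t / float(t @ t)
        w_o = p - float(w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break  # no orthogonal variation left
        w_o /= n_wo
        t_o = E @ w_o
        p_o = E.T @ t_o / float(t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        t_orth.append(t_o)
        p_orth.append(p_o)
        w_orth.append(w_o)
    w = E.T @ y / float(y @ y)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("predictive weight degenerated to zero (y orthogonal to X)")
    w /= nw
    t = E @ w
    tt = float(t @ t)
    if tt == 0:
        raise ValueError("predictive score degenerated to zero")
    p = E.T @ t / tt
    c = float(y @ t) / tt
    return w, t, p, c, t_orth, p_orth, w_orth


def fit_opls(X, y, n_orth: int = 1,
             scaling: "ScalingSpec | ScalingMode | str" = ScalingMode.UV,
             classes: tuple | None = None) -> OplsModel:
    """Fit a single-response OPLS model.

    ``y`` is a continuous response (e.g. run order); for class labels use
    :func:`fit_oplsda`.  ``y`` is centered and scaled to unit variance
    internally, so the model is invariant to affine increasing relabelings
    of the response.
    """
    if n_orth < 0:
        raise ValueError("n_orth must be nonnegative")
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    if Xf.shape[0] < 6:
        raise ValueError("OPLS requires at least 6 samples")
    yv, cls = _encode_y(y, classes)
    if len(yv) != Xf.shape[0]:
        raise ValueError("y length does not match X")
    y_mean = float(yv.mean())
    yc = yv - y_mean
    y_scale = float(np.sqrt((yc ** 2).sum() / (len(yc) - 1)))
    if y_scale == 0:
        raise ValueError("response has zero variance")
    yc = yc / y_scale
    Xs_df, spec = scale_matrix(Xf, scaling)
    Xs = Xs_df.to_numpy(dtype=float)
    if np.isnan(Xs).any():
        raise ValueError("OPLS does not accept missing values; impute or drop first")
    w, t, p, c, t_orth, p_orth, w_orth = _fit_opls_core(Xs, yc, n_orth)
    total_ss = float((Xs ** 2).sum())
    r2x_pred = float((t @ t) * (p @ p)) / total_ss
    r2x_orth = np.array([float((to @ to) * (po @ po)) / total_ss
                         for to, po in zip(t_orth, p_orth)])
    resid = yc - c * t
    r2y = 1.0 - float(resid @ resid) / float(yc @ yc)
    # p(corr): correlation of the predictive score with each *original*
    # scaled column (before any orthogonal deflation)
    tc = t - t.mean()
    Xc = Xs - Xs.mean(axis=0)
    denom = np.sqrt((tc @ tc) * (Xc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcorr = np.where(denom > 0, Xc.T @ tc / denom, np.nan)
    cols = Xf.columns
    ao = len(t_orth)
    return OplsModel(
        t=pd.Series(t, index=Xf.index, name="t"),
        p=pd.Series(p, index=cols, name="p"),
        w=pd.Series(w, index=cols, name="w"),
        c=c,
        t_orth=pd.DataFrame(np.column_stack(t_orth) if ao else np.empty((len(t), 0)),
                            index=Xf.index, columns=[f"to{i+1}" for i in range(ao)]),
        p_orth=pd.DataFrame(np.column_stack(p_orth) if ao else np.empty((len(cols), 0)),
                            index=cols, columns=[f"po{i+1}" for i in range(ao)]),
        w_orth=pd.DataFrame(np.column_stack(w_orth) if ao else np.empty((len(cols), 0)),
                            index=cols, columns=[f"wo{i+1}" for i in range(ao)]),
        pcorr=pd.Series(pcorr, index=cols, name="pcorr"),
        r2x_pred=r2x_pred, r2x_orth=r2x_orth, r2y_cum=r2y,
        scaling=spec, y_mean=y_mean, y_scale=y_scale, n_orth=ao, classes=cls,
    )


def fit_oplsda(X, y_class, n_orth: int = 1,
               scaling: "ScalingSpec | ScalingMode | str" = ScalingMode.UV,
               positive_class=None) -> OplsModel:
    """Two-class OPLS-DA: the response is a centered class dummy.

    ``positive_class`` gets dummy value 1 (defaults to the lexicographically
    larger label); positive p(corr) then means "more abundant in the
    positive class".
    """
    labels = pd.Series(y_class)
    uniq = sorted(labels.unique(), key=str)
    if len(uniq) != 2:
        raise ValueError(f"OPLS-DA requires exactly 2 classes, got {uniq}")
    if positive_class is None:
        positive_class = uniq[1]
    if positive_class not in uniq:
        raise ValueError(f"positive_class {positive_class!r} not among labels {uniq}")
    negative_class = uniq[0] if positive_class == uniq[1] else uniq[1]
    return fit_opls(X, labels.to_numpy(), n_orth=n_orth, scaling=scaling,
                    classes=(negative_class, positive_class))


def predict_scores(model: OplsModel, X_new) -> pd.Series:
    """Predictive score of new rows: orthogonal components removed first."""
    Xf = X_new if isinstance(X_new, pd.DataFrame) else pd.DataFrame(
        np.asarray(X_new, dtype=float), columns=model.w.index)
    if list(Xf.columns) != list(model.w.index):
        raise ValueError("X_new columns do not match the fitted model")
    Xs, _ = scale_matrix(Xf, model.scaling)
    E = Xs.to_numpy(dtype=float)
    for a in range(model.n_orth):
        w_o = model.w_orth.iloc[:, a].to_numpy()
        p_o = model.p_orth.iloc[:, a].to_numpy()
        t_o = E @ w_o
        E = E - np.outer(t_o, p_o)
    t = E @ model.w.to_numpy()
    return pd.Series(t, index=Xf.index, name="t")


def predict_response(model: OplsModel, X_new) -> pd.Series:
    """Predicted response on the original y scale."""
    t = predict_scores(model, X_new)
    return t * model.c * model.y_scale + model.y_mean


def stratified_folds(labels: pd.Series, folds: int,
                     seed: int | None = None) -> pd.Series:
    """Round-robin fold assignment within each class, by input order.

    Guarantees both classes in every training split whenever each class has
    at least 2 members.  Empty folds (more folds than members of a class on
    both sides) are renumbered away, so the returned labels are contiguous.
    """
    labels = pd.Series(labels)
    order = np.arange(len(labels))
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(labels))
    fold = pd.Series(index=labels.index, dtype=int)
    for cls in sorted(labels.unique(), key=str):
        members = [labels.index[i] for i in order if labels.iloc[i] == cls]
        for j, sid in enumerate(members):
            fold.loc[sid] = j % folds
    present = sorted(fold.unique())
    remap = {f: i for i, f in enumerate(present)}
    return fold.map(remap)


def crossvalidate_jackknife(X, y_class, folds: int = 7, n_orth: int = 1,
                            scaling: "ScalingSpec | ScalingMode | str" = ScalingMode.UV,
                            positive_class=None, seed: int | None = None,
                            full_model: OplsModel | None = None,
                            fold_labels: pd.Series | None = None):
    """Sevenfold cross-validation of an OPLS-DA model with jackknifed p(corr).

    One sub-model is fitted per cross-validation group, excluding that
    group.  Q2 pools the class-dummy PRESS over groups; the jackknife
    standard error of each p(corr) is taken over the sub-model estimates
    after sign-aligning every sub-model's predictive score with the full
    model (scores carry an arbitrary sign, and an accidental flip would
    inflate the spread).
    """
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    labels = pd.Series(y_class)
    labels.index = Xf.index
    if full_model is None:
        full_model = fit_oplsda(Xf, labels, n_orth=n_orth, scaling=scaling,
                                positive_class=positive_class)
    pos = full_model.classes[1]
    if fold_labels is not None:
        fold = pd.Series(fold_labels).astype(int)
        fold.index = Xf.index
    else:
        fold = stratified_folds(labels, folds, seed=seed)
    n_groups = int(fold.max()) + 1
    press = 0.0
    ss = 0.0
    sub_pcorr = []
    for g in range(n_groups):
        train = fold.index[fold != g]
        test = fold.index[fold == g]
        train_labels = labels.loc[train]
        if train_labels.nunique() < 2:
            raise ValueError(
                "a cross-validation training split contains one class only; "
                "use stratified fold assignment or fewer folds")
        sub = fit_oplsda(Xf.loc[train], train_labels, n_orth=n_orth,
                         scaling=scaling if isinstance(scaling, (ScalingMode, str))
                         else ScalingSpec(mode=scaling.mode),
                         positive_class=pos)
        # sign-align with the full model's predictive score on the training rows
        ref = full_model.t.loc[train].to_numpy()
        if float(sub.t.to_numpy() @ ref) < 0:
            sub_pc = -sub.pcorr
        else:
            sub_pc = sub.pcorr
        sub_pcorr.append(sub_pc)
        y_test = np.where(labels.loc[test].to_numpy() == pos, 1.0, 0.0)
        y_hat = predict_response(sub, Xf.loc[test]).to_numpy()
        press += float(((y_test - y_hat) ** 2).sum())
        ss += float(((y_test - sub.y_mean) ** 2).sum())
    if ss == 0:
        raise ValueError("zero-variance response in cross-validation")
    q2 = 1.0 - press / ss
    theta = pd.DataFrame(sub_pcorr,
                         index=[f"cv{g+1}" for g in range(n_groups)])
    mean = theta.mean(axis=0)
    se = np.sqrt((n_groups - 1) / n_groups * ((theta - mean) ** 2).sum(axis=0))
    return CvResult(q2=q2, submodel_pcorr=theta,
                    jackknife_se=se.rename("jackknife_se"), n_groups=n_groups)


def jackknife_se(estimates) -> float:
    """Delete-one-group jackknife SE of a set of N sub-model estimates."""
    v = np.asarray(estimates, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("jackknife needs at least 2 estimates")
    return float(np.sqrt((n - 1) / n * ((v - v.mean()) ** 2).sum()))


def ci_from_se(se, N: int, alpha: float = 0.05):
    """Confidence-interval half-width: t(1 - alpha/2, N - 1) * SE."""
    if N < 2:
        raise ValueError("N must be at least 2 for a t-based interval")
    se_arr = np.asarray(se, dtype=float)
    if (se_arr < 0).any():
        raise ValueError("standard errors must be nonnegative")
    mult = float(stats.t.ppf(1.0 - alpha / 2.0, N - 1))
    out = mult * se_arr
    if isinstance(se, pd.Series):
        return pd.Series(out, index=se.index, name="ci")
    if np.isscalar(se) or out.ndim == 0:
        return float(out)
    return out


def run_order_effect(X, run_order,
                     scaling: "ScalingSpec | ScalingMode | str" = ScalingMode.UV):
    """Instrument-drift diagnostic: percent of X variation tied to run order.

    Fits a 1 + 1 OPLS model with all metabolite signals as X and the sample
    injection order as the (continuous) response, and reports the predictive
    component's percent of X variation.  Large values flag a batch whose
    data are dominated by sensitivity drift.
    """
    ro = np.asarray(run_order, dtype=float)
    if len(np.unique(ro)) != len(ro):
        raise ValueError("run_order values must be distinct")
    if np.ptp(ro) == 0:
        raise ValueError("run_order is constant")
    model = fit_opls(X, ro, n_orth=1, scaling=scaling)
    return model.r2x_pred_percent, model


def fit_batch(X, y_class, batch_id=None, folds: int = 7, n_orth: int = 1,
              scaling: "ScalingSpec | ScalingMode | str" = ScalingMode.UV,
              positive_class=None, alpha: float = 0.05,
              seed: int | None = None) -> BatchResult:
    """Fit, cross-validate and jackknife one batch's OPLS-DA model."""
    model = fit_oplsda(X, y_class, n_orth=n_orth, scaling=scaling,
                       positive_class=positive_class)
    cv = crossvalidate_jackknife(X, y_class, folds=folds, n_orth=n_orth,
                                 scaling=scaling, positive_class=positive_class,
                                 seed=seed, full_model=model)
    model.q2 = cv.q2
    model.cv = cv
    return BatchResult(batch_id=batch_id, pcorr=model.pcorr,
                       jackknife_se=cv.jackknife_se, n_cv_groups=cv.n_groups,
                       model=model, alpha=alpha)
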