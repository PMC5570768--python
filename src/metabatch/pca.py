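"""NIPALS principal component analysis with missing-value tolerance.

Components are extracted sequentially with deflation; the regression steps
skip missing cells, so moderately incomplete descriptor tables can be
summarized without imputation.  Per-component explained variation (R2X) and
sevenfold cross-validated predictive ability (Q2) follow the conventions of
mainstream chemometrics software: Q2_a = 1 - PRESS_a / SS_{a-1}, pooled over
cross-validation groups, and a component is judged significant when its Q2
exceeds a small positive threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ScalingMode, ScalingSpec, scale_matrix

__all__ = ["PcaModel", "fit_pca", "q2_crossvalidate", "project", "assign_folds"]

#: NIPALS stops when the relative change of the score vector drops below this.
#: Power iteration slows as the eigenvalue ratio approaches 1 (noise-like
#: data), so the iteration cap is generous; per-iteration cost is tiny at
#: the matrix sizes this package targets.
NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 100_000

#: Default cap on the per-column missing fraction.
MISSING_CAP = 0.5

#: A component is retained when its cross-validated Q2 exceeds this.
Q2_THRESHOLD = 0.05


@dataclass
class PcaModel:
    """Fitted PCA: scores ``T`` (n x A), unit-norm loadings ``P`` (K x A)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    r2x_per_component: np.ndarray
    scaling: ScalingSpec
    q2_per_component: np.ndarray | None = None
    total_ss: float = field(default=np.nan, repr=False)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def assign_folds(n: int, folds: int, seed: int | None = None) -> np.ndarray:
    """Deterministic fold labels in ``0..folds-1``.

    Round-robin on input order by default (the "every Nth sample"
    convention); pass a seed for a reproducible shuffled assignment.
    """
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds the number of samples n={n}")
    labels = np.arange(n) % folds
    if seed is not None:
        rng = np.random.default_rng(seed)
        labels = labels[rng.permutation(n)]
    return labels


def _nipals_component(E: np.ndarray, mask: np.ndarray,
                      tol: float = NIPALS_TOL,
                      max_iter: int = NIPALS_MAX_ITER) -> tuple[np.ndarray, np.ndarray]:
    """One NIPALS component of ``E`` (missing cells flagged False in mask).

    Returns ``(t, p)`` with ``p`` unit-norm.  Regressions run over observed
    cells only.
    """
    Ez = np.where(mask, E, 0.0)
    col_ss = (Ez ** 2).sum(axis=0)
    start = int(np.argmax(col_ss))
    t = Ez[:, start].astype(float).copy()
    if np.linalg.norm(t) == 0:
        t = np.where(mask.any(axis=1), 1.0, 0.0)
    complete = bool(mask.all())
    if complete:
        # complete data: the regressions reduce to plain matrix products
        for it in range(max_iter):
            p = Ez.T @ t
            norm_p = np.linalg.norm(p)
            if norm_p == 0:
                raise ValueError("NIPALS: loading vector degenerated to zero")
            p /= norm_p
            t_new = Ez @ p
            dt = np.linalg.norm(t_new - t)
            t = t_new
            if dt <= tol * max(np.linalg.norm(t), 1e-300):
                return t, p
        raise ValueError(
            f"NIPALS did not converge within {max_iter} iterations "
            f"(last relative change {dt / max(np.linalg.norm(t), 1e-300):.2e})"
        )
    for it in range(max_iter):
        # p_k = sum_i t_i x_ik / sum_i t_i^2   (observed cells)
        tw = np.where(mask, t[:, None], 0.0)
        denom_p = (tw ** 2).sum(axis=0)
        if np.all(denom_p == 0):
            raise ValueError("NIPALS: score vector degenerated to zero")
        p = (tw * Ez).sum(axis=0) / np.where(denom_p == 0, 1.0, denom_p)
        norm_p = np.linalg.norm(p)
        if norm_p == 0:
            raise ValueError("NIPALS: loading vector degenerated to zero")
        p /= norm_p
        # t_i = sum_k x_ik p_k / sum_k p_k^2   (observed cells)
        pw = np.where(mask, p[None, :], 0.0)
        denom_t = (pw ** 2).sum(axis=1)
        t_new = (Ez * pw).sum(axis=1) / np.where(denom_t == 0, 1.0, denom_t)
        dt = np.linalg.norm(t_new - t)
        t = t_new
        if dt <= tol * max(np.linalg.norm(t), 1e-300):
            return t, p
    raise ValueError(
        f"NIPALS did not converge within {max_iter} iterations "
        f"(last relative change {dt / max(np.linalg.norm(t), 1e-300):.2e})"
    )


def _check_matrix(X: pd.DataFrame, missing_cap: float) -> None:
    n, k = X.shape
    if n < 3:
        raise ValueError("PCA requires at least 3 samples")
    vals = X.to_numpy(dtype=float)
    frac_missing = np.isnan(vals).mean(axis=0)
    if (frac_missing >= 1.0).any():
        bad = X.columns[frac_missing >= 1.0].tolist()
        raise ValueError(f"all-missing column(s): {bad}")
    if (frac_missing > missing_cap).any():
        bad = X.columns[frac_missing > missing_cap].tolist()
        raise ValueError(
            f"column(s) exceed the missing-fraction cap of {missing_cap}: {bad}"
        )


def fit_pca(X, n_components: int = 2,
            scaling: "ScalingSpec | ScalingMode | str" = ScalingMode.UV,
            select: str = "fixed",
            folds: int = 7,
            q2_threshold: float = Q2_THRESHOLD,
            seed: int | None = None,
            missing_cap: float = MISSING_CAP,
            tol: float = NIPALS_TOL,
            max_iter: int = NIPALS_MAX_ITER) -> PcaModel:
    """Fit a NIPALS PCA after applying the requested column scaling.

    Parameters
    ----------
    n_components
        Maximum number of components.
    select
        ``"fixed"`` extracts exactly ``n_components`` (stopping early only if
        the residual is numerically exhausted); ``"q2"`` additionally stops
        as soon as a component's sevenfold cross-validated Q2 falls at or
        below ``q2_threshold``, mirroring the usual chemometrics rule.
    """
    if n_components < 1:
        raise ValueError("n_components must be positive")
    if select not in ("fixed", "q2"):
        raise ValueError("select must be 'fixed' or 'q2'")
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    _check_matrix(Xf, missing_cap)
    Xs, spec = scale_matrix(Xf, scaling)
    vals = Xs.to_numpy(dtype=float)
    mask = ~np.isnan(vals)
    total_ss = float(np.nansum(vals ** 2))
    if total_ss == 0:
        raise ValueError("matrix has no variation after scaling")

    q2 = None
    if select == "q2":
        q2 = q2_crossvalidate(Xf, n_components=n_components,
                              scaling=ScalingSpec(mode=spec.mode), folds=folds,
                              seed=seed, missing_cap=missing_cap)

    E = np.where(mask, vals, 0.0)
    ts, ps, r2x = [], [], []
    for a in range(n_components):
        if select == "q2" and (a >= len(q2) or q2[a] <= q2_threshold):
            break
        resid_ss = float((E ** 2).sum())
        if resid_ss <= 1e-12 * total_ss:
            break  # residual exhausted (exact low rank)
        try:
            t, p = _nipals_component(E, mask, tol=tol, max_iter=max_iter)
        except ValueError as exc:
            raise ValueError(f"component {a + 1}: {exc}") from exc
        comp_ss = float((t ** 2).sum() * (p ** 2).sum())
        ts.append(t)
        ps.append(p)
        r2x.append(comp_ss / total_ss)
        E = E - np.where(mask, np.outer(t, p), 0.0)
    if not ts:
        raise ValueError("no component met the significance rule")
    T = pd.DataFrame(np.column_stack(ts), index=Xf.index,
                     columns=[f"t{a + 1}" for a in range(len(ts))])
    P = pd.DataFrame(np.column_stack(ps), index=Xf.columns,
                     columns=[f"p{a + 1}" for a in range(len(ps))])
    return PcaModel(scores=T, loadings=P, r2x_per_component=np.asarray(r2x),
                    scaling=spec, total_ss=total_ss,
                    q2_per_component=None if q2 is None else q2[: len(ts)])


def _predict_row_cells(e_row: np.ndarray, obs: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Predict each observed cell of a held-out row from the *other* cells.

    For cell k, the score is regressed on the loading using all observed
    cells except k, then the cell is reconstructed as t^(-k) * p_k.  Leaving
    the target cell out of its own score estimate removes the self-prediction
    bias that would otherwise make pure noise appear predictable.
    """
    pw = np.where(obs, p, 0.0)
    num_full = float((e_row[obs] * p[obs]).sum())
    den_full = float((pw ** 2).sum())
    pred = np.full_like(e_row, np.nan)
    for k in np.nonzero(obs)[0]:
        den = den_full - p[k] ** 2
        if den <= 0:
            continue
        t_minus = (num_full - e_row[k] * p[k]) / den
        pred[k] = t_minus * p[k]
    return pred


def q2_crossvalidate(X, n_components: int = 2,
                     scaling: "ScalingSpec | ScalingMode | str" = ScalingMode.UV,
                     folds: int = 7, seed: int | None = None,
                     missing_cap: float = MISSING_CAP) -> np.ndarray:
    """Per-component Q2 from row-wise sevenfold cross-validation.

    Rows are assigned to groups round-robin (seedable shuffle optional).  For
    each group a PCA is refitted on the remaining rows (scaling refitted on
    the training rows as well); each held-out cell is predicted from the
    other cells of its row via the training loadings.  Q2_a pools
    1 - PRESS_a / SS_{a-1} over groups.
    """
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    _check_matrix(Xf, missing_cap)
    n = Xf.shape[0]
    labels = assign_folds(n, folds, seed=seed)
    if isinstance(scaling, (ScalingMode, str)):
        base_mode = ScalingMode(str(scaling).upper() if not isinstance(scaling, ScalingMode) else scaling)
    else:
        base_mode = scaling.mode
    press = np.zeros(n_components)
    ss = np.zeros(n_components)
    for g in range(folds):
        train = Xf.iloc[labels != g]
        test = Xf.iloc[labels == g]
        if train.shape[0] < 3 or test.shape[0] == 0:
            raise ValueError("cross-validation fold too small; reduce folds")
        try:
            model = fit_pca(train, n_components=n_components,
                            scaling=ScalingSpec(mode=base_mode), select="fixed",
                            missing_cap=1.0)
        except ValueError as exc:
            raise ValueError(f"cross-validation fold {g}: {exc}") from exc
        test_s, _ = scale_matrix(test, model.scaling)
        E = test_s.to_numpy(dtype=float)
        obs = ~np.isnan(E)
        P = model.loadings.to_numpy()
        for a in range(min(n_components, P.shape[1])):
            p = P[:, a]
            for i in range(E.shape[0]):
                row = np.where(obs[i], E[i], 0.0)
                ss[a] += float((row ** 2).sum())
                pred = _predict_row_cells(row, obs[i], p)
                ok = obs[i] & ~np.isnan(pred)
                press[a] += float(((row[ok] - pred[ok]) ** 2).sum())
                # deflate the held-out row with the full-row score
                den = float((p[obs[i]] ** 2).sum())
                if den > 0:
                    t_full = float((row[obs[i]] * p[obs[i]]).sum()) / den
                    E[i] = np.where(obs[i], E[i] - t_full * p, E[i])
    if np.any(ss == 0):
        raise ValueError("zero-variance reference in cross-validation (degenerate data)")
    return 1.0 - press / ss


def project(model: PcaModel, X_new) -> pd.DataFrame:
    """Score new rows with a fitted model (stored scaling replayed).

    Missing cells are skipped in the score regressions, as during fitting.
    """
    Xf = X_new if isinstance(X_new, pd.DataFrame) else pd.DataFrame(
        np.asarray(X_new, dtype=float), columns=model.loadings.index)
    if list(Xf.columns) != list(model.loadings.index):
        raise ValueError("X_new columns do not match the fitted model")
    Xs, _ = scale_matrix(Xf, model.scaling)
    E = Xs.to_numpy(dtype=float)
    obs = ~np.isnan(E)
    E = np.where(obs, E, 0.0)
    P = model.loadings.to_numpy()
    scores = np.zeros((E.shape[0], P.shape[1]))
    for a in range(P.shape[1]):
        p = P[:, a]
        pw = np.where(obs, p[None, :], 0.0)
        den = (pw ** 2).sum(axis=1)
        t = (E * pw).sum(axis=1) / np.where(den == 0, 1.0, den)
        scores[:, a] = t
        E = E - np.where(obs, np.outer(t, p), 0.0)
    return pd.DataFrame(scores, index=Xf.index, columns=list(model.scores.columns))
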