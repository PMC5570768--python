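"""Seeded synthetic cohorts and multi-batch peak-area matrices.

The generator emulates the statistical structure the pipeline is built for:

* a descriptor table driven by a low-dimensional latent structure, so that
  PCA-based multivariate characterization is meaningful;
* log-normal peak areas with planted two-class (case versus control) effects
  on selected metabolites, per-batch location/scale effects, within-batch
  run-order drift, and a per-sample multiplicative injection factor applied
  to every channel -- internal standards included, which is exactly what IS
  normalization exploits;
* IS channels that carry injection and instrument effects but no biology.

Default dimensions mirror a mid-size clinical metabolomics study: five
disease subgroups plus controls, 23 samples per group, 205 descriptors,
73 identified metabolites, 11 internal standards, four analytical batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doe_select import DescriptorTable
from .preprocess import PeakAreaMatrix

__all__ = [
    "SimulationConfig",
    "simulate_descriptors",
    "simulate_peak_areas",
    "ground_truth",
    "default_effects",
]

DEFAULT_GROUPS = ("ANA_neg", "aPL", "SmRNP", "SSA_SSB", "other", "control")


def default_effects(k_metabolites: int, n_effects: int = 8,
                    magnitude: float = 1.5) -> np.ndarray:
    """Planted standardized effects: the first ``n_effects`` metabolites get
    alternating +/- ``magnitude`` (in units of the residual log-scale sd),
    the rest are null."""
    eff = np.zeros(k_metabolites)
    for i in range(min(n_effects, k_metabolites)):
        eff[i] = magnitude if i % 2 == 0 else -magnitude
    return eff


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; every field has a study-scale default."""

    n_per_group: int = 23
    groups: tuple = DEFAULT_GROUPS
    control_group: str = "control"
    n_descriptors: int = 205
    k_metabolites: int = 73
    n_is: int = 11
    n_batches: int = 4
    latent_dims: int = 2
    #: standardized case-vs-control effect per metabolite (length k_metabolites)
    effect_sizes: np.ndarray | None = None
    #: residual biological + analytical log-scale noise sd
    noise_sd: float = 0.3
    #: per-batch, per-metabolite additive log-scale shift sd
    batch_shift_sd: float = 0.3
    #: per-batch multiplicative distortion of the biological signal
    batch_scale_sd: float = 0.1
    #: sd of the per-batch common drift slope (log scale over a full run)
    drift_slope_sd: float = 0.2
    #: sd of log injection factor (per-sample multiplicative, all channels)
    injection_factor_sd: float = 0.2
    #: descriptor noise sd relative to unit-variance latent factors
    descriptor_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "batch_shift_sd", "batch_scale_sd",
                     "drift_slope_sd", "injection_factor_sd",
                     "descriptor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.effect_sizes is None:
            self.effect_sizes = default_effects(self.k_metabolites)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if len(self.effect_sizes) != self.k_metabolites:
            raise ValueError("effect_sizes length must equal k_metabolites")
        if self.control_group not in self.groups:
            raise ValueError("control_group must be one of groups")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1:03d}" for g in self.groups
                for i in range(self.n_per_group)]

    @property
    def metabolite_ids(self) -> list[str]:
        return [f"met_{k + 1:03d}" for k in range(self.k_metabolites)]

    @property
    def is_ids(self) -> list[str]:
        return [f"IS_{j + 1:02d}" for j in range(self.n_is)]

    def group_labels(self) -> pd.Series:
        return pd.Series([g for g in self.groups
                          for _ in range(self.n_per_group)],
                         index=self.sample_ids, name="group")


def simulate_descriptors(cfg: SimulationConfig) -> DescriptorTable:
    """Clinical/personal descriptor table with latent 2-factor structure.

    Each sample draws ``latent_dims`` standard-normal factors (plus a mild
    group-dependent location shift); descriptors are random linear reads of
    the factors plus noise, so a two-component PCA recovers most of the
    systematic variation.
    """
    if cfg.n_per_group < 4:
        raise ValueError("n_per_group must be at least 4")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_group * len(cfg.groups)
    Z = rng.standard_normal((n, cfg.latent_dims))
    # group-level location offsets on the latent factors (mild heterogeneity)
    offsets = rng.normal(0.0, 0.5, size=(len(cfg.groups), cfg.latent_dims))
    Z += np.repeat(offsets, cfg.n_per_group, axis=0)
    # decaying factor scales so PCA component order is well defined
    scales = np.array([2.0 * 0.7 ** d for d in range(cfg.latent_dims)])
    L = rng.standard_normal((cfg.latent_dims, cfg.n_descriptors))
    X = (Z * scales) @ L + rng.normal(0.0, cfg.descriptor_noise_sd,
                                      size=(n, cfg.n_descriptors))
    data = pd.DataFrame(X, index=cfg.sample_ids,
                        columns=[f"desc_{j + 1:03d}" for j in range(cfg.n_descriptors)])
    return DescriptorTable(data=data, group=cfg.group_labels())


def _default_batches(cfg: SimulationConfig) -> pd.Series:
    """Round-robin batch assignment within each group (balanced fallback)."""
    labels = []
    for _ in cfg.groups:
        labels.extend([(i % cfg.n_batches) + 1 for i in range(cfg.n_per_group)])
    return pd.Series(labels, index=cfg.sample_ids, name="batch")


def simulate_peak_areas(cfg: SimulationConfig,
                        batch_assignment: pd.Series | None = None,
                        drift_slopes: dict | None = None) -> PeakAreaMatrix:
    """Multi-batch peak-area matrix with planted effects and nuisances.

    The log-scale model for metabolite k of sample i in batch b at run
    position r is::

        log x_ik = baseline_k + effect_k * case_i * noise_sd
                   + shift_bk + scale_bk * z_i
                   + slope_b * d_k * r_scaled + eps_ik

    exponentiated and finally multiplied by the sample's injection factor.
    ``case_i`` is 1 for every non-control group, so the planted contrast is
    case-versus-control with effects standardized against ``noise_sd``.
    IS channels receive baseline, drift, noise and injection factor only.

    ``drift_slopes`` optionally fixes the per-batch drift slope (overriding
    the random draw), e.g. ``{4: 0.5}`` to plant drift in batch 4 only.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ids = cfg.sample_ids
    group = cfg.group_labels()
    batch = (_default_batches(cfg) if batch_assignment is None
             else pd.Series(batch_assignment).reindex(ids))
    if batch.isna().any():
        missing = batch.index[batch.isna()].tolist()
        raise ValueError(f"batch assignment missing for samples: {missing}")
    n = len(ids)
    K, J = cfg.k_metabolites, cfg.n_is

    baseline = rng.normal(np.log(1e5), 0.5, size=K)
    baseline_is = rng.normal(np.log(1e6), 0.3, size=J)
    case = (group != cfg.control_group).to_numpy(dtype=float)
    z = rng.standard_normal(n)                      # per-sample biological latent
    batches = sorted(batch.unique())
    shift = {b: rng.normal(0.0, cfg.batch_shift_sd, size=K) for b in batches}
    scale = {b: rng.normal(0.0, cfg.batch_scale_sd, size=K) for b in batches}
    slope = {b: rng.normal(0.0, cfg.drift_slope_sd) for b in batches}
    if drift_slopes:
        slope.update(drift_slopes)
    d_k = rng.normal(1.0, 0.3, size=K)              # per-metabolite drift sensitivity
    # IS compounds are spiked, chemically stable species: they track
    # sensitivity drift more weakly than the analytes, so t1 normalization
    # removes only part of the drift (as observed in practice)
    d_is = rng.normal(0.4, 0.15, size=J)
    inj = np.exp(rng.normal(0.0, cfg.injection_factor_sd, size=n))

    run_order = pd.Series(index=ids, dtype=int, name="run_order")
    logx = np.empty((n, K))
    logis = np.empty((n, J))
    pos = {i: ii for ii, i in enumerate(ids)}
    for b in batches:
        members = [i for i in ids if batch.loc[i] == b]
        order = rng.permutation(len(members))       # injection sequence within batch
        for rank, m in enumerate(order):
            run_order.loc[members[m]] = rank + 1
        nb = len(members)
        for m in members:
            i = pos[m]
            r = (run_order.loc[m] - (nb + 1) / 2.0) / max(nb - 1, 1)
            logx[i] = (baseline
                       + cfg.effect_sizes * case[i] * cfg.noise_sd
                       + shift[b] + scale[b] * z[i]
                       + slope[b] * d_k * r
                       + rng.normal(0.0, cfg.noise_sd, size=K))
            logis[i] = (baseline_is
                        + slope[b] * d_is * r
                        + rng.normal(0.0, cfg.noise_sd / 3.0, size=J))
    data = pd.DataFrame(np.exp(np.hstack([logx, logis])) * inj[:, None],
                        index=ids, columns=cfg.metabolite_ids + cfg.is_ids)
    return PeakAreaMatrix(data=data, is_columns=cfg.is_ids, group=group,
                          batch=batch, run_order=run_order)


def ground_truth(cfg: SimulationConfig) -> pd.DataFrame:
    """Planted per-metabolite truth table for recovery scoring."""
    eff = cfg.effect_sizes
    return pd.DataFrame({
        "effect": eff,
        "direction": np.sign(eff).astype(int),
        "is_null": eff == 0.0,
    }, index=cfg.metabolite_ids)
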