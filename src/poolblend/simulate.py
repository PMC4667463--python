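"""Synthetic pooled-expression experiments with full ground truth.

The generator reproduces the stochastic structure of a pooled one-color
experiment.  Per transcript ``g``:

* a mean expression level ``mu_g ~ U[8, 14]`` (log2 scale);
* a randomly chosen subset of transcripts is differentially expressed,
  with a treatment shift drawn from ``U[0.5, 1.5]`` times a random sign,
  applied to the second treatment group;
* individual expressions ``x ~ N(mu, sigma_b^2)`` on the log scale;
* a pool of ``gamma`` individuals with aliquot weights ``w`` measures the
  pooled signal ``log(w' exp(x))`` (exact, not the linear approximation);
* weights are Dirichlet with concentration ``a_i = 1/sigma_z^2 - 1/gamma``
  for blending-affected transcripts — symmetric with mean ``1/gamma`` and
  variance exactly ``(gamma-1)/gamma^3 * sigma_z^2`` — and exactly uniform
  otherwise;
* technical errors ``N(0, sigma_t^2)`` are added independently per
  measurement; technical replicates of one mixture share the pooled value
  and differ only through those errors.  Individuals re-used between
  single measurements and pools keep one expression draw.

On the model scale the implied variance components are
``sigma1^2 = exp(sigma_b^2) - 1`` and
``sigma2^2 = (exp(sigma_b^2) - 1) * sigma_z^2`` (with the blending term
scaled by ``(gamma-1)/gamma^2``), which is what the estimator-consistency
checks assert.

The default variance calibration :data:`MOUSE_CALIBRATION`
(sigma_b^2 = 0.103, sigma_t^2 = 0.017, sigma_z^2 = 2.7) reproduces the
mean variance-component estimates of the mouse ovary experiment on the
model scale: sigma1^2 = e^0.103 - 1 = 0.109, sigma_e^2 = 0.017 and
sigma2^2 = 0.109 * 2.7 = 0.295.  It is used both by the scenario runs
s1/s2/s3 (null and power behaviour of the RLRT) and by the repeated
model-comparison (DE detection) study; :data:`MOUSE_CALIBRATION_ALT`
(sigma_b^2 = 0.094) is a nearby variant with a slightly smaller
biological variance.

Randomness is split into one child stream per transcript (plus one for
the transcript-level draws), so results are bit-reproducible and
independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .design import PoolDesign
from .designs import mouse_design

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "MOUSE_CALIBRATION",
    "MOUSE_CALIBRATION_ALT",
    "draw_weights",
    "pool_signal",
    "simulate_experiment",
    "scenario",
]

#: default calibration, matching the mouse-data mean variance components
#: (sigma1^2 = 0.109, sigma2^2 = 0.295, sigma_e^2 = 0.017 on the model scale)
MOUSE_CALIBRATION = {"sigma_b2": 0.103, "sigma_t2": 0.017, "sigma_z2": 2.7}

#: nearby variant with a slightly smaller biological variance
MOUSE_CALIBRATION_ALT = {"sigma_b2": 0.094, "sigma_t2": 0.017, "sigma_z2": 2.7}


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic experiment.

    ``blending_fraction`` is the proportion of transcripts affected by
    imperfect blending (scenarios s1/s2/s3 use 0, 1/3 and 1).
    ``weights_mode`` controls whether aliquot weights are redrawn per
    transcript (matching the per-transcript random-effect model being
    validated; the default) or drawn once per physical mixture and shared
    by all transcripts.
    """

    design: PoolDesign = field(default_factory=mouse_design)
    m: int = 9000
    de_fraction: float = 1.0 / 3.0
    effect_low: float = 0.5
    effect_high: float = 1.5
    mean_low: float = 8.0
    mean_high: float = 14.0
    sigma_b2: float = MOUSE_CALIBRATION["sigma_b2"]
    sigma_t2: float = MOUSE_CALIBRATION["sigma_t2"]
    sigma_z2: float = MOUSE_CALIBRATION["sigma_z2"]
    blending_fraction: float = 1.0
    weights_mode: str = "per-transcript"
    seed: int | None = None
    keep_decomposition: bool = True

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.blending_fraction <= 1.0:
            raise ValueError("blending_fraction must lie in [0, 1]")
        if min(self.sigma_b2, self.sigma_t2, self.sigma_z2) < 0:
            raise ValueError("variances must be nonnegative")
        if self.weights_mode not in ("per-transcript", "per-pool"):
            raise ValueError(f"unknown weights_mode {self.weights_mode!r}")
        if self.blending_fraction > 0 and self.sigma_z2 > 0:
            for pool in self.design.pools:
                if pool.size >= 2 and self.sigma_z2 >= pool.size:
                    raise ValueError(
                        f"sigma_z2 = {self.sigma_z2} is not admissible for pool "
                        f"'{pool.id}' of size {pool.size}: the Dirichlet "
                        "concentrations a_i = 1/sigma_z2 - 1/gamma must be > 0"
                    )


@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment.

    The per-measurement decomposition satisfies, exactly,

        observation = mu (+ effect) + u1 + log_bias + u2 + tech_error

    with ``u1`` the deviation of the sample's mean individual effect,
    ``u2 = log(w'exp(x)) - log(mean(exp(x)))`` the imperfect-blending
    deviation (zero for uniform weights) and ``log_bias`` the Jensen gap
    ``log(mean(exp(x))) - mean(x)``.
    """

    transcript_ids: np.ndarray
    mu: np.ndarray
    is_de: np.ndarray
    effect: np.ndarray
    is_blended: np.ndarray
    group2_level: str
    u1: np.ndarray | None = None
    u2: np.ndarray | None = None
    log_bias: np.ndarray | None = None
    tech_error: np.ndarray | None = None
    weights: dict | None = None  # pool id -> (m, gamma) weight array


def draw_weights(gamma: int, sigma_z2: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Aliquot proportions of one pool of size ``gamma``.

    Symmetric Dirichlet with concentration ``a = 1/sigma_z2 - 1/gamma``:
    mean ``1/gamma`` and variance ``(gamma-1)/gamma^3 * sigma_z2`` per
    component.  ``sigma_z2 = 0`` returns exactly uniform weights; values
    ``>= gamma`` are inadmissible (the concentration must be positive).
    """
    if gamma < 2:
        raise ValueError("weights are only defined for pools of size >= 2")
    if sigma_z2 == 0.0:
        return np.full(gamma, 1.0 / gamma)
    if not 0.0 < sigma_z2 < gamma:
        raise ValueError(
            f"sigma_z2 must lie in [0, gamma) = [0, {gamma}); the Dirichlet "
            "concentrations a_i = 1/sigma_z2 - 1/gamma must be positive")
    a = 1.0 / sigma_z2 - 1.0 / gamma
    return rng.dirichlet(np.full(gamma, a))


def pool_signal(x: np.ndarray, w: np.ndarray) -> float:
    """Pooled log-expression ``log(w' exp(x))`` (overflow-safe).

    By Jensen's inequality the result is at least ``w'x``; a constant
    vector maps to that constant for any valid weights.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ValueError(f"x and w must match, got {x.shape} vs {w.shape}")
    return float(logsumexp(x, b=w))


def scenario(name: str, base: SimulationConfig | None = None) -> SimulationConfig:
    """Named blending scenarios: s1 (none), s2 (one third), s3 (all affected)."""
    fractions = {"s1": 0.0, "s2": 1.0 / 3.0, "s3": 1.0}
    if name not in fractions:
        raise ValueError(f"unknown scenario {name!r}; expected one of "
                         f"{sorted(fractions)}")
    base = base if base is not None else SimulationConfig()
    return replace(base, blending_fraction=fractions[name])



def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, PoolDesign, SimulationTruth]:
    """Generate one experiment: expression matrix, design and ground truth."""
    cfg.validate()
    design = cfg.design
    if design.platform != "one-color":
        raise ValueError("the generator emulates one-color designs")
    n = len(design.measurements)
    individuals = [ind.id for ind in design.individuals]
    ind_index = {iid: k for k, iid in enumerate(individuals)}
    levels = design.treatment_levels
    if len(levels) != 2:
        raise ValueError("the generator needs exactly two treatment groups")
    group2 = levels[1]
    ind_group2 = np.array(
        [ind.treatment == group2 for ind in design.individuals])

    pools = [p for p in design.pools]
    pool_members = {p.id: np.array([ind_index[i] for i in p.members])
                    for p in pools}
    blend_pools = [p.id for p in pools if p.size >= 2]
    meas_sample = [m.sample for m in design.measurements]

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.m + 1)
    g_rng = np.random.default_rng(children[0])

    mu = g_rng.uniform(cfg.mean_low, cfg.mean_high, cfg.m)
    n_de = int(round(cfg.de_fraction * cfg.m))
    de_idx = g_rng.permutation(cfg.m)[:n_de]
    is_de = np.zeros(cfg.m, dtype=bool)
    is_de[de_idx] = True
    effect = np.zeros(cfg.m)
    effect[de_idx] = (g_rng.uniform(cfg.effect_low, cfg.effect_high, n_de)
                      * g_rng.choice([-1.0, 1.0], n_de))
    n_blend = int(round(cfg.blending_fraction * cfg.m))
    blend_idx = g_rng.permutation(cfg.m)[:n_blend]
    is_blended = np.zeros(cfg.m, dtype=bool)
    is_blended[blend_idx] = True

    # static index structure shared by every transcript
    n_ind = len(individuals)
    n_bp = len(blend_pools)
    bp_pos = {pid: k for k, pid in enumerate(blend_pools)}
    gamma_groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for gam in sorted({len(pool_members[pid]) for pid in blend_pools}):
        pos = np.array([bp_pos[pid] for pid in blend_pools
                        if len(pool_members[pid]) == gam])
        mm = np.stack([pool_members[pid] for pid in blend_pools
                       if len(pool_members[pid]) == gam])
        gamma_groups[gam] = (pos, mm)
    pool_grp2 = np.array([bool(ind_group2[pool_members[pid][0]])
                          for pid in blend_pools])
    meas_is_single = np.array([pool_members[s].size == 1 for s in meas_sample])
    meas_ind = np.array([pool_members[s][0] if pool_members[s].size == 1 else 0
                         for s in meas_sample])
    meas_pool = np.array([bp_pos[s] if pool_members[s].size > 1 else 0
                          for s in meas_sample])
    single_pos = np.flatnonzero(meas_is_single)
    pool_pos = np.flatnonzero(~meas_is_single)

    shared_gamma_w: dict[int, np.ndarray] = {}
    if cfg.weights_mode == "per-pool":
        for gam, (pos, mm) in gamma_groups.items():
            if cfg.sigma_z2 > 0:
                shared_gamma_w[gam] = np.stack(
                    [draw_weights(gam, cfg.sigma_z2, g_rng) for _ in pos])
            else:
                shared_gamma_w[gam] = np.full((pos.size, gam), 1.0 / gam)

    Y = np.empty((cfg.m, n))
    keep = cfg.keep_decomposition
    u1_obs = np.empty((cfg.m, n)) if keep else None
    u2_obs = np.zeros((cfg.m, n)) if keep else None
    bias_obs = np.zeros((cfg.m, n)) if keep else None
    tech_obs = np.empty((cfg.m, n)) if keep else None
    weights_store = ({pid: np.empty((cfg.m, len(pool_members[pid])))
                      for pid in blend_pools} if keep else None)

    sd_b = float(np.sqrt(cfg.sigma_b2))
    sd_t = float(np.sqrt(cfg.sigma_t2))

    for g in range(cfg.m):
        rng = np.random.default_rng(children[g + 1])
        center = mu[g] + np.where(ind_group2, effect[g], 0.0)
        x = center + sd_b * rng.standard_normal(n_ind)
        pooled = np.empty(n_bp)
        xbar = np.empty(n_bp)
        bias = np.empty(n_bp)
        w_rows: dict[int, np.ndarray] = {}
        for gam, (pos, mm) in gamma_groups.items():
            xm = x[mm]  # (k, gamma)
            if is_blended[g] and cfg.sigma_z2 > 0:
                if shared_gamma_w:
                    Wg = shared_gamma_w[gam]
                else:
                    a = 1.0 / cfg.sigma_z2 - 1.0 / gam
                    draws = rng.standard_gamma(a, size=(pos.size, gam))
                    Wg = draws / draws.sum(axis=1, keepdims=True)
            else:
                Wg = np.full((pos.size, gam), 1.0 / gam)
            pooled[pos] = logsumexp(xm + np.log(Wg), axis=1)
            if keep:
                xbar[pos] = xm.mean(axis=1)
                bias[pos] = logsumexp(xm, axis=1) - np.log(gam) - xbar[pos]
                w_rows[gam] = Wg
        tech = sd_t * rng.standard_normal(n)
        base = np.empty(n)
        base[single_pos] = x[meas_ind[single_pos]]
        base[pool_pos] = pooled[meas_pool[pool_pos]]
        Y[g] = base + tech
        if keep:
            center_meas = mu[g] + np.where(ind_group2[meas_ind], effect[g], 0.0)
            u1_obs[g, single_pos] = (x[meas_ind[single_pos]]
                                     - center_meas[single_pos])
            pool_center = mu[g] + np.where(pool_grp2, effect[g], 0.0)
            u1_obs[g, pool_pos] = (xbar - pool_center)[meas_pool[pool_pos]]
            u2_obs[g, pool_pos] = (pooled - xbar - bias)[meas_pool[pool_pos]]
            bias_obs[g, pool_pos] = bias[meas_pool[pool_pos]]
            tech_obs[g] = tech
            for gam, (pos, mm) in gamma_groups.items():
                Wg = w_rows[gam]
                for k, pp in enumerate(pos):
                    weights_store[blend_pools[pp]][g] = Wg[k]

    ids = np.array([f"t{g + 1:05d}" for g in range(cfg.m)])
    expr = pd.DataFrame(Y, index=ids,
                        columns=[m.array for m in design.measurements])
    truth = SimulationTruth(
        transcript_ids=ids, mu=mu, is_de=is_de, effect=effect,
        is_blended=is_blended, group2_level=group2,
        u1=u1_obs, u2=u2_obs, log_bias=bias_obs, tech_error=tech_obs,
        weights=weights_store,
    )
    return expr, design, truth
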