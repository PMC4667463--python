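"""Experiment descriptions and mixed-model design matrices for pooled samples.

A pooled gene-expression experiment is described declaratively: the
individuals (each with a treatment label), the pools (physical RNA mixtures
of one or more individuals), and the measurements (which sample was
hybridized on which array/channel).  From such a description this module
realizes, per transcript, the matrices of the linear mixed model

    y = X beta + Z1 u1 + Z2 u2 + e,

where ``u1`` carries biological effects of samples (variance ``sigma1^2``
scaled by ``G1``), ``u2`` carries one blending effect per physical mixture
(variance ``sigma2^2`` scaled by ``G2``), and ``e`` is the residual
technical error.  The covariance of the observations is

    V(y) = Z1 G1 Z1' sigma1^2 + Z2 G2 Z2' sigma2^2 + I sigma_e^2.

A pool of ``gamma`` individuals has average biological variance
``sigma1^2 / gamma`` and a blending variance scaled by
``(gamma - 1) / gamma^2``; single individuals (``gamma = 1``) carry no
blending effect at all.

Two equivalent parameterizations of the biological term are offered:

``composition``
    one random effect per distinct sample composition (set of members),
    with ``G1[i, j] = |members_i & members_j| / (gamma_i * gamma_j)`` so
    that shared individuals between pools induce the correct covariance.
``individual``
    one effect per individually-resolved animal plus one composite effect
    per pool whose members never appear elsewhere; ``Z1`` rows carry the
    reciprocal pool size for resolved members.  This reproduces the
    conventional published layout for designs in which some pool members
    are also measured singly.

Both yield the identical marginal covariance contribution ``Z1 G1 Z1'``.

Two-color arrays are modeled on per-array differences ``M = log R - log G``:
each row of ``X``, ``Z1`` and ``Z2`` is the red-sample row minus the
green-sample row, and the intercept absorbs the dye effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Individual",
    "PoolSpec",
    "Measurement",
    "PoolDesign",
    "ModelMatrices",
    "VarianceComponents",
    "DesignError",
    "DesignRankError",
    "build_fixed_design",
    "build_biological_matrices",
    "build_blending_matrices",
    "build_model_matrices",
    "assemble_covariance",
    "load_design",
    "save_design",
    "dump_matrices",
]


class DesignError(ValueError):
    """Raised when an experiment description is inconsistent."""


class DesignRankError(DesignError):
    """Raised when fixed effects are confounded (rank-deficient X)."""


@dataclass(frozen=True)
class Individual:
    """One biological individual with its treatment-group label."""

    id: str
    treatment: str
    covariates: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PoolSpec:
    """A physical sample: one or more individuals blended into one mixture.

    ``blend_event`` identifies the physical act of blending.  Technical
    replicates of one mixture share the blend event (and hence one blending
    effect); re-blending the same members into a fresh mixture is a new
    event.  Defaults to the pool id.
    """

    id: str
    members: tuple[str, ...]
    blend_event: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def event(self) -> str:
        return self.blend_event if self.blend_event is not None else self.id


@dataclass(frozen=True)
class Measurement:
    """One observed intensity (or, for two-color arrays, one channel).

    ``channel`` is ``"single"`` for one-color platforms and ``"red"`` /
    ``"green"`` for two-color arrays.  ``covariates`` hold nuisance-factor
    levels attached to the measurement (e.g. tissue).
    """

    array: str
    sample: str
    channel: str = "single"
    covariates: Mapping[str, str] = field(default_factory=dict)


@dataclass
class PoolDesign:
    """Full declarative description of a pooled expression experiment."""

    platform: str  # "one-color" | "two-color"
    individuals: tuple[Individual, ...]
    pools: tuple[PoolSpec, ...]
    measurements: tuple[Measurement, ...]
    treatment_levels: tuple[str, ...]
    factors: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individuals = tuple(self.individuals)
        self.pools = tuple(self.pools)
        self.measurements = tuple(self.measurements)
        self.treatment_levels = tuple(self.treatment_levels)
        self.factors = dict(self.factors)
        self.validate()

    # -- lookups -------------------------------------------------------
    @property
    def individual_by_id(self) -> dict[str, Individual]:
        return {ind.id: ind for ind in self.individuals}

    @property
    def pool_by_id(self) -> dict[str, PoolSpec]:
        return {p.id: p for p in self.pools}

    def pool_treatment(self, pool_id: str) -> str:
        """Treatment level of a pool (members must be homogeneous)."""
        by_id = self.individual_by_id
        levels = {by_id[m].treatment for m in self.pool_by_id[pool_id].members}
        if len(levels) != 1:
            raise DesignError(
                f"pool '{pool_id}': members span several treatments {sorted(levels)}; "
                "a pool must be treatment-homogeneous"
            )
        return levels.pop()

    @property
    def arrays(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.measurements:
            seen.setdefault(m.array, None)
        return tuple(seen)

    @property
    def n_rows(self) -> int:
        """Number of model rows: measurements (one-color) or arrays (two-color)."""
        if self.platform == "one-color":
            return len(self.measurements)
        return len(self.arrays)

    def row_ids(self) -> tuple[str, ...]:
        if self.platform == "one-color":
            return tuple(m.array for m in self.measurements)
        return self.arrays

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.platform not in ("one-color", "two-color"):
            raise DesignError(f"platform must be 'one-color' or 'two-color', got {self.platform!r}")
        if len(self.treatment_levels) < 1:
            raise DesignError("at least one treatment level must be declared")

        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise DesignError("individual ids are not unique")
        for i, ind in enumerate(self.individuals):
            if ind.treatment not in self.treatment_levels:
                raise DesignError(
                    f"individuals[{i}] (id '{ind.id}'): treatment '{ind.treatment}' "
                    f"not among declared levels {list(self.treatment_levels)}"
                )

        known = set(ids)
        pool_ids = [p.id for p in self.pools]
        if len(set(pool_ids)) != len(pool_ids):
            raise DesignError("pool ids are not unique")
        event_members: dict[str, frozenset[str]] = {}
        for i, pool in enumerate(self.pools):
            if pool.size < 1:
                raise DesignError(f"pools[{i}] (id '{pool.id}'): empty pool")
            if len(set(pool.members)) != pool.size:
                raise DesignError(f"pools[{i}] (id '{pool.id}'): duplicate members")
            for m in pool.members:
                if m not in known:
                    raise DesignError(f"pools[{i}] (id '{pool.id}'): unknown member '{m}'")
            mem = frozenset(pool.members)
            if pool.event in event_members and event_members[pool.event] != mem:
                raise DesignError(
                    f"pools[{i}] (id '{pool.id}'): blend_event '{pool.event}' reused "
                    "for a different member set"
                )
            event_members[pool.event] = mem

        by_pool = {p.id: p for p in self.pools}
        for i, meas in enumerate(self.measurements):
            if meas.sample not in by_pool:
                raise DesignError(f"measurements[{i}]: unknown sample '{meas.sample}'")
            for fac, lev in meas.covariates.items():
                if fac in self.factors and lev not in self.factors[fac]:
                    raise DesignError(
                        f"measurements[{i}] (array '{meas.array}'): level '{lev}' "
                        f"not among declared levels of factor '{fac}'"
                    )
        if self.platform == "one-color":
            bad = [m.array for m in self.measurements if m.channel != "single"]
            if bad:
                raise DesignError(f"one-color design has non-'single' channels on arrays {bad}")
        else:
            per_array: dict[str, list[str]] = {}
            for m in self.measurements:
                if m.channel not in ("red", "green"):
                    raise DesignError(
                        f"two-color design: array '{m.array}' has channel '{m.channel}'"
                    )
                per_array.setdefault(m.array, []).append(m.channel)
            for arr, channels in per_array.items():
                if sorted(channels) != ["green", "red"]:
                    raise DesignError(
                        f"array '{arr}' must carry exactly one red and one green "
                        f"measurement, got {channels}"
                    )


@dataclass
class VarianceComponents:
    """The three variance components of the pooled-sample mixed model.

    ``blending`` may be ``None`` for the reduced model (m1) that omits the
    blending random effect.
    """

    biological: float
    residual: float
    blending: float | None = None

    def validate(self) -> None:
        vals = [self.biological, self.residual] + ([] if self.blending is None else [self.blending])
        if any(v < 0 for v in vals):
            raise ValueError(f"variance components must be nonnegative, got {self}")

    def as_vector(self) -> np.ndarray:
        """Estimate vector in the order (sigma1^2[, sigma2^2], sigma_e^2)."""
        if self.blending is None:
            return np.array([self.biological, self.residual])
        return np.array([self.biological, self.blending, self.residual])


@dataclass
class ModelMatrices:
    """Realized matrices of the mixed model for one experiment.

    ``treatment_slice`` indexes the columns of ``X`` that carry the
    treatment contrast(s).
    """

    X: np.ndarray
    x_labels: tuple[str, ...]
    Z1: np.ndarray
    G1: np.ndarray
    z1_labels: tuple[str, ...]
    Z2: np.ndarray
    G2: np.ndarray
    z2_labels: tuple[str, ...]
    row_ids: tuple[str, ...]
    treatment_slice: slice = field(default_factory=lambda: slice(0, 0))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def treatment_contrast(self) -> np.ndarray:
        """Rows selecting the treatment coefficients (for Wald F-tests)."""
        p = self.X.shape[1]
        cols = range(*self.treatment_slice.indices(p))
        L = np.zeros((len(list(cols)), p))
        for r, c in enumerate(range(*self.treatment_slice.indices(p))):
            L[r, c] = 1.0
        return L


# ---------------------------------------------------------------------------
# fixed design
# ---------------------------------------------------------------------------

def _covariate_row(design: PoolDesign, meas: Measurement,
                   factor_levels: dict[str, tuple[str, ...]]) -> np.ndarray:
    """Reference-coded covariate row (without intercept) for one measurement."""
    cols: list[float] = []
    trt = design.pool_treatment(meas.sample)
    for lev in design.treatment_levels[1:]:
        cols.append(1.0 if trt == lev else 0.0)
    for fac, levels in factor_levels.items():
        val = meas.covariates.get(fac)
        if val is None:
            raise DesignError(
                f"array '{meas.array}': measurement lacks a level for factor '{fac}'"
            )
        for lev in levels[1:]:
            cols.append(1.0 if val == lev else 0.0)
    return np.array(cols)


def build_fixed_design(design: PoolDesign) -> tuple[np.ndarray, tuple[str, ...], slice]:
    """Build the fixed-effect design matrix ``X`` with coefficient labels.

    One-color: intercept + reference-coded treatment (+ declared nuisance
    factors), one row per measurement.  Two-color: one row per array equal
    to the red sample's covariate row minus the green sample's, plus an
    all-ones intercept column that absorbs the dye effect.

    Raises :class:`DesignRankError` when the treatment columns are
    confounded with the rest of the design.
    """
    factor_levels = {f: tuple(lv) for f, lv in design.factors.items()}
    labels = ["(Intercept)"]
    labels += [f"treatment[{lev}]" for lev in design.treatment_levels[1:]]
    for fac, levels in factor_levels.items():
        labels += [f"{fac}[{lev}]" for lev in levels[1:]]
    n_trt = len(design.treatment_levels) - 1

    if design.platform == "one-color":
        rows = [
            np.concatenate(([1.0], _covariate_row(design, m, factor_levels)))
            for m in design.measurements
        ]
    else:
        by_array: dict[str, dict[str, Measurement]] = {}
        for m in design.measurements:
            by_array.setdefault(m.array, {})[m.channel] = m
        rows = []
        for arr in design.arrays:
            red, green = by_array[arr]["red"], by_array[arr]["green"]
            diff = (_covariate_row(design, red, factor_levels)
                    - _covariate_row(design, green, factor_levels))
            rows.append(np.concatenate(([1.0], diff)))
    X = np.vstack(rows) if rows else np.zeros((0, len(labels)))

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns through pivoted QR
        _, _, piv = _qr_pivot(X)
        aliased = [labels[j] for j in piv[rank:]]
        raise DesignRankError(
            f"fixed design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}"
        )
    return X, tuple(labels), slice(1, 1 + n_trt)


def _qr_pivot(A: np.ndarray):
    import scipy.linalg

    return scipy.linalg.qr(A, mode="economic", pivoting=True)


# ---------------------------------------------------------------------------
# random-effect matrices
# ---------------------------------------------------------------------------

def _signed_rows(design: PoolDesign, col_of_sample, n_cols: int) -> np.ndarray:
    """Build Z rows given a callback mapping a sample id to column weights.

    ``col_of_sample(sample_id)`` returns a list of (column, weight) pairs.
    One-color: one row per measurement.  Two-color: red minus green per
    array.
    """
    if design.platform == "one-color":
        Z = np.zeros((len(design.measurements), n_cols))
        for i, meas in enumerate(design.measurements):
            for j, w in col_of_sample(meas.sample):
                Z[i, j] += w
        return Z
    by_array: dict[str, dict[str, Measurement]] = {}
    for m in design.measurements:
        by_array.setdefault(m.array, {})[m.channel] = m
    arrays = design.arrays
    Z = np.zeros((len(arrays), n_cols))
    for i, arr in enumerate(arrays):
        for j, w in col_of_sample(by_array[arr]["red"].sample):
            Z[i, j] += w
        for j, w in col_of_sample(by_array[arr]["green"].sample):
            Z[i, j] -= w
    return Z


def build_biological_matrices(
    design: PoolDesign, parameterization: str = "composition"
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Build ``(Z1, G1)`` for the biological random effects.

    ``parameterization="composition"`` gives one effect per distinct sample
    composition with overlap-based ``G1`` (the canonical internal form);
    ``"individual"`` resolves pools into per-individual effects where the
    membership structure allows it, plus one composite effect per pool whose
    members never appear elsewhere (``G1`` diagonal with 1 for individuals
    and ``1/gamma`` for composite pool effects).
    """
    pools = design.pools
    if parameterization == "composition":
        comp_index: dict[frozenset[str], int] = {}
        comp_sets: list[frozenset[str]] = []
        labels: list[str] = []
        for p in pools:
            key = frozenset(p.members)
            if key not in comp_index:
                comp_index[key] = len(comp_sets)
                comp_sets.append(key)
                labels.append(f"comp:{p.id}")
        q = len(comp_sets)
        G1 = np.zeros((q, q))
        for i, si in enumerate(comp_sets):
            for j, sj in enumerate(comp_sets):
                G1[i, j] = len(si & sj) / (len(si) * len(sj))

        def cols(sample_id: str):
            return [(comp_index[frozenset(design.pool_by_id[sample_id].members)], 1.0)]

        Z1 = _signed_rows(design, cols, q)
        return Z1, G1, tuple(labels)

    if parameterization != "individual":
        raise ValueError(f"unknown parameterization {parameterization!r}")

    # individuals are "resolved" when they appear in more than one distinct
    # composition or in a singleton pool; pools containing any resolved
    # member are expanded into member effects (closure over membership).
    comp_of_ind: dict[str, set[frozenset[str]]] = {}
    for p in pools:
        key = frozenset(p.members)
        for m in p.members:
            comp_of_ind.setdefault(m, set()).add(key)
    resolved = {
        m for m, comps in comp_of_ind.items()
        if len(comps) > 1 or any(len(c) == 1 for c in comps)
    }
    changed = True
    while changed:
        changed = False
        for p in pools:
            mem = set(p.members)
            if mem & resolved and not mem <= resolved:
                resolved |= mem
                changed = True

    effect_index: dict[str, int] = {}
    labels = []
    g_diag: list[float] = []
    composite_of_comp: dict[frozenset[str], int] = {}
    for p in pools:
        key = frozenset(p.members)
        if set(p.members) <= resolved:
            for m in p.members:
                if ("ind", m) not in effect_index:
                    effect_index[("ind", m)] = len(labels)
                    labels.append(f"ind:{m}")
                    g_diag.append(1.0)
        else:
            if key not in composite_of_comp:
                composite_of_comp[key] = len(labels)
                effect_index[("comp", key)] = len(labels)
                labels.append(f"pool:{p.id}")
                g_diag.append(1.0 / p.size)
    q = len(labels)
    G1 = np.diag(g_diag)

    def cols(sample_id: str):
        p = design.pool_by_id[sample_id]
        key = frozenset(p.members)
        if set(p.members) <= resolved:
            return [(effect_index[("ind", m)], 1.0 / p.size) for m in p.members]
        return [(effect_index[("comp", key)], 1.0)]

    Z1 = _signed_rows(design, cols, q)
    return Z1, G1, tuple(labels)


def build_blending_matrices(
    design: PoolDesign,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Build ``(Z2, G2)`` for the blending random effects.

    One effect per blend event of a pool with ``gamma >= 2``; ``G2`` is
    diagonal with entries ``(gamma - 1) / gamma**2``.  Rows of measurements
    of single individuals are identically zero.
    """
    event_index: dict[str, int] = {}
    labels: list[str] = []
    g_diag: list[float] = []
    for p in design.pools:
        if p.size >= 2 and p.event not in event_index:
            event_index[p.event] = len(labels)
            labels.append(f"blend:{p.event}")
            g_diag.append((p.size - 1) / p.size**2)
    q = len(labels)
    G2 = np.diag(g_diag) if q else np.zeros((0, 0))

    def cols(sample_id: str):
        p = design.pool_by_id[sample_id]
        if p.size < 2:
            return []
        return [(event_index[p.event], 1.0)]

    Z2 = _signed_rows(design, cols, q)
    return Z2, G2, tuple(labels)


def build_model_matrices(
    design: PoolDesign, parameterization: str = "composition"
) -> ModelMatrices:
    """Realize all model matrices of a design in one call."""
    X, x_labels, trt = build_fixed_design(design)
    Z1, G1, z1_labels = build_biological_matrices(design, parameterization)
    Z2, G2, z2_labels = build_blending_matrices(design)
    return ModelMatrices(
        X=X, x_labels=x_labels,
        Z1=Z1, G1=G1, z1_labels=z1_labels,
        Z2=Z2, G2=G2, z2_labels=z2_labels,
        row_ids=design.row_ids(), treatment_slice=trt,
    )


def assemble_covariance(mats: ModelMatrices, vc: VarianceComponents) -> np.ndarray:
    """Covariance of the observations, ``Z1 G1 Z1' s1 + Z2 G2 Z2' s2 + I se``."""
    vc.validate()
    n = mats.n
    if mats.Z1.shape[0] != n or mats.Z2.shape[0] != n:
        raise ValueError("Z matrices do not match the number of model rows")
    if mats.Z1.shape[1] != mats.G1.shape[0] or mats.Z2.shape[1] != mats.G2.shape[0]:
        raise ValueError("Z/G dimension mismatch")
    V = vc.biological * (mats.Z1 @ mats.G1 @ mats.Z1.T)
    if vc.blending is not None and mats.Z2.shape[1] > 0:
        V = V + vc.blending * (mats.Z2 @ mats.G2 @ mats.Z2.T)
    V = V + vc.residual * np.eye(n)
    return V


# ---------------------------------------------------------------------------
# design file I/O
# ---------------------------------------------------------------------------

def design_to_dict(design: PoolDesign) -> dict:
    return {
        "platform": design.platform,
        "treatment_levels": list(design.treatment_levels),
        "factors": {f: list(lv) for f, lv in design.factors.items()},
        "individuals": [
            {"id": i.id, "treatment": i.treatment,
             **({"covariates": dict(i.covariates)} if i.covariates else {})}
            for i in design.individuals
        ],
        "pools": [
            {"id": p.id, "members": list(p.members),
             **({"blend_event": p.blend_event} if p.blend_event else {})}
            for p in design.pools
        ],
        "measurements": [
            {"array": m.array, "sample": m.sample, "channel": m.channel,
             **({"covariates": dict(m.covariates)} if m.covariates else {})}
            for m in design.measurements
        ],
    }


def design_from_dict(data: Mapping) -> PoolDesign:
    def need(key: str, where: str = "design"):
        if key not in data:
            raise DesignError(f"{where}: missing required section '{key}'")
        return data[key]

    individuals = []
    for i, entry in enumerate(need("individuals")):
        try:
            individuals.append(Individual(
                id=str(entry["id"]), treatment=str(entry["treatment"]),
                covariates=dict(entry.get("covariates", {})),
            ))
        except KeyError as e:
            raise DesignError(f"individuals[{i}]: missing key {e}") from None
    pools = []
    for i, entry in enumerate(need("pools")):
        try:
            pools.append(PoolSpec(
                id=str(entry["id"]), members=tuple(str(m) for m in entry["members"]),
                blend_event=entry.get("blend_event"),
            ))
        except KeyError as e:
            raise DesignError(f"pools[{i}]: missing key {e}") from None
    measurements = []
    for i, entry in enumerate(need("measurements")):
        try:
            measurements.append(Measurement(
                array=str(entry["array"]), sample=str(entry["sample"]),
                channel=str(entry.get("channel", "single")),
                covariates=dict(entry.get("covariates", {})),
            ))
        except KeyError as e:
            raise DesignError(f"measurements[{i}]: missing key {e}") from None
    return PoolDesign(
        platform=str(need("platform")),
        individuals=tuple(individuals),
        pools=tuple(pools),
        measurements=tuple(measurements),
        treatment_levels=tuple(str(t) for t in need("treatment_levels")),
        factors={f: tuple(lv) for f, lv in dict(data.get("factors", {})).items()},
    )


def load_design(path: str | Path) -> PoolDesign:
    """Read a design description from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise DesignError(f"{path}: design file must contain a mapping at top level")
    return design_from_dict(data)


def save_design(design: PoolDesign, path: str | Path) -> None:
    path = Path(path)
    data = design_to_dict(design)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def dump_matrices(mats: ModelMatrices, out_dir: str | Path) -> None:
    """Export X, Z1, G1, Z2, G2 as TSV files for audit."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(mats.X, index=mats.row_ids, columns=mats.x_labels).to_csv(
        out / "X.tsv", sep="\t")
    pd.DataFrame(mats.Z1, index=mats.row_ids, columns=mats.z1_labels).to_csv(
        out / "Z1.tsv", sep="\t")
    pd.DataFrame(mats.G1, index=mats.z1_labels, columns=mats.z1_labels).to_csv(
        out / "G1.tsv", sep="\t")
    pd.DataFrame(mats.Z2, index=mats.row_ids, columns=mats.z2_labels).to_csv(
        out / "Z2.tsv", sep="\t")
    pd.DataFrame(mats.G2, index=mats.z2_labels, columns=mats.z2_labels).to_csv(
        out / "G2.tsv", sep="\t")
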