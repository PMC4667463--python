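"""End-to-end per-transcript analysis of a pooled expression study.

For every transcript passing the expression filter the pipeline fits the
reduced (m1) and full (m2) mixed models by EM-REML, tests the blending
variance by the boundary RLRT, tests the treatment contrast by
Kenward-Roger adjusted F-tests under both models, and controls each
p-value family (RLRT, F under m1, F under m2) separately at a 5 % FDR
with a bootstrap pi0 estimate.  The study report aggregates the counts a
reader of such an analysis expects: transcripts with a significant
blending variance and the estimated non-null proportion pi1, declared-DE
counts per model and their overlap, mean variance components per model,
and — when simulation ground truth is available — the intersection cells
of (DE-m1, DE-m2, truly-DE, significant-VC) from which realized false
discovery proportions are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._batch import fit_transcripts, reduce_design
from .design import ModelMatrices, PoolDesign, build_model_matrices, load_design
from .inference import kr_ftest_batch, rlrt_pvalues
from .multiplicity import fdr_analysis
from .reml import FitConfig
from .simulate import SimulationConfig, SimulationTruth, simulate_experiment

__all__ = [
    "StudyConfig",
    "StudyReport",
    "filter_expressed",
    "analyze",
    "run_study",
    "replicate_study",
    "rank_agreement",
    "load_truth",
    "save_truth",
]


@dataclass
class StudyConfig:
    """File-level configuration of one study run (CLI entry point)."""

    expression: str | Path
    design: str | Path
    out_dir: str | Path = "."
    truth: str | Path | None = None
    alpha: float = 0.05
    expression_threshold: float = 8.0
    fit: FitConfig = field(default_factory=FitConfig)
    pi0_method: str = "bootstrap"
    top_k: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class StudyReport:
    """Aggregated counts and estimates of one study run."""

    n_total: int
    n_kept: int
    n_failed: int
    rlrt_pi0: float
    n_sig_vc: int
    n_de_m1: int
    n_de_m2: int
    n_de_both: int
    mean_vc_m1: dict
    mean_vc_m2: dict
    kendall_tau_top: float
    n_nonconverged_m1: int
    n_nonconverged_m2: int
    alpha: float
    truth_cells: dict | None = None
    truth_summary: dict | None = None

    @property
    def rlrt_pi1(self) -> float:
        return 1.0 - self.rlrt_pi0

    def to_dict(self) -> dict:
        out = {
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "n_failed": self.n_failed,
            "rlrt_pi0": self.rlrt_pi0,
            "rlrt_pi1": self.rlrt_pi1,
            "n_sig_vc": self.n_sig_vc,
            "n_de_m1": self.n_de_m1,
            "n_de_m2": self.n_de_m2,
            "n_de_both": self.n_de_both,
            "n_de_m1_only": self.n_de_m1 - self.n_de_both,
            "n_de_m2_only": self.n_de_m2 - self.n_de_both,
            "mean_vc_m1": self.mean_vc_m1,
            "mean_vc_m2": self.mean_vc_m2,
            "kendall_tau_top": self.kendall_tau_top,
            "n_nonconverged_m1": self.n_nonconverged_m1,
            "n_nonconverged_m2": self.n_nonconverged_m2,
            "alpha": self.alpha,
        }
        if self.truth_cells is not None:
            out["truth_cells"] = self.truth_cells
        if self.truth_summary is not None:
            out["truth_summary"] = self.truth_summary
        return out

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [
            "Pooled-study report",
            "===================",
            f"transcripts total / passing filter / failed fits: "
            f"{d['n_total']} / {d['n_kept']} / {d['n_failed']}",
            f"blending variance (RLRT at FDR {self.alpha:g}): "
            f"{d['n_sig_vc']} significant, pi1-hat = {d['rlrt_pi1']:.3f}",
            f"declared DE at FDR {self.alpha:g}: m1 {d['n_de_m1']}, "
            f"m2 {d['n_de_m2']}, shared {d['n_de_both']}",
            f"mean variance components m1: {self.mean_vc_m1}",
            f"mean variance components m2: {self.mean_vc_m2}",
            f"Kendall tau (union of top lists): {self.kendall_tau_top:.3f}",
        ]
        if self.truth_summary:
            t = self.truth_summary
            lines += [
                "against simulation truth:",
                f"  truly DE: {t['n_true_de']}; missed by m1/m2: "
                f"{t['missed_m1']} / {t['missed_m2']}",
                f"  false DE m1/m2: {t['false_de_m1']} / {t['false_de_m2']} "
                f"(prop. of {t['n_true_null']} nulls: "
                f"{t['fdp_m1']:.3f} / {t['fdp_m2']:.3f})",
                f"  false DE within significant-VC set m1/m2: "
                f"{t['false_de_sigvc_m1']} / {t['false_de_sigvc_m2']}",
            ]
        return "\n".join(lines)


def filter_expressed(
    matrix: np.ndarray | pd.DataFrame,
    groups: np.ndarray,
    threshold: float = 8.0,
) -> np.ndarray:
    """Keep transcripts whose mean log-expression reaches the threshold in
    at least one treatment group (excluded only when all groups are below).
    """
    Y = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    groups = np.asarray(groups)
    if groups.shape[0] != Y.shape[1]:
        raise ValueError("one group label per column (array) is required")
    keep = np.zeros(Y.shape[0], dtype=bool)
    for lev in np.unique(groups):
        keep |= Y[:, groups == lev].mean(axis=1) >= threshold
    return keep


def rank_agreement(p_m1: np.ndarray, p_m2: np.ndarray, k: int = 100) -> float:
    """Kendall's tau (tie-corrected) between the two p-value rankings,
    restricted to the union of each model's top-k transcripts."""
    p1 = np.asarray(p_m1, dtype=float)
    p2 = np.asarray(p_m2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p-value vectors must be aligned")
    if k < 2 or k > p1.size:
        raise ValueError(f"k must lie in [2, {p1.size}]")
    top1 = np.argsort(p1, kind="mergesort")[:k]
    top2 = np.argsort(p2, kind="mergesort")[:k]
    union = np.union1d(top1, top2)
    tau, _ = stats.kendalltau(p1[union], p2[union])
    return float(tau)


def _repair_nesting(mats, Yk, fit_cfg, red, fit1, fit2) -> None:
    """Restore the nested-model likelihood ordering where EM found a local
    optimum.

    The m2 parameter space contains every m1 solution, so the m2 restricted
    likelihood must weakly dominate m1's.  On rare transcripts (about 1 in
    250 on blending-affected data) the m2 EM converges to a local maximum
    below the m1 optimum; re-running it warm-started from the m1 solution
    with a small blending variance recovers the dominating solution (EM
    ascent guarantees no loss).  ``fit2`` is updated in place.
    """
    from dataclasses import replace as dc_replace

    bad = np.flatnonzero(fit1.ok & fit2.ok
                         & (fit2.loglik < fit1.loglik - 1e-9))
    for i in bad:
        scale = fit1.sigma1[i] + fit1.sigma_e[i]
        init = (max(fit1.sigma1[i], 1e-8 * scale), 1e-3 * scale,
                fit1.sigma_e[i])
        refit = fit_transcripts(mats, Yk[i:i + 1],
                                dc_replace(fit_cfg, init=init),
                                include_blending=True, red=red)
        if refit.loglik[0] > fit2.loglik[i]:
            for field_ in ("sigma1", "sigma2", "sigma_e", "loglik",
                           "iterations", "converged", "sigma1_at_floor",
                           "sigma2_at_floor"):
                getattr(fit2, field_)[i] = getattr(refit, field_)[0]


def _group_labels(design: PoolDesign) -> np.ndarray:
    return np.array([design.pool_treatment(m.sample)
                     for m in design.measurements])


def analyze(
    expr: pd.DataFrame,
    design: PoolDesign,
    truth: SimulationTruth | None = None,
    alpha: float = 0.05,
    expression_threshold: float = 8.0,
    fit_cfg: FitConfig | None = None,
    pi0_method: str = "bootstrap",
    top_k: int = 100,
    seed: int | None = None,
    mats: ModelMatrices | None = None,
) -> tuple[pd.DataFrame, StudyReport]:
    """Run the full per-transcript analysis of one expression matrix.

    ``expr`` holds normalized log-intensities (transcripts x arrays) with
    columns matching the design's measurement arrays.  Returns the
    per-transcript record table and the aggregated report.
    """
    fit_cfg = fit_cfg or FitConfig()
    if mats is None:
        mats = build_model_matrices(design, "individual")
    order = [m.array for m in design.measurements]
    missing = [a for a in order if a not in expr.columns]
    if missing:
        raise ValueError(f"expression matrix lacks arrays {missing[:5]}...")
    Y = expr[order].to_numpy(dtype=float)
    m_total = Y.shape[0]
    groups = _group_labels(design)

    keep = filter_expressed(Y, groups, expression_threshold)
    Yk = Y[keep]
    red = reduce_design(mats)
    fit1 = fit_transcripts(mats, Yk, fit_cfg, include_blending=False, red=red)
    fit2 = fit_transcripts(mats, Yk, fit_cfg, include_blending=True, red=red)
    _repair_nesting(mats, Yk, fit_cfg, red, fit1, fit2)
    ok = fit1.ok & fit2.ok

    boundary = fit2.sigma2_at_floor | (fit2.sigma2 == 0.0)
    rlrt_t, rlrt_p = rlrt_pvalues(fit1.loglik, fit2.loglik, boundary)
    f1, df1, p1, fb1 = kr_ftest_batch(mats, Yk, fit1.sigma1, None,
                                      fit1.sigma_e, model="m1")
    f2, df2, p2, fb2 = kr_ftest_batch(mats, Yk, fit2.sigma1, fit2.sigma2,
                                      fit2.sigma_e, model="m2")

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(3)]

    def family(pv: np.ndarray, rng) -> tuple[np.ndarray, float, np.ndarray]:
        valid = ok & np.isfinite(pv)
        q = np.full(pv.shape, np.nan)
        if valid.sum() == 0:
            return q, np.nan, np.zeros_like(valid)
        res = fdr_analysis(pv[valid], alpha=alpha, pi0_method=pi0_method,
                           rng=rng)
        q[valid] = res.q_values
        sig = np.zeros_like(valid)
        sig[valid] = res.significant
        return q, res.pi0, sig

    rlrt_q, rlrt_pi0, sig_vc = family(rlrt_p, rngs[0])
    q1, _, de1 = family(p1, rngs[1])
    q2, _, de2 = family(p2, rngs[2])

    try:
        tau = rank_agreement(np.where(np.isfinite(p1), p1, 1.0),
                             np.where(np.isfinite(p2), p2, 1.0),
                             min(top_k, max(2, int(ok.sum()))))
    except ValueError:
        tau = float("nan")

    kept_ids = expr.index.to_numpy()[keep]
    records = pd.DataFrame({
        "transcript": kept_ids,
        "m1_sigma1": fit1.sigma1, "m1_sigma_e": fit1.sigma_e,
        "m1_loglik": fit1.loglik, "m1_iterations": fit1.iterations,
        "m1_converged": fit1.converged,
        "m2_sigma1": fit2.sigma1, "m2_sigma2": fit2.sigma2,
        "m2_sigma_e": fit2.sigma_e, "m2_loglik": fit2.loglik,
        "m2_iterations": fit2.iterations, "m2_converged": fit2.converged,
        "rlrt_stat": rlrt_t, "rlrt_p": rlrt_p, "rlrt_q": rlrt_q,
        "sig_vc": sig_vc,
        "f_m1": f1, "df_m1": df1, "p_m1": p1, "q_m1": q1, "de_m1": de1,
        "f_m2": f2, "df_m2": df2, "p_m2": p2, "q_m2": q2, "de_m2": de2,
    })
    full = pd.DataFrame({"transcript": expr.index.to_numpy()})
    full["pass_filter"] = keep
    records = full.merge(records, on="transcript", how="left")

    mean_vc_m1 = {
        "sigma1": float(np.nanmean(fit1.sigma1)),
        "sigma_e": float(np.nanmean(fit1.sigma_e)),
    }
    mean_vc_m2 = {
        "sigma1": float(np.nanmean(fit2.sigma1)),
        "sigma2": float(np.nanmean(fit2.sigma2)),
        "sigma_e": float(np.nanmean(fit2.sigma_e)),
    }

    truth_cells = truth_summary = None
    if truth is not None:
        t_de = np.asarray(truth.is_de)[keep]
        cells: dict[str, int] = {}
        for a in (False, True):
            for b in (False, True):
                for c in (False, True):
                    for d in (False, True):
                        mask = (de1 == a) & (de2 == b) & (t_de == c) & (sig_vc == d)
                        parts = [name for flag, name in
                                 ((a, "m1"), (b, "m2"), (c, "sim"), (d, "vc"))
                                 if flag]
                        cells["&".join(parts) if parts else "none"] = int(mask.sum())
        n_true_null = int((~t_de).sum())
        false1 = int((de1 & ~t_de).sum())
        false2 = int((de2 & ~t_de).sum())
        truth_summary = {
            "n_true_de": int(t_de.sum()),
            "n_true_null": n_true_null,
            "missed_m1": int((t_de & ~de1).sum()),
            "missed_m2": int((t_de & ~de2).sum()),
            "false_de_m1": false1,
            "false_de_m2": false2,
            "fdp_m1": false1 / n_true_null if n_true_null else float("nan"),
            "fdp_m2": false2 / n_true_null if n_true_null else float("nan"),
            "false_de_sigvc_m1": int((de1 & ~t_de & sig_vc).sum()),
            "false_de_sigvc_m2": int((de2 & ~t_de & sig_vc).sum()),
        }
        truth_cells = cells

    report = StudyReport(
        n_total=m_total,
        n_kept=int(keep.sum()),
        n_failed=int((~ok).sum()),
        rlrt_pi0=rlrt_pi0,
        n_sig_vc=int(sig_vc.sum()),
        n_de_m1=int(de1.sum()),
        n_de_m2=int(de2.sum()),
        n_de_both=int((de1 & de2).sum()),
        mean_vc_m1=mean_vc_m1,
        mean_vc_m2=mean_vc_m2,
        kendall_tau_top=tau,
        n_nonconverged_m1=int((fit1.ok & ~fit1.converged).sum()),
        n_nonconverged_m2=int((fit2.ok & ~fit2.converged).sum()),
        alpha=alpha,
        truth_cells=truth_cells,
        truth_summary=truth_summary,
    )
    return records, report


def run_study(cfg: StudyConfig) -> tuple[pd.DataFrame, StudyReport]:
    """File-based study run: read inputs, analyze, write outputs."""
    expr = pd.read_csv(cfg.expression, sep="\t", index_col=0)
    design = load_design(cfg.design)
    truth = load_truth(cfg.truth) if cfg.truth else None
    records, report = analyze(
        expr, design, truth=truth, alpha=cfg.alpha,
        expression_threshold=cfg.expression_threshold, fit_cfg=cfg.fit,
        pi0_method=cfg.pi0_method, top_k=cfg.top_k, seed=cfg.seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.tsv", sep="\t", index=False,
                   float_format="%.6g")
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out / "report.txt").write_text(report.to_text() + "\n")
    return records, report


def replicate_study(
    base: SimulationConfig,
    reps: int,
    seed: int | None = None,
    **analyze_kwargs,
) -> dict:
    """Repeat simulate-and-analyze and average the report counts.

    Each repetition draws a fresh dataset from an independent child seed.
    Returns means, Monte-Carlo standard errors and the per-rep table of
    every numeric report field.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    from dataclasses import replace
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    rows = []
    for r in range(reps):
        child_seed = int(children[r].generate_state(1)[0] % (2**31))
        cfg = replace(base, seed=child_seed, keep_decomposition=False)
        expr, design, truth = simulate_experiment(cfg)
        _, report = analyze(expr, design, truth=truth, seed=child_seed,
                            **analyze_kwargs)
        flat = _flatten(report.to_dict())
        rows.append(flat)
    table = pd.DataFrame(rows)
    num = table.select_dtypes(include=[np.number])
    means = num.mean().to_dict()
    ses = (num.std(ddof=1) / np.sqrt(reps)).to_dict() if reps > 1 else \
        {k: float("nan") for k in means}
    return {"reps": reps, "mean": means, "se": ses, "per_rep": table}


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, f"{key}."))
        else:
            out[key] = v
    return out


def save_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Write the per-transcript part of the ground truth as TSV."""
    pd.DataFrame({
        "transcript": truth.transcript_ids,
        "mu": truth.mu,
        "is_de": truth.is_de.astype(int),
        "effect": truth.effect,
        "is_blended": truth.is_blended.astype(int),
    }).to_csv(path, sep="\t", index=False, float_format="%.8g")


def load_truth(path: str | Path) -> SimulationTruth:
    """Read a truth TSV written by :func:`save_truth`."""
    t = pd.read_csv(path, sep="\t")
    return SimulationTruth(
        transcript_ids=t["transcript"].to_numpy(),
        mu=t["mu"].to_numpy(),
        is_de=t["is_de"].to_numpy().astype(bool),
        effect=t["effect"].to_numpy(),
        is_blended=t["is_blended"].to_numpy().astype(bool),
        group2_level="",
    )
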