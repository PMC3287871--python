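"""Comparison harness: null calibration and power of the association methods.

Turns per-gene, per-method, per-replicate p-values plus causal-gene truth
labels into the study's comparison outputs: empirical false-positive rates
with exact binomial intervals, Q-Q data under the null with the genomic
inflation factor lambda, and ROC curves truncated at a low false-positive
rate (only the low-FPR regime matters for gene discovery), with the partial
area under the truncated curve as a scalar summary.

``run_study`` orchestrates the whole pipeline from a configuration: simulate
(or load) a study, build the relatedness matrices and PC covariates,
collapse genes, scan all replicates under the requested methods, and write
machine-readable summaries plus figures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import sim as famsim
from .collapse import collapse_all
from .genotype import (
    filter_variants,
    ibs_matrix,
    pca_eigenvectors,
    sample_markers,
)
from .mixed import ModelSpec, results_to_frame, run_all, spectral_decomposition
from .pedigree import kinship_matrix, relationship_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "RateEstimate",
    "QQData",
    "RocCurve",
    "StudyConfig",
    "empirical_rate",
    "qq_data",
    "roc_curve",
    "run_study",
]

# median of the 1-df chi-square distribution, the null expectation of the
# median association statistic
_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class RateEstimate:
    """Empirical rejection proportion with a Clopper-Pearson 95% interval."""

    rate: float
    ci_low: float
    ci_high: float
    n_tests: int
    n_rejected: int
    alpha: float


@dataclass
class QQData:
    """Paired expected/observed -log10(p) quantiles plus inflation lambda."""

    expected: np.ndarray  # descending
    observed: np.ndarray  # descending
    lambda_gc: float


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    fpr_max: float
    partial_auc: float


def empirical_rate(pvals, alpha: float) -> RateEstimate:
    """Proportion of p-values <= alpha, with an exact binomial interval."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empirical_rate needs at least one p-value")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    k = int((p <= alpha).sum())
    n = p.size
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return RateEstimate(k / n, lo, hi, n, k, alpha)


def qq_data(pvals) -> QQData:
    """Q-Q quantiles of -log10(p) against uniform plotting positions.

    Expected quantiles use the (i - 0.5)/m convention.  The genomic
    inflation factor is the median of the implied 1-df chi-square statistics
    divided by the null chi-square median (~0.4549).  Zero p-values are
    clamped to the smallest positive float with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("qq_data needs at least one p-value")
    if (p == 0).any():
        logger.warning("qq_data: clamping %d zero p-values", int((p == 0).sum()))
        p = np.maximum(p, np.finfo(float).tiny)
    m = p.size
    observed = -np.log10(np.sort(p))  # ascending p = descending -log10
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    lam = float(np.median(stats.chi2.isf(p, 1)) / _CHI2_MEDIAN)
    return QQData(expected=expected, observed=observed, lambda_gc=lam)


def roc_curve(p_null, p_causal, fpr_max: float = 0.1) -> RocCurve:
    """ROC of causal vs null tests, truncated at FPR <= ``fpr_max``.

    The p-value threshold sweeps the observed values; TPR (FPR) is the
    fraction of causal (null) tests at or below the threshold.  The partial
    area integrates the staircase curve up to ``fpr_max``.
    """
    p_null = np.asarray(p_null, dtype=float)
    p_causal = np.asarray(p_causal, dtype=float)
    if p_causal.size == 0:
        raise ValueError("roc_curve needs causal-gene tests")
    if p_null.size == 0:
        raise ValueError("roc_curve needs null-gene tests")
    thresholds = np.unique(np.concatenate([p_null, p_causal]))
    tpr = np.searchsorted(np.sort(p_causal), thresholds, side="right") / p_causal.size
    fpr = np.searchsorted(np.sort(p_null), thresholds, side="right") / p_null.size
    keep = fpr <= fpr_max
    fpr_pts = np.concatenate([[0.0], fpr[keep]])
    tpr_pts = np.concatenate([[0.0], tpr[keep]])
    # staircase integral, extended at the last achieved TPR out to fpr_max
    widths = np.diff(np.concatenate([fpr_pts, [fpr_max]]))
    pauc = float(np.sum(tpr_pts * widths))
    return RocCurve(fpr=fpr_pts, tpr=tpr_pts, fpr_max=fpr_max, partial_auc=pauc)


@dataclass
class StudyConfig:
    """End-to-end study configuration (simulation plus analysis settings)."""

    sim: famsim.SimConfig = field(default_factory=famsim.SimConfig)
    methods: tuple[str, ...] = ("REG", "PC", "KIN", "PC-KIN", "IBS", "PC-IBS")
    n_pcs: int = 10
    maf_threshold: float = 0.01
    ibs_markers: int = 5000
    ibs_maf_min: float = 0.05
    pca_maf_min: float = 0.10
    alphas: tuple[float, ...] = (0.01, 0.05)
    fpr_max: float = 0.1
    study_dir: str | None = None  # read an on-disk study instead of simulating

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"] = asdict(self.sim)
        d["sim"]["offspring_range"] = list(self.sim.offspring_range)
        d["sim"]["rare_maf_range"] = list(self.sim.rare_maf_range)
        d["sim"]["common_maf_range"] = list(self.sim.common_maf_range)
        if not isinstance(self.sim.variants_per_gene, int):
            d["sim"]["variants_per_gene"] = list(self.sim.variants_per_gene)
        d["methods"] = list(self.methods)
        d["alphas"] = list(self.alphas)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        simd = d.pop("sim", {})
        for key in ("offspring_range", "rare_maf_range", "common_maf_range",
                    "total_size_range", "variants_per_gene"):
            if key in simd and isinstance(simd[key], list):
                simd[key] = tuple(simd[key])
        d["sim"] = famsim.SimConfig(**simd)
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "alphas" in d:
            d["alphas"] = tuple(d["alphas"])
        return cls(**d)


def _build_matrices(study: famsim.ReplicateStudy, cfg: StudyConfig):
    """Relatedness matrices and PC covariates for the configured methods."""
    relmats = {}
    q = None
    methods = set(cfg.methods)
    if {"KIN", "PC-KIN"} & methods:
        relmats["relationship_2phi"] = relationship_matrix(
            kinship_matrix(study.pedigree)
        )
    if {"IBS", "PC-IBS"} & methods:
        common = filter_variants(study.genotypes, min_maf=cfg.ibs_maf_min,
                                 min_strict=True)
        count = min(cfg.ibs_markers, common.n_variants)
        if count < cfg.ibs_markers:
            logger.warning(
                "only %d markers with MAF > %.2f available for IBS "
                "(requested %d)", count, cfg.ibs_maf_min, cfg.ibs_markers,
            )
        panel = sample_markers(common, count, seed=study.config.seed + 101)
        relmats["ibs"] = ibs_matrix(panel)
    if {"PC", "PC-KIN", "PC-IBS"} & methods:
        common = filter_variants(study.genotypes, min_maf=cfg.pca_maf_min,
                                 min_strict=True)
        q = pca_eigenvectors(common, cfg.n_pcs)
    return relmats, q


def run_study(cfg: StudyConfig, outdir=None) -> tuple[pd.DataFrame, dict]:
    """Simulate (or load), analyse and summarise a full replicate study.

    Returns ``(table, report)``: the long evaluation table with one row per
    (method, gene, replicate) and a JSON-serialisable report with per-method
    lambda, FPR/power at each alpha and, when causal genes exist, the
    truncated-ROC partial AUC.  When ``outdir`` is given, TSV/JSON summaries
    and Q-Q / ROC figures are written there; outputs are deterministic for a
    fixed config and seed.
    """
    if cfg.study_dir is not None:
        study = famsim.read_study(cfg.study_dir)
    else:
        study = famsim.simulate_study(cfg.sim)

    relmats, q = _build_matrices(study, cfg)
    eigen_cache = {kind: spectral_decomposition(m) for kind, m in relmats.items()}
    designs = collapse_all(study.genotypes, cfg.maf_threshold)
    specs = [ModelSpec(m, cfg.n_pcs if m in ("PC", "PC-KIN", "PC-IBS") else 0)
             for m in cfg.methods]

    frames = []
    for r in range(study.n_replicates):
        if r and r % 20 == 0:
            logger.info("run_study: replicate %d/%d", r, study.n_replicates)
        res = run_all(specs, designs, study.traits[r], q, relmats, eigen_cache)
        df = results_to_frame(res)
        df.insert(2, "replicate", r + 1)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    causal_map = dict(zip(study.truth["gene"], study.truth["causal"]))
    table["causal"] = table["gene"].map(causal_map).astype(bool)

    report = summarize(table, alphas=cfg.alphas, fpr_max=cfg.fpr_max)
    report["n_subjects"] = len(study.pedigree)
    report["n_families"] = len(study.pedigree.family_ids)
    report["n_replicates"] = int(study.n_replicates)
    report["n_genes"] = int(len(study.truth))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "results.tsv", sep="\t", index=False,
                     float_format="%.10g")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _write_figures(table, report, cfg, outdir)
    return table, report


def summarize(table: pd.DataFrame, alphas=(0.01, 0.05), fpr_max: float = 0.1) -> dict:
    """Per-method calibration and power summaries from the long table.

    Null summaries (Q-Q lambda, FPR) use non-causal genes only; rows whose
    fit did not succeed are excluded from every denominator and counted in
    ``n_excluded``.
    """
    report: dict = {"methods": {}, "alphas": list(alphas), "fpr_max": fpr_max}
    for method, sub in table.groupby("method", sort=True):
        ok = sub[sub["status"] == "ok"]
        null_p = ok.loc[~ok["causal"], "p_value"].to_numpy()
        causal_p = ok.loc[ok["causal"], "p_value"].to_numpy()
        entry: dict = {
            "n_tests_ok": int(len(ok)),
            "n_excluded": int(len(sub) - len(ok)),
            "n_null": int(null_p.size),
            "n_causal": int(causal_p.size),
        }
        if null_p.size:
            qq = qq_data(null_p)
            entry["lambda_gc"] = qq.lambda_gc
            entry["fpr"] = {}
            for a in alphas:
                est = empirical_rate(null_p, a)
                entry["fpr"][str(a)] = {
                    "rate": est.rate, "ci_low": est.ci_low,
                    "ci_high": est.ci_high, "n": est.n_tests,
                }
        if causal_p.size:
            entry["power"] = {
                str(a): empirical_rate(causal_p, a).rate for a in alphas
            }
            if null_p.size:
                roc = roc_curve(null_p, causal_p, fpr_max)
                entry["partial_auc"] = roc.partial_auc
        report["methods"][method] = entry
    return report


def _write_figures(table: pd.DataFrame, report: dict, cfg: StudyConfig, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = sorted(table["method"].unique())
    ok = table[table["status"] == "ok"]

    fig, axes = plt.subplots(2, 3, figsize=(12, 8), squeeze=False)
    for ax, method in zip(axes.ravel(), methods):
        null_p = ok.loc[(ok["method"] == method) & ~ok["causal"], "p_value"]
        if len(null_p) == 0:
            ax.set_visible(False)
            continue
        qq = qq_data(null_p.to_numpy())
        lim = max(qq.expected.max(), qq.observed.max())
        ax.plot([0, lim], [0, lim], "k-", lw=1)
        ax.plot(qq.expected, qq.observed, "r.", ms=3)
        ax.set_title(f"{method} (lambda={qq.lambda_gc:.2f})")
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
    for ax in axes.ravel()[len(methods):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(outdir / "qq.png", dpi=120)
    plt.close(fig)

    if table["causal"].any():
        fig, ax = plt.subplots(figsize=(6, 5))
        n_curves = 0
        for method in methods:
            sub = ok[ok["method"] == method]
            null_p = sub.loc[~sub["causal"], "p_value"].to_numpy()
            causal_p = sub.loc[sub["causal"], "p_value"].to_numpy()
            if null_p.size == 0 or causal_p.size == 0:
                continue
            roc = roc_curve(null_p, causal_p, cfg.fpr_max)
            ax.step(roc.fpr, roc.tpr, where="post",
                    label=f"{method} (pAUC={roc.partial_auc:.3f})")
            n_curves += 1
        if n_curves:
            ax.set_xlabel("false-positive rate")
            ax.set_ylabel("true-positive rate")
            ax.set_xlim(0, cfg.fpr_max)
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(outdir / "roc.png", dpi=120)
        plt.close(fig)
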