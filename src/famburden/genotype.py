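"""Genotype-matrix utilities.

The container stores minor-allele dosages (0/1/2, with missing) for *n*
subjects by *m* variants, plus per-variant metadata (variant id, gene label,
minor-allele frequency).  From it we build the two genotype-derived
structures of the association models:

* the **IBS matrix** — mean allele-sharing ``1 - |g_i - g_j| / 2`` over
  markers, used as the covariance structure of the polygenic effect when no
  pedigree is available;
* **principal-component covariates** — top eigenvectors of the covariance of
  the Eigenstrat-normalised dosage matrix, used as fixed-effect adjustments
  for population structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "CovariateMatrix",
    "minor_allele_freq",
    "filter_variants",
    "sample_markers",
    "ibs_matrix",
    "pca_eigenvectors",
    "read_genotypes",
    "read_vcf",
]

MISSING = -1  # sentinel for a missing dosage in the integer matrix


@dataclass
class GenotypeMatrix:
    """Subjects-by-variants minor-allele dosage matrix.

    ``dosages`` is an int8 array with values in {0, 1, 2} and ``MISSING``
    (-1) for no-calls.  ``variant_meta`` is a DataFrame with columns
    ``variant_id``, ``gene`` (nullable) and, once computed, ``maf``.
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    subject_order: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        n, m = self.dosages.shape
        if len(self.subject_order) != n:
            raise ValueError("subject_order length does not match dosage rows")
        if len(self.variant_meta) != m:
            raise ValueError("variant_meta length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        self.variant_meta = self.variant_meta.reset_index(drop=True)
        if "gene" not in self.variant_meta.columns:
            self.variant_meta["gene"] = pd.NA

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variant_meta["variant_id"])

    @property
    def maf(self) -> np.ndarray:
        if "maf" not in self.variant_meta.columns:
            raise ValueError("minor-allele frequencies not computed yet")
        return self.variant_meta["maf"].to_numpy(dtype=float)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.variant_meta.iloc[np.asarray(idx)].reset_index(drop=True),
            list(self.subject_order),
        )

    def genes(self) -> list[str]:
        """Distinct gene labels in first-appearance order, missing excluded."""
        seen: list[str] = []
        for g in self.variant_meta["gene"]:
            if pd.isna(g):
                continue
            if g not in seen:
                seen.append(g)
        return seen

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.dosages.astype(np.int16),
            index=self.subject_order,
            columns=self.variant_ids,
        ).astype("Int16")
        df = df.mask(df < 0)
        df.to_csv(path, sep="\t", index_label="subject", na_rep="NA")


@dataclass
class CovariateMatrix:
    """Top-k PCA eigenvectors used as population-structure covariates."""

    values: np.ndarray
    subject_order: list[str]
    eigenvalues: np.ndarray
    variance_captured: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        n, k = self.values.shape
        if len(self.subject_order) != n:
            raise ValueError("subject_order length does not match rows")
        if len(self.eigenvalues) != k:
            raise ValueError("one eigenvalue per eigenvector required")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            index=self.subject_order,
            columns=[f"PC{i+1}" for i in range(self.n_components)],
        )
        df.to_csv(path, sep="\t", index_label="subject")


def minor_allele_freq(g: GenotypeMatrix) -> np.ndarray:
    """Compute folded minor-allele frequencies and store them in the metadata.

    freq = sum(dosages) / (2 * n_nonmissing), folded to min(freq, 1 - freq).
    """
    miss = g.missing_mask()
    d = np.where(miss, 0, g.dosages).astype(np.int64)
    n_obs = (~miss).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [g.variant_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"variants with all dosages missing: {bad}")
    freq = d.sum(axis=0) / (2.0 * n_obs)
    maf = np.minimum(freq, 1.0 - freq)
    g.variant_meta["maf"] = maf
    return maf


def filter_variants(
    g: GenotypeMatrix,
    min_maf: float | None = None,
    max_maf: float | None = None,
    min_strict: bool = True,
    max_strict: bool = True,
) -> GenotypeMatrix:
    """Keep variants inside the given MAF bounds (order preserved).

    ``min_strict`` / ``max_strict`` select open (>) vs closed (>=) bounds.
    """
    if min_maf is not None and max_maf is not None and min_maf > max_maf:
        raise ValueError(f"min_maf {min_maf} exceeds max_maf {max_maf}")
    maf = g.maf
    keep = np.ones(g.n_variants, dtype=bool)
    if min_maf is not None:
        keep &= (maf > min_maf) if min_strict else (maf >= min_maf)
    if max_maf is not None:
        keep &= (maf < max_maf) if max_strict else (maf <= max_maf)
    return g.take_variants(np.flatnonzero(keep))


def sample_markers(g: GenotypeMatrix, count: int, seed: int) -> GenotypeMatrix:
    """Uniform order-preserving sample of ``count`` variants without replacement."""
    if count > g.n_variants:
        raise ValueError(
            f"requested {count} markers but only {g.n_variants} available"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(g.n_variants, size=count, replace=False))
    return g.take_variants(idx)


def ibs_matrix(g: GenotypeMatrix) -> "RelatednessMatrix":
    """Identity-by-state similarity: mean over markers of 1 - |g_i - g_j| / 2.

    Pairs of subjects are compared over their jointly non-missing markers
    (pairwise deletion); the diagonal is forced to exactly 1.
    """
    from .pedigree import RelatednessMatrix

    if g.n_variants < 1:
        raise ValueError("IBS requires at least one variant")
    # Sum_v |g_i - g_j| decomposes over dosage-class indicator matrices:
    # |a - b| over {0,1,2} is 1 for adjacent classes and 2 for the 0/2 pair.
    n = g.n_subjects
    obs = (~g.missing_mask()).astype(np.float64)
    n_joint = obs @ obs.T
    if np.any(n_joint == 0):
        i, j = np.argwhere(n_joint == 0)[0]
        raise ValueError(
            f"subjects {g.subject_order[i]!r} and {g.subject_order[j]!r} share "
            "no jointly observed variants"
        )
    ind = [(g.dosages == a).astype(np.float64) for a in (0, 1, 2)]
    cross01 = ind[0] @ ind[1].T
    cross12 = ind[1] @ ind[2].T
    cross02 = ind[0] @ ind[2].T
    absdiff = (cross01 + cross01.T) + (cross12 + cross12.T) + 2.0 * (cross02 + cross02.T)
    s = 1.0 - absdiff / (2.0 * n_joint)
    np.fill_diagonal(s, 1.0)
    return RelatednessMatrix(s, list(g.subject_order), "ibs")


def pca_eigenvectors(g: GenotypeMatrix, k: int) -> CovariateMatrix:
    """Top-k principal components of the normalised genotype matrix.

    Missing dosages are imputed with the variant mean; each variant is
    centred and scaled by sqrt(p(1-p)) with the shrunk frequency estimate
    p = (1 + sum dosages) / (2 + 2n).  Eigenvectors are of the n-by-n
    covariance of the normalised matrix; signs are fixed by making the
    largest-magnitude entry of each eigenvector positive.
    """
    n, m = g.dosages.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds available rank min(n-1, m)")
    miss = g.missing_mask()
    d = np.where(miss, 0, g.dosages).astype(np.float64)
    n_obs = (~miss).sum(axis=0)
    col_sum = d.sum(axis=0)
    col_mean = col_sum / n_obs
    d = np.where(miss, col_mean[None, :], d)
    p_shrunk = (1.0 + col_sum) / (2.0 + 2.0 * n_obs)
    scale = np.sqrt(p_shrunk * (1.0 - p_shrunk))
    keep = scale > 0
    centred = d - col_mean[None, :]
    zero_var = keep & (np.abs(centred).max(axis=0) == 0)
    keep &= ~zero_var
    if not keep.all():
        dropped = int((~keep).sum())
        logger.warning("PCA: dropped %d zero-variance variants", dropped)
    x = centred[:, keep] / scale[None, keep]
    cov = (x @ x.T) / keep.sum()
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals[eigvals > 0]
    rank = len(pos)
    if k > rank:
        raise ValueError(f"k={k} exceeds numerical rank {rank}")
    top_vals = eigvals[:k]
    top_vecs = eigvecs[:, :k]
    for j in range(k):  # deterministic sign convention
        i_max = np.argmax(np.abs(top_vecs[:, j]))
        if top_vecs[i_max, j] < 0:
            top_vecs[:, j] = -top_vecs[:, j]
    return CovariateMatrix(
        values=top_vecs,
        subject_order=list(g.subject_order),
        eigenvalues=top_vals,
        variance_captured=float(top_vals.sum() / pos.sum()),
    )


def read_genotypes(geno_path, annot_path=None) -> GenotypeMatrix:
    """Read a dosage TSV (first column subject id, header of variant ids)
    plus an optional variant-annotation TSV with columns variant_id, gene."""
    df = pd.read_csv(geno_path, sep=r"\s+", index_col=0, na_values=["NA"])
    dos = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dos), MISSING, dos).astype(np.int8)
    meta = pd.DataFrame({"variant_id": [str(c) for c in df.columns]})
    if annot_path is not None:
        annot = pd.read_csv(annot_path, sep="\t", dtype=str)
        gene_map = dict(zip(annot["variant_id"], annot["gene"]))
        meta["gene"] = [gene_map.get(v, pd.NA) for v in meta["variant_id"]]
    return GenotypeMatrix(dosages, meta, [str(s) for s in df.index])


def read_vcf(path) -> GenotypeMatrix:
    """Optional VCF reader: minor-allele dosage from GT, biallelic sites only.

    The ALT allele count is folded to the minor allele per site after reading.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        gt = np.asarray(variant.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(dos.astype(np.int8))
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if not rows:
        raise ValueError(f"no biallelic sites in {path}")
    dosages = np.stack(rows, axis=1)
    # fold so the stored dosage counts the minor allele
    with np.errstate(invalid="ignore"):
        miss = dosages == MISSING
        d = np.where(miss, 0, dosages)
        n_obs = (~miss).sum(axis=0)
        freq = d.sum(axis=0) / np.maximum(2 * n_obs, 1)
    flip = freq > 0.5
    dosages[:, flip] = np.where(
        miss[:, flip], MISSING, 2 - dosages[:, flip]
    ).astype(np.int8)
    meta = pd.DataFrame({"variant_id": ids})
    return GenotypeMatrix(dosages, meta, subjects)
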