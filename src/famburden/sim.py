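"""Synthetic family-study generator.

Emulates the structure of a multi-family sequencing study of a quantitative
trait: a fixed set of extended pedigrees, rare variants grouped into genes
plus a common-marker panel (for IBS and PCA), genotypes produced by gene
dropping from founder allele frequencies, and replicate traits drawn from

    y = sum_c beta_c * X_c + u + e,
    u ~ N(0, sigma2_g * 2*Phi),   e ~ N(0, sigma2_e * I),

where X_c is the collapsed rare-carrier indicator of causal gene c.  The
genotypes are fixed across replicates; only u and e are redrawn, so all
replicates share one genetic architecture.

Defaults describe the emulated study: 8 extended three-generation families
totalling roughly 700 subjects and 200 trait replicates, with polygenic
heritability 0.6 on unit total variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .collapse import collapse_gene
from .genotype import GenotypeMatrix, minor_allele_freq, read_genotypes
from .pedigree import (
    Pedigree,
    PedigreeRecord,
    kinship_matrix,
    read_pedigree,
    relationship_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "ReplicateStudy",
    "simulate_pedigree",
    "gene_drop",
    "simulate_traits",
    "simulate_study",
    "write_study",
    "read_study",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic family study.

    ``offspring_range`` is inclusive; each mated couple draws its number of
    children uniformly from it.  ``causal_genes`` maps gene labels to burden
    effect sizes in trait units; ``per_variant_effects=True`` switches the
    causal architecture from the collapsed indicator to a beta-per-rare-allele
    model (misspecification stress mode).  ``subpop_fst`` > 0 splits families
    into two founder subpopulations whose common-marker frequencies diverge
    Balding-Nichols style, giving PCA genuine structure to find.
    """

    n_families: int = 8
    generations: int = 3
    offspring_range: tuple[int, int] = (6, 10)
    total_size_range: tuple[int, int] | None = None
    n_genes: int = 60
    variants_per_gene: int | tuple[int, int] = 8
    rare_maf_range: tuple[float, float] = (0.0005, 0.009)
    n_common_markers: int = 6000
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    subpop_fst: float = 0.0
    causal_genes: dict[str, float] = field(default_factory=dict)
    per_variant_effects: bool = False
    heritability_polygenic: float = 0.6
    sigma2_e: float = 0.4
    maf_threshold: float = 0.01
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability_polygenic < 1.0:
            raise ValueError("heritability_polygenic must be in [0, 1)")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.offspring_range[0] < 1 or self.offspring_range[0] > self.offspring_range[1]:
            raise ValueError("invalid offspring_range")
        if self.generations < 2:
            raise ValueError("at least two generations required")

    @property
    def sigma2_g(self) -> float:
        """Polygenic variance implied by the heritability and sigma2_e."""
        h2 = self.heritability_polygenic
        return self.sigma2_e * h2 / (1.0 - h2)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["offspring_range"] = list(self.offspring_range)
        d["rare_maf_range"] = list(self.rare_maf_range)
        d["common_maf_range"] = list(self.common_maf_range)
        if self.total_size_range is not None:
            d["total_size_range"] = list(self.total_size_range)
        if not isinstance(self.variants_per_gene, int):
            d["variants_per_gene"] = list(self.variants_per_gene)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("offspring_range", "rare_maf_range", "common_maf_range",
                    "total_size_range", "variants_per_gene"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ReplicateStudy:
    """One simulated study: fixed pedigree and genotypes, replicated traits."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    traits: np.ndarray  # (n_replicates, n_subjects)
    truth: pd.DataFrame  # columns: gene, causal, beta, zero_power
    config: SimConfig

    def __post_init__(self) -> None:
        self.traits = np.atleast_2d(np.asarray(self.traits, dtype=float))
        if self.traits.shape[1] != len(self.pedigree.subject_order):
            raise ValueError("trait vectors do not conform to the pedigree")

    @property
    def n_replicates(self) -> int:
        return self.traits.shape[0]

    def causal_genes(self) -> list[str]:
        return list(self.truth.loc[self.truth["causal"], "gene"])


def _component_rng(root_seed: int, component: int) -> np.random.Generator:
    """Independent, reproducible stream per pipeline component."""
    return np.random.default_rng(np.random.SeedSequence([root_seed, component]))


# component indices for derived seed streams
_PEDIGREE, _FREQS, _GENEDROP, _TRAITS = 0, 1, 2, 3


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Independent multi-generation families.

    Each family starts from one founder couple; every child of a non-final
    generation marries a new founder (so the pedigree is outbred) and the
    couple's offspring count is drawn uniformly from ``offspring_range``.
    Children of the final generation are unmarried leaves.
    """
    rng = _component_rng(cfg.seed, _PEDIGREE)
    lo, hi = cfg.offspring_range
    records: list[PedigreeRecord] = []
    for f in range(1, cfg.n_families + 1):
        fam = f"FAM{f}"
        serial = 0

        def new_id() -> str:
            nonlocal serial
            serial += 1
            return f"{fam}_{serial}"

        father0, mother0 = new_id(), new_id()
        records.append(PedigreeRecord(fam, father0, None, None, 1))
        records.append(PedigreeRecord(fam, mother0, None, None, 2))
        couples = [(father0, mother0)]
        for gen in range(2, cfg.generations + 1):
            next_couples: list[tuple[str, str]] = []
            for (fa, mo) in couples:
                n_kids = int(rng.integers(lo, hi + 1))
                for _ in range(n_kids):
                    kid = new_id()
                    sex = int(rng.integers(1, 3))
                    records.append(PedigreeRecord(fam, kid, fa, mo, sex))
                    if gen < cfg.generations:
                        spouse = new_id()
                        spouse_sex = 2 if sex == 1 else 1
                        records.append(PedigreeRecord(fam, spouse, None, None, spouse_sex))
                        if sex == 1:
                            next_couples.append((kid, spouse))
                        else:
                            next_couples.append((spouse, kid))
            couples = next_couples
    ped = Pedigree(records)
    if cfg.total_size_range is not None:
        lo_n, hi_n = cfg.total_size_range
        if not lo_n <= len(ped) <= hi_n:
            raise ValueError(
                f"simulated pedigree has {len(ped)} subjects, outside the "
                f"configured range [{lo_n}, {hi_n}]"
            )
    logger.info("simulated pedigree: %d subjects in %d families", len(ped), cfg.n_families)
    return ped


def _founder_frequencies(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Variant metadata plus per-variant founder frequencies.

    Returns (meta, freqs) where freqs has shape (2, m) giving the founder
    allele frequency in each of the two subpopulations (identical rows when
    ``subpop_fst`` is 0; rare gene variants never diverge — only the common
    panel carries population structure).
    """
    if isinstance(cfg.variants_per_gene, int):
        counts = np.full(cfg.n_genes, cfg.variants_per_gene)
    else:
        lo, hi = cfg.variants_per_gene
        counts = rng.integers(lo, hi + 1, size=cfg.n_genes)
    gene_labels: list[str] = []
    variant_ids: list[str] = []
    for gi, c in enumerate(counts, start=1):
        gene = f"gene{gi:04d}"
        for vi in range(1, c + 1):
            gene_labels.append(gene)
            variant_ids.append(f"{gene}_v{vi}")
    n_rare = len(variant_ids)
    rare_freq = rng.uniform(*cfg.rare_maf_range, size=n_rare)
    common_freq = rng.uniform(*cfg.common_maf_range, size=cfg.n_common_markers)
    variant_ids += [f"cm{j:05d}" for j in range(1, cfg.n_common_markers + 1)]
    gene_labels += [None] * cfg.n_common_markers

    base = np.concatenate([rare_freq, common_freq])
    freqs = np.vstack([base, base])
    if cfg.subpop_fst > 0:
        fst = cfg.subpop_fst
        a = base * (1.0 - fst) / fst
        b = (1.0 - base) * (1.0 - fst) / fst
        for pop in range(2):
            drawn = rng.beta(a, b)
            # only common markers carry the divergence
            freqs[pop, n_rare:] = drawn[n_rare:]
    meta = pd.DataFrame({"variant_id": variant_ids, "gene": gene_labels})
    return meta, freqs


def gene_drop(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Drop founder alleles through the pedigree, one variant at a time.

    Founders draw two alleles i.i.d. Bernoulli(founder frequency); each
    non-founder inherits one uniformly chosen allele from each parent,
    independently across variants (no linkage).  Realised sample MAFs are
    computed on the finished matrix.
    """
    rng_f = _component_rng(cfg.seed, _FREQS)
    meta, freqs = _founder_frequencies(cfg, rng_f)
    rng = _component_rng(cfg.seed, _GENEDROP)
    n = len(ped)
    m = len(meta)
    # families alternate between the two founder subpopulations
    fam_ids = ped.family_ids
    fam_pop = {fam: i % 2 for i, fam in enumerate(fam_ids)}
    pop_of = np.array([fam_pop[r.family_id] for r in ped.records])

    a1 = np.zeros((n, m), dtype=np.int8)
    a2 = np.zeros((n, m), dtype=np.int8)
    parents = ped.parent_indices()
    order = ped._topological_order()
    for i in order:
        fa, mo = parents[i]
        if fa < 0 and mo < 0:
            p = freqs[pop_of[i]]
            a1[i] = rng.random(m) < p
            a2[i] = rng.random(m) < p
        else:
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            a1[i] = np.where(pick_f == 0, a1[fa], a2[fa])
            a2[i] = np.where(pick_m == 0, a1[mo], a2[mo])
    g = GenotypeMatrix((a1 + a2).astype(np.int8), meta, list(ped.subject_order))
    minor_allele_freq(g)
    return g


def simulate_traits(ped: Pedigree, geno: GenotypeMatrix, cfg: SimConfig) -> ReplicateStudy:
    """Replicate trait vectors from the polygenic + collapsed-burden model."""
    genes = geno.genes()
    for gene in cfg.causal_genes:
        if gene not in genes:
            raise ValueError(f"causal gene {gene!r} not present in the genotypes")

    n = len(ped)
    fixed = np.zeros(n)
    zero_power: dict[str, bool] = {}
    for gene, beta in cfg.causal_genes.items():
        if cfg.per_variant_effects:
            mask = (geno.variant_meta["gene"] == gene).to_numpy(dtype=bool)
            mask &= geno.maf < cfg.maf_threshold
            dos = np.where(geno.dosages[:, mask] > 0, geno.dosages[:, mask], 0)
            x = dos.sum(axis=1).astype(float)
        else:
            design = collapse_gene(geno, gene, cfg.maf_threshold)
            x = design.indicator.astype(float)
        if x.sum() == 0:
            logger.warning("causal gene %s has zero carriers (zero power)", gene)
            zero_power[gene] = True
        else:
            zero_power[gene] = False
        fixed = fixed + beta * x

    sigma2_g = cfg.sigma2_g
    rng = _component_rng(cfg.seed, _TRAITS)
    if sigma2_g > 0:
        k2 = relationship_matrix(kinship_matrix(ped)).values
        # 2*Phi is PSD; tiny jitter guards the Cholesky against exact ties
        chol = np.linalg.cholesky(k2 + 1e-10 * np.eye(n))
    else:
        chol = None
    traits = np.empty((cfg.n_replicates, n))
    for r in range(cfg.n_replicates):
        y = fixed.copy()
        if chol is not None:
            y += np.sqrt(sigma2_g) * (chol @ rng.standard_normal(n))
        y += np.sqrt(cfg.sigma2_e) * rng.standard_normal(n)
        traits[r] = y

    truth = pd.DataFrame(
        {
            "gene": genes,
            "causal": [g in cfg.causal_genes for g in genes],
            "beta": [cfg.causal_genes.get(g, 0.0) for g in genes],
            "zero_power": [zero_power.get(g, False) for g in genes],
        }
    )
    return ReplicateStudy(ped, geno, traits, truth, cfg)


def simulate_study(cfg: SimConfig) -> ReplicateStudy:
    """Full generator: pedigree -> gene dropping -> replicate traits."""
    ped = simulate_pedigree(cfg)
    geno = gene_drop(ped, cfg)
    return simulate_traits(ped, geno, cfg)


def write_study(study: ReplicateStudy, outdir) -> None:
    """Write the study as plain-text files that round-trip bit-exactly.

    Emits ``pedigree.fam``, ``genotypes.tsv``, ``variants.tsv``,
    ``truth.tsv``, ``simconfig.yaml`` and one ``traits/replicate_NNN.tsv``
    per replicate.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "pedigree.fam", "w") as fh:
        for r in study.pedigree.records:
            fh.write(
                f"{r.family_id}\t{r.individual_id}\t{r.father_id or '0'}\t"
                f"{r.mother_id or '0'}\t{r.sex}\t-9\n"
            )
    study.genotypes.write_tsv(outdir / "genotypes.tsv")
    meta = study.genotypes.variant_meta.copy()
    meta["gene"] = meta["gene"].fillna("NA")
    meta.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    study.config.to_yaml(outdir / "simconfig.yaml")
    traits_dir = outdir / "traits"
    traits_dir.mkdir(exist_ok=True)
    for r in range(study.n_replicates):
        df = pd.DataFrame(
            {"subject": study.pedigree.subject_order, "value": study.traits[r]}
        )
        df.to_csv(traits_dir / f"replicate_{r + 1:03d}.tsv", sep="\t",
                  index=False, float_format="%.17g")


def read_study(indir) -> ReplicateStudy:
    """Read back a study written by :func:`write_study`."""
    indir = Path(indir)
    ped = read_pedigree(indir / "pedigree.fam")
    geno = read_genotypes(indir / "genotypes.tsv")
    meta = pd.read_csv(indir / "variants.tsv", sep="\t", dtype=str)
    gene = meta["gene"].where(meta["gene"] != "NA", pd.NA)
    geno.variant_meta["gene"] = gene.to_numpy()
    minor_allele_freq(geno)
    truth = pd.read_csv(indir / "truth.tsv", sep="\t")
    cfg = SimConfig.from_yaml(indir / "simconfig.yaml")
    trait_files = sorted((indir / "traits").glob("replicate_*.tsv"))
    traits = np.vstack(
        [pd.read_csv(f, sep="\t", float_precision="round_trip")["value"].to_numpy()
         for f in trait_files]
    )
    return ReplicateStudy(ped, geno, traits, truth, cfg)
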