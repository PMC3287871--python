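"""Rare-variant collapsing (Li & Leal CMC presence/absence coding).

A gene's rare variants (folded MAF strictly below a threshold, 0.01 by
default) are collapsed into a single binary indicator per subject: 1 if the
subject carries at least one minor allele at at least one rare variant of the
gene, else 0.  Missing genotypes count as non-carrier.  The indicator is the
fixed-effect genotype predictor tested by the association models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["CollapsedDesign", "collapse_gene", "collapse_all", "designs_to_frame"]

DEFAULT_MAF_THRESHOLD = 0.01


@dataclass
class CollapsedDesign:
    """Binary carrier indicator for one gene's rare-variant set."""

    gene: str
    indicator: np.ndarray  # n-vector of 0/1 (int8)
    carrier_count: int
    n_rare_variants: int
    maf_threshold: float
    subject_order: list[str]

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=np.int8)
        if self.carrier_count != int(self.indicator.sum()):
            raise ValueError("carrier_count inconsistent with indicator")
        if self.n_rare_variants == 0 and self.carrier_count != 0:
            raise ValueError("no rare variants but nonzero carriers")

    @property
    def testable(self) -> bool:
        """False when the indicator is constant (all 0 or all 1)."""
        return 0 < self.carrier_count < len(self.indicator)


def collapse_gene(
    g: GenotypeMatrix, gene: str, maf_threshold: float = DEFAULT_MAF_THRESHOLD
) -> CollapsedDesign:
    """Collapse one gene's rare variants into a 0/1 carrier indicator.

    Rare = folded MAF strictly below ``maf_threshold``.  A subject is a
    carrier iff it has dosage >= 1 at >= 1 rare variant of the gene; missing
    dosages are read as non-carrier.
    """
    gene_mask = (g.variant_meta["gene"] == gene).to_numpy(dtype=bool)
    if not gene_mask.any():
        raise KeyError(f"gene {gene!r} not present in variant annotations")
    maf = g.maf
    rare = gene_mask & (maf < maf_threshold)
    n_rare = int(rare.sum())
    if n_rare == 0:
        indicator = np.zeros(g.n_subjects, dtype=np.int8)
    else:
        dos = g.dosages[:, rare]
        carrier = (dos != MISSING) & (dos >= 1)
        if (dos == MISSING).any():
            logger.info("gene %s: missing dosages read as non-carrier", gene)
        indicator = carrier.any(axis=1).astype(np.int8)
    return CollapsedDesign(
        gene=gene,
        indicator=indicator,
        carrier_count=int(indicator.sum()),
        n_rare_variants=n_rare,
        maf_threshold=maf_threshold,
        subject_order=list(g.subject_order),
    )


def collapse_all(
    g: GenotypeMatrix, maf_threshold: float = DEFAULT_MAF_THRESHOLD
) -> list[CollapsedDesign]:
    """One CollapsedDesign per distinct annotated gene, in first-appearance order.

    Designs with a constant indicator remain in the list; downstream code
    reports them as untestable rather than dropping them silently.
    """
    genes = g.genes()
    if not genes:
        raise ValueError("genotype matrix has no gene annotations")
    designs = [collapse_gene(g, gene, maf_threshold) for gene in genes]
    n_untestable = sum(not d.testable for d in designs)
    if n_untestable:
        logger.info(
            "collapse_all: %d of %d genes have a constant indicator (untestable)",
            n_untestable,
            len(designs),
        )
    return designs


def designs_to_frame(designs: list[CollapsedDesign]) -> pd.DataFrame:
    """Subjects-by-genes 0/1 table of the collapsed indicators."""
    if not designs:
        raise ValueError("no designs to export")
    return pd.DataFrame(
        {d.gene: d.indicator for d in designs}, index=designs[0].subject_order
    )
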