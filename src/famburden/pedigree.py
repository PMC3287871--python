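"""Pedigree handling and pedigree-based kinship.

A pedigree is read from a whitespace-delimited PLINK ``.fam``-style file
(family, individual, father, mother, sex, [phenotype, ignored]).  The kinship
coefficient :math:`\\varphi(i,j)` — the probability that an allele sampled at
random from *i* is identical by descent to one sampled from *j* — is computed
by the standard recursion over a parents-before-children ordering:

.. math::

    \\varphi(i,i) = \\tfrac{1}{2}\\bigl(1 + \\varphi(f_i, m_i)\\bigr), \\qquad
    \\varphi(i,j) = \\tfrac{1}{2}\\bigl(\\varphi(f_i, j) + \\varphi(m_i, j)\\bigr)

where the second rule is applied with *i* chosen so that *j* is not a
descendant of *i*, and any missing-parent term contributes 0.  Doubling the
kinship matrix gives the additive relationship matrix :math:`2\\Phi` used as
the covariance structure of the polygenic random effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PedigreeError",
    "PedigreeFormatError",
    "PedigreeReferenceError",
    "PedigreeStructureError",
    "PedigreeRecord",
    "Pedigree",
    "RelatednessMatrix",
    "read_pedigree",
    "kinship_matrix",
    "relationship_matrix",
]

MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class PedigreeFormatError(PedigreeError):
    """Malformed record, e.g. a duplicated individual id."""


class PedigreeReferenceError(PedigreeError):
    """A parent id that does not refer to any individual in the file."""


class PedigreeStructureError(PedigreeError):
    """A structural impossibility, e.g. an individual who is its own ancestor."""


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 = male, 2 = female, 0 = unknown

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """Validated pedigree with a canonical subject ordering.

    ``subject_order`` (the file row order) is the ordering shared by every
    matrix and vector derived from this pedigree; downstream code aligns by
    these labels, never by position alone.
    """

    records: list[PedigreeRecord]
    subject_order: list[str] = field(init=False)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.subject_order = [r.individual_id for r in self.records]
        self._index = {iid: k for k, iid in enumerate(self.subject_order)}
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            for r in self.records:
                if r.individual_id in seen:
                    raise PedigreeFormatError(
                        f"duplicate individual id {r.individual_id!r}"
                    )
                seen.add(r.individual_id)
        for r in self.records:
            for which, pid in (("father", r.father_id), ("mother", r.mother_id)):
                if pid is not None and pid not in self._index:
                    raise PedigreeReferenceError(
                        f"{which} id {pid!r} of individual "
                        f"{r.individual_id!r} is not in the pedigree"
                    )
        self._topological_order()  # raises on cycles

    def _topological_order(self) -> list[int]:
        """Indices ordered parents-before-children; raises on a cycle."""
        n = len(self.records)
        state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 in progress, 2 done
        order: list[int] = []

        for start in range(n):
            if state[start] == 2:
                continue
            # iterative DFS on the parent relation
            stack: list[tuple[int, int]] = [(start, 0)]
            while stack:
                node, phase = stack.pop()
                if phase == 0:
                    if state[node] == 2:
                        continue
                    if state[node] == 1:
                        raise PedigreeStructureError(
                            f"pedigree cycle involving individual "
                            f"{self.records[node].individual_id!r}"
                        )
                    state[node] = 1
                    stack.append((node, 1))
                    for pid in (
                        self.records[node].father_id,
                        self.records[node].mother_id,
                    ):
                        if pid is not None:
                            p = self._index[pid]
                            if state[p] == 1:
                                raise PedigreeStructureError(
                                    f"pedigree cycle involving individual "
                                    f"{self.records[p].individual_id!r}"
                                )
                            if state[p] == 0:
                                stack.append((p, 0))
                else:
                    state[node] = 2
                    order.append(node)
        return order

    # -- conveniences ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    @property
    def family_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.family_id not in out:
                out.append(r.family_id)
        return out

    def founders(self) -> list[str]:
        return [r.individual_id for r in self.records if r.is_founder]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of father/mother row indices, -1 where missing."""
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for k, r in enumerate(self.records):
            if r.father_id is not None:
                out[k, 0] = self._index[r.father_id]
            if r.mother_id is not None:
                out[k, 1] = self._index[r.mother_id]
        return out


@dataclass
class RelatednessMatrix:
    """Symmetric subject-by-subject matrix used as a random-effect covariance.

    ``kind`` is one of ``pedigree_kinship`` (entries are kinship coefficients
    phi), ``relationship_2phi`` (the additive relationship matrix 2*phi) or
    ``ibs`` (marker allele-sharing similarity).
    """

    values: np.ndarray
    subject_order: list[str]
    kind: str

    VALID_KINDS = ("pedigree_kinship", "relationship_2phi", "ibs")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"unknown relatedness kind {self.kind!r}")
        n = len(self.subject_order)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} subject labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("relatedness matrix is not symmetric")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.subject_order, columns=self.subject_order
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="subject")

    @classmethod
    def read_tsv(cls, path, kind: str) -> "RelatednessMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], kind)


def read_pedigree(path, dialect: str = "fam6col") -> Pedigree:
    """Read a whitespace-delimited PLINK-style pedigree file.

    Columns: family, individual, father, mother, sex[, phenotype ignored].
    A parent id of ``"0"`` means missing; founders have both parents missing.
    """
    if dialect != "fam6col":
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    records: list[PedigreeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 5:
                raise PedigreeFormatError(
                    f"{path}:{lineno}: expected >= 5 columns, got {len(fields)}"
                )
            fam, iid, fid, mid, sex = fields[:5]
            try:
                sex_code = int(sex)
            except ValueError:
                sex_code = 0
            if sex_code not in (1, 2):
                sex_code = 0
            records.append(
                PedigreeRecord(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if fid == MISSING_PARENT else fid,
                    mother_id=None if mid == MISSING_PARENT else mid,
                    sex=sex_code,
                )
            )
    return Pedigree(records)


def kinship_matrix(ped: Pedigree) -> RelatednessMatrix:
    """Pedigree kinship matrix by the parents-first recursion.

    Individuals from different families are unrelated by construction, so the
    matrix is block diagonal in families and each block is filled
    independently.  Inbreeding is handled through the diagonal recursion
    ``phi(i,i) = (1 + phi(father, mother)) / 2``.
    """
    n = len(ped)
    phi = np.zeros((n, n))
    order = ped._topological_order()
    parents = ped.parent_indices()
    fam = np.array([r.family_id for r in ped.records])

    # position of each individual within the topological order; ancestors of i
    # always have a smaller position, so when we process i every phi involving
    # its parents and any earlier-processed j is final.
    pos = np.empty(n, dtype=np.int64)
    pos[np.array(order)] = np.arange(n)

    for i in order:
        f, m = parents[i]
        if f < 0 and m < 0:
            phi[i, i] = 0.5
        else:
            phi_fm = phi[f, m] if (f >= 0 and m >= 0) else 0.0
            phi[i, i] = 0.5 * (1.0 + phi_fm)
        same_family = np.flatnonzero((fam == fam[i]) & (pos < pos[i]))
        if same_family.size:
            contrib = np.zeros(same_family.size)
            if f >= 0:
                contrib += phi[f, same_family]
            if m >= 0:
                contrib += phi[m, same_family]
            phi[i, same_family] = 0.5 * contrib
            phi[same_family, i] = phi[i, same_family]
    return RelatednessMatrix(phi, list(ped.subject_order), "pedigree_kinship")


def relationship_matrix(k: RelatednessMatrix) -> RelatednessMatrix:
    """Double a kinship matrix into the additive relationship matrix 2*phi."""
    if k.kind != "pedigree_kinship":
        raise ValueError(
            f"relationship_matrix expects kind='pedigree_kinship', got {k.kind!r}"
        )
    return RelatednessMatrix(2.0 * k.values, list(k.subject_order), "relationship_2phi")
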