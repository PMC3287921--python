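"""Core containers shared by all stages of the pipeline.

A :class:`GenotypeMatrix` holds minor-allele dosages for one panel
(family or unrelated case-control); a :class:`PhenotypeTable` holds
affection status plus optional pedigree links; a :class:`SibPairSet`
indexes sib pairs into the family matrix; a :class:`GroupMap` assigns
variant columns to genes (or any other grouping of the variant set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype in ``GenotypeMatrix.counts``.
MISSING = -1

CONCORDANT_AFFECTED = "concordant_affected"
DISCORDANT = "discordant"
PAIR_TYPES = (CONCORDANT_AFFECTED, DISCORDANT)


@dataclass
class GenotypeMatrix:
    """Individuals x variants minor-allele dosage matrix.

    ``counts[k, j]`` is the number of copies of the minor allele of
    variant ``j`` carried by individual ``k`` (0, 1 or 2), or
    :data:`MISSING`.  ``variant_meta`` is indexed by variant id with
    columns ``chrom``, ``position`` (1-based), ``group_id`` and
    ``flipped`` (True where the counted allele is the VCF REF allele
    because ALT was the major allele in the loaded panel).
    """

    individual_ids: list[str]
    variant_ids: list[str]
    counts: np.ndarray
    variant_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.variant_meta is None:
            self.variant_meta = pd.DataFrame(
                {
                    "chrom": "1",
                    "position": np.arange(1, len(self.variant_ids) + 1),
                    "group_id": "g",
                    "flipped": False,
                },
                index=pd.Index(self.variant_ids, name="variant_id"),
            )
        self.validate()

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def validate(self) -> None:
        n, m = self.counts.shape
        if n != len(self.individual_ids):
            raise ValueError(
                f"counts has {n} rows but {len(self.individual_ids)} individual ids"
            )
        if m != len(self.variant_ids):
            raise ValueError(
                f"counts has {m} columns but {len(self.variant_ids)} variant ids"
            )
        bad = ~np.isin(self.counts, (0, 1, 2, MISSING))
        if bad.any():
            k, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.counts[k, j]} at individual "
                f"{self.individual_ids[k]}, variant {self.variant_ids[j]}"
            )
        if len(self.variant_meta) != m:
            raise ValueError("variant_meta length does not match variant count")

    def dosages(self, cols: np.ndarray | None = None) -> np.ndarray:
        """Float dosage matrix with missing genotypes imputed to 0 copies.

        Zero-imputation is conservative for a burden score (it can only
        shrink a carrier count, never inflate it).  Pass ``cols`` to
        restrict to a group's variant columns without materializing the
        full panel.
        """
        c = self.counts if cols is None else self.counts[:, np.asarray(cols, dtype=np.intp)]
        d = c.astype(np.float64)
        d[c == MISSING] = 0.0
        return d

    @property
    def n_missing(self) -> int:
        return int((self.counts == MISSING).sum())

    def index_of(self, individual_ids: Iterable[str]) -> np.ndarray:
        lookup = {iid: k for k, iid in enumerate(self.individual_ids)}
        return np.array([lookup[i] for i in individual_ids], dtype=np.intp)


@dataclass
class PhenotypeTable:
    """Affection status, optionally with pedigree structure.

    ``table`` is indexed by individual id with a boolean ``affected``
    column and optional ``family_id``, ``father_id``, ``mother_id``
    columns (empty string / "0" meaning unknown parent, as in PED files).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "affected" not in self.table.columns:
            raise ValueError("phenotype table needs an 'affected' column")
        self.table = self.table.copy()
        self.table["affected"] = self.table["affected"].astype(bool)

    @classmethod
    def from_status(
        cls, individual_ids: Iterable[str], affected: Iterable[bool]
    ) -> "PhenotypeTable":
        ids = list(individual_ids)
        return cls(
            pd.DataFrame(
                {"affected": np.asarray(list(affected), dtype=bool)},
                index=pd.Index(ids, name="individual_id"),
            )
        )

    def status_vector(self, individual_ids: Iterable[str]) -> np.ndarray:
        """Boolean affected-status vector aligned to ``individual_ids``."""
        missing = [i for i in individual_ids if i not in self.table.index]
        if missing:
            raise KeyError(f"no phenotype for individuals: {missing[:5]}")
        return self.table.loc[list(individual_ids), "affected"].to_numpy(dtype=bool)

    @property
    def has_pedigree(self) -> bool:
        return {"family_id", "father_id", "mother_id"} <= set(self.table.columns)


@dataclass(frozen=True)
class SibPair:
    """One sib pair; for discordant pairs ``sib1`` is the affected sib."""

    sib1: int
    sib2: int
    pair_type: str

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"unknown pair_type {self.pair_type!r}")


@dataclass
class SibPairSet:
    pairs: list[SibPair]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[SibPair]:
        return iter(self.pairs)

    def of_type(self, pair_type: str) -> "SibPairSet":
        if pair_type not in PAIR_TYPES:
            raise ValueError(f"unknown pair_type {pair_type!r}")
        return SibPairSet([p for p in self.pairs if p.pair_type == pair_type])

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(sib1 indices, sib2 indices) as integer arrays."""
        s1 = np.array([p.sib1 for p in self.pairs], dtype=np.intp)
        s2 = np.array([p.sib2 for p in self.pairs], dtype=np.intp)
        return s1, s2

    def validate(self, n_individuals: int, pheno: PhenotypeTable | None = None,
                 individual_ids: list[str] | None = None) -> None:
        for p in self.pairs:
            if not (0 <= p.sib1 < n_individuals and 0 <= p.sib2 < n_individuals):
                raise ValueError(f"pair index out of range: {p}")
        if pheno is not None and individual_ids is not None:
            aff = pheno.status_vector(individual_ids)
            for p in self.pairs:
                if p.pair_type == CONCORDANT_AFFECTED:
                    ok = aff[p.sib1] and aff[p.sib2]
                else:
                    ok = aff[p.sib1] and not aff[p.sib2]
                if not ok:
                    raise ValueError(f"pair {p} inconsistent with phenotype statuses")


@dataclass
class GroupMap:
    """Ordered mapping group_id -> variant column indices (disjoint)."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {g: np.asarray(idx, dtype=np.intp) for g, idx in self.groups.items()}
        seen: set[int] = set()
        for g, idx in self.groups.items():
            dup = seen.intersection(idx.tolist())
            if dup:
                raise ValueError(f"variant indices {sorted(dup)[:5]} appear in more than one group")
            seen.update(idx.tolist())

    def __len__(self) -> int:
        return len(self.groups)

    def items(self):
        return self.groups.items()

    @classmethod
    def from_variant_meta(cls, variant_meta: pd.DataFrame) -> "GroupMap":
        """Build from the ``group_id`` column of a variant metadata frame."""
        groups: dict[str, list[int]] = {}
        for j, g in enumerate(variant_meta["group_id"]):
            groups.setdefault(str(g), []).append(j)
        return cls({g: np.array(idx, dtype=np.intp) for g, idx in groups.items()})


@dataclass
class GeneTestResult:
    """Outcome of one association test on one variant group."""

    group_id: str
    method: str
    statistic: float  # NaN when the statistic is undefined (degenerate group)
    p_value: float
    n_weighted_variants: int
    n_rare_variants: int
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.n_weighted_variants < 0:
            raise ValueError("n_weighted_variants must be >= 0")
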