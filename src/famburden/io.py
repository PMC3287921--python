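"""Readers and writers for the supported on-disk formats.

Supported inputs: VCF (GT field only, via cyvcf2), a minimal
``matrix_tsv`` dialect (header row of variant ids, first column
individual id, entries 0/1/2/NA), PED-style pedigree/phenotype files,
and group maps given either as an explicit two-column
``variant_id<TAB>group_id`` table or as BED intervals.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CONCORDANT_AFFECTED,
    DISCORDANT,
    MISSING,
    GeneTestResult,
    GenotypeMatrix,
    GroupMap,
    PhenotypeTable,
    SibPair,
    SibPairSet,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    on_multiallelic: str = "error",
) -> GenotypeMatrix:
    """Load a genotype panel in minor-allele orientation.

    The counted allele at each site is the less frequent allele *in the
    loaded panel*; where the VCF ALT allele is the major allele the
    column is flipped to REF dosage and flagged in
    ``variant_meta['flipped']``.

    Parameters
    ----------
    format
        ``"vcf"`` or ``"matrix_tsv"``.
    on_multiallelic
        ``"error"`` (default) or ``"skip"`` for VCF records with more
        than one ALT allele.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path, on_multiallelic)
    if format == "matrix_tsv":
        return read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, on_multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path), gts012=True)
    individual_ids = list(vcf.samples)
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    chroms: list[str] = []
    positions: list[int] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if on_multiallelic == "skip":
                logger.warning("skipping multiallelic record at %s:%d", rec.CHROM, rec.POS)
                continue
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                "(pass on_multiallelic='skip' to drop such sites)"
            )
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variant_ids.append(vid)
        columns.append(g)
        chroms.append(str(rec.CHROM))
        positions.append(int(rec.POS))
    counts = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(individual_ids), 0), dtype=np.int8)
    )
    meta = pd.DataFrame(
        {"chrom": chroms, "position": positions, "group_id": "", "flipped": False},
        index=pd.Index(variant_ids, name="variant_id"),
    )
    gm = GenotypeMatrix(individual_ids, variant_ids, counts, meta)
    _orient_to_minor(gm)
    return gm


def _orient_to_minor(gm: GenotypeMatrix) -> None:
    """Flip columns where the counted allele is the major allele in this panel."""
    if gm.n_variants == 0:
        return
    obs = gm.counts != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            obs.sum(axis=0) > 0,
            np.where(obs, gm.counts, 0).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1)),
            0.0,
        )
    flip = freq > 0.5
    if flip.any():
        cols = gm.counts[:, flip]
        flipped = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
        gm.counts[:, flip] = flipped
        gm.variant_meta.loc[flip, "flipped"] = True


def read_matrix_tsv(path: str | Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise ValueError(f"cannot parse matrix_tsv {path}: {exc}") from exc
    counts = df.replace("NA", str(MISSING)).astype(np.int8).to_numpy()
    gm = GenotypeMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], counts
    )
    _orient_to_minor(gm)
    return gm


def write_matrix_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        gm.counts.astype(object), index=gm.individual_ids, columns=gm.variant_ids
    )
    df[gm.counts == MISSING] = "NA"
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pedigree / phenotype

#: PED affection codes
_PED_STATUS = {"1": False, "2": True}


def read_pedigree(path: str | Path) -> PhenotypeTable:
    """Read a PED-style file: family, individual, father, mother, sex, status.

    Status codes 1 = unaffected, 2 = affected; anything else (0, -9)
    marks the individual's phenotype unknown and the row is kept with
    ``affected = False`` but flagged in ``status_known``.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "status"],
        dtype=str,
        comment="#",
    )
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"duplicate individual id {dup!r} in {path}")
    df["affected"] = df["status"].eq("2")
    df["status_known"] = df["status"].isin(list(_PED_STATUS))
    df = df.set_index("individual_id")
    return PhenotypeTable(df[["affected", "status_known", "family_id", "father_id", "mother_id", "sex"]])


def extract_sib_pairs(
    pheno: PhenotypeTable, individual_ids: list[str]
) -> SibPairSet:
    """Enumerate all full-sib pairs among ``individual_ids``.

    Two individuals form a full-sib pair when they share the same family
    and both (known) parents.  Pairs are classified as
    concordant-affected (both affected) or discordant (exactly one
    affected, listed first); unaffected-unaffected pairs are dropped.
    Sibships larger than two contribute every qualifying pair.
    Individuals with an unknown parent or phenotype are skipped with a
    logged warning.
    """
    if not pheno.has_pedigree:
        raise ValueError("phenotype table has no pedigree columns")
    t = pheno.table
    index_of = {iid: k for k, iid in enumerate(individual_ids)}
    sibships: dict[tuple[str, str, str], list[str]] = {}
    n_skipped = 0
    for iid in individual_ids:
        if iid not in t.index:
            n_skipped += 1
            continue
        row = t.loc[iid]
        fa, mo = str(row["father_id"]), str(row["mother_id"])
        if fa in ("0", "", "nan") or mo in ("0", "", "nan"):
            n_skipped += 1
            continue
        if "status_known" in t.columns and not row["status_known"]:
            n_skipped += 1
            continue
        sibships.setdefault((str(row["family_id"]), fa, mo), []).append(iid)
    if n_skipped:
        logger.warning(
            "extract_sib_pairs: skipped %d individuals with missing parents/phenotype",
            n_skipped,
        )
    pairs: list[SibPair] = []
    for sibs in sibships.values():
        sibs = sorted(sibs, key=lambda i: index_of[i])
        for a, b in itertools.combinations(sibs, 2):
            aff_a = bool(t.loc[a, "affected"])
            aff_b = bool(t.loc[b, "affected"])
            if aff_a and aff_b:
                pairs.append(SibPair(index_of[a], index_of[b], CONCORDANT_AFFECTED))
            elif aff_a != aff_b:
                affected, other = (a, b) if aff_a else (b, a)
                pairs.append(SibPair(index_of[affected], index_of[other], DISCORDANT))
    return SibPairSet(pairs)


# ---------------------------------------------------------------------------
# group maps


def read_group_map(
    path: str | Path, variant_meta: pd.DataFrame
) -> GroupMap:
    """Read a variant grouping and resolve it to column indices.

    Two dialects are auto-detected: an explicit two-column
    ``variant_id<TAB>group_id`` table, and a BED-like four-column
    ``chrom  start  end  group_id`` interval file (0-based half-open
    intervals, matched against the 1-based ``position`` column of
    ``variant_meta``).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] == 2:
        df.columns = ["variant_id", "group_id"]
        col_of = {vid: j for j, vid in enumerate(variant_meta.index)}
        groups: dict[str, list[int]] = {}
        for vid, gid in zip(df["variant_id"], df["group_id"]):
            if vid not in col_of:
                raise ValueError(f"group map references unknown variant {vid!r}")
            groups.setdefault(gid, []).append(col_of[vid])
        return GroupMap({g: np.array(ix, dtype=np.intp) for g, ix in groups.items()})
    if df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "start", "end", "group_id"]
        pos = variant_meta["position"].to_numpy(dtype=np.int64)
        chrom = variant_meta["chrom"].astype(str).to_numpy()
        groups = {}
        assigned = np.zeros(len(variant_meta), dtype=bool)
        for _, row in df.iterrows():
            start, end = int(row["start"]), int(row["end"])
            hit = (chrom == str(row["chrom"])) & (pos > start) & (pos <= end)
            hit &= ~assigned
            assigned |= hit
            groups.setdefault(str(row["group_id"]), []).extend(np.flatnonzero(hit).tolist())
        return GroupMap({g: np.array(ix, dtype=np.intp) for g, ix in groups.items()})
    raise ValueError(f"group map {path} must have 2 (variant,group) or 4 (BED) columns")


# ---------------------------------------------------------------------------
# results

RESULT_COLUMNS = [
    "group_id",
    "method",
    "statistic",
    "p_value",
    "n_weighted_variants",
    "n_rare_variants",
]


def results_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    rows = [
        {
            "group_id": r.group_id,
            "method": r.method,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "n_weighted_variants": r.n_weighted_variants,
            "n_rare_variants": r.n_rare_variants,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: list[GeneTestResult], path: str | Path) -> None:
    """Write one tab-delimited row per tested group, full-precision p-values."""
    df = results_frame(results)
    df["statistic"] = df["statistic"].map(lambda x: repr(float(x)))
    df["p_value"] = df["p_value"].map(lambda x: repr(float(x)))
    df.to_csv(path, sep="\t", index=False)
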