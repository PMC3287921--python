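"""Synthetic cohorts with the statistical structure the method assumes.

The generator emulates an exome-style rare-variant study: per-gene
variant panels with a MAF spectrum concentrated below 1%, a logistic
liability model in which a subset of rare variants in causal genes
carries large effects, nuclear families ascertained for concordant-
affected or discordant sib pairs, and independently ascertained
unrelated cases and controls.  Sites are simulated in linkage
equilibrium with per-site independent Mendelian transmission, so every
moment (MAF recovery, sib dosage correlation of 1/2 at neutral sites,
baseline prevalence) has a closed-form check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import (
    CONCORDANT_AFFECTED,
    DISCORDANT,
    GenotypeMatrix,
    GroupMap,
    PhenotypeTable,
    SibPair,
    SibPairSet,
)


@dataclass
class SimulationScenario:
    """One study condition: genome architecture, disease model, sampling
    targets.

    Per gene, ``variants_per_gene`` sites get MAFs drawn from a mixture:
    ``rare_fraction`` of sites uniform on ``maf_rare_range`` and the
    rest uniform on ``maf_common_range``.  In each gene listed in
    ``causal_genes``, each *rare* site is causal with probability
    ``causal_variant_fraction``, with per-allele log-odds drawn uniform
    on ``effect_range``; all other sites have effect 0.  Affection is
    logit(P) = logit(prevalence) + sum_j beta_j g_j.
    """

    n_genes: int = 5
    variants_per_gene: int = 20
    rare_fraction: float = 0.8
    maf_rare_range: tuple[float, float] = (0.0005, 0.01)
    maf_common_range: tuple[float, float] = (0.01, 0.3)
    causal_genes: tuple[int, ...] = ()
    causal_variant_fraction: float = 0.5
    effect_range: tuple[float, float] = (1.5, 3.0)
    prevalence: float = 0.1
    n_affected_pairs: int = 0
    n_discordant_pairs: int = 0
    n_cases: int = 0
    n_controls: int = 0
    seed: int = 0
    max_attempt_factor: int = 2000  # cap on simulated units per requested unit

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        for lo, hi in (self.maf_rare_range, self.maf_common_range):
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError("MAF ranges must lie in (0, 0.5]")
        if min(self.n_affected_pairs, self.n_discordant_pairs,
               self.n_cases, self.n_controls) < 0:
            raise ValueError("ascertainment counts must be >= 0")
        if any(g < 0 or g >= self.n_genes for g in self.causal_genes):
            raise ValueError("causal gene index out of range")

    @property
    def n_variants(self) -> int:
        return self.n_genes * self.variants_per_gene


@dataclass
class GenomeArchitecture:
    """Frozen per-variant truth drawn once per scenario realization."""

    maf: np.ndarray
    beta: np.ndarray  # per-allele log-odds
    variant_ids: list[str]
    variant_meta: pd.DataFrame
    group_map: GroupMap

    @property
    def is_causal(self) -> np.ndarray:
        return self.beta != 0.0

    @property
    def is_rare(self) -> np.ndarray:
        return self.maf <= 0.01


def draw_architecture(
    scn: SimulationScenario, rng: np.random.Generator
) -> GenomeArchitecture:
    L = scn.n_variants
    is_rare = rng.random(L) < scn.rare_fraction
    maf = np.where(
        is_rare,
        rng.uniform(*scn.maf_rare_range, size=L),
        rng.uniform(*scn.maf_common_range, size=L),
    )
    gene_of = np.repeat(np.arange(scn.n_genes), scn.variants_per_gene)
    beta = np.zeros(L)
    for g in scn.causal_genes:
        in_gene = gene_of == g
        cand = in_gene & is_rare
        causal = cand & (rng.random(L) < scn.causal_variant_fraction)
        beta[causal] = rng.uniform(*scn.effect_range, size=int(causal.sum()))
    variant_ids = [
        f"gene{g}_v{j}" for g, j in zip(gene_of, np.tile(np.arange(scn.variants_per_gene), scn.n_genes))
    ]
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "position": np.arange(L) * 100 + 1,
            "group_id": [f"gene{g}" for g in gene_of],
            "flipped": False,
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    group_map = GroupMap.from_variant_meta(meta)
    return GenomeArchitecture(maf, beta, variant_ids, meta, group_map)


def sample_genotypes(
    n: int, maf: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """n individuals x L sites, dosage ~ Binomial(2, maf), sites independent."""
    return rng.binomial(2, maf, size=(n, maf.size)).astype(np.int8)


def disease_probability(
    dosages: np.ndarray, beta: np.ndarray, prevalence: float
) -> np.ndarray:
    return expit(logit(prevalence) + dosages @ beta)


def sample_trio_offspring(
    n_families: int, maf: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Parent dosages and two offspring dosages by Mendelian transmission.

    Parents' haplotypes are population draws (Bernoulli(maf) per site);
    each offspring receives one uniformly chosen haplotype per parent,
    independently per site (sites are in linkage equilibrium, so the
    absence of a recombination map changes nothing).
    Returns (father, mother, sib1, sib2), each n_families x L, int8.
    """
    L = maf.size
    # int8, not bool: dosages are allele counts and must add, not OR
    hap = (rng.random((n_families, 4, L)) < maf).astype(np.int8)  # fa1 fa2 mo1 mo2
    father = hap[:, 0] + hap[:, 1]
    mother = hap[:, 2] + hap[:, 3]
    def child() -> np.ndarray:
        pick_f = rng.integers(0, 2, size=(n_families, L))
        pick_m = rng.integers(0, 2, size=(n_families, L))
        from_f = np.where(pick_f == 0, hap[:, 0], hap[:, 1])
        from_m = np.where(pick_m == 0, hap[:, 2], hap[:, 3])
        return (from_f + from_m).astype(np.int8)
    return father.astype(np.int8), mother.astype(np.int8), child(), child()


def simulate_unrelateds(
    scn: SimulationScenario,
    arch: GenomeArchitecture | None = None,
    rng: np.random.Generator | None = None,
    batch: int = 2000,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Rejection-sample unrelated individuals until the case/control
    targets are met; cases and controls are drawn from one population
    stream so the panel is self-consistent."""
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    arch = arch if arch is not None else draw_architecture(scn, rng)
    need_case, need_ctrl = scn.n_cases, scn.n_controls
    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    n_case = n_ctrl = 0
    simulated = 0
    cap = scn.max_attempt_factor * max(need_case + need_ctrl, 1)
    while n_case < need_case or n_ctrl < need_ctrl:
        if simulated >= cap:
            raise RuntimeError(
                f"ascertainment failed: {n_case}/{need_case} cases, "
                f"{n_ctrl}/{need_ctrl} controls after {simulated} simulated individuals"
            )
        G = sample_genotypes(batch, arch.maf, rng)
        affected = rng.random(batch) < disease_probability(G, arch.beta, scn.prevalence)
        simulated += batch
        if n_case < need_case:
            take = G[affected][: need_case - n_case]
            cases.append(take)
            n_case += take.shape[0]
        if n_ctrl < need_ctrl:
            take = G[~affected][: need_ctrl - n_ctrl]
            ctrls.append(take)
            n_ctrl += take.shape[0]
    counts = np.concatenate(
        [c for c in cases + ctrls if c.shape[0]] or
        [np.empty((0, arch.maf.size), dtype=np.int8)]
    )
    ids = [f"case{i}" for i in range(need_case)] + [f"ctrl{i}" for i in range(need_ctrl)]
    status = [True] * need_case + [False] * need_ctrl
    gm = GenotypeMatrix(ids, list(arch.variant_ids), counts, arch.variant_meta.copy())
    return gm, PhenotypeTable.from_status(ids, status)


def simulate_sib_pairs(
    scn: SimulationScenario,
    arch: GenomeArchitecture | None = None,
    rng: np.random.Generator | None = None,
    batch: int = 500,
) -> tuple[GenotypeMatrix, PhenotypeTable, SibPairSet]:
    """Ascertain nuclear families until the sib-pair targets are met.

    The returned panel contains parents and both sibs of every kept
    family (parents recorded unaffected-by-convention and linked via
    the pedigree columns, so :func:`famburden.io.extract_sib_pairs`
    recovers the same pairs).  For discordant pairs the affected sib is
    listed first in the pair index.
    """
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    arch = arch if arch is not None else draw_architecture(scn, rng)
    need = {CONCORDANT_AFFECTED: scn.n_affected_pairs, DISCORDANT: scn.n_discordant_pairs}
    kept: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool, bool, str]] = []
    have = {CONCORDANT_AFFECTED: 0, DISCORDANT: 0}
    simulated = 0
    cap = scn.max_attempt_factor * max(sum(need.values()), 1)
    while have[CONCORDANT_AFFECTED] < need[CONCORDANT_AFFECTED] or have[DISCORDANT] < need[DISCORDANT]:
        if simulated >= cap:
            raise RuntimeError(
                f"family ascertainment failed: {have} of {need} pairs "
                f"after {simulated} simulated families"
            )
        fa, mo, s1, s2 = sample_trio_offspring(batch, arch.maf, rng)
        p1 = disease_probability(s1, arch.beta, scn.prevalence)
        p2 = disease_probability(s2, arch.beta, scn.prevalence)
        a1 = rng.random(batch) < p1
        a2 = rng.random(batch) < p2
        simulated += batch
        for i in range(batch):
            if a1[i] and a2[i]:
                ptype = CONCORDANT_AFFECTED
            elif a1[i] or a2[i]:
                ptype = DISCORDANT
            else:
                continue
            if have[ptype] >= need[ptype]:
                continue
            kept.append((fa[i], mo[i], s1[i], s2[i], bool(a1[i]), bool(a2[i]), ptype))
            have[ptype] += 1
    rows: list[np.ndarray] = []
    ids: list[str] = []
    ped_rows: list[dict] = []
    pairs: list[SibPair] = []
    for f, (fa_g, mo_g, s1_g, s2_g, aff1, aff2, ptype) in enumerate(kept):
        fam_id = f"F{f}"
        pid_fa, pid_mo = f"{fam_id}_pa", f"{fam_id}_mo"
        pid_s1, pid_s2 = f"{fam_id}_s1", f"{fam_id}_s2"
        base = len(ids)
        for pid, g, fa_ref, mo_ref, aff, sex in (
            (pid_fa, fa_g, "0", "0", False, "1"),
            (pid_mo, mo_g, "0", "0", False, "2"),
            (pid_s1, s1_g, pid_fa, pid_mo, aff1, "1"),
            (pid_s2, s2_g, pid_fa, pid_mo, aff2, "2"),
        ):
            ids.append(pid)
            rows.append(g)
            ped_rows.append(
                {
                    "individual_id": pid,
                    "family_id": fam_id,
                    "father_id": fa_ref,
                    "mother_id": mo_ref,
                    "sex": sex,
                    "affected": aff,
                    "status_known": fa_ref != "0",  # parents' phenotypes unobserved
                }
            )
        i1, i2 = base + 2, base + 3
        if ptype == DISCORDANT and not aff1:
            i1, i2 = i2, i1  # affected sib first
        pairs.append(SibPair(i1, i2, ptype))
    counts = (
        np.stack(rows) if rows else np.empty((0, arch.maf.size), dtype=np.int8)
    )
    gm = GenotypeMatrix(ids, list(arch.variant_ids), counts, arch.variant_meta.copy())
    ped = pd.DataFrame(ped_rows).set_index("individual_id") if ped_rows else pd.DataFrame(
        columns=["family_id", "father_id", "mother_id", "sex", "affected", "status_known"]
    )
    pheno = PhenotypeTable(ped) if len(ped) else PhenotypeTable.from_status([], [])
    return gm, pheno, SibPairSet(pairs)


@dataclass
class SimulatedStudy:
    """Everything one scenario realization produced."""

    scenario: SimulationScenario
    architecture: GenomeArchitecture
    family: GenotypeMatrix
    family_pheno: PhenotypeTable
    pairs: SibPairSet
    cc: GenotypeMatrix
    cc_pheno: PhenotypeTable


def simulate_study(
    scn: SimulationScenario, rng: np.random.Generator | None = None
) -> SimulatedStudy:
    """Draw one architecture and both panels (family, then unrelateds)."""
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    arch = draw_architecture(scn, rng)
    fam, fam_pheno, pairs = simulate_sib_pairs(scn, arch, rng)
    cc, cc_pheno = simulate_unrelateds(scn, arch, rng)
    return SimulatedStudy(scn, arch, fam, fam_pheno, pairs, cc, cc_pheno)


# ---------------------------------------------------------------------------
# fixtures on disk


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        meta = gm.variant_meta
        for j, vid in enumerate(gm.variant_ids):
            fields = [
                str(meta["chrom"].iloc[j]),
                str(int(meta["position"].iloc[j])),
                vid,
                "A",
                "T",
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt[int(c)] for c in gm.counts[:, j]]
            fh.write("\t".join(fields) + "\n")


def _write_ped(pheno: PhenotypeTable, path: Path) -> None:
    t = pheno.table
    with open(path, "w") as fh:
        for iid, row in t.iterrows():
            known = bool(row.get("status_known", True))
            status = ("2" if row["affected"] else "1") if known else "0"
            fh.write(
                "\t".join(
                    [
                        str(row.get("family_id", iid)),
                        str(iid),
                        str(row.get("father_id", "0")),
                        str(row.get("mother_id", "0")),
                        str(row.get("sex", "0")),
                        status,
                    ]
                )
                + "\n"
            )


def make_fixture(scn: SimulationScenario, outdir: str | Path) -> dict[str, Path]:
    """Write a complete study to ``outdir``: family VCF+PED, case-control
    VCF+phenotype, and a variant->gene group map.  Deterministic given
    ``scn.seed``; two runs produce byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(scn)
    paths = {
        "family_vcf": outdir / "family.vcf",
        "family_ped": outdir / "family.ped",
        "cc_vcf": outdir / "cases_controls.vcf",
        "cc_pheno": outdir / "cases_controls.ped",
        "groups": outdir / "groups.tsv",
    }
    _write_vcf(study.family, paths["family_vcf"])
    _write_ped(study.family_pheno, paths["family_ped"])
    _write_vcf(study.cc, paths["cc_vcf"])
    _write_ped(study.cc_pheno, paths["cc_pheno"])
    with open(paths["groups"], "w") as fh:
        for vid, gid in zip(study.cc.variant_ids, study.cc.variant_meta["group_id"]):
            fh.write(f"{vid}\t{gid}\n")
    return paths


def scenario_from_config(path: str | Path) -> SimulationScenario:
    """Parse a flat key=value scenario file (``#`` comments allowed)."""
    values: dict[str, object] = {}
    tuple_fields = {"maf_rare_range", "maf_common_range", "causal_genes", "effect_range"}
    int_fields = {
        "n_genes", "variants_per_gene", "n_affected_pairs", "n_discordant_pairs",
        "n_cases", "n_controls", "seed", "max_attempt_factor",
    }
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"cannot parse scenario line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in tuple_fields:
            parts = [p for p in val.replace(",", " ").split() if p]
            conv = int if key == "causal_genes" else float
            values[key] = tuple(conv(p) for p in parts)
        elif key in int_fields:
            values[key] = int(val)
        else:
            values[key] = float(val)
    return SimulationScenario(**values)  # type: ignore[arg-type]
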