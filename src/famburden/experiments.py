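"""Power / type-I-error harness and genome-wide scan utilities.

The power design mirrors the comparison the method was built for: the
family-weighted test spends part of its genotyping budget on sib pairs
(weights) and the rest on unrelated cases/controls (testing), while
the Madsen-Browning comparator spends the whole budget on unrelated
subjects.  With ``equal_n`` set the harness enforces equal totals,
counting each pair as two genotyped individuals
(e.g. 100 pairs + 500/500 vs 600/600).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .burden_test import METHOD_FAMILY, test_group
from .datamodel import (
    CONCORDANT_AFFECTED,
    GeneTestResult,
    GenotypeMatrix,
    GroupMap,
    PhenotypeTable,
    SibPairSet,
)
from .family_weights import PairScoreConfig
from .madsen_browning import METHOD_MB, MBConfig, mb_test
from .simulate import SimulationScenario, simulate_study, simulate_unrelateds


def bonferroni_threshold(n_tests: int, level: float = 0.05) -> float:
    """Family-wise threshold level / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return level / n_tests


@dataclass
class ExperimentPlan:
    """One power-comparison run.

    ``scenario`` fixes the genome and disease model; the two design
    tuples fix each arm's sample sizes.  Power and type-I error are the
    fractions of causal-gene and null-gene p-values below
    ``nominal_level``.
    """

    scenario: SimulationScenario
    n_replicates: int = 100
    nominal_level: float = 0.05
    design_family: tuple[int, int, int] = (100, 500, 500)  # pairs, cases, controls
    design_mb: tuple[int, int] = (600, 600)
    equal_n: bool = True
    seed: int = 0
    pair_cfg: PairScoreConfig = field(default_factory=PairScoreConfig)
    mb_cfg: MBConfig = field(default_factory=MBConfig)

    def __post_init__(self) -> None:
        if self.equal_n:
            n_fam = 2 * self.design_family[0] + self.design_family[1] + self.design_family[2]
            n_mb = self.design_mb[0] + self.design_mb[1]
            if n_fam != n_mb:
                raise ValueError(
                    f"equal_n: family arm genotypes {n_fam} individuals "
                    f"but the comparator arm {n_mb}"
                )


@dataclass
class PowerStudyResult:
    summary: pd.DataFrame
    pvalues: pd.DataFrame  # one row per (replicate, method, gene)

    def recount(self, nominal_level: float) -> pd.DataFrame:
        """Recompute the summary fractions from the per-test p-values."""
        df = self.pvalues
        rows = []
        for method, sub in df.groupby("method", sort=True):
            for causal, subc in sub.groupby("causal", sort=True):
                frac = float((subc["p_value"] < nominal_level).mean())
                n = len(subc)
                rows.append(
                    {
                        "method": method,
                        "measure": "power" if causal else "type_I_error",
                        "value": frac,
                        "se": float(np.sqrt(frac * (1 - frac) / n)) if n else float("nan"),
                        "n_tests": n,
                    }
                )
        return pd.DataFrame(rows, columns=["method", "measure", "value", "se", "n_tests"])


def run_power_study(plan: ExperimentPlan) -> PowerStudyResult:
    """Simulate ``n_replicates`` fresh studies and test every gene with
    both methods under its own arm's design."""
    records: list[dict] = []
    ss = np.random.SeedSequence(plan.seed)
    children = ss.spawn(max(plan.n_replicates, 1))
    n_pairs, n_cases_f, n_ctrl_f = plan.design_family
    n_cases_mb, n_ctrl_mb = plan.design_mb
    for r in range(plan.n_replicates):
        rng = np.random.default_rng(children[r])
        scn = replace(
            plan.scenario,
            n_affected_pairs=n_pairs,
            n_discordant_pairs=0,
            n_cases=n_cases_f,
            n_controls=n_ctrl_f,
        )
        study = simulate_study(scn, rng)
        pairs = study.pairs.of_type(CONCORDANT_AFFECTED)
        # comparator arm: same architecture, its own unrelated panel
        scn_mb = replace(scn, n_cases=n_cases_mb, n_controls=n_ctrl_mb)
        cc_mb, pheno_mb = simulate_unrelateds(scn_mb, study.architecture, rng)
        causal = set(f"gene{g}" for g in plan.scenario.causal_genes)
        for gid, cols in study.architecture.group_map.items():
            res_f = test_group(
                study.family, pairs, study.cc, study.cc_pheno, gid, cols, plan.pair_cfg
            )
            res_mb = mb_test(
                cc_mb, pheno_mb, gid, cols, plan.mb_cfg,
                rng=np.random.default_rng(children[r].spawn(1)[0]),
            )
            for res in (res_f, res_mb):
                records.append(
                    {
                        "replicate": r,
                        "method": res.method,
                        "group_id": gid,
                        "causal": gid in causal,
                        "p_value": res.p_value,
                        "statistic": res.statistic,
                        "n_weighted_variants": res.n_weighted_variants,
                    }
                )
    pvalues = pd.DataFrame(
        records,
        columns=[
            "replicate", "method", "group_id", "causal",
            "p_value", "statistic", "n_weighted_variants",
        ],
    )
    result = PowerStudyResult(summary=pd.DataFrame(), pvalues=pvalues)
    result.summary = result.recount(plan.nominal_level)
    return result


def genome_scan(
    fam: GenotypeMatrix,
    pairs: SibPairSet,
    cc: GenotypeMatrix,
    pheno: PhenotypeTable,
    groups: GroupMap,
    pair_cfg: PairScoreConfig | None = None,
    mb_cfg: MBConfig | None = None,
    methods: tuple[str, ...] = (METHOD_FAMILY, METHOD_MB),
    level: float = 0.05,
) -> tuple[list[GeneTestResult], pd.DataFrame]:
    """Test every group with the requested methods and flag Bonferroni
    significance; returns the results plus a Manhattan-ready table
    (group, position, -log10 p, method, significant)."""
    pair_cfg = pair_cfg or PairScoreConfig()
    mb_cfg = mb_cfg or MBConfig()
    results: list[GeneTestResult] = []
    for gid, cols in groups.items():
        if METHOD_FAMILY in methods:
            results.append(test_group(fam, pairs, cc, pheno, gid, cols, pair_cfg))
        if METHOD_MB in methods:
            results.append(mb_test(cc, pheno, gid, cols, mb_cfg))
    if len(groups) == 0:
        return results, pd.DataFrame(
            columns=["group_id", "position", "method", "p_value", "neg_log10_p", "significant"]
        )
    thr = bonferroni_threshold(len(groups), level)
    pos_of = {
        gid: int(cc.variant_meta["position"].iloc[cols[0]]) if len(cols) else 0
        for gid, cols in groups.items()
    }
    rows = [
        {
            "group_id": r.group_id,
            "position": pos_of.get(r.group_id, 0),
            "method": r.method,
            "p_value": r.p_value,
            "neg_log10_p": float(-np.log10(max(r.p_value, 1e-300))),
            "significant": r.p_value < thr,
        }
        for r in results
    ]
    return results, pd.DataFrame(rows)


def null_calibration(
    n_genes: int = 2000,
    variants_per_gene: int = 10,
    n_pairs: int = 100,
    n_cases: int = 1000,
    n_controls: int = 1000,
    nominal_level: float = 0.05,
    seed: int = 0,
    pair_cfg: PairScoreConfig | None = None,
    mb_cfg: MBConfig | None = None,
) -> pd.DataFrame:
    """Empirical type-I error of both methods over many null genes.

    One all-null study is simulated (weights come from families that are
    independent of the unrelated panel); each gene is an independent
    null test since sites are in linkage equilibrium across genes.
    """
    scn = SimulationScenario(
        n_genes=n_genes,
        variants_per_gene=variants_per_gene,
        causal_genes=(),
        n_affected_pairs=n_pairs,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    study = simulate_study(scn, rng)
    pairs = study.pairs.of_type(CONCORDANT_AFFECTED)
    pair_cfg = pair_cfg or PairScoreConfig()
    mb_cfg = mb_cfg or MBConfig(seed=seed)
    p_fam: list[float] = []
    p_mb: list[float] = []
    for gid, cols in study.architecture.group_map.items():
        p_fam.append(
            test_group(study.family, pairs, study.cc, study.cc_pheno, gid, cols, pair_cfg).p_value
        )
        p_mb.append(mb_test(study.cc, study.cc_pheno, gid, cols, mb_cfg).p_value)
    rows = []
    for method, ps in ((METHOD_FAMILY, p_fam), (METHOD_MB, p_mb)):
        ps_arr = np.asarray(ps)
        frac = float((ps_arr < nominal_level).mean())
        rows.append(
            {
                "method": method,
                "type_I_error": frac,
                "se": float(np.sqrt(frac * (1 - frac) / ps_arr.size)),
                "n_genes": int(ps_arr.size),
            }
        )
    return pd.DataFrame(rows)
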