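"""Weighted burden test on the unrelated case-control panel.

Each unrelated individual k gets a genetic score
gamma_k = sum_j w_j g_kj over the group's variants, with w_j the
family-derived weights.  Under the null of no association the case and
control score means agree, so the test statistic is the two-sample z

    T = (mean_D - mean_C) / sqrt(s2_D / N_D + s2_C / N_C)

with unbiased (n-1) sample variances, referred to the standard normal.
A group with no retained weight, or zero score variance in both arms,
is degenerate: it reports p = 1 with an undefined (NaN) statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import GeneTestResult, GenotypeMatrix, PhenotypeTable, SibPairSet
from .family_weights import PairScoreConfig, VariantWeights, compute_weights

METHOD_FAMILY = "family_weighted"


@dataclass
class CohortScores:
    """Per-individual genetic scores with case/control labels."""

    gamma: np.ndarray
    is_case: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.gamma.shape != self.is_case.shape:
            raise ValueError("gamma and status vectors must be aligned")


def genetic_scores(
    cc: GenotypeMatrix,
    weights: VariantWeights,
    pheno: PhenotypeTable,
) -> CohortScores:
    """gamma_k = sum_j w_j g_kj over the weighted group columns."""
    cols = weights.variant_indices
    if weights.w.shape[0] != cols.shape[0]:
        raise ValueError("weight vector misaligned with its group columns")
    gamma = cc.dosages(cols) @ weights.w
    is_case = pheno.status_vector(cc.individual_ids)
    return CohortScores(gamma, is_case)


def z_test(
    scores: CohortScores,
    group_id: str = "",
    n_weighted_variants: int | None = None,
    n_rare_variants: int = 0,
    alternative: str = "two-sided",
) -> GeneTestResult:
    """Two-sample z test of equal mean genetic score in cases vs controls.

    ``n_weighted_variants=None`` means "not tracked" (raw score vectors);
    an explicit 0 marks the group degenerate regardless of the scores.
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    cases = scores.gamma[scores.is_case]
    controls = scores.gamma[~scores.is_case]
    n_d, n_c = cases.size, controls.size
    if n_d < 2 or n_c < 2:
        raise ValueError(f"need >=2 cases and >=2 controls, got {n_d}/{n_c}")
    var_d = cases.var(ddof=1)
    var_c = controls.var(ddof=1)
    denom = np.sqrt(var_d / n_d + var_c / n_c)
    if denom == 0.0 or n_weighted_variants == 0:
        stat, p = float("nan"), 1.0
    else:
        stat = float((cases.mean() - controls.mean()) / denom)
        if alternative == "two-sided":
            p = float(2.0 * stats.norm.sf(abs(stat)))
        else:
            p = float(stats.norm.sf(stat))
    return GeneTestResult(
        group_id=group_id,
        method=METHOD_FAMILY,
        statistic=stat,
        p_value=min(p, 1.0),
        n_weighted_variants=0 if n_weighted_variants is None else n_weighted_variants,
        n_rare_variants=n_rare_variants,
        n_cases=n_d,
        n_controls=n_c,
    )


def test_group(
    fam: GenotypeMatrix,
    pairs: SibPairSet,
    cc: GenotypeMatrix,
    pheno: PhenotypeTable,
    group_id: str,
    group_cols: np.ndarray,
    cfg: PairScoreConfig | None = None,
    alternative: str = "two-sided",
) -> GeneTestResult:
    """Full family-weighted pipeline for one group: weights on the family
    panel, burden scores and the z test on the unrelated panel."""
    cfg = cfg or PairScoreConfig()
    weights = compute_weights(fam, pairs, cc, group_cols, cfg, cc_pheno=pheno)
    scores = genetic_scores(cc, weights, pheno)
    return z_test(
        scores,
        group_id=group_id,
        n_weighted_variants=weights.n_weighted,
        n_rare_variants=weights.n_rare,
        alternative=alternative,
    )
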