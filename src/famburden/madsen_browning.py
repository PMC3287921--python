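"""Madsen-Browning weighted-sum comparator.

Rare variants (control-panel MAF below alpha) are weighted by the
inverse of their binomial standard deviation estimated in controls,
each individual's weighted dosages are summed into a genetic score,
and the scores are rank-tested: the observed sum of case ranks X is
standardized against its distribution over random relabelings,

    Z = (X - mean(X*)) / sd(X*),

which is approximately standard normal under the null.  Ties in the
(typically very sparse) score vectors are handled with midranks.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .burden_test import CohortScores
from .datamodel import GeneTestResult, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

METHOD_MB = "madsen_browning"


@dataclass
class MBConfig:
    """alpha: rare-variant MAF cutoff; n_permutations: relabelings used to
    standardize the rank sum; maf_estimator: 'controls_plus_pseudocount'
    (Madsen-Browning's q_j = (m_j + 1) / (2 n_U + 2)) or 'controls_plain'."""

    alpha: float = 0.01
    n_permutations: int = 1000
    seed: int = 0
    maf_estimator: str = "controls_plus_pseudocount"

    def __post_init__(self) -> None:
        if self.n_permutations < 2:
            raise ValueError("n_permutations must be >= 2")
        if self.maf_estimator not in ("controls_plus_pseudocount", "controls_plain"):
            raise ValueError(f"unknown maf_estimator {self.maf_estimator!r}")


def mb_weights(
    cc: GenotypeMatrix,
    pheno: PhenotypeTable,
    group_cols: np.ndarray,
    cfg: MBConfig | None = None,
) -> np.ndarray:
    """Inverse-standard-deviation weights from the control subjects.

    w_j = 1 / sqrt(n_U q_j (1 - q_j)) for variants with control MAF
    strictly below alpha, 0 otherwise; q_j per ``cfg.maf_estimator``.
    """
    cfg = cfg or MBConfig()
    group_cols = np.asarray(group_cols, dtype=np.intp)
    is_case = pheno.status_vector(cc.individual_ids)
    n_u = int((~is_case).sum())
    if n_u == 0:
        raise ValueError("Madsen-Browning weights require at least one control")
    controls = cc.dosages(group_cols)[~is_case]
    m = controls.sum(axis=0)  # minor alleles among controls
    maf_ctrl = m / (2.0 * n_u)
    if cfg.maf_estimator == "controls_plus_pseudocount":
        q = (m + 1.0) / (2.0 * n_u + 2.0)
    else:
        q = maf_ctrl
    w = np.zeros(group_cols.size, dtype=np.float64)
    rare = maf_ctrl < cfg.alpha
    pq = q * (1.0 - q)
    degenerate = rare & (pq == 0.0)
    if degenerate.any():
        logger.warning(
            "mb_weights: %d monomorphic-in-controls variants get weight 0 "
            "under the plain MAF estimator", int(degenerate.sum())
        )
    ok = rare & (pq > 0.0)
    w[ok] = 1.0 / np.sqrt(n_u * pq[ok])
    return w


def mb_rank_sum(scores: CohortScores) -> float:
    """Sum of the case subjects' (mid)ranks of the genetic score."""
    if not scores.is_case.any():
        raise ValueError("rank sum needs at least one case")
    ranks = stats.rankdata(scores.gamma, method="average")
    return float(ranks[scores.is_case].sum())


def _permuted_rank_sums(
    ranks: np.ndarray, n_case: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Rank sums over ``n_perm`` random case-label assignments of fixed size."""
    n = ranks.size
    keys = rng.random((n_perm, n))
    case_idx = np.argpartition(keys, n_case - 1, axis=1)[:, :n_case]
    return ranks[case_idx].sum(axis=1)


def mb_test(
    cc: GenotypeMatrix,
    pheno: PhenotypeTable,
    group_id: str,
    group_cols: np.ndarray,
    cfg: MBConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GeneTestResult:
    """Weighted-sum test for one group with permutation standardization.

    The permutation stream is seeded from ``(cfg.seed, group_id)`` when
    no generator is supplied, so per-group results are reproducible and
    independent of evaluation order.
    """
    cfg = cfg or MBConfig()
    group_cols = np.asarray(group_cols, dtype=np.intp)
    is_case = pheno.status_vector(cc.individual_ids)
    n_d, n_c = int(is_case.sum()), int((~is_case).sum())
    if n_d < 2 or n_c < 2:
        raise ValueError(f"need >=2 cases and >=2 controls, got {n_d}/{n_c}")
    if rng is None:
        rng = rng_for_group(cfg.seed, group_id)
    w = mb_weights(cc, pheno, group_cols, cfg)
    gamma = cc.dosages(group_cols) @ w
    scores = CohortScores(gamma, is_case)
    ranks = stats.rankdata(gamma, method="average")
    x_obs = mb_rank_sum(scores)
    x_perm = _permuted_rank_sums(ranks, n_d, cfg.n_permutations, rng)
    sd = float(x_perm.std(ddof=1))
    if sd == 0.0:
        stat, p = float("nan"), 1.0
    else:
        stat = float((x_obs - x_perm.mean()) / sd)
        p = float(2.0 * stats.norm.sf(abs(stat)))
    n_rare = int((w > 0).sum())
    return GeneTestResult(
        group_id=group_id,
        method=METHOD_MB,
        statistic=stat,
        p_value=min(p, 1.0),
        n_weighted_variants=n_rare,
        n_rare_variants=n_rare,
        n_cases=n_d,
        n_controls=n_c,
    )


def rng_for_group(seed: int, group_id: str) -> np.random.Generator:
    """Deterministic per-group generator from a global seed and group id."""
    tag = zlib.crc32(group_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
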