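"""Per-variant weights derived from sib-pair genotype sharing.

Rare risk alleles segregate within families, so two affected sibs carry
the same rare causal allele far more often than chance, while a
discordant pair tends to carry it in the affected sib only.  Each sib
pair therefore scores each rare variant on a three-level scale
(supportive / ambiguous / unsupportive), the ambiguous case being
discounted by the number K of *other* rare alleles in the region that
could explain the pair's affection instead.  Pair scores are averaged
over pairs, standardized by the binomial scale sqrt(p_j (1 - p_j)) of
the variant's case-control MAF p_j, and only the top quartile of
standardized scores within the group retain a (positive) weight.

The resulting weight vector is handed to :mod:`famburden.burden_test`
for use on an independent unrelated case-control panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .datamodel import (
    CONCORDANT_AFFECTED,
    PAIR_TYPES,
    GenotypeMatrix,
    PhenotypeTable,
    SibPairSet,
)


def default_mixed_rule(K: int | np.ndarray) -> float | np.ndarray:
    """Ambiguous-case score 1/(1+K): full weight 1 when no other rare
    allele in the region could carry the signal, shrinking as more do."""
    return 1.0 / (1.0 + K)


@dataclass
class PairScoreConfig:
    """Knobs of the sib-pair scoring and weighting scheme.

    alpha
        MAF threshold defining "rare"; variants with MAF > alpha get
        weight 0 unconditionally.
    score_both / score_neither / score_mixed_rule
        The three case values of the pair score.  For affected pairs:
        both sibs carry the minor allele / neither does / exactly one
        does.  For discordant pairs: affected carries and unaffected
        does not / affected does not carry / both carry.  The mixed
        rule is a function of K (other rare variants carried by the
        relevant sib in the region).
    top_fraction
        Fraction of eligible (rare) variants in the group that retain a
        positive weight, by descending standardized score.
    maf_source
        Panel used to estimate p_j: the combined case-control panel
        (default) or controls only.
    standardization
        ``inv_sd``: b_j = s_bar_j / sqrt(p_j (1-p_j)) (default);
        ``inv_var``: divide by p_j (1-p_j); ``none``: b_j = s_bar_j.
    """

    alpha: float = 0.01
    score_both: float = 2.0
    score_neither: float = 0.0
    score_mixed_rule: Callable[[np.ndarray], np.ndarray] = field(
        default=default_mixed_rule
    )
    top_fraction: float = 0.25
    maf_source: str = "combined_case_control"
    standardization: str = "inv_sd"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.maf_source not in ("combined_case_control", "controls_only"):
            raise ValueError(f"unknown maf_source {self.maf_source!r}")
        if self.standardization not in ("inv_sd", "inv_var", "none"):
            raise ValueError(f"unknown standardization {self.standardization!r}")
        for k in (0, 1, 10):
            v = float(self.score_mixed_rule(k))
            if not math.isfinite(v):
                raise ValueError(f"score_mixed_rule({k}) is not finite")


@dataclass
class VariantWeights:
    """Per-variant weight table for one group (aligned to its columns)."""

    variant_indices: np.ndarray  # columns in the full matrix
    maf: np.ndarray  # p_j
    s_bar: np.ndarray  # mean pair score
    b: np.ndarray  # standardized score
    rank: np.ndarray  # descending rank of b among eligible (0 = not eligible)
    w: np.ndarray  # final weight, 0 outside the retained top fraction

    @property
    def n_weighted(self) -> int:
        return int((self.w > 0).sum())

    @property
    def n_rare(self) -> int:
        return int(self.rank.size and (self.rank > 0).sum())


# ---------------------------------------------------------------------------
# scalar operations (reference semantics; the pair loop below vectorizes them)


def pair_genotype_score(
    g1: int,
    g2: int,
    pair_type: str,
    K: int,
    cfg: PairScoreConfig,
    is_rare: bool = True,
) -> float:
    """Score one variant for one sib pair.

    For discordant pairs ``g1`` must be the affected sib.  Variants with
    MAF above alpha (``is_rare=False``) always score 0.
    """
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"unknown pair_type {pair_type!r}")
    if not is_rare:
        return 0.0
    c1, c2 = g1 > 0, g2 > 0
    if pair_type == CONCORDANT_AFFECTED:
        if c1 and c2:
            return float(cfg.score_both)
        if not c1 and not c2:
            return float(cfg.score_neither)
        return float(cfg.score_mixed_rule(K))
    # discordant: g1 affected
    if c1 and not c2:
        return float(cfg.score_both)
    if not c1:
        return float(cfg.score_neither)
    return float(cfg.score_mixed_rule(K))


def count_other_rare_carried(
    geno_row: np.ndarray, j: int, rare_mask: np.ndarray
) -> int:
    """K = number of rare variants at positions m != j carried (dosage >= 1)
    in ``geno_row``, the row of the sib relevant to the ambiguous case."""
    geno_row = np.asarray(geno_row)
    rare_mask = np.asarray(rare_mask, dtype=bool)
    carried = rare_mask & (geno_row >= 1)
    k = int(carried.sum())
    if carried[j]:
        k -= 1
    return k


# ---------------------------------------------------------------------------
# vectorized pipeline


def mean_pair_scores(
    dosages: np.ndarray,
    pairs: SibPairSet,
    rare_mask: np.ndarray,
    cfg: PairScoreConfig,
) -> np.ndarray:
    """Mean pair score s_bar_j over the pairs, per variant.

    ``dosages`` is the family panel restricted to one group's columns
    (missing already imputed); ``pairs`` must be non-empty and of a
    single pair type, since affected and discordant pairs measure
    different sharing events.
    """
    if len(pairs) == 0:
        raise ValueError("mean_pair_scores requires at least one sib pair")
    types = {p.pair_type for p in pairs}
    if len(types) > 1:
        raise ValueError("pairs must be of a single pair_type; use SibPairSet.of_type")
    pair_type = types.pop()
    rare_mask = np.asarray(rare_mask, dtype=bool)
    s1, s2 = pairs.index_arrays()
    G1 = dosages[s1] > 0  # carrier flags, pairs x variants
    G2 = dosages[s2] > 0
    # rare variants carried per sib within this region
    n_rare1 = (G1 & rare_mask).sum(axis=1)
    n_rare2 = (G2 & rare_mask).sum(axis=1)

    scores = np.zeros(G1.shape, dtype=np.float64)
    if pair_type == CONCORDANT_AFFECTED:
        both = G1 & G2
        only1 = G1 & ~G2  # sib2 is the non-carrying "other" sib
        only2 = G2 & ~G1
        scores[both] = cfg.score_both
        # K for the mixed case: rare variants (other than j) carried by the
        # non-carrier; the non-carrier does not carry j, so no self-count.
        K1 = np.broadcast_to(n_rare2[:, None], scores.shape)
        K2 = np.broadcast_to(n_rare1[:, None], scores.shape)
        scores[only1] = np.asarray(cfg.score_mixed_rule(K1), dtype=np.float64)[only1]
        scores[only2] = np.asarray(cfg.score_mixed_rule(K2), dtype=np.float64)[only2]
        if cfg.score_neither != 0.0:
            scores[~G1 & ~G2] = cfg.score_neither
    else:  # discordant, sib1 affected
        supp = G1 & ~G2
        ambig = G1 & G2
        scores[supp] = cfg.score_both
        # affected sib carries j, so exclude it from its own K count
        K = np.maximum(np.broadcast_to(n_rare1[:, None], scores.shape) - 1, 0)
        scores[ambig] = np.asarray(cfg.score_mixed_rule(K), dtype=np.float64)[ambig]
        if cfg.score_neither != 0.0:
            scores[~G1] = cfg.score_neither
    scores[:, ~rare_mask] = 0.0
    return scores.mean(axis=0)


def standardize_scores(
    s_bar: np.ndarray, maf: np.ndarray, cfg: PairScoreConfig
) -> np.ndarray:
    """b_j = s_bar_j scaled by the chosen function of p_j (1 - p_j).

    Monomorphic sites (p_j = 0), common sites (p_j > alpha) and sites
    with zero mean pair score all get b_j = 0.
    """
    s_bar = np.asarray(s_bar, dtype=np.float64)
    maf = np.asarray(maf, dtype=np.float64)
    if ((maf < 0) | (maf > 0.5)).any():
        raise ValueError("MAF values must lie in [0, 0.5]")
    pq = maf * (1.0 - maf)
    with np.errstate(divide="ignore", invalid="ignore"):
        if cfg.standardization == "inv_sd":
            b = s_bar / np.sqrt(pq)
        elif cfg.standardization == "inv_var":
            b = s_bar / pq
        else:
            b = s_bar.copy()
    b[(maf == 0.0) | (maf > cfg.alpha) | (s_bar == 0.0)] = 0.0
    return b


def truncate_to_top_quartile(
    b: np.ndarray,
    cfg: PairScoreConfig,
    eligible: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep w_j = b_j for the top ceil(top_fraction * n_eligible) of
    eligible variants by descending b_j, 0 elsewhere.

    Ties at the cut are broken by ascending variant index; a variant
    with b_j = 0 never receives a positive weight even when the slot
    count would reach it.  Returns ``(w, rank)`` where ``rank`` is the
    1-based descending rank among eligible variants (0 = ineligible).
    """
    b = np.asarray(b, dtype=np.float64)
    if eligible is None:
        eligible = np.ones(b.shape, dtype=bool)
    eligible = np.asarray(eligible, dtype=bool)
    w = np.zeros_like(b)
    rank = np.zeros(b.shape, dtype=np.intp)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return w, rank
    order = idx[np.lexsort((idx, -b[idx]))]  # descending b, ties by index
    rank[order] = np.arange(1, idx.size + 1)
    n_keep = math.ceil(cfg.top_fraction * idx.size)
    keep = order[:n_keep]
    keep = keep[b[keep] > 0.0]
    w[keep] = b[keep]
    return w, rank


def panel_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor allele frequency per column of a dosage matrix (already in
    minor-allele orientation, so this is just mean dosage / 2)."""
    return np.clip(dosages.mean(axis=0) / 2.0, 0.0, 0.5)


def compute_weights(
    fam: GenotypeMatrix,
    pairs: SibPairSet,
    cc: GenotypeMatrix,
    group_cols: np.ndarray,
    cfg: PairScoreConfig | None = None,
    cc_pheno: PhenotypeTable | None = None,
) -> VariantWeights:
    """End-to-end weights for one group.

    MAF p_j comes from the unrelated panel per ``cfg.maf_source``; the
    rare mask is MAF <= alpha; pair scores, standardization and
    top-quartile truncation follow.  ``fam`` and ``cc`` must share the
    group's variant columns.
    """
    cfg = cfg or PairScoreConfig()
    group_cols = np.asarray(group_cols, dtype=np.intp)
    if fam.n_variants != cc.n_variants:
        raise ValueError("family and case-control panels must share the variant set")
    cc_dos = cc.dosages(group_cols)
    if cfg.maf_source == "controls_only":
        if cc_pheno is None:
            raise ValueError("maf_source='controls_only' requires the case-control phenotypes")
        is_case = cc_pheno.status_vector(cc.individual_ids)
        cc_dos_for_maf = cc_dos[~is_case]
    else:
        cc_dos_for_maf = cc_dos
    maf = panel_maf(cc_dos_for_maf)
    rare = maf <= cfg.alpha
    fam_dos = fam.dosages(group_cols)
    s_bar = mean_pair_scores(fam_dos, pairs, rare, cfg)
    b = standardize_scores(s_bar, maf, cfg)
    w, rank = truncate_to_top_quartile(b, cfg, eligible=rare)
    return VariantWeights(group_cols, maf, s_bar, b, rank, w)
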