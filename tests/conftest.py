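"""Shared fixtures and the independent brute-force oracle.

The oracle re-derives per-variant weights with plain Python loops,
straight from the written scoring rules, so the vectorized pipeline is
checked against an implementation that shares no code with it.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import famburden as fb


# ---------------------------------------------------------------------------
# brute-force weight oracle (pure loops, no shared code with the package)


def oracle_weights(
    fam_counts: np.ndarray,
    pairs: list[tuple[int, int, str]],
    cc_counts: np.ndarray,
    alpha: float = 0.01,
    score_both: float = 2.0,
    score_neither: float = 0.0,
    top_fraction: float = 0.25,
):
    """Exhaustive enumeration of pair scores, their means, the
    standardized scores and the top-quartile truncation.

    ``pairs`` entries are (sib1, sib2, pair_type); for discordant pairs
    sib1 is the affected sib.  Returns (maf, s_bar, b, w).
    """
    n_cc, L = cc_counts.shape
    maf = []
    for j in range(L):
        total = sum(max(int(cc_counts[k][j]), 0) for k in range(n_cc))
        maf.append(min(total / (2 * n_cc), 0.5))
    rare = [maf[j] <= alpha for j in range(L)]

    def carries(row, j):
        return max(int(fam_counts[row][j]), 0) >= 1

    def k_other(row, j):
        return sum(
            1 for m in range(L) if m != j and rare[m] and carries(row, m)
        )

    s_bar = []
    for j in range(L):
        if not rare[j]:
            s_bar.append(0.0)
            continue
        total = 0.0
        for (s1, s2, ptype) in pairs:
            c1, c2 = carries(s1, j), carries(s2, j)
            if ptype == "concordant_affected":
                if c1 and c2:
                    score = score_both
                elif not c1 and not c2:
                    score = score_neither
                else:
                    non_carrier = s2 if c1 else s1
                    score = 1.0 / (1.0 + k_other(non_carrier, j))
            else:
                if c1 and not c2:
                    score = score_both
                elif not c1:
                    score = score_neither
                else:
                    score = 1.0 / (1.0 + k_other(s1, j))
            total += score
        s_bar.append(total / len(pairs))

    b = []
    for j in range(L):
        if maf[j] == 0.0 or maf[j] > alpha or s_bar[j] == 0.0:
            b.append(0.0)
        else:
            b.append(s_bar[j] / math.sqrt(maf[j] * (1.0 - maf[j])))

    eligible = [j for j in range(L) if rare[j]]
    order = sorted(eligible, key=lambda j: (-b[j], j))
    n_keep = math.ceil(top_fraction * len(eligible))
    keep = {j for j in order[:n_keep] if b[j] > 0.0}
    w = [b[j] if j in keep else 0.0 for j in range(L)]
    return np.array(maf), np.array(s_bar), np.array(b), np.array(w)


@pytest.fixture
def weights_oracle():
    return oracle_weights


# ---------------------------------------------------------------------------
# scenarios


#: Deep-rare causal architecture: most causal alleles well below the MAF
#: cutoff even after case enrichment, a minority of a causal gene's rare
#: variants carrying the effect, so indiscriminate weighting is diluted.
CAUSAL_SCENARIO = dict(
    n_genes=2,
    variants_per_gene=40,
    maf_rare_range=(0.0005, 0.003),
    causal_genes=(0,),
    causal_variant_fraction=0.3,
)


@pytest.fixture(scope="session")
def tiny_study():
    """Small end-to-end study reused by fast tests."""
    scn = fb.SimulationScenario(
        n_genes=3,
        variants_per_gene=10,
        causal_genes=(0,),
        n_affected_pairs=15,
        n_discordant_pairs=10,
        n_cases=60,
        n_controls=60,
        seed=42,
    )
    return fb.simulate_study(scn)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk fixture written once per session."""
    scn = fb.SimulationScenario(
        n_genes=5,
        variants_per_gene=20,
        causal_genes=(0,),
        n_affected_pairs=12,
        n_discordant_pairs=6,
        n_cases=40,
        n_controls=40,
        seed=9,
    )
    outdir = tmp_path_factory.mktemp("fixture")
    paths = fb.make_fixture(scn, outdir)
    return scn, paths


def random_small_panel(rng: np.random.Generator, pair_type: str):
    """Random panel of <=5 pairs x <=6 variants for oracle comparisons."""
    n_pairs = int(rng.integers(1, 6))
    L = int(rng.integers(1, 7))
    fam_counts = rng.integers(0, 3, size=(2 * n_pairs, L)).astype(np.int8)
    # skew case-control counts toward rarity so the alpha filter bites
    n_cc = 60
    cc_counts = (rng.random((n_cc, L)) < rng.uniform(0.0, 0.02, size=L)).astype(np.int8)
    pairs = [(2 * i, 2 * i + 1, pair_type) for i in range(n_pairs)]
    return fam_counts, pairs, cc_counts
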