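"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: alignment
is checked by an all-offsets window scan, the rank test by enumeration of
group assignments with itertools, the hypergeometric tails by counting
subsets, and BH by a from-scratch step-up.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

import probedex as px


# ---------------------------------------------------------------- oracles

def oracle_best_match(probe_seq: str, tx_seq: str) -> tuple[int, int] | None:
    """(match_len, t_start 1-based) of the longest contiguous exact match
    between revcomp(probe) and the transcript plus strand; leftmost on ties."""
    rc = probe_seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    best = None
    for i in range(len(rc)):
        for j in range(len(tx_seq)):
            l = 0
            while i + l < len(rc) and j + l < len(tx_seq) and rc[i + l] == tx_seq[j + l]:
                l += 1
            if l > 0:
                key = (-l, j)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    return -best[0], best[1] + 1


def oracle_mw_tails(x, y) -> tuple[float, float]:
    """Exact Mann-Whitney tails by explicit enumeration of all group
    assignments of the pooled mid-ranked values."""
    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), n)]
    upper = sum(1 for s in sums if s >= obs - 1e-9) / len(sums)
    lower = sum(1 for s in sums if s <= obs + 1e-9) / len(sums)
    return upper, lower


def oracle_hypergeom_tail(x_a: int, a_size: int, x_t: int, t: int) -> float:
    """P(>= x_a marked) when a_size items are drawn from t with x_t marked,
    by enumerating every subset."""
    if a_size == 0:
        return 1.0 if x_a == 0 else 0.0
    combos = np.array(list(combinations(range(t), a_size)))
    hits = (combos < x_t).sum(axis=1)
    return float((hits >= x_a).mean())


def oracle_bh(p):
    """Benjamini-Hochberg step-up, written independently of statsmodels."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_pos in range(m, 0, -1):
        i = order[rank_pos - 1]
        running = min(running, p[i] * m / rank_pos)
        adj[i] = running
    return adj


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def design():
    return px.default_design()


@pytest.fixture(scope="session")
def plan():
    return px.default_plan()


# planted position sets that are self-consistent across the seven
# overlapping comparisons (see simulate module docstring)
HYPOXIA_BOTH = (4, 5, 6, 7)   # hypoxia-responsive in both genotypes
GENOTYPE_ALL = (1, 2, 3)      # constitutive genotype difference


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Small noiseless experiment with symmetric hypoxia plants.

    Only position sets that bump both genotype branches equally are planted:
    under zero noise every unaffected comparison is then an exact tie for
    every probe (p = 1, letter E), so the planted strings are recovered
    exactly.  Asymmetric plants would let planted probes cross unplanted
    ones in rank space, which with zero noise turns infinitesimal rank
    shifts into complete separations — a compositional artifact of rank
    normalization, not a property under test here.
    """
    cfg = px.SimConfig(
        n_transcripts=12,
        n_decoy_probes=3,
        n_multimap_probes=1,
        noise_sd=0.0,
        baseline_log_sd=1.0,
        planted_effects=(
            px.PlantedEffect("tx1", HYPOXIA_BOTH, 2.0),
            px.PlantedEffect("tx2", HYPOXIA_BOTH, -2.0),
        ),
        seed=42,
    )
    return px.simulate_bundle(cfg)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_bundle):
    b = noiseless_bundle
    return px.run_pipeline_in_memory(b.probes, b.transcriptome.records, b.matrix, plan=b.plan)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Moderate-noise experiment mixing genotype and hypoxia plants."""
    cfg = px.SimConfig(
        n_transcripts=40,
        n_decoy_probes=4,
        noise_sd=0.25,
        planted_effects=(
            px.PlantedEffect("tx1", HYPOXIA_BOTH, 2.0),
            px.PlantedEffect("tx2", HYPOXIA_BOTH, -2.0),
            px.PlantedEffect("tx3", GENOTYPE_ALL, 2.0),
            px.PlantedEffect("tx4", GENOTYPE_ALL, -2.0),
        ),
        seed=2024,
    )
    return px.simulate_bundle(cfg)


@pytest.fixture(scope="session")
def noisy_result(noisy_bundle):
    b = noisy_bundle
    return px.run_pipeline_in_memory(b.probes, b.transcriptome.records, b.matrix, plan=b.plan)
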