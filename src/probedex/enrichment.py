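"""Gene-list over-representation and the ddCt qPCR fold-change utility.

Enrichment of a differentially-regulated gene set Q against a published
target list T inside a universe of ``universe_size`` genes is the summed
hypergeometric density from the observed intersection QT up to min(Q, T) —
the probability of an intersection at least as large by chance.  The
universe size ("total number of mouse genes" in the original use) is a
required user parameter.

The ddCt (delta-delta-Ct) helper converts qPCR cycle thresholds into a
relative fold change, 2**-ddCt, with amplification efficiency fixed at 2.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .attribution import bh_adjust
from .errors import InputError


def list_enrichment(qt: int, q: int, t: int, universe_size: int) -> float:
    """P(intersection >= qt) when q genes are drawn from a universe with t targets.

    Parameters use the enrichment formula's symbols: ``qt`` observed
    intersection, ``q`` differentially regulated genes, ``t`` target-list
    size, ``universe_size`` total genes.
    """
    if not (0 <= q <= universe_size and 0 <= t <= universe_size):
        raise InputError(f"Q={q} and T={t} must lie in [0, universe={universe_size}]")
    if not 0 <= qt <= min(q, t):
        raise InputError(f"QT={qt} must lie in [0, min(Q={q}, T={t})]")
    if qt == 0:
        return 1.0
    return float(hypergeom.sf(qt - 1, universe_size, t, q))


def cross_validate(
    de_genes: set[str] | Sequence[str],
    target_lists: Mapping[str, set[str] | Sequence[str]],
    universe_size: int,
    adjust: bool = True,
) -> pd.DataFrame:
    """Enrichment of the DE gene set against each named target list.

    Identifiers must share one namespace; no ID mapping is attempted.
    Returns one row per list, in input order, with columns
    ``list_name, Q, T, QT, p`` (plus ``p_adj`` across lists when
    ``adjust`` is true).
    """
    if universe_size <= 0:
        raise InputError("universe_size must be positive")
    de = set(de_genes)
    rows = []
    for name, lst in target_lists.items():
        targets = set(lst)
        qt = len(de & targets)
        rows.append(
            {
                "list_name": name,
                "Q": len(de),
                "T": len(targets),
                "QT": qt,
                "p": list_enrichment(qt, len(de), len(targets), universe_size),
            }
        )
    table = pd.DataFrame(rows, columns=["list_name", "Q", "T", "QT", "p"])
    if adjust and len(table):
        table["p_adj"] = bh_adjust(table["p"].tolist())
    return table


def ddct_fold_change(
    ct_target_exp: float,
    ct_ref_exp: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression fold change 2**-ddCt.

    ddCt = (Ct_target - Ct_reference) in the experimental condition minus
    the same difference in the control condition; the reference gene (e.g.
    beta-actin) normalizes input amounts.
    """
    cts = (ct_target_exp, ct_ref_exp, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise InputError(f"Ct values must be finite, got {cts}")
    ddct = (ct_target_exp - ct_ref_exp) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
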