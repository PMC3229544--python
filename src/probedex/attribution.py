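"""Hypergeometric attribution of expression profiles to transcripts.

A transcript X is attributed a differential-expression profile A when its
probes are over-represented inside the cluster of probes sharing string A.
With T retained probes in total, X^T of them hitting X, a cluster of size A
and X^A of the transcript's probes inside that cluster, the attribution
error probability is the hypergeometric upper tail

    pAX = sum_{i = X^A}^{min(A, X^T)}  hg(i; T, X^T, A)

i.e. the chance of drawing at least X^A of the transcript's probes when A
probes are sampled without replacement from the T retained ones.  Raw pAX
values are Benjamini-Hochberg adjusted over all emitted (transcript,
profile) records; adjusted p < 0.05 declares the transcript differentially
expressed with that profile.  Downstream helpers derive per-comparison DE
lists, mean-relative-rank effect sizes, product-of-p reliability rankings
and genotype-contrast sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .align import ProbeIndex
from .design import ComparisonPlan
from .errors import ConfigError, InputError
from .stats import RankMatrix


@dataclass(frozen=True)
class AttributionRecord:
    """One tested (transcript, profile) pair with its counts and p-values."""

    transcript: str
    profile: str
    x_a: int       # probes with profile A hitting X
    a_size: int    # probes with profile A
    x_t: int       # probes hitting X
    t: int         # retained probes in the analysis
    p_raw: float
    p_adj: float | None = None


@dataclass(frozen=True)
class DECall:
    """A transcript declared differentially expressed at one comparison."""

    transcript: str
    position: int          # 1-based position in the comparison plan
    direction: str         # 'H' or 'L'
    p_adj: float
    effect: float | None = None   # mean relative-rank difference, in (-1, 1)
    ambiguous: bool = False
    profile: str | None = None    # supporting attribution's expression string


@dataclass
class ContrastSets:
    """Genotype-contrast transcript sets derived from plan positions 1-3."""

    naive_diff: dict[str, str]   # transcript -> letter at the naive contrast
    consistent: dict[str, str]   # DE same direction at 90 min and 24 h, not naive
    only_90: dict[str, str]
    only_24: dict[str, str]


def hypergeom_tail(x_a: int, a_size: int, x_t: int, t: int) -> float:
    """Upper-tail hypergeometric probability including the observed count."""
    if not (0 <= x_t <= t and 0 <= a_size <= t and 0 <= x_a <= min(a_size, x_t)):
        raise InputError(
            f"invalid counts: X_A={x_a}, A={a_size}, X_T={x_t}, T={t} "
            "(need 0 <= X_A <= min(A, X_T), X_T <= T, A <= T)"
        )
    if x_a == 0:
        return 1.0
    return float(hypergeom.sf(x_a - 1, t, x_t, a_size))


def attribute(
    clusters: Mapping[str, set[str]], index: ProbeIndex
) -> list[AttributionRecord]:
    """Build raw attribution records from profile clusters and the probe index.

    One record per (transcript, profile) pair with X^A >= 1.  The all-'E'
    profile encodes "no differential expression anywhere" and is excluded
    from testing.
    """
    cluster_universe = set().union(*clusters.values()) if clusters else set()
    if cluster_universe != index.retained_probe_ids:
        raise InputError(
            "clusters and probe index cover different probe universes "
            f"({len(cluster_universe)} vs {index.T} probes)"
        )
    t_total = index.T
    records: list[AttributionRecord] = []
    for profile in sorted(clusters):
        if set(profile) == {"E"}:
            continue
        members = clusters[profile]
        a_size = len(members)
        counts: dict[str, int] = {}
        for probe in members:
            for tx in index.hits[probe]:
                counts[tx] = counts.get(tx, 0) + 1
        for tx in sorted(counts):
            x_a = counts[tx]
            records.append(
                AttributionRecord(
                    transcript=tx,
                    profile=profile,
                    x_a=x_a,
                    a_size=a_size,
                    x_t=index.targets[tx],
                    t=t_total,
                    p_raw=hypergeom_tail(x_a, a_size, index.targets[tx], t_total),
                )
            )
    return records


def bh_adjust(p_values: Sequence[float], m_total: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    ``m_total`` sets the size of the hypothesis family when it exceeds the
    number of supplied p-values: the missing hypotheses are treated as
    having p = 1 (they occupy the trailing ranks and are never rejected,
    but they scale the correction for the supplied ones).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise InputError("p-values must lie in (0, 1]")
    if m_total is None:
        m_total = p.size
    if m_total < p.size:
        raise InputError(f"family size {m_total} smaller than {p.size} supplied p-values")
    padded = np.concatenate([p, np.ones(m_total - p.size)])
    adjusted = multipletests(padded, method="fdr_bh")[1]
    return adjusted[: p.size].tolist()


def adjust_records(
    records: Sequence[AttributionRecord], family_size: int | None = None
) -> list[AttributionRecord]:
    """Attach BH-adjusted p-values in one global family.

    The family is every (transcript, profile) pair the formula applies to
    — all indexed transcripts crossed with all observed non-trivial
    profiles — not just the pairs with overlapping probes.  Pairs with no
    overlap have pAX = 1 and are represented implicitly through
    ``family_size``; omitting them from the family (adjusting only over
    records with X^A >= 1) is anti-conservative, because the discrete
    singleton records all share the identical p-value X^T/T and a chance
    excess of them can then cascade through the step-up rule.
    """
    adj = bh_adjust([r.p_raw for r in records], m_total=family_size)
    return [replace(r, p_adj=a) for r, a in zip(records, adj)]


def attribution_family_size(
    clusters: Mapping[str, set[str]], index: ProbeIndex
) -> int:
    """All indexed transcripts x all observed profiles except the all-'E' one."""
    n_profiles = sum(1 for profile in clusters if set(profile) != {"E"})
    return len(index.targets) * n_profiles


def _resolve_positions(
    records: Iterable[AttributionRecord], alpha: float
) -> dict[int, dict[str, tuple[AttributionRecord, bool]]]:
    """Per plan position: transcript -> (minimal-p_adj significant record with
    a non-E letter there, ambiguity flag).

    A transcript is ambiguous at a position when significant records carry
    both 'H' and 'L' there; it resolves to the smaller adjusted p.
    """
    out: dict[int, dict[str, tuple[AttributionRecord, bool]]] = {}
    sig = [r for r in records if r.p_adj is not None and r.p_adj < alpha]
    for r in sig:
        for pos0, letter in enumerate(r.profile):
            if letter == "E":
                continue
            slot = out.setdefault(pos0 + 1, {})
            prev = slot.get(r.transcript)
            if prev is None:
                slot[r.transcript] = (r, False)
            else:
                best, amb = prev
                amb = amb or (r.profile[pos0] != best.profile[pos0])
                if (r.p_adj, r.transcript, r.profile) < (best.p_adj, best.transcript, best.profile):
                    best = r
                slot[r.transcript] = (best, amb)
    return out


def call_de(
    records: Sequence[AttributionRecord],
    alpha: float = 0.05,
    position: int = 1,
    letter: str = "H",
) -> list[DECall]:
    """Transcripts DE in the given direction at the given plan position.

    Membership requires an attribution with adjusted p strictly below
    ``alpha`` whose profile carries ``letter`` at ``position``; per
    transcript the minimal-p_adj supporting record decides.
    """
    if letter not in ("H", "L"):
        raise InputError(f"letter must be 'H' or 'L', got {letter!r}")
    plan_len = len(records[0].profile) if records else 0
    if records and not 1 <= position <= plan_len:
        raise InputError(f"position {position} outside plan of length {plan_len}")
    resolved = _resolve_positions(records, alpha).get(position, {})
    calls = [
        DECall(tx, position, letter, best.p_adj, ambiguous=amb, profile=best.profile)
        for tx, (best, amb) in resolved.items()
        if best.profile[position - 1] == letter
    ]
    return sorted(calls, key=lambda c: (c.p_adj, c.transcript))


def effect_size(
    transcript: str,
    profile: str,
    position: int,
    ranks: RankMatrix,
    plan: ComparisonPlan,
    index: ProbeIndex,
    clusters: Mapping[str, set[str]],
) -> float:
    """Mean relative-rank difference of the supporting probes.

    Averaged over the X^A probes of ``transcript`` inside cluster
    ``profile``: (mean relative rank on the comparison's experimental
    arrays) minus (mean on its control arrays).  Bounded in (-1, 1); the
    sign follows the attributed letter.
    """
    if not 1 <= position <= len(plan):
        raise InputError(f"position {position} outside plan of length {len(plan)}")
    if profile[position - 1] == "E":
        raise InputError(
            f"profile {profile!r} has no differential call at position {position}"
        )
    support = [
        p for p in clusters.get(profile, ()) if transcript in index.hits.get(p, ())
    ]
    if not support:
        raise InputError(f"no probes support ({transcript!r}, {profile!r})")
    comp = plan[position - 1]
    exp_ids = ranks.design.group_arrays(comp.experimental)
    ctrl_ids = ranks.design.group_arrays(comp.control)
    sub = ranks.ranks.loc[sorted(support)]
    diffs = sub[exp_ids].mean(axis=1) - sub[ctrl_ids].mean(axis=1)
    return float(diffs.mean())


def p_product_ranking(
    records_wt: Sequence[AttributionRecord],
    records_null: Sequence[AttributionRecord],
    position_pairs: Sequence[tuple[int, int]],
    alpha: float = 0.05,
) -> dict[tuple[int, int], list[tuple[str, float]]]:
    """Reliability ranking of transcripts DE in both genotypes at a timepoint.

    For each ``(wt_position, null_position)`` pair, transcripts DE (either
    direction) at both positions are ordered by the ascending product of
    their adjusted p-values; ties break on transcript id.
    """
    out: dict[tuple[int, int], list[tuple[str, float]]] = {}
    for pos_wt, pos_null in position_pairs:
        res_wt = _resolve_positions(records_wt, alpha).get(pos_wt, {})
        res_null = _resolve_positions(records_null, alpha).get(pos_null, {})
        common = set(res_wt) & set(res_null)
        ranked = sorted(
            ((tx, res_wt[tx][0].p_adj * res_null[tx][0].p_adj) for tx in common),
            key=lambda item: (item[1], item[0]),
        )
        out[(pos_wt, pos_null)] = ranked
    return out


def contrast_sets(
    records: Sequence[AttributionRecord],
    alpha: float = 0.05,
    genotype_positions: tuple[int, int, int] = (1, 2, 3),
) -> ContrastSets:
    """Genotype-contrast transcript sets from the three genotype comparisons.

    With resolved per-position letters L1, L2, L3 at the naive, 90-min and
    24-h genotype contrasts (E when not significant):

    - ``naive_diff``: L1 != E;
    - ``consistent``: L1 == E and L2 == L3 != E;
    - ``only_90``: L1 == E, L2 != E, L3 == E;
    - ``only_24``: L1 == E, L2 == E, L3 != E.

    The four sets are mutually disjoint by construction.
    """
    if records:
        plan_len = len(records[0].profile)
        if max(genotype_positions) > plan_len:
            raise ConfigError(
                f"plan of length {plan_len} lacks genotype positions {genotype_positions}"
            )
    resolved = _resolve_positions(records, alpha)
    p1, p2, p3 = genotype_positions

    def letter_at(pos: int, tx: str) -> str:
        entry = resolved.get(pos, {}).get(tx)
        return entry[0].profile[pos - 1] if entry else "E"

    transcripts = {r.transcript for r in records}
    naive_diff: dict[str, str] = {}
    consistent: dict[str, str] = {}
    only_90: dict[str, str] = {}
    only_24: dict[str, str] = {}
    for tx in sorted(transcripts):
        l1, l2, l3 = letter_at(p1, tx), letter_at(p2, tx), letter_at(p3, tx)
        if l1 != "E":
            naive_diff[tx] = l1
        elif l2 != "E" and l2 == l3:
            consistent[tx] = l2
        elif l2 != "E" and l3 == "E":
            only_90[tx] = l2
        elif l3 != "E" and l2 == "E":
            only_24[tx] = l3
    return ContrastSets(naive_diff, consistent, only_90, only_24)


def records_to_frame(records: Sequence[AttributionRecord]) -> pd.DataFrame:
    """Tabular view of attribution records (one row per tested pair)."""
    return pd.DataFrame(
        {
            "transcript": [r.transcript for r in records],
            "profile": [r.profile for r in records],
            "X_A": [r.x_a for r in records],
            "A_size": [r.a_size for r in records],
            "X_T": [r.x_t for r in records],
            "T": [r.t for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
        }
    )
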