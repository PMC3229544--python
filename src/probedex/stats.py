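"""Rank normalization, exact rank tests and H/L/E expression strings.

The analysis never models fluorescence values directly.  Each array is
normalized by relative ranking (rank / number-of-retained-probes, mid-ranks
on ties), which forces identical marginal distributions across arrays.  For
every probe and every planned two-group comparison an exact Mann-Whitney
rank-sum test is computed by full enumeration of the C(n+m, n) group
assignments of the pooled mid-ranked values — the study's group sizes are
3-5 animals, far too small for the normal approximation.  Each comparison
yields a letter: 'H' (higher in the experimental group, upper-tail p <=
alpha), 'L' (lower, lower-tail p <= alpha) or 'E' (neither); concatenating
the letters in plan order gives the probe's expression string, and probes
sharing an identical string form a profile cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import ComparisonPlan, ExperimentDesign, default_plan
from .errors import ConfigError, InputError

# rank sums of mid-ranked values are exact multiples of 0.5; this guard only
# absorbs float summation noise
_EPS = 1e-9


@dataclass
class IntensityMatrix:
    """Probe x array fluorescence values with the array design attached."""

    values: pd.DataFrame  # index: probe_ids, columns: array_ids, all > 0
    design: ExperimentDesign

    def __post_init__(self):
        if list(self.values.columns) != self.design.array_ids:
            missing = set(self.design.array_ids) - set(self.values.columns)
            if missing:
                raise InputError(f"intensity matrix lacks design arrays: {sorted(missing)}")
            self.values = self.values[self.design.array_ids]
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (not np.isfinite(arr).all() or (arr <= 0).any()):
            r, c = np.argwhere(~(np.isfinite(arr) & (arr > 0)))[0]
            raise InputError(
                f"non-positive or missing intensity at probe {self.values.index[r]!r}, "
                f"array {self.values.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, probe_ids: Sequence[str]) -> "IntensityMatrix":
        """Subset to the given probes (e.g. the aligner's retained set)."""
        keep = [p for p in self.probe_ids if p in set(probe_ids)]
        return IntensityMatrix(self.values.loc[keep], self.design)


@dataclass
class RankMatrix:
    """Per-array relative ranks in (0, 1]; the normalized expression measure."""

    ranks: pd.DataFrame
    design: ExperimentDesign

    @property
    def probe_ids(self) -> list[str]:
        return list(self.ranks.index)


def rank_normalize(matrix: IntensityMatrix) -> RankMatrix:
    """Relative-rank each array independently: rank/P with mid-ranks on ties.

    The per-array sum of relative ranks is (P+1)/2 exactly, ties or not.
    """
    if matrix.values.empty:
        raise InputError("cannot rank-normalize an empty intensity matrix")
    arr = matrix.values.to_numpy(dtype=float)
    P = arr.shape[0]
    ranks = rankdata(arr, axis=0, method="average") / P
    return RankMatrix(
        pd.DataFrame(ranks, index=matrix.values.index, columns=matrix.values.columns),
        matrix.design,
    )


@lru_cache(maxsize=64)
def _subset_masks(n_total: int, n_exp: int) -> np.ndarray:
    """Boolean matrix (C(n_total, n_exp) x n_total): all experimental-group
    index subsets, used as the exact permutation null."""
    combos = list(combinations(range(n_total), n_exp))
    masks = np.zeros((len(combos), n_total), dtype=float)
    for i, c in enumerate(combos):
        masks[i, list(c)] = 1.0
    return masks


def mw_exact_matrix(exp: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized exact Mann-Whitney tails for many probes at once.

    Parameters
    ----------
    exp, ctrl
        Arrays of shape (n_probes, n_exp) and (n_probes, n_ctrl) holding the
        probes' relative ranks on the two groups' arrays.

    Returns
    -------
    (p_upper, p_lower), each of shape (n_probes,).  Both tails include the
    observed rank-sum statistic; ties are handled by mid-ranking the pooled
    values before enumeration.
    """
    n_exp, n_ctrl = exp.shape[1], ctrl.shape[1]
    if n_exp < 2 or n_ctrl < 2:
        raise InputError(f"each group needs >= 2 values (got {n_exp} and {n_ctrl})")
    pooled = np.concatenate([exp, ctrl], axis=1)
    midranks = rankdata(pooled, axis=1, method="average")
    w_obs = midranks[:, :n_exp].sum(axis=1)
    masks = _subset_masks(n_exp + n_ctrl, n_exp)
    w_all = midranks @ masks.T  # (n_probes, n_assignments)
    p_upper = (w_all >= w_obs[:, None] - _EPS).mean(axis=1)
    p_lower = (w_all <= w_obs[:, None] + _EPS).mean(axis=1)
    return p_upper, p_lower


def mw_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact one-sided Mann-Whitney tail probabilities for one probe.

    ``x`` holds the experimental-group values, ``y`` the control-group
    values (typically the probe's relative ranks on those arrays).  Returns
    ``(p_upper, p_lower)`` where p_upper tests "experimental higher".
    """
    xa = np.asarray(x, dtype=float)[None, :]
    ya = np.asarray(y, dtype=float)[None, :]
    pu, pl = mw_exact_matrix(xa, ya)
    return float(pu[0]), float(pl[0])


def assign_letter(p_upper: float, p_lower: float, alpha: float = 0.05) -> str:
    """H if p_upper <= alpha, L if p_lower <= alpha, else E (inclusive cut)."""
    if not 0 < alpha < 0.5:
        raise ConfigError(f"alpha must lie in (0, 0.5), got {alpha}")
    if p_upper <= alpha:
        return "H"
    if p_lower <= alpha:
        return "L"
    return "E"


def build_expression_strings(
    ranks: RankMatrix,
    plan: ComparisonPlan | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-probe H/L/E string across the comparison plan.

    Returns a DataFrame indexed by probe_id with the column
    ``expression_string`` plus ``p_upper:<label>`` / ``p_lower:<label>``
    columns for each comparison, in plan order.
    """
    if plan is None:
        plan = default_plan()
    if not 0 < alpha < 0.5:
        raise ConfigError(f"alpha must lie in (0, 0.5), got {alpha}")
    plan.validate_against(ranks.design, min_group=2)

    letters = []
    cols: dict[str, np.ndarray] = {}
    for comp in plan:
        exp_ids = ranks.design.group_arrays(comp.experimental)
        ctrl_ids = ranks.design.group_arrays(comp.control)
        exp = ranks.ranks[exp_ids].to_numpy(dtype=float)
        ctrl = ranks.ranks[ctrl_ids].to_numpy(dtype=float)
        pu, pl = mw_exact_matrix(exp, ctrl)
        cols[f"p_upper:{comp.label}"] = pu
        cols[f"p_lower:{comp.label}"] = pl
        lett = np.full(len(pu), "E", dtype="<U1")
        lett[pl <= alpha] = "L"
        lett[pu <= alpha] = "H"  # upper tail wins; exact tails cannot co-fire at alpha < 0.5
        letters.append(lett)

    strings = np.apply_along_axis("".join, 0, np.vstack(letters)) if letters else []
    out = pd.DataFrame({"expression_string": strings}, index=ranks.ranks.index)
    for name, vals in cols.items():
        out[name] = vals
    return out


def expression_string_map(strings: pd.DataFrame) -> dict[str, str]:
    """Plain probe_id -> string view of :func:`build_expression_strings` output."""
    return strings["expression_string"].to_dict()


def cluster_probes(strings: Mapping[str, str]) -> dict[str, set[str]]:
    """Group probes by identical expression string; cluster size is A."""
    clusters: dict[str, set[str]] = {}
    for probe, s in strings.items():
        clusters.setdefault(s, set()).add(probe)
    return clusters
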