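"""Experiment design and comparison plan.

The study design is a 2 genotype (wild-type vs knockout) x 3 timepoint
(naive, 90 min hypoxia, 24 h hypoxia) layout.  Every probe receives one
two-group comparison per entry of the :class:`ComparisonPlan`; the default
plan holds the seven canonical comparisons: genotype contrasts at each
timepoint, then each genotype's hypoxia timepoints against its own naive
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import ConfigError, InputError

GENOTYPES = ("wt", "null")
TIMEPOINTS = ("0", "90min", "24h")

GroupKey = tuple[str, str]  # (genotype, timepoint)


@dataclass(frozen=True)
class ArrayRecord:
    array_id: str
    genotype: str
    timepoint: str

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise InputError(f"unknown genotype {self.genotype!r} for array {self.array_id!r}")
        if self.timepoint not in TIMEPOINTS:
            raise InputError(f"unknown timepoint {self.timepoint!r} for array {self.array_id!r}")

    @property
    def group(self) -> GroupKey:
        return (self.genotype, self.timepoint)


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered list of arrays with their (genotype, timepoint) labels."""

    arrays: tuple[ArrayRecord, ...]

    def __post_init__(self):
        ids = [a.array_id for a in self.arrays]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise InputError(f"duplicate array_id {dup!r} in design")

    @property
    def array_ids(self) -> list[str]:
        return [a.array_id for a in self.arrays]

    def groups(self) -> dict[GroupKey, list[str]]:
        out: dict[GroupKey, list[str]] = {}
        for a in self.arrays:
            out.setdefault(a.group, []).append(a.array_id)
        return out

    def group_arrays(self, group: GroupKey) -> list[str]:
        arrs = [a.array_id for a in self.arrays if a.group == group]
        if not arrs:
            raise InputError(f"design has no arrays in group {group}")
        return arrs


@dataclass(frozen=True)
class Comparison:
    """A two-group comparison; 'H' means higher in the experimental group."""

    label: str
    experimental: GroupKey
    control: GroupKey


@dataclass(frozen=True)
class ComparisonPlan:
    comparisons: tuple[Comparison, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.comparisons)

    def __iter__(self):
        return iter(self.comparisons)

    def __getitem__(self, i: int) -> Comparison:
        return self.comparisons[i]

    def labels(self) -> list[str]:
        return [c.label for c in self.comparisons]

    def validate_against(self, design: ExperimentDesign, min_group: int = 2) -> None:
        groups = design.groups()
        for c in self.comparisons:
            for g in (c.experimental, c.control):
                if g not in groups:
                    raise ConfigError(f"comparison {c.label!r} references missing group {g}")
                if len(groups[g]) < min_group:
                    raise ConfigError(
                        f"comparison {c.label!r}: group {g} has {len(groups[g])} arrays; "
                        f"need at least {min_group}"
                    )


def default_design(
    group_sizes: Iterable[int] = (3, 5, 5, 5, 5, 4),
) -> ExperimentDesign:
    """The study's 6-group design.

    Group order (matching *group_sizes*): naive wt, naive knockout, 90-min wt,
    90-min knockout, 24-h wt, 24-h knockout; defaults are the published
    animal counts (3, 5, 5, 5, 5, 4).
    """
    order: list[GroupKey] = [
        ("wt", "0"), ("null", "0"),
        ("wt", "90min"), ("null", "90min"),
        ("wt", "24h"), ("null", "24h"),
    ]
    sizes = list(group_sizes)
    if len(sizes) != len(order):
        raise ConfigError(f"expected {len(order)} group sizes, got {len(sizes)}")
    arrays = []
    for (geno, tp), n in zip(order, sizes):
        for k in range(1, n + 1):
            arrays.append(ArrayRecord(f"{geno}_{tp}_{k}", geno, tp))
    return ExperimentDesign(tuple(arrays))


def default_plan() -> ComparisonPlan:
    """Canonical 7-comparison plan.

    Positions 1-3: knockout vs wt at 0 h, 90 min, 24 h (experimental group is
    the knockout).  Positions 4-5: wt 90 min / 24 h vs naive wt.  Positions
    6-7: knockout 90 min / 24 h vs naive knockout.
    """
    c = Comparison
    return ComparisonPlan((
        c("null_vs_wt_0", ("null", "0"), ("wt", "0")),
        c("null_vs_wt_90min", ("null", "90min"), ("wt", "90min")),
        c("null_vs_wt_24h", ("null", "24h"), ("wt", "24h")),
        c("wt_90min_vs_0", ("wt", "90min"), ("wt", "0")),
        c("wt_24h_vs_0", ("wt", "24h"), ("wt", "0")),
        c("null_90min_vs_0", ("null", "90min"), ("null", "0")),
        c("null_24h_vs_0", ("null", "24h"), ("null", "0")),
    ))
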