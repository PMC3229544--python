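"""End-to-end pipeline: align, normalize, test, cluster, attribute, report.

``run_pipeline`` wires the stages together and writes every result table
as TSV under the configured output directory; it is fully deterministic
for fixed inputs, so re-running produces byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import attribution as attr
from .align import ProbeIndex, align_probes, build_probe_index
from .design import Comparison, ComparisonPlan, ExperimentDesign, default_plan
from .errors import ConfigError, PipelineError
from .io import (
    hits_to_frame,
    read_design_tsv,
    read_fasta,
    read_intensity_tsv,
    write_table,
)
from .stats import (
    IntensityMatrix,
    RankMatrix,
    build_expression_strings,
    cluster_probes,
    expression_string_map,
    rank_normalize,
)

log = logging.getLogger("probedex")


@dataclass
class RunConfig:
    probes_fasta: str
    transcripts_fasta: str
    intensities_tsv: str
    design_tsv: str
    out_dir: str
    alpha: float = 0.05
    min_match: int = 22
    plan: ComparisonPlan | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 0.5:
            raise ConfigError(f"alpha must lie in (0, 0.5), got {self.alpha}")
        if not 15 <= self.min_match <= 25:
            raise ConfigError(f"min_match must lie in [15, 25], got {self.min_match}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        plan = None
        if "plan" in raw:
            plan = ComparisonPlan(
                tuple(
                    Comparison(
                        c["label"],
                        (c["experimental"]["genotype"], c["experimental"]["timepoint"]),
                        (c["control"]["genotype"], c["control"]["timepoint"]),
                    )
                    for c in raw.pop("plan")
                )
            )
        return cls(plan=plan, **raw)


@dataclass
class PipelineResult:
    index: ProbeIndex
    ranks: RankMatrix
    strings: pd.DataFrame
    clusters: dict[str, set[str]]
    records: list[attr.AttributionRecord]
    de_calls: dict[int, list[attr.DECall]]        # plan position -> calls (both directions)
    contrasts: attr.ContrastSets
    rankings: dict[tuple[int, int], list[tuple[str, float]]]
    plan: ComparisonPlan
    stage_counts: dict[str, int]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline_in_memory(
    probes: Sequence[tuple[str, str]],
    transcripts: Sequence[tuple[str, str]],
    matrix: IntensityMatrix,
    plan: ComparisonPlan | None = None,
    alpha: float = 0.05,
    min_match: int = 22,
) -> PipelineResult:
    """The full analysis on in-memory inputs; see module docstring."""
    if plan is None:
        plan = default_plan()
    plan.validate_against(matrix.design)

    hits = _stage("align")(align_probes)(probes, transcripts, min_match)
    index = build_probe_index(hits, [p for p, _ in probes])
    log.info("align: %d/%d probes retained, %d discarded",
             index.T, index.n_input_probes, index.n_discarded)
    if index.T == 0:
        raise PipelineError("align", "0 probes retained: no probe aligned to any transcript")

    retained = _stage("restrict")(matrix.restrict)(index.retained_probe_ids)
    ranks = _stage("rank_normalize")(rank_normalize)(retained)
    strings = _stage("expression_strings")(build_expression_strings)(ranks, plan, alpha)
    smap = expression_string_map(strings)
    clusters = cluster_probes(smap)
    log.info("strings: %d probes, %d distinct profiles", len(smap), len(clusters))

    records = _stage("attribute")(attr.attribute)(clusters, index)
    records = attr.adjust_records(
        records, family_size=attr.attribution_family_size(clusters, index)
    )
    n_sig = sum(1 for r in records if r.p_adj is not None and r.p_adj < alpha)
    log.info("attribute: %d records tested, %d significant at adjusted p < %g",
             len(records), n_sig, alpha)

    de_calls: dict[int, list[attr.DECall]] = {}
    for pos in range(1, len(plan) + 1):
        calls = []
        for letter in ("H", "L"):
            for call in attr.call_de(records, alpha, pos, letter):
                eff = attr.effect_size(
                    call.transcript, call.profile, pos, ranks, plan, index, clusters
                )
                calls.append(
                    attr.DECall(call.transcript, pos, letter, call.p_adj, eff,
                                call.ambiguous, call.profile)
                )
        de_calls[pos] = sorted(calls, key=lambda c: (c.p_adj, c.transcript))

    contrasts = attr.contrast_sets(records, alpha)
    rankings = attr.p_product_ranking(records, records, [(4, 6), (5, 7)], alpha) \
        if len(plan) >= 7 else {}

    counts = {
        "probes_input": index.n_input_probes,
        "probes_retained": index.T,
        "probes_discarded": index.n_discarded,
        "clusters": len(clusters),
        "records_tested": len(records),
        "significant_attributions": n_sig,
    }
    return PipelineResult(index, ranks, strings, clusters, records, de_calls,
                          contrasts, rankings, plan, counts)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs per the config, run the analysis, write all TSV outputs."""
    design = _stage("read_design")(read_design_tsv)(config.design_tsv)
    probes = _stage("read_probes")(read_fasta)(config.probes_fasta)
    transcripts = _stage("read_transcripts")(read_fasta)(config.transcripts_fasta)
    matrix = _stage("read_intensities")(read_intensity_tsv)(config.intensities_tsv, design)

    result = run_pipeline_in_memory(
        probes, transcripts, matrix,
        plan=config.plan, alpha=config.alpha, min_match=config.min_match,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hits = align_probes(probes, transcripts, config.min_match)
    write_table(out / "hits.tsv", hits_to_frame(hits))
    write_table(
        out / "expression_strings.tsv",
        result.strings.rename_axis("probe_id").reset_index(),
    )
    write_table(out / "attributions.tsv", attr.records_to_frame(result.records))

    labels = result.plan.labels()
    for pos, calls in result.de_calls.items():
        write_table(
            out / f"de_{pos}_{labels[pos - 1]}.tsv",
            pd.DataFrame(
                {
                    "transcript": [c.transcript for c in calls],
                    "direction": [c.direction for c in calls],
                    "p_adj": [c.p_adj for c in calls],
                    "effect": [c.effect for c in calls],
                    "ambiguous": [int(c.ambiguous) for c in calls],
                }
            ),
        )
    for name, members in (
        ("naive_diff", result.contrasts.naive_diff),
        ("consistent", result.contrasts.consistent),
        ("only_90min", result.contrasts.only_90),
        ("only_24h", result.contrasts.only_24),
    ):
        write_table(
            out / f"contrast_{name}.tsv",
            pd.DataFrame(
                {"transcript": sorted(members), "direction": [members[t] for t in sorted(members)]}
            ),
        )
    for (pw, pn), ranked in result.rankings.items():
        write_table(
            out / f"ranking_wt{pw}_null{pn}.tsv",
            pd.DataFrame(
                {
                    "transcript": [t for t, _ in ranked],
                    "p_product": [p for _, p in ranked],
                }
            ),
        )
    write_table(
        out / "stage_counts.tsv",
        pd.DataFrame({"stage": list(result.stage_counts), "count": list(result.stage_counts.values())}),
    )
    return result
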