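"""Synthetic transcriptomes, probe sets and intensity matrices.

Everything downstream of raw data is testable against a known truth: this
module generates (i) random transcript sequences, optionally with shared
25-mer windows so that some probes multi-map, (ii) 25-nt probes as reverse
complements of transcript windows (the aligner's minus-strand rule then
finds them) plus decoy probes guaranteed to have no >= 22-nt match
anywhere, and (iii) a probe x array fluorescence matrix under a
log-additive model: per-probe affinity intercepts, planted group-level
log2 fold changes, and Gaussian log-scale noise.  The method under test is
rank-based, so only the ordering the model induces matters.

Planted effects name comparison-plan positions; each named position's
experimental group receives the log2 fold change for all probes of the
planted transcript.  Because the six design groups enter seven overlapping
comparisons, a bump to one group can shift comparisons other than the
named one (e.g. raising 90-min wt arrays perturbs the 90-min genotype
contrast too).  The :class:`GroundTruth` ledger therefore records the
*realized* per-comparison group-difference profile, which equals the
planted letters exactly when the planted position set is self-consistent
(e.g. {1,2,3} or {4,5,6,7} with one fold change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import align_probes, revcomp
from .design import ComparisonPlan, ExperimentDesign, default_design, default_plan
from .errors import ConfigError, InputError
from .stats import IntensityMatrix

_LN2 = math.log(2.0)
PROBE_LENGTH = 25


@dataclass(frozen=True)
class PlantedEffect:
    """A transcript's differential expression at selected plan positions."""

    transcript_id: str
    positions: tuple[int, ...]   # 1-based comparison-plan positions
    log2_fold_change: float


@dataclass
class SimConfig:
    n_transcripts: int = 200
    transcript_length: int = 500
    probes_per_transcript: int = 9
    probe_length: int = PROBE_LENGTH
    n_decoy_probes: int = 0
    n_multimap_probes: int = 0
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.25
    planted_effects: tuple[PlantedEffect, ...] = field(default_factory=tuple)
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory; no hidden global randomness")
        if self.probe_length != PROBE_LENGTH:
            raise ConfigError(f"probe_length is fixed at {PROBE_LENGTH} nt")
        if self.n_transcripts < 0 or self.n_decoy_probes < 0 or self.n_multimap_probes < 0:
            raise ConfigError("counts must be non-negative")
        if self.noise_sd < 0 or self.baseline_log_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        if self.n_transcripts > 0 and self.transcript_length < (
            self.probe_length + self.probes_per_transcript - 1
        ):
            raise ConfigError(
                f"transcript_length={self.transcript_length} too short to tile "
                f"{self.probes_per_transcript} distinct-start {self.probe_length}-nt windows"
            )
        if self.n_multimap_probes > self.n_transcripts // 2:
            raise ConfigError("n_multimap_probes needs two transcripts per shared window")


@dataclass(frozen=True)
class SharedWindow:
    """A 25-mer window duplicated verbatim from one transcript into another."""

    source_tx: str
    source_start: int  # 0-based
    dest_tx: str
    dest_start: int


@dataclass
class Transcriptome:
    records: list[tuple[str, str]]
    shared_windows: list[SharedWindow] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Ledger of what was planted, for parameter-recovery tests.

    ``true_profile`` and ``true_fold`` reflect realized group-level
    differences per comparison (see module docstring).
    """

    probe_origin: dict[str, str]              # probe_id -> transcript_id or "decoy"
    true_profile: dict[str, str]              # transcript_id -> H/L/E string
    true_fold: dict[str, tuple[float, ...]]   # transcript_id -> per-comparison log2 FC


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def simulate_transcriptome(config: SimConfig) -> Transcriptome:
    """Random ACGT transcripts; deterministic given the seed.

    All 25-mers are unique across the transcriptome except the
    ``n_multimap_probes`` deliberately duplicated windows.
    """
    config.validate()
    rng = _rng(config, 1)
    bases = np.array(list("ACGT"))
    records: list[tuple[str, str]] = []
    seen_kmers: set[str] = set()
    for i in range(config.n_transcripts):
        # rejection-sample transcripts whose 25-mers collide (astronomically rare)
        for _ in range(100):
            seq = "".join(rng.choice(bases, size=config.transcript_length))
            kmers = {
                seq[j : j + PROBE_LENGTH]
                for j in range(len(seq) - PROBE_LENGTH + 1)
            }
            if len(kmers) == config.transcript_length - PROBE_LENGTH + 1 and not (
                kmers & seen_kmers
            ):
                break
        else:  # pragma: no cover
            raise ConfigError("could not generate collision-free transcripts")
        seen_kmers |= kmers
        records.append((f"tx{i + 1}", seq))

    shared: list[SharedWindow] = []
    if config.n_multimap_probes:
        # pair distinct transcripts: copy a window of the source verbatim
        # into the destination, creating exactly one duplicated 25-mer each
        order = rng.permutation(config.n_transcripts)
        for k in range(config.n_multimap_probes):
            si, di = int(order[2 * k]), int(order[2 * k + 1])
            src_id, src_seq = records[si]
            dst_id, dst_seq = records[di]
            s_start = int(rng.integers(0, len(src_seq) - PROBE_LENGTH + 1))
            d_start = int(rng.integers(0, len(dst_seq) - PROBE_LENGTH + 1))
            window = src_seq[s_start : s_start + PROBE_LENGTH]
            new_dst = list(dst_seq[:d_start] + window + dst_seq[d_start + PROBE_LENGTH :])
            # break the flanks so the duplication is exactly one 25-mer:
            # a flank base equal to the source's flank would extend the
            # shared window and duplicate neighbouring 25-mers too
            for d_flank, s_flank in (
                (d_start - 1, s_start - 1),
                (d_start + PROBE_LENGTH, s_start + PROBE_LENGTH),
            ):
                if 0 <= d_flank < len(new_dst) and 0 <= s_flank < len(src_seq):
                    if new_dst[d_flank] == src_seq[s_flank]:
                        alternatives = [b for b in "ACGT" if b != src_seq[s_flank]]
                        new_dst[d_flank] = alternatives[int(rng.integers(0, 3))]
            records[di] = (dst_id, "".join(new_dst))
            shared.append(SharedWindow(src_id, s_start, dst_id, d_start))
    return Transcriptome(records, shared)


def design_probes(
    transcriptome: Transcriptome, config: SimConfig
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Probes as reverse complements of distinct transcript windows.

    Per transcript, ``probes_per_transcript`` windows with distinct starts;
    windows duplicated into a second transcript (multi-mapping) are always
    among the chosen ones.  ``n_decoy_probes`` additional random 25-mers
    are rejection-sampled until they share no >= 22-nt contiguous match
    with any transcript minus strand, guaranteeing they are discarded by
    the aligner.

    Returns ``(probes, probe_origin)``.
    """
    config.validate()
    rng = _rng(config, 2)
    probes: list[tuple[str, str]] = []
    origin: dict[str, str] = {}
    forced: dict[str, list[int]] = {}
    for w in transcriptome.shared_windows:
        forced.setdefault(w.source_tx, []).append(w.source_start)

    for tx_id, seq in transcriptome.records:
        n_starts = len(seq) - PROBE_LENGTH + 1
        starts = list(forced.get(tx_id, []))
        if len(starts) > config.probes_per_transcript:
            raise ConfigError(f"transcript {tx_id!r}: more forced windows than probes")
        pool = [s for s in range(n_starts) if s not in set(starts)]
        need = config.probes_per_transcript - len(starts)
        if need > len(pool):
            raise ConfigError(
                f"transcript {tx_id!r}: cannot place {config.probes_per_transcript} "
                "distinct-start windows"
            )
        starts += [pool[int(i)] for i in rng.choice(len(pool), size=need, replace=False)]
        for m, s in enumerate(sorted(starts), start=1):
            pid = f"{tx_id}_probe{m}"
            probes.append((pid, revcomp(seq[s : s + PROBE_LENGTH])))
            origin[pid] = tx_id

    # 22-mer set of all transcripts: any >= 22-nt match implies membership
    k = 22
    kmer_set: set[str] = set()
    for _, seq in transcriptome.records:
        for j in range(len(seq) - k + 1):
            kmer_set.add(seq[j : j + k])
    bases = np.array(list("ACGT"))
    for d in range(1, config.n_decoy_probes + 1):
        for _ in range(1000):
            cand = "".join(rng.choice(bases, size=PROBE_LENGTH))
            rc = revcomp(cand)
            if all(rc[o : o + k] not in kmer_set for o in range(PROBE_LENGTH - k + 1)):
                break
        else:  # pragma: no cover
            raise ConfigError("could not sample a decoy probe with no 22-nt match")
        pid = f"decoy{d}"
        probes.append((pid, cand))
        origin[pid] = "decoy"
    return probes, origin


def _group_bumps(
    effects: Sequence[PlantedEffect], plan: ComparisonPlan
) -> dict[str, dict[tuple[str, str], float]]:
    """Per planted transcript, the natural-log bump applied to each group."""
    bumps: dict[str, dict[tuple[str, str], float]] = {}
    for eff in effects:
        tx_bumps = bumps.setdefault(eff.transcript_id, {})
        for pos in eff.positions:
            if not 1 <= pos <= len(plan):
                raise InputError(
                    f"planted position {pos} outside plan of length {len(plan)}"
                )
            grp = plan[pos - 1].experimental
            tx_bumps[grp] = tx_bumps.get(grp, 0.0) + _LN2 * eff.log2_fold_change
    return bumps


def realized_truth(
    effects: Sequence[PlantedEffect], plan: ComparisonPlan
) -> tuple[dict[str, str], dict[str, tuple[float, ...]]]:
    """Realized per-comparison letters and log2 fold changes per transcript."""
    bumps = _group_bumps(effects, plan)
    profiles: dict[str, str] = {}
    folds: dict[str, tuple[float, ...]] = {}
    for tx, tx_bumps in bumps.items():
        deltas = []
        letters = []
        for comp in plan:
            d = tx_bumps.get(comp.experimental, 0.0) - tx_bumps.get(comp.control, 0.0)
            deltas.append(d / _LN2)
            letters.append("H" if d > 1e-12 else "L" if d < -1e-12 else "E")
        profiles[tx] = "".join(letters)
        folds[tx] = tuple(deltas)
    return profiles, folds


def simulate_intensities(
    design: ExperimentDesign,
    probes: Sequence[tuple[str, str]],
    probe_origin: dict[str, str],
    config: SimConfig,
    plan: ComparisonPlan | None = None,
) -> tuple[IntensityMatrix, GroundTruth]:
    """Fluorescence matrix under the log-additive model.

    log intensity(p, a) = b_p + bump(origin(p), group(a)) + eps(p, a) with
    b_p ~ N(baseline_log_mean, baseline_log_sd) drawn once per probe and
    eps ~ N(0, noise_sd).  All values are positive; deterministic given
    the seed.
    """
    config.validate()
    if plan is None:
        plan = default_plan()
    transcript_ids = {o for o in probe_origin.values() if o != "decoy"}
    for eff in config.planted_effects:
        if eff.transcript_id not in transcript_ids:
            raise InputError(f"planted transcript {eff.transcript_id!r} has no probes")

    rng = _rng(config, 3)
    probe_ids = [pid for pid, _ in probes]
    n_p, n_a = len(probe_ids), len(design.arrays)
    b = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_p)
    eps = rng.normal(0.0, config.noise_sd, size=(n_p, n_a)) if config.noise_sd > 0 else np.zeros((n_p, n_a))

    bumps = _group_bumps(config.planted_effects, plan)
    log_vals = b[:, None] + eps
    for pi, pid in enumerate(probe_ids):
        tx_bumps = bumps.get(probe_origin.get(pid, "decoy"))
        if tx_bumps:
            for ai, arr in enumerate(design.arrays):
                log_vals[pi, ai] += tx_bumps.get(arr.group, 0.0)

    values = pd.DataFrame(np.exp(log_vals), index=probe_ids, columns=design.array_ids)
    profiles, folds = realized_truth(config.planted_effects, plan)
    truth = GroundTruth(probe_origin=dict(probe_origin), true_profile=profiles, true_fold=folds)
    return IntensityMatrix(values, design), truth


@dataclass
class SyntheticBundle:
    """Everything one simulated experiment produces."""

    transcriptome: Transcriptome
    probes: list[tuple[str, str]]
    matrix: IntensityMatrix
    truth: GroundTruth
    design: ExperimentDesign
    plan: ComparisonPlan


def simulate_bundle(
    config: SimConfig,
    design: ExperimentDesign | None = None,
    plan: ComparisonPlan | None = None,
) -> SyntheticBundle:
    """Convenience wrapper running the three generation stages in order."""
    if design is None:
        design = default_design()
    if plan is None:
        plan = default_plan()
    plan.validate_against(design)
    transcriptome = simulate_transcriptome(config)
    probes, origin = design_probes(transcriptome, config)
    if not probes:
        raise ConfigError("configuration produces no probes at all")
    matrix, truth = simulate_intensities(design, probes, origin, config, plan)
    # decoy guarantee, checked mechanically at generation time
    decoys = [p for p in probes if truth.probe_origin[p[0]] == "decoy"]
    if decoys and transcriptome.records:
        stray = align_probes(decoys, transcriptome.records, min_match=22)
        if stray:  # pragma: no cover
            raise RuntimeError(f"decoy probe produced alignment hits: {stray[0]}")
    return SyntheticBundle(transcriptome, probes, matrix, truth, design, plan)
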