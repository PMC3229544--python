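"""Calibration experiments on synthetic data: null FDR and recovery.

Two standard experiments characterize the pipeline under the study's
design (group sizes 3, 5, 5, 5, 5, 4):

* the **null experiment** plants nothing and measures the fraction of
  transcripts declared differentially expressed — the realized false
  discovery rate, which BH adjustment should hold at or below alpha;
* the **recovery experiment** plants known fold changes in a subset of
  transcripts and measures how many are recovered with the correct
  direction at every affected comparison, and how often a detection's
  direction contradicts the planted truth.

Both iterate over independent seeds so the numbers are averages over
simulated experiments, not single draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .attribution import call_de
from .design import default_design, default_plan
from .errors import ConfigError
from .pipeline import run_pipeline_in_memory
from .simulate import PlantedEffect, SimConfig, simulate_bundle

#: planted position sets consistent across the seven overlapping
#: comparisons: hypoxia response shared by both genotypes, and a
#: constitutive genotype difference
HYPOXIA_BOTH = (4, 5, 6, 7)
GENOTYPE_ALL = (1, 2, 3)


@dataclass
class NullExperimentResult:
    per_seed_fraction: list[float]

    @property
    def mean_fraction(self) -> float:
        return sum(self.per_seed_fraction) / len(self.per_seed_fraction)


@dataclass
class RecoveryExperimentResult:
    per_seed_recovered: list[int]
    n_planted: int
    direction_errors: int = 0
    n_detections: int = 0

    @property
    def recovery_rate(self) -> float:
        total = self.n_planted * len(self.per_seed_recovered)
        return sum(self.per_seed_recovered) / total


def _run(config: SimConfig):
    bundle = simulate_bundle(config)
    result = run_pipeline_in_memory(
        bundle.probes, bundle.transcriptome.records, bundle.matrix, plan=bundle.plan
    )
    return bundle, result


def null_experiment(
    n_transcripts: int = 200,
    probes_per_transcript: int = 9,
    seeds: Sequence[int] = tuple(range(10)),
    alpha: float = 0.05,
) -> NullExperimentResult:
    """Fraction of transcripts called DE when nothing is planted.

    Returns the per-seed fraction of transcripts with any attribution at
    adjusted p < alpha; the mean should not exceed alpha.
    """
    fractions = []
    for seed in seeds:
        config = SimConfig(
            n_transcripts=n_transcripts,
            probes_per_transcript=probes_per_transcript,
            seed=seed,
        )
        _, result = _run(config)
        called = {
            r.transcript
            for r in result.records
            if r.p_adj is not None and r.p_adj < alpha
        }
        fractions.append(len(called) / n_transcripts)
    return NullExperimentResult(fractions)


def default_planted_effects(
    n_planted: int = 20, log2fc: float = 2.0
) -> tuple[PlantedEffect, ...]:
    """A balanced planted set: up/down hypoxia response in both genotypes
    and up/down constitutive genotype differences, |log2FC| = ``log2fc``."""
    if n_planted % 4:
        raise ConfigError("n_planted must be divisible by 4 for a balanced set")
    quarter = n_planted // 4
    effects = []
    i = 1
    for positions, sign in (
        (HYPOXIA_BOTH, +1), (HYPOXIA_BOTH, -1),
        (GENOTYPE_ALL, +1), (GENOTYPE_ALL, -1),
    ):
        for _ in range(quarter):
            effects.append(PlantedEffect(f"tx{i}", positions, sign * log2fc))
            i += 1
    return tuple(effects)


def recovery_experiment(
    n_transcripts: int = 200,
    n_planted: int = 20,
    log2fc: float = 2.0,
    noise_sd: float = 0.25,
    seeds: Sequence[int] = tuple(range(10)),
    alpha: float = 0.05,
) -> RecoveryExperimentResult:
    """Recovery of planted transcripts with correct directions.

    A planted transcript counts as recovered when, at every comparison
    where its realized truth profile is not 'E', it is called DE with the
    truth letter.  ``direction_errors`` counts detections of planted
    transcripts at affected positions whose letter contradicts the truth.
    """
    effects = default_planted_effects(n_planted, log2fc)
    recovered_per_seed = []
    direction_errors = 0
    n_detections = 0
    for seed in seeds:
        config = SimConfig(
            n_transcripts=n_transcripts,
            noise_sd=noise_sd,
            planted_effects=effects,
            seed=seed,
        )
        bundle, result = _run(config)
        calls = {
            (pos, letter): {c.transcript for c in call_de(result.records, alpha, pos, letter)}
            for pos in range(1, len(bundle.plan) + 1)
            for letter in "HL"
        }
        recovered = 0
        for tx, prof in bundle.truth.true_profile.items():
            ok = True
            for pos, letter in enumerate(prof, start=1):
                if letter == "E":
                    continue
                hit = tx in calls[(pos, letter)]
                wrong = tx in calls[(pos, "L" if letter == "H" else "H")]
                if hit:
                    n_detections += 1
                if wrong:
                    direction_errors += 1
                ok = ok and hit and not wrong
            recovered += ok
        recovered_per_seed.append(recovered)
    return RecoveryExperimentResult(
        recovered_per_seed, n_planted, direction_errors, n_detections
    )
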