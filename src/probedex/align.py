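"""Ungapped exact-match alignment of 25-nt probes to a transcriptome.

A probe is considered to target a transcript when the reverse complement of
the probe shares a contiguous exact match of at least ``min_match``
nucleotides (default 22) with the transcript plus strand — equivalently,
when the probe matches the transcript minus strand.  Probes with no hit
anywhere are discarded before any statistics are computed; the retained
count ``T`` and the per-transcript probe tallies ``X^T`` drive the
hypergeometric attribution downstream.

The implementation seeds with a ``min_match``-mer hash of the transcriptome
and extends each seed to its maximal exact window; every qualifying match
window of length >= min_match contains such a seed, so the scan is exhaustive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InputError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = re.compile(r"^[ACGT]+$")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_seq(rec_id: str, seq: str, what: str) -> None:
    if not _VALID.match(seq):
        bad = next(ch for ch in seq if ch not in "ACGT")
        raise InputError(f"{what} {rec_id!r} contains non-ACGT character {bad!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """One maximal ungapped match of a probe on a transcript plus strand.

    Coordinates are 1-based inclusive.  Exactly one hit is reported per
    (probe, transcript) pair: the longest match, leftmost on ties.
    """

    probe_id: str
    transcript_id: str
    t_start: int
    t_end: int
    match_len: int


@dataclass
class ProbeIndex:
    """Probe -> transcript membership after discarding unaligned probes."""

    hits: dict[str, frozenset[str]]      # retained probe -> transcripts hit
    targets: dict[str, int]              # transcript -> X^T (probes hitting it)
    n_input_probes: int

    @property
    def T(self) -> int:
        return len(self.hits)

    @property
    def n_discarded(self) -> int:
        return self.n_input_probes - self.T

    @property
    def retained_probe_ids(self) -> set[str]:
        return set(self.hits)


def _kmer_index(
    transcripts: Sequence[tuple[str, str]], k: int
) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ti, (_, seq) in enumerate(transcripts):
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((ti, pos))
    return index


def align_probes(
    probes: Sequence[tuple[str, str]],
    transcripts: Sequence[tuple[str, str]],
    min_match: int = 22,
) -> list[AlignmentHit]:
    """Align probes to transcripts; see module docstring for the match rule.

    Parameters
    ----------
    probes, transcripts
        Sequences of ``(id, ACGT-sequence)`` records.
    min_match
        Minimum contiguous exact match length, in nucleotides.

    Returns
    -------
    Hits in (probe, transcript) input order, one per pair.
    """
    for pid, seq in probes:
        _check_seq(pid, seq, "probe")
        if min_match > len(seq):
            raise InputError(f"min_match={min_match} exceeds probe {pid!r} length {len(seq)}")
    for tid, seq in transcripts:
        _check_seq(tid, seq, "transcript")

    index = _kmer_index(transcripts, min_match)
    hits: list[AlignmentHit] = []
    for pid, pseq in probes:
        rc = revcomp(pseq)
        # best per transcript: (-match_len, t_start) minimised
        best: dict[int, tuple[int, int]] = {}
        seen: dict[int, set[tuple[int, int]]] = {}
        for off in range(len(rc) - min_match + 1):
            for ti, pos in index.get(rc[off : off + min_match], ()):
                tseq = transcripts[ti][1]
                # extend the seed to its maximal exact window
                left = 0
                while off - left - 1 >= 0 and pos - left - 1 >= 0 and rc[off - left - 1] == tseq[pos - left - 1]:
                    left += 1
                right = min_match
                while off + right < len(rc) and pos + right < len(tseq) and rc[off + right] == tseq[pos + right]:
                    right += 1
                start = pos - left
                length = left + right
                window = (start, length)
                if window in seen.setdefault(ti, set()):
                    continue
                seen[ti].add(window)
                key = (-length, start)
                if ti not in best or key < best[ti]:
                    best[ti] = key
        for ti in sorted(best):
            neg_len, start = best[ti]
            length = -neg_len
            hits.append(
                AlignmentHit(
                    probe_id=pid,
                    transcript_id=transcripts[ti][0],
                    t_start=start + 1,
                    t_end=start + length,
                    match_len=length,
                )
            )
    return hits


def build_probe_index(
    hits: Iterable[AlignmentHit], all_probe_ids: Sequence[str]
) -> ProbeIndex:
    """Discard unaligned probes and tally per-transcript probe counts.

    A multi-mapping probe counts once per transcript it hits but only once
    in the retained total ``T``.
    """
    by_probe: dict[str, set[str]] = {}
    for h in hits:
        by_probe.setdefault(h.probe_id, set()).add(h.transcript_id)
    targets: dict[str, int] = {}
    for txs in by_probe.values():
        for tx in txs:
            targets[tx] = targets.get(tx, 0) + 1
    return ProbeIndex(
        hits={p: frozenset(t) for p, t in by_probe.items()},
        targets=targets,
        n_input_probes=len(all_probe_ids),
    )
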