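"""File formats: FASTA, intensity/design TSVs, gene lists, result tables.

TSV with a fixed header row is the interchange format throughout; floats
are printed with 6 significant digits so repeated runs are byte-stable.
Binary vendor formats (CEL files) are out of scope — users convert to a
probe x array TSV upstream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .design import ArrayRecord, ExperimentDesign
from .errors import InputError, ParseError
from .simulate import GroundTruth
from .stats import IntensityMatrix

FLOAT_FMT = "%.6g"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, upper-cased sequence) records; duplicate IDs rejected.

    Malformed headers and empty sequences raise :class:`ParseError` with
    the offending line number.
    """
    path = Path(path)
    # light pre-scan for the error contract (line numbers, empty records)
    header_line: dict[str, int] = {}
    last_header: str | None = None
    last_line = 0
    has_seq = False
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if last_header is not None and not has_seq:
                    raise ParseError(f"{path}:{last_line}: record {last_header!r} has an empty sequence")
                rid = line[1:].split()[0] if len(line) > 1 else ""
                if not rid:
                    raise ParseError(f"{path}:{ln}: malformed FASTA header {line!r}")
                if rid in header_line:
                    raise ParseError(
                        f"{path}:{ln}: duplicate record ID {rid!r} "
                        f"(first seen at line {header_line[rid]})"
                    )
                header_line[rid] = ln
                last_header, last_line, has_seq = rid, ln, False
            else:
                if last_header is None:
                    raise ParseError(f"{path}:{ln}: sequence data before any FASTA header")
                has_seq = True
    if last_header is not None and not has_seq:
        raise ParseError(f"{path}:{last_line}: record {last_header!r} has an empty sequence")

    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq.upper()}\n")


def read_design_tsv(path: str | Path) -> ExperimentDesign:
    """Design table with columns ``array_id  genotype  timepoint``."""
    # keep_default_na: the knockout genotype label "null" is data, not NaN
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["array_id", "genotype", "timepoint"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return ExperimentDesign(
        tuple(ArrayRecord(r.array_id, r.genotype, r.timepoint) for r in df.itertuples())
    )


def write_design_tsv(path: str | Path, design: ExperimentDesign) -> None:
    pd.DataFrame(
        {
            "array_id": [a.array_id for a in design.arrays],
            "genotype": [a.genotype for a in design.arrays],
            "timepoint": [a.timepoint for a in design.arrays],
        }
    ).to_csv(path, sep="\t", index=False)


def read_intensity_tsv(path: str | Path, design: ExperimentDesign) -> IntensityMatrix:
    """Probe x array matrix; first column ``probe_id``, one column per array.

    Array membership is cross-checked against the design; non-numeric or
    non-positive cells raise with their coordinates.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if df.columns[0] != "probe_id":
        raise ParseError(f"{path}: first column must be 'probe_id', got {df.columns[0]!r}")
    df = df.set_index("probe_id")
    missing = set(design.array_ids) - set(df.columns)
    if missing:
        raise InputError(f"{path}: design arrays missing from header: {sorted(missing)}")
    df = df[design.array_ids]
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric <= 0)
        if bad.any():
            probe = df.index[bad.argmax()]
            raise InputError(
                f"{path}: non-positive or non-numeric intensity at probe "
                f"{probe!r}, array {col!r}: {df.loc[probe, col]!r}"
            )
        df[col] = numeric.astype(float)
    return IntensityMatrix(df, design)


def write_intensity_tsv(path: str | Path, matrix: IntensityMatrix) -> None:
    matrix.values.rename_axis("probe_id").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; '#' starts a comment; order preserved."""
    out: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def write_table(path: str | Path, table: pd.DataFrame, index: bool = False) -> None:
    """Byte-stable TSV output: 6-significant-digit floats, plain ints."""
    table.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_ground_truth(out_dir: str | Path, truth: GroundTruth, labels: Sequence[str]) -> None:
    """GroundTruth as two TSVs: probe origins and per-transcript truth."""
    out_dir = Path(out_dir)
    write_table(
        out_dir / "truth_probe_origin.tsv",
        pd.DataFrame(
            {"probe_id": list(truth.probe_origin), "origin": list(truth.probe_origin.values())}
        ),
    )
    rows = []
    for tx, prof in sorted(truth.true_profile.items()):
        row: dict[str, object] = {"transcript": tx, "true_profile": prof}
        for lab, fc in zip(labels, truth.true_fold[tx]):
            row[f"log2fc:{lab}"] = fc
        rows.append(row)
    write_table(out_dir / "truth_profiles.tsv", pd.DataFrame(rows))


def hits_to_frame(hits) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [h.probe_id for h in hits],
            "transcript_id": [h.transcript_id for h in hits],
            "t_start": [h.t_start for h in hits],
            "t_end": [h.t_end for h in hits],
            "match_len": [h.match_len for h in hits],
        }
    )
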