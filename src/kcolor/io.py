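"""File formats: FASTA references, csfasta-style encoded reads, score
configuration, and TSV reports."""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aligner import Alignment
from .encoding import EncodedRead, EncodingError
from .scoring import ScoringScheme
from .simulate import SimulationMetrics

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_encoded_reads",
    "write_encoded_reads",
    "read_scores_config",
    "write_scores_config",
    "write_alignment_report",
    "write_metrics_report",
]

ALIGNMENT_COLUMNS = (
    "read",
    "score",
    "ref_start",
    "ref_end",
    "cigar",
    "decoded",
    "color_error_positions",
    "snp_positions",
)

_SCORE_KEYS = {
    "color_match": "color_match",
    "color_mismatch": "color_mismatch",
    "base_match": "base_match",
    "base_mismatch": "base_mismatch",
    "gap_open": "gap_open",
    "gap_extend": "gap_extend",
}


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_fasta(path: str | Path | TextIO) -> dict[str, str]:
    """Parse FASTA into {name: uppercase sequence}; multi-record supported."""
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    out: dict[str, str] = {}
    for rec in records:
        if not len(rec.seq):
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path: str | Path | TextIO) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta-2line")
    else:
        SeqIO.write(records, path, "fasta-2line")


def _iter_lines(path: str | Path | TextIO):
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            yield from enumerate(fh, start=1)
    else:
        yield from enumerate(path, start=1)


def read_encoded_reads(path: str | Path | TextIO, k: int) -> list[EncodedRead]:
    """Parse generalized csfasta: '>' header lines, then adaptor + color digits."""
    reads: list[EncodedRead] = []
    name: str | None = None
    for lineno, raw in _iter_lines(path):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if name is not None:
                raise FormatError(f"line {lineno}: header {name!r} has no read line")
            name = line[1:].split()[0] if len(line) > 1 else ""
            continue
        if name is None:
            raise FormatError(f"line {lineno}: read line before any '>' header")
        try:
            reads.append(EncodedRead.from_line(line, k=k, name=name))
        except EncodingError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        name = None
    if name is not None:
        raise FormatError(f"header {name!r} at end of file has no read line")
    if not reads:
        raise FormatError(f"no encoded reads found in {path}")
    return reads


def write_encoded_reads(reads: Iterable[EncodedRead], path: str | Path | TextIO) -> None:
    buf = _io.StringIO()
    for read in reads:
        buf.write(f">{read.name}\n{read.to_line()}\n")
    text = buf.getvalue()
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


def read_scores_config(path: str | Path | TextIO) -> ScoringScheme:
    """Flat key=value (or key<TAB>value) scoring configuration."""
    values: dict[str, int] = {}
    for lineno, raw in _iter_lines(path):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        else:
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, val = parts
        key = key.strip().lower()
        if key not in _SCORE_KEYS:
            raise FormatError(f"line {lineno}: unknown score key {key!r}")
        try:
            values[_SCORE_KEYS[key]] = int(val.strip())
        except ValueError as exc:
            raise FormatError(f"line {lineno}: score {key!r} must be an integer") from exc
    return ScoringScheme(**values)


def write_scores_config(scheme: ScoringScheme, path: str | Path | TextIO) -> None:
    text = "".join(
        f"{key} = {getattr(scheme, key)}\n" for key in _SCORE_KEYS
    )
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


def _fmt_positions(positions: Sequence[int]) -> str:
    return ",".join(str(p) for p in positions) if positions else "-"


def write_alignment_report(alignments: Iterable[Alignment], path: str | Path | TextIO) -> None:
    """TSV with one row per alignment, columns as in ALIGNMENT_COLUMNS."""
    buf = _io.StringIO()
    buf.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
    for al in alignments:
        buf.write(
            "\t".join(
                (
                    al.read_name or "-",
                    str(al.score),
                    str(al.ref_start),
                    str(al.ref_end),
                    al.cigar,
                    al.decoded_read,
                    _fmt_positions(al.color_error_positions),
                    _fmt_positions(al.snp_positions),
                )
            )
            + "\n"
        )
    text = buf.getvalue()
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


def write_metrics_report(
    rows: Sequence[tuple[dict, SimulationMetrics]], path: str | Path | TextIO
) -> None:
    """TSV of simulation metrics; each row pairs config fields with metrics."""
    keys = sorted({k for fields, _ in rows for k in fields})
    header = keys + [
        "power", "fp_snp_rate", "fn_snp_rate", "n_reads",
        "n_correct", "n_fp", "n_fn",
    ]
    buf = _io.StringIO()
    buf.write("\t".join(header) + "\n")
    for fields, m in rows:
        cells = [str(fields.get(k, "-")) for k in keys] + [
            f"{m.power:.6g}", f"{m.fp_snp_rate:.6g}", f"{m.fn_snp_rate:.6g}",
            str(m.n_reads), str(m.n_correct), str(m.n_fp), str(m.n_fn),
        ]
        buf.write("\t".join(cells) + "\n")
    text = buf.getvalue()
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)
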