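"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ are parsed strictly (uppercase A/C/G/T plus N on input;
anything else is a parse error with a line number) — the pipeline's own
files are simple enough that precise diagnostics beat leniency. The pileup
dialect is a four-count TSV (contig, 1-based position, reference base,
coverage, counts A/C/G/T) rather than samtools' base-string mpileup: the
statistics need only the counts, and the dialect round-trips losslessly.
TSV/JSON outputs carry '#' header lines with the tool version and the
seeds/config that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from ._seq import decode, encode
from .mapper import Pileup, Placement
from .readsim import ReadPair

__all__ = [
    "ParseError",
    "PairingError",
    "read_fasta",
    "write_fasta",
    "read_fastq_pair",
    "write_fastq_pair",
    "write_pileup_tsv",
    "read_pileup_tsv",
    "write_placements_tsv",
    "metadata_header",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None) -> None:
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


class PairingError(ValueError):
    pass


def metadata_header(**fields) -> list[str]:
    """'# key: value' header lines stamped into emitted TSV/JSON files."""
    from . import __version__

    lines = [f"# ervdiff-version: {__version__}"]
    lines += [f"# {key}: {value}" for key, value in fields.items()]
    return lines


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """(id, sequence) records in file order; bases are uppercased and must
    be A/C/G/T/N."""
    records: list[tuple[str, str]] = []
    name: Optional[str] = None
    chunks: list[str] = []
    name_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", ";")):
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError("empty FASTA header", lineno)
                chunks = []
                name_line = lineno
            else:
                if name is None:
                    raise ParseError("sequence before first '>' header", lineno)
                seq = line.upper()
                if any(b not in "ACGTN" for b in seq):
                    bad = next(b for b in seq if b not in "ACGTN")
                    raise ParseError(f"invalid base {bad!r}", lineno)
                chunks.append(seq)
    if name is not None:
        if not chunks:
            raise ParseError(f"record {name!r} has no sequence", name_line)
        records.append((name, "".join(chunks)))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: PathLike, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (two-file paired layout; flat quality, never consulted)


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def _read_fastq(path: PathLike) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(
            f"{path}: FASTQ record count not a multiple of 4", len(lines)
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ParseError("expected '@' header", i + 1)
        if not plus.startswith("+"):
            raise ParseError("expected '+' separator", i + 3)
        if len(seq) != len(qual):
            raise ParseError("sequence/quality length mismatch", i + 4)
        seq = seq.upper()
        if any(b not in "ACGTN" for b in seq):
            raise ParseError("invalid base in read", i + 2)
        records.append((head[1:].split()[0], seq))
    return records


def read_fastq_pair(
    path1: PathLike, path2: PathLike
) -> list[tuple[str, str, str]]:
    """(id, mate1, mate2) triples; ids must match after stripping /1 /2."""
    r1 = _read_fastq(path1)
    r2 = _read_fastq(path2)
    if len(r1) != len(r2):
        raise PairingError(
            f"mate files differ in record count ({len(r1)} vs {len(r2)})"
        )
    out = []
    for (n1, s1), (n2, s2) in zip(r1, r2):
        b1, b2 = _strip_mate_suffix(n1), _strip_mate_suffix(n2)
        if b1 != b2:
            raise PairingError(f"mate id mismatch: {n1!r} vs {n2!r}")
        out.append((b1, s1, s2))
    return out


def write_fastq_pair(
    pairs: Sequence[ReadPair],
    prefix: PathLike,
    quality_char: str = "I",
) -> tuple[Path, Path]:
    """Write mates to <prefix>_1.fastq / <prefix>_2.fastq; read names encode
    the template of origin and fragment start for truth tracking."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_1.fastq")
    p2 = prefix.with_name(prefix.name + "_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for i, pair in enumerate(pairs):
            name = f"pair{i:06d}:t{pair.template_index}:s{pair.fragment_start}"
            f1.write(f"@{name}/1\n{pair.mate1}\n+\n{quality_char * len(pair.mate1)}\n")
            f2.write(f"@{name}/2\n{pair.mate2}\n+\n{quality_char * len(pair.mate2)}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# pileup TSV


_PILEUP_COLUMNS = ("contig", "pos", "ref", "cov", "A", "C", "G", "T")


def write_pileup_tsv(
    pileup: Pileup, path: PathLike, metadata: Optional[dict] = None
) -> None:
    """Columns: contig, 1-based position, reference base, coverage and the
    four allele counts; coverage always equals A+C+G+T."""
    with open(path, "w") as fh:
        for line in metadata_header(**(metadata or {})):
            fh.write(line + "\n")
        fh.write("\t".join(_PILEUP_COLUMNS) + "\n")
        cov = pileup.coverage
        refs = decode(pileup.ref_codes)
        for j in range(pileup.n_positions):
            counts = pileup.counts[:, j]
            fh.write(
                f"{pileup.name}\t{j + 1}\t{refs[j]}\t{cov[j]}\t"
                f"{counts[0]}\t{counts[1]}\t{counts[2]}\t{counts[3]}\n"
            )


def read_pileup_tsv(path: PathLike) -> Pileup:
    rows: list[tuple[str, int, str, list[int]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "contig" and parts[1] == "pos":
                continue
            if len(parts) != len(_PILEUP_COLUMNS):
                raise ParseError(
                    f"expected {len(_PILEUP_COLUMNS)} columns, got {len(parts)}",
                    lineno,
                )
            try:
                pos = int(parts[1])
                counts = [int(x) for x in parts[4:8]]
                cov = int(parts[3])
            except ValueError as exc:
                raise ParseError(f"non-integer field: {exc}", lineno) from None
            if cov != sum(counts):
                raise ParseError("coverage does not equal allele sum", lineno)
            rows.append((parts[0], pos, parts[2], counts))
    if not rows:
        return Pileup(
            counts=np.zeros((4, 0), dtype=np.int32),
            ref_codes=np.zeros(0, dtype=np.uint8),
        )
    n = len(rows)
    counts = np.zeros((4, n), dtype=np.int32)
    ref = "".join(r[2] for r in rows)
    for j, (_, pos, _, cts) in enumerate(rows):
        if pos != j + 1:
            raise ParseError(f"positions not consecutive at {pos}")
        counts[:, j] = cts
    return Pileup(
        counts=counts, ref_codes=encode(ref, allow_n=True), name=rows[0][0]
    )


def write_placements_tsv(
    placements: Iterable[Optional[Placement]],
    path: PathLike,
    metadata: Optional[dict] = None,
) -> None:
    """SAM-like TSV of mapped reads: read id, 1-based position, strand and
    mismatch count (NM)."""
    with open(path, "w") as fh:
        for line in metadata_header(**(metadata or {})):
            fh.write(line + "\n")
        fh.write("read\tpos\tstrand\tnm\n")
        for pl in placements:
            if pl is None:
                continue
            fh.write(f"{pl.read_id}\t{pl.pos + 1}\t{pl.strand}\t{pl.n_mismatch}\n")


def write_json(obj: dict, path: PathLike, metadata: Optional[dict] = None) -> None:
    payload = dict(obj)
    if metadata:
        payload["_meta"] = {
            "ervdiff_version": __import__("ervdiff").__version__,
            **metadata,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
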