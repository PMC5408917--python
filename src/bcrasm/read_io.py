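"""Reading the cell's sequencing reads and basic sequence utilities.

Reads are treated as orientation-agnostic sequences: base qualities are
discarded and paired-end mates become two independent reads (the assembler
never uses pairing information). Reads in which more than 20% of bases are
N are dropped, since they can neither seed anchors nor support exact
overlaps.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

MAX_N_FRACTION = 0.20


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    id: str
    seq: str


@dataclass
class ReadSet:
    """All reads of one cell, plus simple summary statistics."""

    reads: list[Read]

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @property
    def length_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for r in self.reads:
            hist[len(r.seq)] = hist.get(len(r.seq), 0) + 1
        return hist


def _open_text(path: Path):
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path, "rt")


def _detect_format(path: Path) -> str:
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: neither FASTA nor FASTQ (first character {first!r})")


def _parse_records(path: Path) -> list[Read]:
    fmt = _detect_format(path)
    out: list[Read] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            out.append(Read(id=rec.id, seq=str(rec.seq).upper()))
    return out


def load_reads(paths: list[str | Path]) -> ReadSet:
    """Load one (single-end) or two (mate pair) FASTQ/FASTA files.

    Mates are interleaved into one flat list with ``/1`` / ``/2`` id
    suffixes. Unequal mate counts and an empty read set are hard errors.
    """
    if not 1 <= len(paths) <= 2:
        raise ValueError("load_reads expects one or two file paths")
    parsed = [_parse_records(Path(p)) for p in paths]
    if len(parsed) == 2:
        r1, r2 = parsed
        if len(r1) != len(r2):
            raise ValueError(
                f"mate files have unequal record counts ({len(r1)} vs {len(r2)})"
            )
        reads = []
        for a, b in zip(r1, r2):
            reads.append(Read(id=_mate_id(a.id, 1), seq=a.seq))
            reads.append(Read(id=_mate_id(b.id, 2), seq=b.seq))
    else:
        reads = parsed[0]

    kept: list[Read] = []
    dropped = 0
    for r in reads:
        if not r.seq:
            dropped += 1
            continue
        if r.seq.count("N") > MAX_N_FRACTION * len(r.seq):
            dropped += 1
            continue
        kept.append(r)
    if dropped:
        log.info("dropped %d reads (empty or >20%% N)", dropped)
    if not kept:
        raise ValueError("no reads after loading and filtering")
    return ReadSet(reads=kept)


def _mate_id(raw: str, mate: int) -> str:
    if raw.endswith(("/1", "/2")):
        raw = raw[:-2]
    return f"{raw}/{mate}"
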