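"""Germline reference sets and their k-mer indices.

The assembler anchors on four *components* of the immunoglobulin loci:
heavy-chain variable (IGHV) and constant (IGHC) genes, and the pooled
kappa/lambda light-chain variable (IGKLV) and constant (IGKLC) genes.
Pooling kappa and lambda means the cell's light-chain locus is decided by
whichever genes win the anchor competition, not by a prior locus choice.

J segments (and the heavy-chain D segments used only by the simulator) are
optional extra components: they are never indexed for anchoring, but the
annotator and the simulator consume them.

Coordinates everywhere in this package are 0-based, half-open.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
_GAP_CHARS = frozenset(".-")
_IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVU")


class Component(str, Enum):
    """The germline components a sequence can belong to."""

    IGHV = "IGHV"
    IGHC = "IGHC"
    IGKLV = "IGKLV"
    IGKLC = "IGKLC"
    J_HEAVY = "J_HEAVY"
    J_LIGHT = "J_LIGHT"
    D_HEAVY = "D_HEAVY"


#: The four components that seed assembly anchors.
ASSEMBLY_COMPONENTS = (
    Component.IGHV,
    Component.IGHC,
    Component.IGKLV,
    Component.IGKLC,
)


@dataclass(frozen=True)
class GermlineSequence:
    """One germline gene segment: a named, component-tagged DNA string."""

    name: str
    component: Component
    seq: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class KmerIndex:
    """Exact k-mer index over one component's germline sequences.

    ``postings`` maps each length-k substring (k-mers containing N are not
    indexed) to the list of ``(sequence name, 0-based offset)`` positions at
    which it occurs.
    """

    k: int
    postings: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


def _clean_sequence(raw: str, name: str) -> str:
    """Uppercase, strip alignment gaps, and map IUPAC ambiguity codes to N.

    Characters outside the DNA alphabet, gaps and IUPAC codes are a hard
    error: they indicate the file is not a nucleotide FASTA.
    """
    seq = raw.upper()
    if _GAP_CHARS.intersection(seq):
        log.warning("germline %s: stripping alignment gap characters", name)
        seq = "".join(c for c in seq if c not in _GAP_CHARS)
    bad = set(seq) - DNA_ALPHABET
    ambiguous = bad & _IUPAC_AMBIGUOUS
    if ambiguous:
        log.warning(
            "germline %s: replacing IUPAC ambiguity codes %s with N",
            name,
            "".join(sorted(ambiguous)),
        )
        seq = "".join("N" if c in _IUPAC_AMBIGUOUS else c for c in seq)
        bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"germline {name!r}: invalid characters {sorted(bad)} in sequence"
        )
    return seq


def load_germline_fasta(
    path: str | Path,
    component: Component,
    min_length: int = 0,
) -> list[GermlineSequence]:
    """Load one component's germline set from a (optionally gzipped) FASTA.

    Records shorter than ``min_length`` are dropped with a warning (the
    caller typically passes the k-mer size for indexed components).
    Duplicate record names and empty files are hard errors.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[GermlineSequence] = []
    seen: set[str] = set()
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            name = rec.id
            if name in seen:
                raise ValueError(
                    f"duplicate name {name!r} in {component.value} file {path}"
                )
            seen.add(name)
            seq = _clean_sequence(str(rec.seq), name)
            if len(seq) < min_length:
                log.warning(
                    "germline %s (%d bp) shorter than %d bp; dropped",
                    name,
                    len(seq),
                    min_length,
                )
                continue
            records.append(GermlineSequence(name=name, component=component, seq=seq))
    if not seen:
        raise ValueError(f"no records in germline FASTA {path}")
    return records


def build_component_index(seqs: list[GermlineSequence], k: int) -> KmerIndex:
    """Index every length-k substring (N-free) of every sequence.

    Sequences shorter than k are skipped with a warning; if *every* sequence
    is shorter than k, indexing is impossible and that is an error.
    """
    if k < 8:
        raise ValueError(f"k-mer size {k} too small (minimum 8)")
    usable = [s for s in seqs if len(s.seq) >= k]
    for s in seqs:
        if len(s.seq) < k:
            log.warning("germline %s shorter than k=%d; not indexed", s.name, k)
    if seqs and not usable:
        raise ValueError(f"k={k} is larger than every sequence in the set")
    postings: dict[str, list[tuple[str, int]]] = {}
    for s in usable:
        seq = s.seq
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if "N" in kmer:
                continue
            postings.setdefault(kmer, []).append((s.name, off))
    return KmerIndex(k=k, postings=postings)


@dataclass
class GermlineDB:
    """All loaded germline components plus k-mer indices for the four
    assembly components."""

    components: dict[Component, list[GermlineSequence]]
    indices: dict[Component, KmerIndex]
    k: int

    @classmethod
    def from_fasta(cls, paths: dict[Component, str | Path], k: int = 16) -> "GermlineDB":
        """Load a database from one FASTA per component and index the
        assembly components."""
        components: dict[Component, list[GermlineSequence]] = {}
        for comp, path in paths.items():
            min_len = k if comp in ASSEMBLY_COMPONENTS else 0
            components[comp] = load_germline_fasta(path, comp, min_length=min_len)
        return cls.from_sequences(components, k=k)

    @classmethod
    def from_sequences(
        cls, components: dict[Component, list[GermlineSequence]], k: int = 16
    ) -> "GermlineDB":
        indices = {
            comp: build_component_index(seqs, k)
            for comp, seqs in components.items()
            if comp in ASSEMBLY_COMPONENTS and seqs
        }
        return cls(components=components, indices=indices, k=k)

    def validate_for_assembly(self) -> None:
        """The four anchor components must each be non-empty."""
        missing = [
            c.value
            for c in ASSEMBLY_COMPONENTS
            if not self.components.get(c)
        ]
        if missing:
            raise ValueError(
                f"assembly requires non-empty germline components: missing {missing}"
            )

    def sequences(self, component: Component) -> list[GermlineSequence]:
        return self.components.get(component, [])

    def has(self, component: Component) -> bool:
        return bool(self.components.get(component))
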