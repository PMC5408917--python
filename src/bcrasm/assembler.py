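"""Stage 2: greedy anchor extension through exact suffix-prefix read overlaps.

Two reads overlap when the prefix of one equals the suffix of the other,
in either orientation. Each anchor is extended one read at a time in the
3' direction, then in the 5' direction, stopping when no read overlaps the
contig end, when the best overlapping read was already incorporated in this
pass (a repeat), or when the contig exceeds a maximum length.

Per chain, if the variable-anchored and constant-anchored extensions agree
(one contains the other, or they share an exact suffix-prefix overlap of at
least m), a single merged sequence is reported; otherwise the two contigs
are reported separately.

Candidate choice per extension step (deterministic): the read with the
longest exact overlap wins; ties go to the shortest appended suffix, then
the lexicographically smallest oriented read sequence, then read id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .anchor_finder import FORWARD, REVCOMP, Anchor
from .germline_db import Component, GermlineDB
from .params import PipelineParams
from .read_io import ReadSet, reverse_complement

log = logging.getLogger(__name__)

MIN_OVERLAP = 10  # overlaps shorter than this are rejected as unreliable

NO_OVERLAP = "no_overlap"
REPEAT = "repeat"
MAX_LENGTH = "max_length"

HEAVY = "heavy"
LIGHT = "light"

MERGED = "merged"
SPLIT = "split"
PARTIAL = "partial"
ABSENT = "absent"


@dataclass
class OverlapIndex:
    """m-prefix lookup over reads in both orientations.

    Each read of length >= m contributes its forward m-prefix and its
    reverse-complement m-prefix; ``max_read_length`` bounds the overlap
    lengths worth probing during extension.
    """

    m: int
    prefix_map: dict[str, list[tuple[str, str]]]
    reads: dict[str, str]
    max_read_length: int


@dataclass(frozen=True)
class ExtensionStep:
    read_id: str
    orientation: str  # relative to the contig's forward strand
    overlap: int
    direction: str  # "3p" or "5p"


@dataclass
class Contig:
    seq: str
    anchor: Anchor
    steps: list[ExtensionStep] = field(default_factory=list)
    stop_3prime: str = NO_OVERLAP
    stop_5prime: str = NO_OVERLAP


@dataclass
class ChainAssembly:
    chain: str  # heavy | light
    status: str  # merged | split | partial | absent
    merged_seq: str | None = None
    variable_contig: Contig | None = None
    constant_contig: Contig | None = None

    def sequences(self) -> dict[str, str]:
        """Reported sequences keyed by role, per the single-vs-two-contig rule."""
        if self.status == MERGED:
            return {MERGED: self.merged_seq}
        out = {}
        if self.variable_contig is not None:
            out["variable"] = self.variable_contig.seq
        if self.constant_contig is not None:
            out["constant"] = self.constant_contig.seq
        return out


def build_overlap_index(reads: ReadSet, m: int) -> OverlapIndex:
    """Index every read's forward and reverse-complement m-prefix.

    Reads shorter than m cannot overlap by m bases and are skipped.
    """
    if m < MIN_OVERLAP:
        raise ValueError(f"minimum overlap m={m} is below {MIN_OVERLAP} bp")
    prefix_map: dict[str, list[tuple[str, str]]] = {}
    seqs: dict[str, str] = {}
    max_len = 0
    for read in reads:
        if len(read.seq) < m:
            continue
        seqs[read.id] = read.seq
        max_len = max(max_len, len(read.seq))
        prefix_map.setdefault(read.seq[:m], []).append((read.id, FORWARD))
        rc = reverse_complement(read.seq)
        prefix_map.setdefault(rc[:m], []).append((read.id, REVCOMP))
    return OverlapIndex(m=m, prefix_map=prefix_map, reads=seqs, max_read_length=max_len)


def _oriented(index: OverlapIndex, read_id: str, orientation: str) -> str:
    seq = index.reads[read_id]
    return seq if orientation == FORWARD else reverse_complement(seq)


def _mismatches_capped(a: str, b: str, cap: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > cap:
                break
    return mm


def _best_3prime_candidate(
    seq: str, index: OverlapIndex, overlap_mismatches: int
) -> tuple[str, str, int, str] | None:
    """Find the best read overlapping the contig's 3' end.

    Probes overlap lengths from the longest possible down to m: an overlap
    of length L places a read's m-prefix at contig position len(seq)-L, so
    that m-mer is looked up in the prefix map and surviving candidates are
    verified over the full overlap. Each read keeps its maximal valid
    overlap. Returns (read_id, orientation, overlap, oriented_seq) or None.
    """
    m = index.m
    best_key = None
    best = None
    seen: set[tuple[str, str]] = set()
    top = min(len(seq), index.max_read_length)
    for L in range(top, m - 1, -1):
        j = len(seq) - L
        hits = index.prefix_map.get(seq[j : j + m])
        if not hits:
            continue
        tail = seq[j:]
        for read_id, orientation in hits:
            if (read_id, orientation) in seen:
                continue
            r = _oriented(index, read_id, orientation)
            if len(r) <= L:
                continue  # contained read: nothing to append
            if overlap_mismatches == 0:
                if not r.startswith(tail):
                    continue
            else:
                if _mismatches_capped(r[m:L], tail[m:], overlap_mismatches) > overlap_mismatches:
                    continue
            seen.add((read_id, orientation))
            key = (-L, len(r) - L, r, read_id)
            if best_key is None or key < best_key:
                best_key = key
                best = (read_id, orientation, L, r)
    return best


def extend_3prime(
    seed: str,
    index: OverlapIndex,
    used: set[str],
    max_len: int,
    overlap_mismatches: int = 0,
    _direction: str = "3p",
) -> tuple[str, list[ExtensionStep], str]:
    """Greedily extend ``seed`` rightward one read at a time.

    Stops with reason ``no_overlap`` (no read overlaps the 3' end by >= m),
    ``repeat`` (the best candidate was already incorporated in this pass),
    or ``max_length``. Incorporated read ids are added to ``used``.
    """
    if len(seed) < index.m:
        raise ValueError("seed shorter than the minimum overlap m")
    seq = seed
    steps: list[ExtensionStep] = []
    while True:
        if len(seq) > max_len:
            return seq, steps, MAX_LENGTH
        cand = _best_3prime_candidate(seq, index, overlap_mismatches)
        if cand is None:
            return seq, steps, NO_OVERLAP
        read_id, orientation, overlap, r = cand
        if read_id in used:
            return seq, steps, REPEAT
        used.add(read_id)
        seq = seq + r[overlap:]
        steps.append(
            ExtensionStep(
                read_id=read_id,
                orientation=orientation,
                overlap=overlap,
                direction=_direction,
            )
        )


def extend_5prime(
    seed: str,
    index: OverlapIndex,
    used: set[str],
    max_len: int,
    overlap_mismatches: int = 0,
) -> tuple[str, list[ExtensionStep], str]:
    """Mirror of extend_3prime: extend leftward.

    Implemented by extending the reverse complement rightward and
    re-complementing; recorded step orientations are flipped back to the
    contig's forward frame.
    """
    rc_seq, steps, reason = extend_3prime(
        reverse_complement(seed), index, used, max_len, overlap_mismatches,
        _direction="5p",
    )
    flipped = [
        ExtensionStep(
            read_id=s.read_id,
            orientation=REVCOMP if s.orientation == FORWARD else FORWARD,
            overlap=s.overlap,
            direction="5p",
        )
        for s in steps
    ]
    return reverse_complement(rc_seq), flipped, reason


def replay_steps(anchor_seq: str, steps: list[ExtensionStep], index: OverlapIndex) -> str:
    """Rebuild a contig from its anchor window and recorded steps.

    3' steps append the read's suffix beyond the overlap; 5' steps prepend
    its prefix before the overlap. Used to assert step validity.
    """
    seq = anchor_seq
    for s in steps:
        r = _oriented(index, s.read_id, s.orientation)
        if s.direction == "3p":
            seq = seq + r[s.overlap :]
        else:
            seq = r[: len(r) - s.overlap] + seq
    return seq


def extend_anchor(anchor: Anchor, index: OverlapIndex, params: PipelineParams) -> Contig:
    """Extend one anchor 3' then 5' with a fresh ``used`` set."""
    used: set[str] = set()
    seq, steps3, stop3 = extend_3prime(
        anchor.seq, index, used, params.max_contig_length, params.overlap_mismatches
    )
    seq, steps5, stop5 = extend_5prime(
        seq, index, used, params.max_contig_length, params.overlap_mismatches
    )
    return Contig(
        seq=seq,
        anchor=anchor,
        steps=steps3 + steps5,
        stop_3prime=stop3,
        stop_5prime=stop5,
    )


def _suffix_prefix_overlap(a: str, b: str, m: int) -> int:
    """Longest L >= m with a's suffix equal to b's prefix, else 0."""
    for L in range(min(len(a), len(b)), m - 1, -1):
        if a[-L:] == b[:L]:
            return L
    return 0


def assemble_chain(
    anchor_v: Anchor | None,
    anchor_c: Anchor | None,
    index: OverlapIndex,
    params: PipelineParams,
    chain: str,
) -> ChainAssembly:
    """Extend the variable and constant anchors of one chain and merge.

    The two anchors extend independently (each with its own ``used`` set,
    since the reporting rule implies two potentially complete sequences).
    Merging: containment, or an exact suffix-prefix overlap of >= m bases
    between the variable-anchored and constant-anchored extensions.
    """
    contig_v = extend_anchor(anchor_v, index, params) if anchor_v else None
    contig_c = extend_anchor(anchor_c, index, params) if anchor_c else None

    if contig_v is None and contig_c is None:
        return ChainAssembly(chain=chain, status=ABSENT)
    if contig_v is None or contig_c is None:
        return ChainAssembly(
            chain=chain,
            status=PARTIAL,
            variable_contig=contig_v,
            constant_contig=contig_c,
        )

    v, c = contig_v.seq, contig_c.seq
    merged: str | None = None
    if v in c:
        merged = c
    elif c in v:
        merged = v
    else:
        ov = _suffix_prefix_overlap(v, c, params.m)
        if ov:
            merged = v + c[ov:]
        else:
            ov = _suffix_prefix_overlap(c, v, params.m)
            if ov:
                merged = c + v[ov:]
    if merged is not None:
        return ChainAssembly(
            chain=chain,
            status=MERGED,
            merged_seq=merged,
            variable_contig=contig_v,
            constant_contig=contig_c,
        )
    return ChainAssembly(
        chain=chain,
        status=SPLIT,
        variable_contig=contig_v,
        constant_contig=contig_c,
    )


def assemble_cell(
    reads: ReadSet, db: GermlineDB, params: PipelineParams | None = None
) -> tuple[ChainAssembly, ChainAssembly]:
    """Full per-cell assembly: anchors, overlap index, both chains.

    The heavy and light chains are computed independently; the result is
    identical regardless of execution order, and assembly is entirely
    deterministic.
    """
    from .anchor_finder import find_anchors  # local to avoid cycle at import

    params = params or PipelineParams()
    anchors = find_anchors(reads, db, params)
    index = build_overlap_index(reads, params.m)
    heavy = assemble_chain(
        anchors[Component.IGHV], anchors[Component.IGHC], index, params, HEAVY
    )
    light = assemble_chain(
        anchors[Component.IGKLV], anchors[Component.IGKLC], index, params, LIGHT
    )
    return heavy, light
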