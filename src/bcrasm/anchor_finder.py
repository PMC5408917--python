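"""Stage 1: map reads to each germline component and pick anchor windows.

Reads are placed on germline sequences by exact k-mer seeding followed by
Hamming verification (substitutions only) in both orientations. For each
of the four assembly components, the anchor is the fixed-length germline
window overlapped by the most read placements; it seeds Stage 2.

Placements may overhang germline ends (variable genes are the 5' end of a
truncated transcript in the worst case): verification covers only the
intersecting span and requires at least k overlapping bases, and the
stored offset may therefore be negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .germline_db import (
    ASSEMBLY_COMPONENTS,
    Component,
    GermlineDB,
    GermlineSequence,
    KmerIndex,
)
from .params import PipelineParams
from .read_io import ReadSet, reverse_complement

log = logging.getLogger(__name__)

FORWARD = "forward"
REVCOMP = "revcomp"


class NoImmunoglobulinSignal(RuntimeError):
    """Raised when no component yields an anchor: the cell's reads carry no
    detectable immunoglobulin transcript."""


@dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    component: Component
    germline_name: str
    offset: int  # 0-based germline position of the read's first base; may be <0
    orientation: str
    mismatches: int
    read_length: int


@dataclass(frozen=True)
class Anchor:
    component: Component
    germline_name: str
    start: int
    seq: str  # germline substring at [start, start + w)
    support: int


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def map_reads_to_component(
    reads: ReadSet,
    index: KmerIndex,
    germlines: list[GermlineSequence],
    max_mismatches: int,
) -> list[ReadPlacement]:
    """Seed-and-verify placement of every read on one component.

    Every k-mer of the read (in each orientation) votes for a
    (germline, diagonal) candidate; each candidate is verified by Hamming
    comparison over the read/germline intersection, which must be at least
    k bases. Per (germline, orientation) only the best diagonal (fewest
    mismatches, then leftmost) is kept; a read may still place on several
    germlines.
    """
    k = index.k
    postings = index.postings
    by_name = {g.name: g.seq for g in germlines}
    component = germlines[0].component if germlines else None
    placements: list[ReadPlacement] = []

    for read in reads:
        for orientation in (FORWARD, REVCOMP):
            s = read.seq if orientation == FORWARD else reverse_complement(read.seq)
            if len(s) < k:
                continue
            candidates: set[tuple[str, int]] = set()
            for i in range(len(s) - k + 1):
                hits = postings.get(s[i : i + k])
                if hits:
                    for name, off in hits:
                        candidates.add((name, off - i))
            best: dict[str, tuple[int, int]] = {}  # germline -> (mismatches, diag)
            for name, diag in candidates:
                g = by_name[name]
                gs = max(0, diag)
                ge = min(len(g), diag + len(s))
                if ge - gs < k:
                    continue
                mm = _hamming(g[gs:ge], s[gs - diag : ge - diag])
                if mm > max_mismatches:
                    continue
                prev = best.get(name)
                if prev is None or (mm, diag) < prev:
                    best[name] = (mm, diag)
            for name, (mm, diag) in sorted(best.items()):
                placements.append(
                    ReadPlacement(
                        read_id=read.id,
                        component=component,
                        germline_name=name,
                        offset=diag,
                        orientation=orientation,
                        mismatches=mm,
                        read_length=len(s),
                    )
                )
    return placements


def select_anchor_window(
    placements: list[ReadPlacement],
    germlines: list[GermlineSequence],
    w: int,
    min_anchor_support: int = 1,
) -> Anchor | None:
    """Pick the length-w germline window overlapped by the most placements.

    A placement supports a window if its aligned span (clipped to the
    germline) intersects the window by >= 1 bp. Ties go to the smallest
    germline name, then the smallest window start, for determinism.
    Returns None when the best support is below ``min_anchor_support``.
    """
    by_name: dict[str, list[ReadPlacement]] = {}
    for p in placements:
        by_name.setdefault(p.germline_name, []).append(p)

    best: tuple[int, str, int] | None = None  # (-support, name, start)
    for g in sorted(germlines, key=lambda g: g.name):
        glen = len(g.seq)
        if glen < w:
            continue
        plist = by_name.get(g.name)
        if not plist:
            continue
        n_windows = glen - w + 1
        delta = np.zeros(n_windows + 1, dtype=np.int64)
        for p in plist:
            s = max(0, p.offset)
            e = min(glen, p.offset + p.read_length)
            if e <= s:
                continue
            lo = max(0, s - w + 1)
            hi = min(n_windows - 1, e - 1)
            if lo <= hi:
                delta[lo] += 1
                delta[hi + 1] -= 1
        support = np.cumsum(delta[:-1])
        start = int(np.argmax(support))
        count = int(support[start])
        if count <= 0:
            continue
        key = (-count, g.name, start)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    count, name, start = -best[0], best[1], best[2]
    if count < min_anchor_support:
        return None
    gseq = next(g.seq for g in germlines if g.name == name)
    component = germlines[0].component
    return Anchor(
        component=component,
        germline_name=name,
        start=start,
        seq=gseq[start : start + w],
        support=count,
    )


def find_anchors(
    reads: ReadSet, db: GermlineDB, params: PipelineParams
) -> dict[Component, Anchor | None]:
    """Run map + select for each of the four assembly components.

    Raises NoImmunoglobulinSignal if no component yields an anchor.
    """
    db.validate_for_assembly()
    anchors: dict[Component, Anchor | None] = {}
    for comp in ASSEMBLY_COMPONENTS:
        germlines = db.sequences(comp)
        placements = map_reads_to_component(
            reads, db.indices[comp], germlines, params.max_mismatches
        )
        anchor = select_anchor_window(
            placements, germlines, params.w, params.min_anchor_support
        )
        anchors[comp] = anchor
        if anchor is None:
            log.info("component %s: no anchor", comp.value)
        else:
            log.info(
                "component %s: anchor %s:%d support=%d",
                comp.value,
                anchor.germline_name,
                anchor.start,
                anchor.support,
            )
    if all(a is None for a in anchors.values()):
        raise NoImmunoglobulinSignal("no immunoglobulin signal in reads")
    return anchors
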