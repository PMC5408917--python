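"""Best-hit gene calling on assembled contigs.

Each contig (or merged chain sequence) is locally aligned against the
candidate germline set for a segment kind (V, J, or C) and the best-scoring
gene is reported, with the alignment span on the contig and the percent
identity over that span. Scoring is fixed (match +1, mismatch -1, gap -2)
so calls are deterministic; ties break lexicographically by gene name.

Calls are gene-level by default (the "*NN" allele suffix is stripped); an
allele-level switch keeps it. D segments are not called: at this alignment
granularity they are too short for a reliable best hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from .assembler import ABSENT, HEAVY, MERGED, ChainAssembly
from .germline_db import Component, GermlineDB, GermlineSequence
from .params import PipelineParams

log = logging.getLogger(__name__)

SEGMENT_V = "V"
SEGMENT_J = "J"
SEGMENT_C = "C"


@dataclass(frozen=True)
class GeneCall:
    contig_id: str
    segment: str
    gene: str
    score: int  # number of matched bases in the best local alignment
    span: tuple[int, int]  # 0-based half-open interval on the contig
    identity: float  # matches / aligned columns over the span


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def gene_level(name: str) -> str:
    """Strip the IMGT-style allele suffix: IGHV1-2*02 -> IGHV1-2."""
    return name.split("*", 1)[0]


def call_segment(
    contig: str,
    candidates: list[GermlineSequence],
    kind: str,
    min_call_score: int = 30,
    allele_level: bool = False,
    contig_id: str = "contig",
) -> GeneCall | None:
    """Best-hit call of one segment kind on one contig, or None if no
    candidate aligns with score >= min_call_score."""
    if not candidates:
        raise ValueError("candidate germline set is empty")
    aligner = _aligner()
    best_name, best_score = None, None
    for cand in sorted(candidates, key=lambda c: c.name):
        score = aligner.score(contig, cand.seq)
        if best_score is None or score > best_score:
            best_name, best_score = cand.name, score
    if best_score is None or best_score < min_call_score:
        return None
    best = next(c for c in candidates if c.name == best_name)
    aln = aligner.align(contig, best.seq)[0]
    blocks_t, blocks_q = aln.aligned
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        columns += te - ts
        matches += sum(
            1 for x, y in zip(contig[ts:te], best.seq[qs:qe]) if x == y
        )
    span = (int(blocks_t[0][0]), int(blocks_t[-1][1]))
    name = best.name if allele_level else gene_level(best.name)
    return GeneCall(
        contig_id=contig_id,
        segment=kind,
        gene=name,
        score=matches,
        span=span,
        identity=matches / columns if columns else 0.0,
    )


def annotate_assembly(
    asm: ChainAssembly, db: GermlineDB, params: PipelineParams | None = None
) -> list[GeneCall]:
    """V, C (and J when a J set is loaded) calls for one chain assembly.

    Merged assemblies are annotated on the merged sequence; split/partial
    assemblies get the V (and J) call on the variable-anchored contig and
    the C call on the constant-anchored contig.
    """
    if asm.status == ABSENT:
        raise ValueError("cannot annotate an absent chain assembly")
    params = params or PipelineParams()
    if asm.chain == HEAVY:
        v_comp, c_comp, j_comp = Component.IGHV, Component.IGHC, Component.J_HEAVY
    else:
        v_comp, c_comp, j_comp = Component.IGKLV, Component.IGKLC, Component.J_LIGHT

    if asm.status == MERGED:
        targets = {
            SEGMENT_V: (asm.merged_seq, f"{asm.chain}_merged"),
            SEGMENT_J: (asm.merged_seq, f"{asm.chain}_merged"),
            SEGMENT_C: (asm.merged_seq, f"{asm.chain}_merged"),
        }
    else:
        targets = {}
        if asm.variable_contig is not None:
            vid = f"{asm.chain}_variable"
            targets[SEGMENT_V] = (asm.variable_contig.seq, vid)
            targets[SEGMENT_J] = (asm.variable_contig.seq, vid)
        if asm.constant_contig is not None:
            targets[SEGMENT_C] = (asm.constant_contig.seq, f"{asm.chain}_constant")

    comp_for = {SEGMENT_V: v_comp, SEGMENT_J: j_comp, SEGMENT_C: c_comp}
    calls: list[GeneCall] = []
    for segment in (SEGMENT_V, SEGMENT_J, SEGMENT_C):
        if segment not in targets:
            continue
        comp = comp_for[segment]
        if segment == SEGMENT_J and not db.has(comp):
            continue  # J annotation only when a J set was supplied
        seq, contig_id = targets[segment]
        call = call_segment(
            seq,
            db.sequences(comp),
            segment,
            min_call_score=params.min_call_score,
            allele_level=params.allele_level,
            contig_id=contig_id,
        )
        if call is not None:
            calls.append(call)
    return calls
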