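"""Tunable parameters of the per-cell assembly pipeline."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class PipelineParams:
    """All assembly/annotation tunables, with their defaults.

    k                  seed k-mer length for germline indexing/mapping (bp)
    w                  anchor window length (bp); one read length by default
    m                  minimum suffix-prefix overlap for extension (bp)
    max_mismatches     substitutions tolerated when placing a read on a
                       germline (absorbs somatic hypermutation + errors)
    min_anchor_support minimum reads overlapping a window to accept it as an
                       anchor (guards against spurious single-read anchors)
    max_contig_length  hard stop for runaway extension (bp); ~a full-length
                       chain transcript
    overlap_mismatches mismatches tolerated in an extension overlap outside
                       the exact m-mer seed (0 = exact overlaps only)
    min_call_score     minimum local-alignment score to report a gene call
    allele_level       report gene calls at allele resolution (keep the
                       "*NN" suffix) instead of gene level
    """

    k: int = 16
    w: int = 50
    m: int = 20
    max_mismatches: int = 3
    min_anchor_support: int = 3
    max_contig_length: int = 1500
    overlap_mismatches: int = 0
    min_call_score: int = 30
    allele_level: bool = False
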