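"""Ground-truthed synthetic B cells: rearranged transcripts and short reads.

The generator emulates the biology the assembler must cope with:

* V(D)J recombination — per chain, one V, (D for heavy), J and constant
  gene chosen uniformly from the germline pools; for the light chain a
  kappa/lambda locus is chosen first so V, J and C are locus-consistent.
* Junctional diversity — 0-3 bases trimmed at each segment joint and a
  random non-templated insertion (length drawn from a configurable range)
  at each junction (heavy: V-D and D-J; light: V-J).
* Somatic hypermutation — i.i.d. point substitutions over the V(D)J span
  at a configurable per-base rate (substitution-only; never an indel, so
  the exact-overlap assembler's recovery property stays well defined).
* Sequencing — fixed-length reads from uniformly placed fragments in both
  orientations, with i.i.d. substitution errors. Fragments may run off
  either transcript end and are clipped, as tagmentation of full-length
  cDNA yields fragments that include the transcript termini; clipped reads
  shorter than a minimum keep-length are redrawn so the realized read
  count equals round(depth * transcript_length / read_length).

A small synthetic germline set (random sequences with IMGT-like names,
explicitly NOT real human alleles) is generated on demand so nothing needs
downloading.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .germline_db import Component, GermlineDB, GermlineSequence
from .read_io import Read, ReadSet, reverse_complement

log = logging.getLogger(__name__)

BASES = "ACGT"
HEAVY = "heavy"
LIGHT = "light"

MIN_CLIPPED_READ = 20  # clipped fragments shorter than this are redrawn


@dataclass
class SimParams:
    """Simulation conditions.

    read_length        bp per read (50 by default, short-read scRNA-seq)
    depth              mean fold-coverage of each chain transcript
    error_rate         per-base sequencing substitution probability
    shm_rate           per-base somatic hypermutation probability over the
                       V(D)J span
    insertion_range    inclusive (lo, hi) length range of non-templated
                       junction insertions
    max_trim           maximum bases trimmed at each segment joint (0
                       disables trimming)
    paired             emit mate pairs from opposite fragment ends
    fragment_mean/sd   fragment length distribution for paired mode (bp)
    chains             which chains the cell expresses
    mask_interval      optional (start, end) transcript interval; reads
                       overlapping it are discarded, creating a coverage gap
    """

    seed: int = 0
    read_length: int = 50
    depth: float = 100.0
    error_rate: float = 0.0
    shm_rate: float = 0.0
    insertion_range: tuple[int, int] = (0, 8)
    max_trim: int = 3
    paired: bool = False
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    chains: tuple[str, ...] = (HEAVY, LIGHT)
    mask_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("error_rate", "shm_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 40:
            warnings.warn(
                f"read_length={self.read_length} is below twice the default "
                "minimum overlap; assembly may fragment",
                stacklevel=2,
            )


@dataclass
class ChainTruth:
    """Ground truth for one simulated chain."""

    chain: str
    v_gene: str
    d_gene: str | None
    j_gene: str
    c_gene: str
    junction_inserts: list[str]
    pre_mutation: str
    post_mutation: str
    mutated_positions: list[int]
    vdj_length: int  # transcript prefix covered by the V(D)J region


@dataclass
class SimTruth:
    cell_id: str
    chains: dict[str, ChainTruth] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_toy_germline_db(seed: int = 20160913, k: int = 16) -> GermlineDB:
    """A small synthetic germline set with IMGT-like names.

    Sequences are random DNA, NOT real human alleles; sizes mimic the real
    segments (~300 bp V, ~15 bp D, ~50 bp J, ~300 bp constant-region
    5' truncation). Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)

    def seqs(comp: Component, names: list[str], length: int) -> list[GermlineSequence]:
        return [
            GermlineSequence(name=n, component=comp, seq=_random_dna(rng, length))
            for n in names
        ]

    components = {
        Component.IGHV: seqs(
            Component.IGHV, [f"IGHV{i}-1*01" for i in range(1, 6)], 300
        ),
        Component.D_HEAVY: seqs(
            Component.D_HEAVY, [f"IGHD{i}-1*01" for i in range(1, 5)], 15
        ),
        Component.J_HEAVY: seqs(
            Component.J_HEAVY, [f"IGHJ{i}*01" for i in range(1, 5)], 52
        ),
        Component.IGHC: seqs(Component.IGHC, ["IGHM*01", "IGHG1*01", "IGHA1*01"], 300),
        Component.IGKLV: (
            seqs(Component.IGKLV, [f"IGKV{i}-1*01" for i in range(1, 4)], 295)
            + seqs(Component.IGKLV, [f"IGLV{i}-1*01" for i in range(1, 3)], 295)
        ),
        Component.J_LIGHT: (
            seqs(Component.J_LIGHT, ["IGKJ1*01", "IGKJ2*01"], 38)
            + seqs(Component.J_LIGHT, ["IGLJ1*01"], 38)
        ),
        Component.IGKLC: (
            seqs(Component.IGKLC, ["IGKC*01"], 310)
            + seqs(Component.IGKLC, ["IGLC1*01"], 310)
        ),
    }
    return GermlineDB.from_sequences(components, k=k)


def _choose(rng: np.random.Generator, seqs: list[GermlineSequence]) -> GermlineSequence:
    return seqs[int(rng.integers(0, len(seqs)))]


def _trim(rng: np.random.Generator, seq: str, max_trim: int, end: str) -> str:
    t = int(rng.integers(0, max_trim + 1)) if max_trim > 0 else 0
    t = min(t, len(seq))
    if t == 0:
        return seq
    return seq[:-t] if end == "3p" else seq[t:]


def _insert(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return _random_dna(rng, n)


def _light_locus_pools(
    db: GermlineDB,
) -> dict[str, tuple[list[GermlineSequence], list[GermlineSequence], list[GermlineSequence]]]:
    """Split the pooled light-chain components by kappa/lambda name prefix."""
    pools = {}
    for locus, prefix in (("kappa", "IGK"), ("lambda", "IGL")):
        v = [s for s in db.sequences(Component.IGKLV) if s.name.startswith(prefix)]
        j = [s for s in db.sequences(Component.J_LIGHT) if s.name.startswith(prefix)]
        c = [s for s in db.sequences(Component.IGKLC) if s.name.startswith(prefix)]
        if v and j and c:
            pools[locus] = (v, j, c)
    return pools


def simulate_receptor(
    db: GermlineDB, params: SimParams, rng: np.random.Generator, cell_id: str = "cell"
) -> SimTruth:
    """Simulate one cell's rearranged transcripts with junctional diversity
    and somatic hypermutation."""
    truth = SimTruth(cell_id=cell_id)
    lo, hi = params.insertion_range
    for chain in params.chains:
        if chain == HEAVY:
            for comp in (Component.IGHV, Component.D_HEAVY, Component.J_HEAVY, Component.IGHC):
                if not db.has(comp):
                    raise ValueError(f"germline set missing component {comp.value}")
            v = _choose(rng, db.sequences(Component.IGHV))
            d = _choose(rng, db.sequences(Component.D_HEAVY))
            j = _choose(rng, db.sequences(Component.J_HEAVY))
            c = _choose(rng, db.sequences(Component.IGHC))
            v_part = _trim(rng, v.seq, params.max_trim, "3p")
            d_part = _trim(
                rng, _trim(rng, d.seq, params.max_trim, "5p"), params.max_trim, "3p"
            )
            j_part = _trim(rng, j.seq, params.max_trim, "5p")
            ins1 = _insert(rng, lo, hi)
            ins2 = _insert(rng, lo, hi)
            vdj = v_part + ins1 + d_part + ins2 + j_part
            inserts = [ins1, ins2]
            d_name: str | None = d.name
        else:
            pools = _light_locus_pools(db)
            if not pools:
                raise ValueError(
                    "germline set missing a locus-consistent light-chain "
                    "V/J/C pool (IGK or IGL)"
                )
            locus = sorted(pools)[int(rng.integers(0, len(pools)))]
            v_pool, j_pool, c_pool = pools[locus]
            v = _choose(rng, v_pool)
            j = _choose(rng, j_pool)
            c = _choose(rng, c_pool)
            v_part = _trim(rng, v.seq, params.max_trim, "3p")
            j_part = _trim(rng, j.seq, params.max_trim, "5p")
            ins1 = _insert(rng, lo, hi)
            vdj = v_part + ins1 + j_part
            inserts = [ins1]
            d_name = None

        pre = vdj + c.seq
        post, positions = _apply_shm(rng, pre, len(vdj), params.shm_rate)
        truth.chains[chain] = ChainTruth(
            chain=chain,
            v_gene=v.name,
            d_gene=d_name,
            j_gene=j.name,
            c_gene=c.name,
            junction_inserts=inserts,
            pre_mutation=pre,
            post_mutation=post,
            mutated_positions=positions,
            vdj_length=len(vdj),
        )
    return truth


def _apply_shm(
    rng: np.random.Generator, seq: str, vdj_len: int, rate: float
) -> tuple[str, list[int]]:
    if rate <= 0 or vdj_len == 0:
        return seq, []
    hits = np.nonzero(rng.random(vdj_len) < rate)[0]
    out = list(seq)
    for pos in hits:
        out[pos] = _substitute(rng, out[pos])
    return "".join(out), [int(p) for p in hits]


def _substitute(rng: np.random.Generator, base: str) -> str:
    others = [b for b in BASES if b != base]
    return others[int(rng.integers(0, 3))] if base in BASES else BASES[int(rng.integers(0, 4))]


def _with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for pos in hits:
        out[pos] = _substitute(rng, out[pos])
    return "".join(out)


def _draw_span(
    rng: np.random.Generator, tlen: int, read_len: int
) -> tuple[int, int]:
    """Uniform fragment start with end overhang, clipped to the transcript.

    Redraws until the clipped span is at least MIN_CLIPPED_READ bases (or
    the whole transcript, if shorter).
    """
    min_keep = min(MIN_CLIPPED_READ, tlen)
    lo = -(read_len - min_keep)
    hi = tlen - min_keep  # inclusive
    while True:
        start = int(rng.integers(lo, hi + 1))
        s, e = max(0, start), min(tlen, start + read_len)
        if e - s >= min_keep:
            return s, e


def simulate_reads(
    truth: SimTruth, params: SimParams, rng: np.random.Generator
) -> ReadSet:
    """Fragment each chain's mutated transcript into error-bearing reads.

    Single-end mode emits round(depth * len / read_length) reads per chain;
    paired mode emits that many total reads as mates from opposite ends of
    normally distributed fragments. Reads overlapping ``mask_interval``
    are discarded (coverage-gap stress tests).
    """
    reads: list[Read] = []
    L = params.read_length
    for chain in sorted(truth.chains):
        t = truth.chains[chain].post_mutation
        if L > len(t):
            raise ValueError(
                f"read length {L} exceeds the {chain} transcript ({len(t)} bp)"
            )
        n_reads = round(params.depth * len(t) / L)
        if params.paired:
            reads.extend(
                _paired_reads(rng, t, chain, truth.cell_id, n_reads, params)
            )
        else:
            reads.extend(
                _single_reads(rng, t, chain, truth.cell_id, n_reads, params)
            )
    if params.mask_interval is not None:
        ms, me = params.mask_interval
        reads = [
            r
            for r in reads
            if _read_span(r.id)[0] >= me or _read_span(r.id)[1] <= ms
        ]
    return ReadSet(reads=reads)


def _read_span(read_id: str) -> tuple[int, int]:
    """Recover the truth span encoded in a simulated read id."""
    _, _, span = read_id.rpartition(":")
    span = span.split("/", 1)[0]
    s, _, e = span.partition("-")
    return int(s), int(e)


def _single_reads(rng, transcript, chain, cell_id, n_reads, params):
    out = []
    for i in range(n_reads):
        s, e = _draw_span(rng, len(transcript), params.read_length)
        frag = transcript[s:e]
        if rng.random() < 0.5:
            frag = reverse_complement(frag)
        frag = _with_errors(rng, frag, params.error_rate)
        out.append(Read(id=f"{cell_id}:{chain}:{i}:{s}-{e}", seq=frag))
    return out


def _paired_reads(rng, transcript, chain, cell_id, n_reads, params):
    out = []
    tlen = len(transcript)
    L = params.read_length
    n_pairs = max(1, n_reads // 2)
    for i in range(n_pairs):
        flen = int(round(rng.normal(params.fragment_mean, params.fragment_sd)))
        flen = min(max(flen, L), tlen)
        fs = int(rng.integers(0, tlen - flen + 1))
        fe = fs + flen
        m1 = transcript[fs : fs + L]
        m2 = reverse_complement(transcript[fe - L : fe])
        if rng.random() < 0.5:  # fragment strand
            m1, m2 = reverse_complement(m2), reverse_complement(m1)
            span1, span2 = (fe - L, fe), (fs, fs + L)
        else:
            span1, span2 = (fs, fs + L), (fe - L, fe)
        m1 = _with_errors(rng, m1, params.error_rate)
        m2 = _with_errors(rng, m2, params.error_rate)
        out.append(Read(id=f"{cell_id}:{chain}:{i}:{span1[0]}-{span1[1]}/1", seq=m1))
        out.append(Read(id=f"{cell_id}:{chain}:{i}:{span2[0]}-{span2[1]}/2", seq=m2))
    return out


# ---------------------------------------------------------------------------
# plain-text writers

def write_fastq(reads: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_germline_fasta(db: GermlineDB, directory: str | Path) -> dict[Component, Path]:
    """One FASTA per component, for feeding back into the assembler CLI."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for comp, seqs in db.components.items():
        if not seqs:
            continue
        path = directory / f"{comp.value}.fasta"
        with open(path, "w") as fh:
            for s in seqs:
                fh.write(f">{s.name}\n{s.seq}\n")
        paths[comp] = path
    return paths


TRUTH_COLUMNS = [
    "cell_id",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "junction_inserts",
    "n_mutations",
    "vdj_length",
    "transcript",
]


def write_truth_tsv(truths: list[SimTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for truth in truths:
            for chain in sorted(truth.chains):
                ct = truth.chains[chain]
                fh.write(
                    "\t".join(
                        [
                            truth.cell_id,
                            ct.chain,
                            ct.v_gene,
                            ct.d_gene or ".",
                            ct.j_gene,
                            ct.c_gene,
                            ",".join(ct.junction_inserts) or ".",
                            str(len(ct.mutated_positions)),
                            str(ct.vdj_length),
                            ct.post_mutation,
                        ]
                    )
                    + "\n"
                )


def write_truth_fasta(truths: list[SimTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        for truth in truths:
            for chain in sorted(truth.chains):
                ct = truth.chains[chain]
                fh.write(f">{truth.cell_id}_{chain}\n{ct.post_mutation}\n")
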