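"""Seeded nanopore-style read simulation for a single-gene amplicon.

Reads are drawn from a weighted mixture of exon-chain transcripts, then
corrupted with i.i.d. per-base substitution/insertion/deletion errors at
rates typical of R9.4.1-era nanopore data.  Every error is logged, so the
module can also emit "oracle" spliced alignments: SAM records whose gapped
(``N``) operations sit exactly at the source transcript's introns and whose
``I``/``D``/mismatch operations sit at the simulated error positions.  The
oracle writer optionally merges deletion runs that touch an intron edge into
the gap, reproducing the junction wobble that real spliced aligners show on
noisy long reads; the resulting displacement is bounded by the deletion run
length.

All randomness flows from ``SimConfig.seed``; identical configurations give
byte-identical FASTQ, truth-table and SAM outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from nanosplice.gene_model import GeneModel

__all__ = [
    "SimConfig",
    "SimRead",
    "simulate_reads",
    "emit_oracle_alignments",
    "write_fastq",
    "write_truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Mixture and error model for one simulation run.

    ``mixture`` maps transcript name -> (exon-id chain, relative abundance);
    abundances are normalised to 1.  Error probabilities are per base.  A
    read is truncated with probability ``truncation_rate``, losing a
    uniformly chosen terminal fraction (5-45%) from a random end.
    """

    mixture: dict[str, tuple[list[str], float]]
    n_reads: int = 1000
    p_sub: float = 0.03
    p_ins: float = 0.02
    p_del: float = 0.03
    truncation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mixture:
            raise SimulationError("empty transcript mixture")
        for name, (chain, w) in self.mixture.items():
            if w <= 0:
                raise SimulationError(f"abundance of {name} must be > 0")
            if not chain:
                raise SimulationError(f"empty chain for {name}")
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not 0 <= p < 0.5:
                raise SimulationError("error probabilities must be in [0, 0.5)")
        if not 0 <= self.truncation_rate <= 1:
            raise SimulationError("truncation_rate must be in [0, 1]")
        if self.n_reads <= 0:
            raise SimulationError("n_reads must be positive")

    @property
    def weights(self) -> dict[str, float]:
        total = sum(w for _, w in self.mixture.values())
        return {n: w / total for n, (_, w) in self.mixture.items()}


@dataclass
class SimRead:
    """One simulated read plus its complete error log (the truth record).

    ``t_start``/``t_end`` delimit the covered transcript interval (half-open,
    transcript coordinates); errors are logged in transcript coordinates:
    substitutions as (pos, original, observed), deletions as (pos, original),
    insertions as (pos, base) meaning ``base`` follows transcript position
    ``pos`` in the read.
    """

    read_id: str
    transcript: str
    chain: list[str]
    t_start: int
    t_end: int
    seq: str
    subs: list[tuple[int, str, str]] = field(default_factory=list)
    ins: list[tuple[int, str]] = field(default_factory=list)
    dels: list[tuple[int, str]] = field(default_factory=list)
    truncated: bool = False


def _transcript_layout(
    model: GeneModel, genome: Mapping[str, str], chain: Sequence[str]
) -> tuple[str, list[tuple[str, int, int, int, int]]]:
    """Spliced sequence and exon segments as (id, t0, t1, g0, g1)."""
    by_id = model.exons_by_id
    segs: list[tuple[str, int, int, int, int]] = []
    t = 0
    for eid in chain:
        e = by_id[eid]
        segs.append((eid, t, t + e.length, e.start, e.end))
        t += e.length
    return model.chain_sequence(genome, chain), segs


def simulate_reads(
    model: GeneModel, genome: Mapping[str, str], cfg: SimConfig
) -> list[SimRead]:
    """Draw ``cfg.n_reads`` error-bearing reads from the transcript mixture."""
    by_id = model.exons_by_id
    for name, (chain, _) in cfg.mixture.items():
        unknown = [e for e in chain if e not in by_id]
        if unknown:
            raise SimulationError(f"mixture transcript {name} references unknown exons {unknown}")

    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.mixture)
    probs = np.array([cfg.weights[n] for n in names])
    layouts = {
        n: _transcript_layout(model, genome, cfg.mixture[n][0]) for n in names
    }
    arrays = {
        n: np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        for n, (seq, _) in layouts.items()
    }
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[b] = i

    picks = rng.choice(len(names), size=cfg.n_reads, p=probs)
    reads: list[SimRead] = []
    for i, k in enumerate(picks):
        name = names[int(k)]
        tarr = arrays[name]
        L = len(tarr)
        t0, t1, truncated = 0, L, False
        if cfg.truncation_rate > 0 and rng.random() < cfg.truncation_rate:
            cut = int(rng.uniform(0.05, 0.45) * L)
            if cut > 0:
                truncated = True
                if rng.random() < 0.5:
                    t0 = cut
                else:
                    t1 = L - cut
        sub = tarr[t0:t1]
        m = t1 - t0
        del_mask = rng.random(m) < cfg.p_del
        sub_mask = (~del_mask) & (rng.random(m) < cfg.p_sub)
        ins_mask = rng.random(m) < cfg.p_ins
        if m:
            ins_mask[-1] = False  # keep reads free of terminal insertions

        out = sub.copy()
        sub_pos = np.flatnonzero(sub_mask)
        new_idx = (lut[sub[sub_pos]] + 1 + rng.integers(0, 3, len(sub_pos))) % 4
        out[sub_pos] = _BASES[new_idx]

        kept = ~del_mask
        body = out[kept]
        ins_pos = np.flatnonzero(ins_mask)
        ins_bases = _BASES[rng.integers(0, 4, len(ins_pos))]
        if len(ins_pos):
            kept_cum = np.cumsum(kept)
            body = np.insert(body, kept_cum[ins_pos], ins_bases)
        seq = body.tobytes().decode()

        del_pos = np.flatnonzero(del_mask)
        reads.append(SimRead(
            read_id=f"read{i:07d}",
            transcript=name,
            chain=list(cfg.mixture[name][0]),
            t_start=t0,
            t_end=t1,
            seq=seq,
            subs=[(int(p) + t0, chr(sub[p]), chr(out[p])) for p in sub_pos],
            ins=[(int(p) + t0, chr(b)) for p, b in zip(ins_pos, ins_bases)],
            dels=[(int(p) + t0, chr(sub[p])) for p in del_pos],
            truncated=truncated,
        ))
    return reads


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_truth_table(reads: Sequence[SimRead], path: str | Path) -> None:
    cols = "read_id transcript chain t_start t_end n_sub n_ins n_del truncated".split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reads:
            fh.write("\t".join(map(str, [
                r.read_id, r.transcript, ",".join(r.chain), r.t_start, r.t_end,
                len(r.subs), len(r.ins), len(r.dels), int(r.truncated),
            ])) + "\n")


# ---------------------------------------------------------------------------
# oracle alignments
# ---------------------------------------------------------------------------

_M, _I, _D, _N = 0, 1, 2, 3  # pysam cigar op codes


def _append_op(ops: list[list[int]], op: int, length: int) -> None:
    if length <= 0:
        return
    if ops and ops[-1][0] == op:
        ops[-1][1] += length
    else:
        ops.append([op, length])


def _read_cigar(
    read: SimRead,
    segs: list[tuple[str, int, int, int, int]],
) -> tuple[int, list[list[int]]]:
    """Reference start and cigar ops for one read, errors at true positions."""
    dels = {p for p, _ in read.dels}
    ins = {p for p, _ in read.ins}
    ops: list[list[int]] = []
    ref_start = None
    prev_gend = None
    for eid, t0, t1, g0, g1 in segs:
        lo, hi = max(t0, read.t_start), min(t1, read.t_end)
        if lo >= hi:
            continue
        gstart = g0 + (lo - t0)
        if ref_start is None:
            ref_start = gstart
        elif prev_gend is not None:
            _append_op(ops, _N, gstart - prev_gend)
        events = sorted(p for p in (dels | ins) if lo <= p < hi)
        cur = lo
        for p in events:
            _append_op(ops, _M, p - cur)
            _append_op(ops, _D if p in dels else _M, 1)
            if p in ins:
                _append_op(ops, _I, 1)
            cur = p + 1
        _append_op(ops, _M, hi - cur)
        prev_gend = g1 if hi == t1 else None
    assert ref_start is not None
    return ref_start, ops


def _trim_edges(pos: int, ops: list[list[int]]) -> tuple[int, list[list[int]]]:
    """Alignments may not begin or end with reference-only operations."""
    while ops and ops[0][0] in (_D, _N):
        pos += ops[0][1]
        ops.pop(0)
    while ops and ops[-1][0] in (_D, _N):
        ops.pop()
    return pos, ops


def _merge_edge_deletions(ops: list[list[int]]) -> list[list[int]]:
    """Absorb deletion runs adjacent to an intron gap into the gap itself."""
    changed = True
    while changed:
        changed = False
        out: list[list[int]] = []
        for op, ln in ops:
            if out and {op, out[-1][0]} == {_N, _D}:
                out[-1] = [_N, out[-1][1] + ln]
                changed = True
            elif out and out[-1][0] == op:
                out[-1][1] += ln
            else:
                out.append([op, ln])
        ops = out
    return ops


def emit_oracle_alignments(
    reads: Sequence[SimRead],
    model: GeneModel,
    genome: Mapping[str, str],
    path: str | Path,
    edge_merge: bool = True,
) -> None:
    """Write one primary SAM record per read with introns at their true sites.

    With ``edge_merge`` (the default) deletion runs touching a gapped intron
    operation are merged into it, so a fraction of junction observations is
    displaced by a few nt, exactly as spliced aligners behave on noisy
    reads; the snap step of the junction caller is responsible for undoing
    this.  With ``edge_merge=False`` junction coordinates are always exact.
    """
    contig = model.contig
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": contig, "LN": len(genome[contig])}],
    })
    layouts: dict[str, list[tuple[str, int, int, int, int]]] = {}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for r in reads:
            if r.transcript not in layouts:
                layouts[r.transcript] = _transcript_layout(model, genome, r.chain)[1]
            segs = layouts[r.transcript]
            if segs[-1][2] < r.t_end:
                raise SimulationError(f"truth/model mismatch for {r.read_id}")
            pos, ops = _read_cigar(r, segs)
            if edge_merge:
                ops = _merge_edge_deletions(ops)
            pos, ops = _trim_edges(pos, ops)
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = [tuple(x) for x in ops]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            qlen = sum(ln for op, ln in ops if op in (_M, _I))
            if qlen != len(r.seq):
                raise SimulationError(f"cigar/query length mismatch for {r.read_id}")
            sam.write(a)
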