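"""Splice-junction extraction, correction, classification and cryptic exons.

A spliced long-read alignment encodes each traversed intron as a gapped
(``N``) operation.  This module turns primary alignments into per-read block
chains, snaps noisy junction coordinates onto annotated splice sites within
a small window, tabulates distinct junctions with read support and a status
(annotated / novel combination of annotated sites / cryptic), and calls
novel exons from internal aligned blocks that overlap no annotated exon.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from nanosplice.gene_model import Exon, GeneModel

__all__ = [
    "ReadChain",
    "NovelExonCall",
    "extract_read_chains",
    "snap_junctions",
    "tabulate_junctions",
    "discover_novel_exons",
    "novel_exons_to_exons",
    "junction_table_to_bed",
]

log = logging.getLogger(__name__)

_REF_BLOCK_OPS = {0, 2, 7, 8}  # M, D, =, X  (consume reference within a block)


@dataclass
class ReadChain:
    """Ordered gapless-or-deletion blocks of one primary alignment.

    Junctions are the gaps between consecutive blocks; they arise only from
    gapped-intron (``N``) operations, never from deletions.
    """

    read_id: str
    blocks: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.blocks, self.blocks[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(f"{self.read_id}: blocks not strictly increasing")

    @property
    def junctions(self) -> list[tuple[int, int]]:
        return [(a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:])]


@dataclass(frozen=True)
class NovelExonCall:
    """A cryptic exon: an exonised interval absent from the annotation."""

    exon_id: str
    start: int
    end: int
    flank_left: str
    flank_right: str
    support: int

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_read_chains(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
) -> list[ReadChain]:
    """One block chain per primary alignment; secondary/supplementary skipped."""
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), "r") as fh:
            if not fh.header.to_dict().get("SQ"):
                raise ValueError(f"{alignments}: SAM header lacks @SQ records")
            return _chains_from_segments(fh)
    return _chains_from_segments(alignments)


def _chains_from_segments(segments: Iterable[pysam.AlignedSegment]) -> list[ReadChain]:
    chains: list[ReadChain] = []
    n_skipped = 0
    for a in segments:
        if a.is_unmapped or a.is_secondary or a.is_supplementary:
            n_skipped += 1
            continue
        pos = a.reference_start
        blocks: list[tuple[int, int]] = []
        cur = pos
        for op, ln in a.cigartuples or []:
            if op in _REF_BLOCK_OPS:
                pos += ln
            elif op == 3:  # N closes the current block
                blocks.append((cur, pos))
                pos += ln
                cur = pos
        blocks.append((cur, pos))
        chains.append(ReadChain(a.query_name, blocks))
    if not chains:
        log.warning("no primary mapped alignments found (%d records skipped)", n_skipped)
    return chains


# ---------------------------------------------------------------------------
# snapping
# ---------------------------------------------------------------------------

def _nearby(sites: np.ndarray, x: int, w: int) -> list[int]:
    i = int(np.searchsorted(sites, x - w))
    out = []
    while i < len(sites) and sites[i] <= x + w:
        out.append(int(sites[i]))
        i += 1
    return out


def snap_junctions(
    chains: Sequence[ReadChain],
    model: GeneModel,
    w: int = 12,
    genome: Mapping[str, str] | None = None,
) -> list[ReadChain]:
    """Move junction ends lying within ``w`` nt of an annotated splice site.

    For each junction the (donor, acceptor) pair minimising the total shift
    is chosen; ties are broken toward a pair forming an annotated junction,
    then toward one with GT..AG intron dinucleotides (when the genome is
    given), then toward smaller coordinates.  Ends with no annotated site
    within ``w`` are left untouched — these are the cryptic-site candidates.
    """
    if w < 0:
        raise ValueError("snap window must be >= 0")
    donors = np.array(model.donor_sites())
    acceptors = np.array(model.acceptor_sites())
    annotated = model.annotated_junctions()
    seq = genome[model.contig] if genome is not None else None

    def is_gtag(d: int, a: int) -> bool:
        if seq is None or a - d < 4:
            return False
        return seq[d:d + 2] == "GT" and seq[a - 2:a] == "AG"

    snapped: list[ReadChain] = []
    for chain in chains:
        blocks = [list(b) for b in chain.blocks]
        for i in range(len(blocks) - 1):
            d, a = blocks[i][1], blocks[i + 1][0]
            cand_d = _nearby(donors, d, w) or [d]
            cand_a = _nearby(acceptors, a, w) or [a]
            cd, ca = min(
                ((x, y) for x in cand_d for y in cand_a),
                key=lambda p: (
                    abs(p[0] - d) + abs(p[1] - a),
                    (p[0], p[1]) not in annotated,
                    not is_gtag(*p),
                    p,
                ),
            )
            if cd > blocks[i][0] and ca < blocks[i + 1][1] and cd < ca:
                blocks[i][1], blocks[i + 1][0] = cd, ca
        snapped.append(replace(chain, blocks=[tuple(b) for b in blocks]))
    return snapped


# ---------------------------------------------------------------------------
# junction table
# ---------------------------------------------------------------------------

def tabulate_junctions(
    chains: Sequence[ReadChain],
    model: GeneModel,
    min_support: int = 5,
    min_fraction: float = 1e-4,
) -> pd.DataFrame:
    """Distinct junctions with read support and status.

    One vote per read per junction.  A junction is ``annotated`` when the
    (donor, acceptor) pair occurs in an annotated transcript,
    ``novel_combination`` when both sites are annotated splice sites but the
    pair is not, and ``cryptic`` otherwise.  Rows with support below
    ``max(min_support, min_fraction * n_reads)`` are suppressed.
    """
    counts: Counter[tuple[int, int]] = Counter()
    for chain in chains:
        for j in set(chain.junctions):
            counts[j] += 1
    threshold = max(min_support, min_fraction * len(chains))
    annotated = model.annotated_junctions()
    donors = set(model.donor_sites())
    acceptors = set(model.acceptor_sites())
    end_to_exon = {e.end: e.id for e in model.annotated_exons}
    start_to_exon = {e.start: e.id for e in model.annotated_exons}

    rows = []
    for (d, a), n in sorted(counts.items()):
        if n < threshold:
            continue
        if (d, a) in annotated:
            status = "annotated"
        elif d in donors and a in acceptors:
            status = "novel_combination"
        else:
            status = "cryptic"
        left = end_to_exon.get(d)
        right = start_to_exon.get(a)
        label = (
            f"{model.exon_label(left)}-{model.exon_label(right)}"
            if left and right else ""
        )
        rows.append((label, d, a, status, n))
    return pd.DataFrame(rows, columns=["label", "donor", "acceptor", "status", "support"])


def junction_table_to_bed(table: pd.DataFrame, contig: str, path: str | Path) -> None:
    """Junction spans as BED intervals (donor..acceptor per row)."""
    with open(path, "w") as fh:
        for _, r in table.iterrows():
            name = str(r["label"]).replace(" ", "_") or f"{r['donor']}-{r['acceptor']}"
            fh.write(f"{contig}\t{r['donor']}\t{r['acceptor']}\t{name}\t{r['support']}\t+\n")


# ---------------------------------------------------------------------------
# novel exon discovery
# ---------------------------------------------------------------------------

def _mode(values: Iterable[int]) -> int:
    """Most frequent value; ties resolved toward the smallest coordinate."""
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, n in counts.items() if n == top)


def discover_novel_exons(
    chains: Sequence[ReadChain],
    model: GeneModel,
    min_support: int = 5,
    w: int = 12,
) -> list[NovelExonCall]:
    """Call cryptic exons from internal blocks outside the annotation.

    A candidate observation is an internal aligned block (flanked by a
    junction on both sides) overlapping no annotated exon.  Observations
    within ``w`` nt of each other are clustered; each cluster is reported at
    its modal start and modal end, provided it reaches ``min_support``
    reads.  Calls are named N1, N2, ... in genomic order.
    """
    tree = IntervalTree()
    for e in model.annotated_exons:
        tree[e.start:e.end] = e.id

    obs: list[tuple[int, int]] = []
    for chain in chains:
        for block in chain.blocks[1:-1]:
            if not tree.overlap(block[0], block[1]):
                obs.append(block)
    if not obs:
        return []

    obs.sort()
    clusters: list[list[tuple[int, int]]] = [[obs[0]]]
    for b in obs[1:]:
        ref = clusters[-1][0]
        if abs(b[0] - ref[0]) <= w and abs(b[1] - ref[1]) <= w:
            clusters[-1].append(b)
        else:
            clusters.append([b])

    ann = sorted(model.annotated_exons, key=lambda e: e.start)
    calls: list[NovelExonCall] = []
    for cluster in clusters:
        if len(cluster) < min_support:
            continue
        start = _mode(b[0] for b in cluster)
        end = _mode(b[1] for b in cluster)
        left = max((e for e in ann if e.end <= start), key=lambda e: e.end, default=None)
        right = min((e for e in ann if e.start >= end), key=lambda e: e.start, default=None)
        calls.append(NovelExonCall(
            exon_id="",
            start=start,
            end=end,
            flank_left=left.id if left else "",
            flank_right=right.id if right else "",
            support=len(cluster),
        ))
    calls.sort(key=lambda c: c.start)
    return [replace(c, exon_id=f"N{i}") for i, c in enumerate(calls, start=1)]


def novel_exons_to_exons(calls: Sequence[NovelExonCall], contig: str) -> list[Exon]:
    return [Exon(c.exon_id, contig, c.start, c.end, annotated=False) for c in calls]
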