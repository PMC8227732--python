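"""ORF prediction, premature-stop / NMD classification and domain presence.

Initiation codons are located by anchor subsequences — short stretches of
sequence surrounding the annotated ATG in exon 2 and the alternative ATGs in
exons 3 and 4 — so the caller works both on variants assembled with genome
coordinates and on bare cDNA sequences (e.g. database deposits).  Anchor
search is exact-substring first, with a fallback pass tolerating one
mismatch.  Priority follows the biology of the locus: the annotated start is
used whenever its exon is present, then the exon-3 and exon-4 alternatives,
and finally a plain longest-ORF scan.

A stop upstream of the annotated termination codon is a premature
termination codon (PTC); a PTC more than ``d_nmd`` nt (default 50, the
standard last-exon-junction rule) upstream of the final exon-exon junction
marks the transcript as a nonsense-mediated-decay candidate.

A protein domain is called present when its exact amino-acid subsequence on
the annotated isoform occurs contiguously in the predicted protein, which
uniformly handles exon skips, internal insertions and frameshifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
from Bio.Seq import Seq

from nanosplice.gene_model import DomainDef, GeneModel

__all__ = [
    "StartAnchors",
    "OrfPrediction",
    "DomainPresence",
    "derive_anchors",
    "predict_orf",
    "classify_nmd",
    "domain_presence",
    "reference_protein",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Anchor:
    """A sequence context locating a codon: the codon starts at ``offset``."""

    origin: str
    seq: str
    offset: int


@dataclass
class StartAnchors:
    """Initiation- and termination-codon contexts for one gene."""

    annotated: Anchor
    alternatives: list[Anchor]
    stop: Anchor


@dataclass
class OrfPrediction:
    """Predicted ORF of one transcript variant.

    ``start``/``stop`` are transcript coordinates (0-based; ``stop`` is the
    exclusive end of the stop codon).  ``protein_length`` counts the
    initiator Met and excludes the stop.  ``ptc`` flags a stop upstream of
    the annotated termination codon; ``nmd_candidate`` additionally requires
    the stop to sit more than the NMD distance upstream of the last
    exon-exon junction.
    """

    variant: str
    start_origin: str  # annotated_exon2 | alt_exon3 | alt_exon4 | scan | none
    start: int | None
    stop: int | None
    protein_length: int
    protein: str
    has_orf: bool
    ptc: bool
    nmd_candidate: bool = False


@dataclass
class DomainPresence:
    variant: str
    presence: dict[str, bool]


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def derive_anchors(
    model: GeneModel,
    genome: Mapping[str, str],
    context: int = 20,
) -> StartAnchors:
    """Extract codon-context anchors from the gene model and genome."""
    if model.annotated_start_codon is None or model.annotated_stop_codon is None:
        raise ValueError("gene model lacks annotated start/stop codons")
    seq = genome[model.contig]
    by_id = model.exons_by_id

    def anchor(origin: str, eid: str, off: int) -> Anchor:
        e = by_id[eid]
        lo = max(e.start, e.start + off - context)
        hi = min(e.end, e.start + off + 3 + context)
        return Anchor(origin, seq[lo:hi], e.start + off - lo)

    se, so = model.annotated_start_codon
    ee, eo = model.annotated_stop_codon
    return StartAnchors(
        annotated=anchor("annotated_exon2", se, so),
        alternatives=[anchor(origin, eid, off) for origin, eid, off in model.alt_start_codons],
        stop=anchor("annotated_stop", ee, eo),
    )


def _find_anchor(cdna: str, anchor: Anchor, max_mismatch: int = 1) -> int | None:
    """Position of the anchored codon in ``cdna``, or None."""
    p = cdna.find(anchor.seq)
    if p >= 0:
        return p + anchor.offset
    if max_mismatch > 0:
        hit = edlib.align(anchor.seq, cdna, mode="HW", task="locations", k=max_mismatch)
        if hit["editDistance"] >= 0 and hit["locations"]:
            start = hit["locations"][0][0]
            return start + anchor.offset
    return None


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

def _first_stop(cdna: str, start: int) -> int | None:
    """Exclusive end of the first in-frame stop codon after ``start``."""
    for i in range(start, len(cdna) - 2, 3):
        if cdna[i:i + 3] in _STOPS:
            return i + 3
    return None


def _translate(cdna: str, start: int, stop: int) -> str:
    return str(Seq(cdna[start:stop - 3]).translate())


def predict_orf(
    cdna: str,
    anchors: StartAnchors,
    variant: str = "",
    min_orf_aa: int = 50,
    max_mismatch: int = 1,
) -> OrfPrediction:
    """Predict the ORF of one spliced cDNA.

    Anchored starts take priority (annotated, then alternatives in order);
    a transcript with no anchor falls back to the longest ATG-initiated ORF
    of at least ``min_orf_aa`` residues.  PTC status compares the stop
    position with the located annotated termination codon.
    """
    if len(cdna) < len(anchors.annotated.seq):
        raise ValueError("cDNA shorter than the start anchor")

    start = stop = None
    origin = "none"
    for a in [anchors.annotated] + anchors.alternatives:
        p = _find_anchor(cdna, a, max_mismatch)
        if p is not None and cdna[p:p + 3] == "ATG":
            s = _first_stop(cdna, p)
            if s is not None:
                start, stop, origin = p, s, a.origin
                break
    if start is None:
        best: tuple[int, int] | None = None
        p = cdna.find("ATG")
        while p >= 0:
            s = _first_stop(cdna, p)
            if s is not None:
                aa = (s - p) // 3 - 1
                if aa >= min_orf_aa and (best is None or aa > (best[1] - best[0]) // 3 - 1):
                    best = (p, s)
            p = cdna.find("ATG", p + 1)
        if best is not None:
            start, stop = best
            origin = "scan"

    if start is None or stop is None:
        return OrfPrediction(
            variant=variant, start_origin="none", start=None, stop=None,
            protein_length=0, protein="", has_orf=False, ptc=False,
        )

    ann_stop = _find_anchor(cdna, anchors.stop, max_mismatch)
    ptc = ann_stop is not None and (stop - 3) < ann_stop
    return OrfPrediction(
        variant=variant,
        start_origin=origin,
        start=start,
        stop=stop,
        protein_length=(stop - start) // 3 - 1,
        protein=_translate(cdna, start, stop),
        has_orf=True,
        ptc=ptc,
    )


def classify_nmd(
    orf: OrfPrediction,
    chain: Sequence[str],
    model: GeneModel,
    d_nmd: int = 50,
) -> OrfPrediction:
    """Apply the last-junction rule: a PTC more than ``d_nmd`` nt upstream
    of the final exon-exon junction marks an NMD candidate; a stop in the
    final exon never does (strict inequality at the boundary)."""
    if not orf.has_orf or not orf.ptc or len(chain) < 2:
        orf.nmd_candidate = False
        return orf
    by_id = model.exons_by_id
    total = sum(by_id[e].length for e in chain)
    last_junction = total - by_id[chain[-1]].length
    assert orf.stop is not None
    orf.nmd_candidate = (last_junction - orf.stop) > d_nmd
    return orf


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------

def reference_protein(model: GeneModel, genome: Mapping[str, str]) -> str:
    """Translate the annotated isoform from its annotated start codon."""
    anchors = derive_anchors(model, genome)
    chain = next(iter(model.transcripts.values()))
    cdna = model.chain_sequence(genome, chain)
    orf = predict_orf(cdna, anchors, variant="reference")
    if orf.start_origin != "annotated_exon2":
        raise ValueError("annotated start codon not found on the annotated transcript")
    return orf.protein


def domain_presence(
    protein: str,
    ref_protein: str,
    domain_defs: Sequence[DomainDef],
    variant: str = "",
) -> DomainPresence:
    """A domain is present iff its reference aa subsequence occurs intact."""
    presence = {
        d.name: bool(protein) and ref_protein[d.aa_start - 1:d.aa_end] in protein
        for d in domain_defs
    }
    return DomainPresence(variant=variant, presence=presence)
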