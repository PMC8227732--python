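"""A synthetic single-gene locus modelled on the human ELF3 amplicon.

The fixture builds a small contig carrying ten annotated exon loci (two
alternative first exons of 120 and 234 nt, then E2..E9) plus two reserved
intronic loci, N1 (156 nt, inside the E7-E8 intron) and N2 (92 nt, inside
the E8-E9 intron), that act as cryptic exons.  All introns are GT..AG.

Sequence engineering
--------------------
Exonic sequence is drawn from the alphabet {A, C, G}; every T on the
transcribed strand is planted deliberately.  Since all three stop codons and
ATG contain a T, this guarantees that start and stop codons exist exactly
where they are planted, in every reading frame of every exon chain:

* an annotated ATG in E2 (after a 5' UTR stub), and in-frame alternative
  ATGs in E3 and E4;
* the annotated TGA at the end of the E9 coding span;
* a stop cassette in the E9 3' UTR with terminators in all three frames, so
  frameshifted chains terminate inside the final exon;
* a TAA inside N1, so the N1-carrying transcript gains a premature stop.

Coding exon spans are multiples of three, so every chain built purely from
annotated exons preserves frame; the 92-nt N2 insertion is the single
frameshifting event.  The five Elf-3 protein domains are laid onto exons as
PNT spanning E2/E3, TAD inside E4, SAR inside E6, the AT-hook inside E7 and
ETS spanning E8/E9, which lets exon-chain edits map one-to-one onto
domain-presence patterns.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from nanosplice.gene_model import DomainDef, Exon, GeneModel, GeneModelError

__all__ = [
    "elf3_fixture",
    "fixture_catalogue",
    "catalogue_mixture",
    "FIXTURE_CONTIG",
    "FIXTURE_GENE",
]

FIXTURE_CONTIG = "ELF3_synth"
FIXTURE_GENE = "ELF3"

# exon lengths in nt; E2 includes a 50-nt 5' UTR stub, E9 a 3' UTR tail
DEFAULT_EXON_LENGTHS: dict[str, int] = {
    "E1a": 120, "E1b": 234, "E2": 200, "E3": 222, "E4": 93,
    "E5": 120, "E6": 90, "E7": 117, "E8": 180, "E9": 450,
    "N1": 156, "N2": 92,
}
E2_UTR5 = 50          # nt of E2 upstream of the annotated ATG
E9_CDS = 144          # coding nt in E9 including the stop codon
ALT3_OFFSET = 30      # in-frame alternative ATG, offset within E3
ALT4_OFFSET = 45      # in-frame alternative ATG, offset within E4
N1_STOP_OFFSET = 30   # in-frame TAA within N1
FRAMESHIFT_PROTEIN_AA = 476  # protein length of the N2 frameshift variant
INTRON = 300
N1_GAP = (150, 194)   # sub-introns flanking N1 inside the E7-E8 intron
N2_GAP = (150, 208)   # sub-introns flanking N2 inside the E8-E9 intron
FLANK = 100

_CODING_ORDER = ["E2", "E3", "E4", "E5", "E6", "E7", "E8", "E9"]


def _coding_lengths(lengths: Mapping[str, int]) -> dict[str, int]:
    c = {e: lengths[e] for e in _CODING_ORDER}
    c["E2"] = lengths["E2"] - E2_UTR5
    c["E9"] = E9_CDS
    return c


def _validate_lengths(lengths: Mapping[str, int]) -> None:
    for k in DEFAULT_EXON_LENGTHS:
        if k not in lengths:
            raise GeneModelError(f"missing exon length for {k}")
    c = _coding_lengths(lengths)
    bad = [e for e, n in c.items() if n % 3 or n <= 0]
    if bad:
        raise GeneModelError(f"coding spans must be positive multiples of 3: {bad}")
    if lengths["N1"] % 3:
        raise GeneModelError("N1 must preserve frame (length % 3 == 0)")
    if lengths["N2"] % 3 == 0:
        raise GeneModelError("N2 must shift frame (length % 3 != 0)")
    if lengths["E2"] <= E2_UTR5:
        raise GeneModelError("E2 shorter than its 5' UTR stub")
    if lengths["E9"] <= E9_CDS:
        raise GeneModelError("E9 leaves no 3' UTR")
    if N1_STOP_OFFSET % 3 or N1_STOP_OFFSET + 3 > lengths["N1"]:
        raise GeneModelError("N1 stop must be in-frame and inside N1")


def _domain_defs(c: Mapping[str, int]) -> list[DomainDef]:
    # cumulative aa boundaries per coding exon (1-based inclusive)
    aa_end: dict[str, int] = {}
    total = 0
    for e in _CODING_ORDER:
        total += c[e] // 3
        aa_end[e] = total
    aa_start = {e: aa_end[e] - c[e] // 3 + 1 for e in _CODING_ORDER}
    defs = [
        DomainDef("PNT", aa_end["E2"] - 10, aa_end["E2"] + 10),
        DomainDef("TAD", aa_start["E4"] + 5, aa_end["E4"] - 5),
        DomainDef("SAR", aa_start["E6"] + 4, aa_end["E6"] - 5),
        DomainDef("AT_hook", aa_start["E7"] + 4, aa_end["E7"] - 4),
        DomainDef("ETS", aa_end["E8"] - 14, aa_end["E8"] + 16),
    ]
    # the alternative starts must truncate PNT (E3 anchor) and TAD (E4 anchor)
    if aa_start["E3"] + ALT3_OFFSET // 3 <= aa_end["E2"] + 10:
        raise GeneModelError("E3 alternative start falls inside PNT")
    if aa_start["E4"] + ALT4_OFFSET // 3 <= aa_start["E4"] + 5:
        raise GeneModelError("E4 alternative start upstream of TAD")
    if aa_end["E8"] + 16 > total - 1:
        raise GeneModelError("ETS runs past the annotated protein")
    return defs


def _rand_acg(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACG"))[rng.integers(0, 3, n)])


def _rand_intron(rng: np.random.Generator, n: int) -> str:
    if n < 10:
        raise GeneModelError("intron too short")
    body = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n - 4)])
    return "GT" + body + "AG"


def _plant(seq: str, offset: int, motif: str) -> str:
    return seq[:offset] + motif + seq[offset + len(motif):]


def elf3_fixture(
    seed: int = 0,
    exon_lengths: Mapping[str, int] | None = None,
) -> tuple[GeneModel, dict[str, str]]:
    """Build the synthetic ELF3-like gene model and its genome.

    Returns the :class:`GeneModel` (annotated exons E1a..E9 plus the reserved
    cryptic loci N1/N2 registered as non-annotated exons) and the genome as a
    ``{contig: sequence}`` mapping.  The same seed always yields the same
    sequence, byte for byte.
    """
    lengths = dict(DEFAULT_EXON_LENGTHS)
    if exon_lengths:
        lengths.update(exon_lengths)
    _validate_lengths(lengths)
    c = _coding_lengths(lengths)

    rng = np.random.default_rng(seed)
    ex_seq = {e: _rand_acg(rng, lengths[e]) for e in lengths}

    # planted coding features
    ex_seq["E2"] = _plant(ex_seq["E2"], E2_UTR5, "ATG")
    ex_seq["E3"] = _plant(ex_seq["E3"], ALT3_OFFSET, "ATG")
    ex_seq["E4"] = _plant(ex_seq["E4"], ALT4_OFFSET, "ATG")
    # the C before TGA prevents an accidental A|TG start codon at the stop
    ex_seq["E9"] = _plant(ex_seq["E9"], E9_CDS - 4, "CTGA")
    ex_seq["N1"] = _plant(ex_seq["N1"], N1_STOP_OFFSET, "TAA")

    # stop cassette for the N2 frameshift: terminators in all three frames,
    # placed so the frameshifted ORF closes at FRAMESHIFT_PROTEIN_AA residues
    pre_n2 = sum(c[e] for e in _CODING_ORDER[:-1])  # coding nt upstream of E9
    cassette_at = 3 * (FRAMESHIFT_PROTEIN_AA + 1) - pre_n2 - lengths["N2"] - 3
    shift_frame = (-(pre_n2 + lengths["N2"])) % 3
    if cassette_at % 3 != shift_frame:
        raise GeneModelError("stop cassette out of frame for the N2 shift")
    if not E9_CDS <= cassette_at <= lengths["E9"] - 12:
        raise GeneModelError("stop cassette falls outside the E9 UTR")
    ex_seq["E9"] = _plant(ex_seq["E9"], cassette_at, "TAACTAACTAA")

    # genome layout: E1a .. E7, [gap N1 gap], E8, [gap N2 gap], E9
    parts: list[tuple[str | None, str]] = [(None, _rand_acg(rng, FLANK))]
    order = ["E1a", "E1b", "E2", "E3", "E4", "E5", "E6", "E7"]
    for e in order:
        parts.append((e, ex_seq[e]))
        if e != "E7":
            parts.append((None, _rand_intron(rng, INTRON)))
    parts += [
        (None, _rand_intron(rng, N1_GAP[0])), ("N1", ex_seq["N1"]),
        (None, _rand_intron(rng, N1_GAP[1])), ("E8", ex_seq["E8"]),
        (None, _rand_intron(rng, N2_GAP[0])), ("N2", ex_seq["N2"]),
        (None, _rand_intron(rng, N2_GAP[1])), ("E9", ex_seq["E9"]),
        (None, _rand_acg(rng, FLANK)),
    ]

    pos = 0
    coords: dict[str, tuple[int, int]] = {}
    chunks: list[str] = []
    for name, s in parts:
        if name is not None:
            coords[name] = (pos, pos + len(s))
        chunks.append(s)
        pos += len(s)
    genome = {FIXTURE_CONTIG: "".join(chunks)}

    exons = [
        Exon(e, FIXTURE_CONTIG, coords[e][0], coords[e][1], annotated=(not e.startswith("N")))
        for e in ["E1a", "E1b", "E2", "E3", "E4", "E5", "E6", "E7", "N1", "E8", "N2", "E9"]
    ]
    annotated_chain = ["E2", "E3", "E4", "E5", "E6", "E7", "E8", "E9"]
    model = GeneModel(
        gene=FIXTURE_GENE,
        contig=FIXTURE_CONTIG,
        strand="+",
        exons=sorted(exons, key=lambda e: e.start),
        transcripts={
            "v.1": ["E1a"] + annotated_chain,
            "v.2": ["E1b"] + annotated_chain,
        },
        annotated_start_codon=("E2", E2_UTR5),
        annotated_stop_codon=("E9", E9_CDS - 3),
        alt_start_codons=[
            ("alt_exon3", "E3", ALT3_OFFSET),
            ("alt_exon4", "E4", ALT4_OFFSET),
        ],
        domain_defs=_domain_defs(c),
    )
    return model, genome


# ---------------------------------------------------------------------------
# reference transcript catalogue
# ---------------------------------------------------------------------------

def fixture_catalogue() -> dict[str, list[str]]:
    """Exon chains of the two annotated and 25 novel transcript variants.

    v.3-v.9 and v.14-v.19 follow the variant descriptions directly; the
    remaining chains are completed so that each uses only the catalogued
    splice junctions, matches the reported domain-presence pattern, and the
    catalogue as a whole exercises all 15 novel junctions between annotated
    exons.
    """
    A = ["E2", "E3", "E4", "E5", "E6", "E7", "E8", "E9"]

    def ch(first: str, *skip: str, insert: tuple[str, str] | None = None) -> list[str]:
        chain = [first] + [e for e in A if e not in skip]
        if insert:
            after, new = insert
            i = chain.index(after)
            chain = chain[:i + 1] + [new] + chain[i + 1:]
        return chain

    return {
        "v.1": ch("E1a"),
        "v.2": ch("E1b"),
        # exon-2-retaining variants
        "v.3": ch("E1a", "E6"),
        "v.4": ch("E1a", "E4"),
        "v.5": ch("E1a", "E3"),
        "v.6": ch("E1a", "E8"),
        "v.7": ch("E1b", "E4"),
        "v.8": ch("E1a", "E4", "E6"),
        "v.9": ch("E1a", "E4", "E8"),
        "v.10": ch("E1a", "E5", "E6", "E7"),
        "v.11": ["E1a", "E2", "E9"],
        "v.12": ["E1a", "E2", "E8", "E9"],
        "v.13": ["E1b", "E2", "E8", "E9"],
        # cryptic-exon variants: all annotated exons plus one novel exon
        "v.14": ch("E1a", insert=("E8", "N2")),
        "v.15": ch("E1a", insert=("E7", "N1")),
        # exon-2-lacking variants
        "v.16": ch("E1a", "E2"),
        "v.17": ch("E1b", "E2"),
        "v.18": ch("E1a", "E2", "E4"),
        "v.19": ch("E1a", "E2", "E6"),
        "v.20": ["E1a", "E3", "E7", "E8", "E9"],
        "v.21": ch("E1a", "E2", "E4", "E8"),
        "v.22": ch("E1a", "E2", "E4", "E6"),
        "v.23": ["E1a", "E3", "E8", "E9"],
        "v.24": ch("E1a", "E2", "E3"),
        "v.25": ch("E1a", "E2", "E3", "E4"),
        "v.26": ["E1a", "E7", "E8", "E9"],
        "v.27": ["E1a", "E8", "E9"],
    }


def catalogue_mixture(
    major: float = 0.60,
    minor_annotated: float = 0.10,
    novel_lo: float = 0.003,
    novel_hi: float = 0.03,
) -> dict[str, float]:
    """Relative transcript abundances for full-catalogue simulations.

    The two annotated variants dominate and the 25 novel variants span a
    geometric ladder from ``novel_hi`` (v.3) down to ``novel_lo`` (v.27),
    mirroring the orders-of-magnitude spread in observed junction support.
    Weights are normalised to sum to 1.
    """
    names = list(fixture_catalogue())
    novel = names[2:]
    ratios = np.geomspace(novel_hi, novel_lo, num=len(novel))
    w = {"v.1": major, "v.2": minor_annotated}
    w.update({n: float(r) for n, r in zip(novel, ratios)})
    total = sum(w.values())
    return {n: v / total for n, v in w.items()}
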