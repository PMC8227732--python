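"""Gene architecture: exons, splice sites, transcripts and protein domains.

A :class:`GeneModel` describes one gene on one reference contig: its exon
intervals (0-based, half-open), the annotated transcript exon chains, the
annotated initiation/termination codons and the amino-acid intervals of the
protein domains on the annotated isoform.  Readers and writers are provided
for BED12 and GTF, the two formats in which single-gene amplicon annotations
are commonly exchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pyfaidx

__all__ = [
    "Exon",
    "DomainDef",
    "GeneModel",
    "load_gene_model",
    "write_gene_model_bed12",
    "write_gene_model_gtf",
    "read_fasta",
    "write_fasta",
]


class GeneModelError(ValueError):
    """Raised when an annotation violates the single-gene model contract."""


@dataclass(frozen=True)
class Exon:
    """A genomic exon interval (0-based, half-open)."""

    id: str
    contig: str
    start: int
    end: int
    annotated: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise GeneModelError(f"exon {self.id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DomainDef:
    """A protein domain as a 1-based inclusive aa interval on the annotated isoform."""

    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise GeneModelError(f"domain {self.name}: bad aa interval")


@dataclass
class GeneModel:
    """One gene on one contig: exons, transcript chains and coding anchors.

    ``annotated_start_codon`` / ``annotated_stop_codon`` are (exon id, offset
    within exon) pairs; ``alt_start_codons`` lists further in-frame initiation
    codons as (origin label, exon id, offset).
    """

    gene: str
    contig: str
    strand: str
    exons: list[Exon]
    transcripts: dict[str, list[str]]
    annotated_start_codon: tuple[str, int] | None = None
    annotated_stop_codon: tuple[str, int] | None = None
    alt_start_codons: list[tuple[str, str, int]] = field(default_factory=list)
    domain_defs: list[DomainDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"bad strand {self.strand!r}")
        ids = [e.id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise GeneModelError("exon ids not unique")
        contigs = {e.contig for e in self.exons}
        if len(contigs) > 1:
            raise GeneModelError(f"exons on multiple contigs: {sorted(contigs)}")
        if not self.transcripts:
            raise GeneModelError("gene model has no transcripts")
        by_id = self.exons_by_id
        for name, chain in self.transcripts.items():
            missing = [eid for eid in chain if eid not in by_id]
            if missing:
                raise GeneModelError(f"transcript {name} references unknown exons {missing}")
            unann = [eid for eid in chain if not by_id[eid].annotated]
            if unann:
                raise GeneModelError(f"annotated transcript {name} uses novel exons {unann}")
            starts = [by_id[eid].start for eid in chain]
            if starts != sorted(starts):
                raise GeneModelError(f"transcript {name} chain not in genomic order")
        names = [d.name for d in self.domain_defs]
        if len(set(names)) != len(names):
            raise GeneModelError("domain names not unique")

    # -- lookups ---------------------------------------------------------

    @property
    def exons_by_id(self) -> dict[str, Exon]:
        return {e.id: e for e in self.exons}

    @property
    def annotated_exons(self) -> list[Exon]:
        return [e for e in self.exons if e.annotated]

    @property
    def first_exon_ids(self) -> list[str]:
        """Exons that begin at least one annotated transcript chain."""
        firsts = {chain[0] for chain in self.transcripts.values()}
        by_id = self.exons_by_id
        return sorted(firsts, key=lambda i: by_id[i].start)

    @property
    def last_exon_id(self) -> str:
        lasts = {chain[-1] for chain in self.transcripts.values()}
        if len(lasts) != 1:
            raise GeneModelError("transcripts do not share a terminal exon")
        return lasts.pop()

    def donor_sites(self) -> list[int]:
        """Ends of annotated exons that can act as splice donors."""
        last = self.exons_by_id[self.last_exon_id]
        return sorted({e.end for e in self.annotated_exons if e.id != last.id})

    def acceptor_sites(self) -> list[int]:
        firsts = set(self.first_exon_ids)
        return sorted({e.start for e in self.annotated_exons if e.id not in firsts})

    def chain_junctions(self, chain: Sequence[str]) -> list[tuple[int, int]]:
        by_id = self.exons_by_id
        return [
            (by_id[a].end, by_id[b].start)
            for a, b in zip(chain, chain[1:])
        ]

    def annotated_junctions(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for chain in self.transcripts.values():
            out.update(self.chain_junctions(chain))
        return out

    def exon_label(self, eid: str) -> str:
        """Human-readable exon label; alternative first exons are qualified by length."""
        m = re.fullmatch(r"E(\d+)([a-z])", eid)
        if m:
            return f"Exon {m.group(1)} ({self.exons_by_id[eid].length} bp)"
        m = re.fullmatch(r"E(\d+)", eid)
        if m:
            return f"Exon {m.group(1)}"
        return eid

    # -- derived models --------------------------------------------------

    def with_novel_exons(self, novel: Iterable[Exon]) -> "GeneModel":
        """Return a copy with additional (non-annotated) exons registered.

        Re-registering an exon identical to an existing one is a no-op; a
        novel exon whose id collides with a different interval is rejected.
        """
        by_id = self.exons_by_id
        extra = []
        for e in novel:
            have = by_id.get(e.id)
            if have is not None:
                if (have.start, have.end) != (e.start, e.end):
                    raise GeneModelError(
                        f"novel exon {e.id} conflicts with existing interval"
                    )
                continue
            extra.append(replace(e, annotated=False))
        exons = sorted(self.exons + extra, key=lambda e: (e.start, e.end))
        return GeneModel(
            gene=self.gene, contig=self.contig, strand=self.strand,
            exons=exons, transcripts=dict(self.transcripts),
            annotated_start_codon=self.annotated_start_codon,
            annotated_stop_codon=self.annotated_stop_codon,
            alt_start_codons=list(self.alt_start_codons),
            domain_defs=list(self.domain_defs),
        )

    # -- sequence --------------------------------------------------------

    def chain_sequence(self, genome: Mapping[str, str], chain: Sequence[str]) -> str:
        """Spliced cDNA of an exon chain (plus strand; minus strand is flipped)."""
        seq = genome[self.contig]
        by_id = self.exons_by_id
        cdna = "".join(seq[by_id[e].start:by_id[e].end] for e in chain)
        if self.strand == "-":
            cdna = _revcomp(cdna)
        return cdna


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


# ---------------------------------------------------------------------------
# exon naming
# ---------------------------------------------------------------------------

def _assign_exon_ids(
    intervals: list[tuple[int, int]],
    chains: dict[str, list[tuple[int, int]]],
) -> dict[tuple[int, int], str]:
    """Name exons E1..En by genomic order; alternative first exons become E1a, E1b, ...

    Two or more distinct transcript-initial exons are treated as alternative
    first exons of the same ordinal, which is how alternative 5' UTR exons of
    a single-promoter-region gene are conventionally labelled.
    """
    firsts = sorted({c[0] for c in chains.values()})
    rest = sorted(i for i in intervals if i not in set(firsts))
    names: dict[tuple[int, int], str] = {}
    if len(firsts) > 1:
        for k, iv in enumerate(firsts):
            names[iv] = f"E1{chr(ord('a') + k)}"
        for k, iv in enumerate(rest, start=2):
            names[iv] = f"E{k}"
    else:
        for k, iv in enumerate(sorted(intervals), start=1):
            names[iv] = f"E{k}"
    return names


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
]


def _model_from_transcript_blocks(
    gene: str,
    contig: str,
    strand: str,
    chains: dict[str, list[tuple[int, int]]],
    thick: tuple[int, int] | None,
) -> GeneModel:
    intervals = sorted({iv for c in chains.values() for iv in c})
    names = _assign_exon_ids(intervals, chains)
    exons = [Exon(names[iv], contig, iv[0], iv[1]) for iv in intervals]
    transcripts = {t: [names[iv] for iv in c] for t, c in chains.items()}
    start_codon = stop_codon = None
    if thick is not None and thick[0] < thick[1]:
        cds_start, cds_end = thick
        for e in exons:
            if e.start <= cds_start < e.end:
                start_codon = (e.id, cds_start - e.start)
            if e.start < cds_end <= e.end:
                stop_codon = (e.id, cds_end - 3 - e.start)
    return GeneModel(
        gene=gene, contig=contig, strand=strand, exons=exons,
        transcripts=transcripts,
        annotated_start_codon=start_codon,
        annotated_stop_codon=stop_codon,
    )


def _load_bed12(path: Path, gene: str) -> GeneModel:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise GeneModelError(f"{path}: zero transcripts") from None
    if df.shape[1] < 12:
        raise GeneModelError(f"{path}: expected 12 BED columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = _BED12_COLS
    if df.empty:
        raise GeneModelError(f"{path}: zero transcripts")
    contigs, strands = set(df["chrom"]), set(df["strand"])
    if len(contigs) > 1 or len(strands) > 1:
        raise GeneModelError(
            f"{path}: transcripts span multiple contigs/strands "
            f"({sorted(contigs)}, {sorted(strands)})"
        )
    chains: dict[str, list[tuple[int, int]]] = {}
    thick: tuple[int, int] | None = None
    for _, row in df.iterrows():
        start = int(row["start"])
        sizes = [int(x) for x in str(row["block_sizes"]).rstrip(",").split(",")]
        offs = [int(x) for x in str(row["block_starts"]).rstrip(",").split(",")]
        if len(sizes) != int(row["block_count"]) or len(offs) != len(sizes):
            raise GeneModelError(f"{path}: inconsistent block fields for {row['name']}")
        chains[row["name"]] = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
        ts, te = int(row["thick_start"]), int(row["thick_end"])
        if ts < te:
            thick = (ts, te)
    return _model_from_transcript_blocks(gene, df["chrom"].iloc[0], df["strand"].iloc[0], chains, thick)


def write_gene_model_bed12(model: GeneModel, path: str | Path) -> None:
    by_id = model.exons_by_id
    thick = _cds_span(model)
    rows = []
    for name, chain in model.transcripts.items():
        exs = [by_id[e] for e in chain]
        start, end = exs[0].start, exs[-1].end
        ts, te = thick if thick else (start, start)
        rows.append("\t".join(map(str, [
            model.contig, start, end, name, 0, model.strand, ts, te, 0,
            len(exs),
            ",".join(str(e.length) for e in exs) + ",",
            ",".join(str(e.start - start) for e in exs) + ",",
        ])))
    Path(path).write_text("\n".join(rows) + "\n")


def _cds_span(model: GeneModel) -> tuple[int, int] | None:
    if model.annotated_start_codon is None or model.annotated_stop_codon is None:
        return None
    by_id = model.exons_by_id
    se, so = model.annotated_start_codon
    ee, eo = model.annotated_stop_codon
    return (by_id[se].start + so, by_id[ee].start + eo + 3)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def write_gene_model_gtf(model: GeneModel, path: str | Path) -> None:
    """Emit the model as GTF (1-based inclusive coordinates on output)."""
    lines = []
    by_id = model.exons_by_id
    for name, chain in model.transcripts.items():
        exs = [by_id[e] for e in chain]
        tstart, tend = exs[0].start + 1, exs[-1].end
        attrs = f'gene_id "{model.gene}"; transcript_id "{name}";'
        lines.append("\t".join(map(str, [
            model.contig, "nanosplice", "transcript", tstart, tend, ".",
            model.strand, ".", attrs,
        ])))
        for e in exs:
            lines.append("\t".join(map(str, [
                model.contig, "nanosplice", "exon", e.start + 1, e.end, ".",
                model.strand, ".", attrs + f' exon_id "{e.id}";',
            ])))
    thick = _cds_span(model)
    if thick:
        attrs = f'gene_id "{model.gene}"; transcript_id "{next(iter(model.transcripts))}";'
        lines.append("\t".join(map(str, [
            model.contig, "nanosplice", "start_codon", thick[0] + 1, thick[0] + 3,
            ".", model.strand, ".", attrs,
        ])))
        lines.append("\t".join(map(str, [
            model.contig, "nanosplice", "stop_codon", thick[1] - 2, thick[1],
            ".", model.strand, ".", attrs,
        ])))
    Path(path).write_text("\n".join(lines) + "\n")


def _load_gtf(path: Path, gene: str) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    chains: dict[str, list[tuple[int, int]]] = {}
    contigs: set[str] = set()
    strands: set[str] = set()
    thick: tuple[int, int] | None = None
    start_c = stop_c = None
    for feat in db.all_features():
        if feat.featuretype == "exon":
            tid = feat.attributes["transcript_id"][0]
            chains.setdefault(tid, []).append((feat.start - 1, feat.end))
            contigs.add(feat.seqid)
            strands.add(feat.strand)
        elif feat.featuretype == "start_codon":
            start_c = feat.start - 1
        elif feat.featuretype == "stop_codon":
            stop_c = feat.end
    if not chains:
        raise GeneModelError(f"{path}: zero transcripts")
    if len(contigs) > 1 or len(strands) > 1:
        raise GeneModelError(f"{path}: transcripts span multiple contigs/strands")
    for tid in chains:
        chains[tid] = sorted(chains[tid])
    if start_c is not None and stop_c is not None:
        thick = (start_c, stop_c)
    return _model_from_transcript_blocks(gene, contigs.pop(), strands.pop(), chains, thick)


def load_gene_model(path: str | Path, gene: str = "gene", fmt: str | None = None) -> GeneModel:
    """Load a single-gene model from BED12 or GTF.

    The exon set is the union of the transcript blocks, deduplicated by
    coordinates and renamed canonically (``E1a``/``E1b`` for alternative first
    exons, then ``E2``..).  All transcripts must share one contig and strand.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in {".gtf", ".gff"} else "bed12"
    if fmt == "bed12":
        return _load_bed12(path, gene)
    if fmt == "gtf":
        return _load_gtf(path, gene)
    raise GeneModelError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
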