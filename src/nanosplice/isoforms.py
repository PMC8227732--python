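"""Collapse full-length amplicon reads into an exon-chain isoform catalogue.

Because the amplicon's primers sit in the first and last exons, a read that
reaches both termini traverses every exon of its source transcript, so its
exon chain identifies the isoform unambiguously — no abundance deconvolution
is needed.  Reads are filtered for full length, mapped to ordered exon-id
chains, and identical chains are merged with summed support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from nanosplice.gene_model import GeneModel, write_fasta
from nanosplice.junctions import NovelExonCall, ReadChain, novel_exons_to_exons

__all__ = [
    "TranscriptVariant",
    "CatalogueMatch",
    "assemble_variants",
    "match_catalogue",
    "write_catalogue_tsv",
    "write_catalogue_fasta",
]

log = logging.getLogger(__name__)


@dataclass
class TranscriptVariant:
    """A distinct exon chain with read support.

    ``category`` is ``annotated`` for a chain equal to an annotated
    transcript, ``novel_with_cryptic_exon`` when the chain includes a called
    novel exon, and ``novel_known_exons`` otherwise.
    """

    name: str
    chain: list[str]
    support: int
    category: str
    retains_exon2: bool


@dataclass
class CatalogueMatch:
    """Assignment of assembled variants to a reference chain catalogue."""

    assignments: dict[str, str]          # assembled variant name -> reference name
    missed: list[str] = field(default_factory=list)    # reference chains not assembled
    spurious: list[str] = field(default_factory=list)  # assembled chains not in reference


def assemble_variants(
    chains: Sequence[ReadChain],
    junction_table: pd.DataFrame,
    novel_exons: Sequence[NovelExonCall],
    model: GeneModel,
    full_length_window: int = 30,
    min_isoform_support: int = 3,
    exon2_id: str = "E2",
) -> list[TranscriptVariant]:
    """Collapse snapped full-length read chains into transcript variants.

    A read is full-length when its alignment starts within
    ``full_length_window`` nt of a first-exon 5' end and ends within the same
    window of the terminal exon's 3' end.  Reads whose blocks span an intron
    (intron retention) or fall outside every exon are excluded, as are
    variant chains with support below ``min_isoform_support`` or containing a
    junction absent from the (already threshold-filtered) junction table.
    """
    ext = model.with_novel_exons(novel_exons_to_exons(novel_exons, model.contig))
    by_id = ext.exons_by_id
    tree = IntervalTree()
    for e in ext.exons:
        tree[e.start:e.end] = e.id

    first_starts = {by_id[i].start for i in model.first_exon_ids}
    last_end = by_id[model.last_exon_id].end
    allowed = {(int(r["donor"]), int(r["acceptor"])) for _, r in junction_table.iterrows()}
    annotated_chains = {tuple(c) for c in model.transcripts.values()}

    counts: dict[tuple[str, ...], int] = {}
    n_full = 0
    for chain in chains:
        start, end = chain.blocks[0][0], chain.blocks[-1][1]
        if not any(abs(start - s) <= full_length_window for s in first_starts):
            continue
        if abs(end - last_end) > full_length_window:
            continue
        n_full += 1
        ids = []
        ok = True
        for b in chain.blocks:
            hits = sorted(tree.overlap(b[0], b[1]), key=lambda iv: iv.begin)
            if len(hits) != 1:  # intron retention or unassignable block
                ok = False
                break
            ids.append(hits[0].data)
        if not ok or len(set(ids)) != len(ids):
            continue
        key = tuple(ids)
        counts[key] = counts.get(key, 0) + 1

    if n_full == 0:
        log.warning("no full-length reads; catalogue is empty")

    variants: list[TranscriptVariant] = []
    for key, support in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if support < min_isoform_support:
            continue
        junctions = ext.chain_junctions(list(key))
        if any(j not in allowed for j in junctions):
            continue
        if key in annotated_chains:
            category = "annotated"
        elif any(not by_id[i].annotated for i in key):
            category = "novel_with_cryptic_exon"
        else:
            category = "novel_known_exons"
        variants.append(TranscriptVariant(
            name=f"asm_{len(variants) + 1:02d}",
            chain=list(key),
            support=support,
            category=category,
            retains_exon2=exon2_id in key,
        ))
    return variants


def match_catalogue(
    variants: Sequence[TranscriptVariant],
    reference: Mapping[str, Sequence[str]],
) -> CatalogueMatch:
    """Label each assembled variant with the reference chain it equals.

    Raises on duplicate chains in the reference.  The assignment depends
    only on chain content, not on variant order.
    """
    seen: dict[tuple[str, ...], str] = {}
    for name, chain in reference.items():
        key = tuple(chain)
        if key in seen:
            raise ValueError(f"duplicate reference chains: {seen[key]} and {name}")
        seen[key] = name

    assignments: dict[str, str] = {}
    found: set[str] = set()
    spurious: list[str] = []
    for v in variants:
        ref = seen.get(tuple(v.chain))
        if ref is None:
            assignments[v.name] = "unassigned"
            spurious.append(v.name)
        else:
            assignments[v.name] = ref
            found.add(ref)
    missed = [n for n in reference if n not in found]
    return CatalogueMatch(assignments=assignments, missed=missed, spurious=spurious)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_catalogue_tsv(
    variants: Sequence[TranscriptVariant], path: str | Path,
    match: CatalogueMatch | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchain\tsupport\tcategory\tretains_exon2\tassigned\n")
        for v in variants:
            assigned = match.assignments.get(v.name, "") if match else ""
            fh.write("\t".join(map(str, [
                v.name, ",".join(v.chain), v.support, v.category,
                int(v.retains_exon2), assigned,
            ])) + "\n")


def write_catalogue_fasta(
    variants: Sequence[TranscriptVariant],
    model: GeneModel,
    genome: Mapping[str, str],
    path: str | Path,
) -> None:
    """Spliced cDNA of each assembled variant."""
    write_fasta({v.name: model.chain_sequence(genome, v.chain) for v in variants}, path)


def variants_as_gene_model(
    variants: Sequence[TranscriptVariant], model: GeneModel
) -> GeneModel:
    """Assembled catalogue as a GeneModel, for BED12/GTF emission.

    Called novel exons become first-class exons of the emitted catalogue.
    """
    from dataclasses import replace

    if not variants:
        return model
    used = {e for v in variants for e in v.chain}
    return GeneModel(
        gene=model.gene, contig=model.contig, strand=model.strand,
        exons=[replace(e, annotated=True) for e in model.exons if e.id in used],
        transcripts={v.name: list(v.chain) for v in variants},
        annotated_start_codon=(
            model.annotated_start_codon
            if model.annotated_start_codon and model.annotated_start_codon[0] in used
            else None
        ),
        annotated_stop_codon=(
            model.annotated_stop_codon
            if model.annotated_stop_codon and model.annotated_stop_codon[0] in used
            else None
        ),
    )
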