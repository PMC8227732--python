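#!/usr/bin/env python
"""Build the synthetic ELF3-like locus and write its reference bundle.

Outputs (results/reference/): the genome FASTA, the gene model as BED12 and
GTF, the 27-transcript reference catalogue and the domain definitions.
"""

from common import RESULTS, locus

from nanosplice.fixture import fixture_catalogue
from nanosplice.gene_model import write_fasta, write_gene_model_bed12, write_gene_model_gtf

out = RESULTS / "reference"
out.mkdir(parents=True, exist_ok=True)

model, genome = locus()
write_fasta(genome, out / "genome.fasta")
write_gene_model_bed12(model, out / "annotation.bed12")
write_gene_model_gtf(model, out / "annotation.gtf")

catalogue = fixture_catalogue()
with open(out / "reference_catalogue.tsv", "w") as fh:
    fh.write("name\tchain\n")
    for name, chain in catalogue.items():
        fh.write(f"{name}\t{','.join(chain)}\n")

with open(out / "domain_definitions.tsv", "w") as fh:
    fh.write("domain\taa_start\taa_end\n")
    for d in model.domain_defs:
        fh.write(f"{d.name}\t{d.aa_start}\t{d.aa_end}\n")

contig = model.contig
print(f"locus: contig {contig}, {len(genome[contig])} nt, "
      f"{len(model.annotated_exons)} annotated exons + 2 reserved cryptic loci")
print(f"reference catalogue: {len(catalogue)} transcript structures "
      f"({sum(1 for n in catalogue if n not in ('v.1', 'v.2'))} novel)")
print(f"wrote reference bundle to {out}")
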