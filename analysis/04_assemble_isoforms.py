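#!/usr/bin/env python
"""Collapse full-length reads into the transcript-variant catalogue.

Writes results/catalogue.tsv with each assembled chain, its read support,
category and the reference variant it matches.
"""

from common import RESULTS, snapped_chains

from nanosplice.fixture import fixture_catalogue
from nanosplice.isoforms import assemble_variants, match_catalogue, write_catalogue_tsv
from nanosplice.junctions import discover_novel_exons, tabulate_junctions

model, genome, chains = snapped_chains()
table = tabulate_junctions(chains, model)
calls = discover_novel_exons(chains, model)
variants = assemble_variants(chains, table, calls, model)
match = match_catalogue(variants, fixture_catalogue())
for v in variants:
    if match.assignments.get(v.name, "unassigned") != "unassigned":
        v.name = match.assignments[v.name]

RESULTS.mkdir(parents=True, exist_ok=True)
write_catalogue_tsv(variants, RESULTS / "catalogue.tsv", match)

n_novel = sum(v.category != "annotated" for v in variants)
print(f"assembled {len(variants)} distinct exon chains "
      f"({n_novel} novel, {len(variants) - n_novel} annotated)")
print(f"unmatched reference chains: {match.missed or 'none'}; "
      f"spurious assemblies: {match.spurious or 'none'}")
print(f"wrote {RESULTS / 'catalogue.tsv'}")
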