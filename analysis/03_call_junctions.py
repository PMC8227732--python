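#!/usr/bin/env python
"""Call splice junctions and cryptic exons from the simulated alignments.

Writes results/junctions.tsv (label, coordinates, status, support) and
results/novel_exons.tsv, and reports the annotated/novel/cryptic breakdown.
"""

import pandas as pd

from common import RESULTS, snapped_chains

from nanosplice.junctions import discover_novel_exons, tabulate_junctions

model, genome, chains = snapped_chains()
table = tabulate_junctions(chains, model)
calls = discover_novel_exons(chains, model)

RESULTS.mkdir(parents=True, exist_ok=True)
table.to_csv(RESULTS / "junctions.tsv", sep="\t", index=False)
pd.DataFrame(
    [(c.exon_id, c.start, c.end, c.length, c.flank_left, c.flank_right, c.support)
     for c in calls],
    columns=["exon_id", "start", "end", "length", "flank_left", "flank_right", "support"],
).to_csv(RESULTS / "novel_exons.tsv", sep="\t", index=False)

by_status = table["status"].value_counts()
print(f"junction table: {len(table)} rows — "
      f"{by_status.get('annotated', 0)} annotated, "
      f"{by_status.get('novel_combination', 0)} novel combinations of annotated sites, "
      f"{by_status.get('cryptic', 0)} cryptic")
for c in calls:
    print(f"novel exon {c.exon_id}: {c.length} nt between {c.flank_left} and "
          f"{c.flank_right} ({c.support} supporting reads)")
print(f"wrote {RESULTS / 'junctions.tsv'} and {RESULTS / 'novel_exons.tsv'}")
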