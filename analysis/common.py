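"""Shared setup for the numbered analysis scripts.

All scripts work from one deterministic dataset: the synthetic ELF3-like
locus (seed 1) and a 20,000-read simulation of the full 27-transcript
catalogue at default nanopore-like error rates (seed 2).  The bulky read
files live under scratch/ and are regenerated on demand; the tables the
scripts derive from them go to results/.
"""

from __future__ import annotations

from pathlib import Path

from nanosplice.fixture import catalogue_mixture, elf3_fixture, fixture_catalogue
from nanosplice.junctions import extract_read_chains, snap_junctions
from nanosplice.simulate import (
    SimConfig,
    emit_oracle_alignments,
    simulate_reads,
    write_fastq,
    write_truth_table,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

FIXTURE_SEED = 1
SIM_SEED = 2
N_READS = 20000


def locus():
    return elf3_fixture(seed=FIXTURE_SEED)


def sim_config():
    catalogue = fixture_catalogue()
    mixture = {n: (catalogue[n], w) for n, w in catalogue_mixture().items()}
    return SimConfig(mixture=mixture, n_reads=N_READS, seed=SIM_SEED)


def ensure_simulation():
    """Simulate (or reuse) the catalogue read set; returns (model, genome, sam path)."""
    model, genome = locus()
    sam = SCRATCH / "alignments.sam"
    if not sam.exists():
        SCRATCH.mkdir(parents=True, exist_ok=True)
        reads = simulate_reads(model, genome, sim_config())
        write_fastq(reads, SCRATCH / "reads.fastq")
        write_truth_table(reads, SCRATCH / "truth.tsv")
        emit_oracle_alignments(reads, model, genome, sam)
    return model, genome, sam


def snapped_chains():
    model, genome, sam = ensure_simulation()
    chains = snap_junctions(extract_read_chains(sam), model, w=12, genome=genome)
    return model, genome, chains
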