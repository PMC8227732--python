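"""Shared fixtures: the synthetic locus and a few reusable simulations."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pytest

from nanosplice.fixture import elf3_fixture, fixture_catalogue
from nanosplice.junctions import (
    discover_novel_exons,
    extract_read_chains,
    snap_junctions,
    tabulate_junctions,
)
from nanosplice.simulate import SimConfig, emit_oracle_alignments, simulate_reads

FIXTURE_SEED = 11


@dataclass
class Run:
    """A simulation together with its downstream junction analysis."""

    reads: list
    sam_path: str
    chains: list
    table: object
    novel_exons: list
    truth_counts: Counter


@pytest.fixture(scope="session")
def locus():
    model, genome = elf3_fixture(seed=FIXTURE_SEED)
    return model, genome


@pytest.fixture(scope="session")
def catalogue():
    return fixture_catalogue()


def make_run(model, genome, mixture, n_reads, tmp_path, seed, **err) -> Run:
    cfg = SimConfig(mixture=mixture, n_reads=n_reads, seed=seed, **err)
    reads = simulate_reads(model, genome, cfg)
    sam = str(tmp_path / "alignments.sam")
    emit_oracle_alignments(reads, model, genome, sam)
    chains = snap_junctions(extract_read_chains(sam), model, w=12, genome=genome)
    table = tabulate_junctions(chains, model)
    calls = discover_novel_exons(chains, model)
    return Run(
        reads=reads,
        sam_path=sam,
        chains=chains,
        table=table,
        novel_exons=calls,
        truth_counts=Counter(r.transcript for r in reads),
    )


@pytest.fixture(scope="session")
def noiseless_run(locus, catalogue, tmp_path_factory) -> Run:
    """540 error-free reads, all 27 catalogue transcripts equally weighted."""
    model, genome = locus
    mixture = {n: (c, 1.0) for n, c in catalogue.items()}
    return make_run(
        model, genome, mixture, 540, tmp_path_factory.mktemp("noiseless"),
        seed=5, p_sub=0.0, p_ins=0.0, p_del=0.0,
    )


@pytest.fixture(scope="session")
def noisy_run(locus, catalogue, tmp_path_factory) -> Run:
    """1620 reads at default nanopore-like error rates, equal weights."""
    model, genome = locus
    mixture = {n: (c, 1.0) for n, c in catalogue.items()}
    return make_run(model, genome, mixture, 1620, tmp_path_factory.mktemp("noisy"), seed=6)
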