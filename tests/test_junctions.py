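"""Junction extraction, snapping, tabulation and cryptic exon discovery."""

from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosplice.gene_model import Exon, GeneModel
from nanosplice.junctions import (
    ReadChain,
    discover_novel_exons,
    extract_read_chains,
    snap_junctions,
    tabulate_junctions,
)
from conftest import make_run

# Novel junction pairs expected from the full catalogue: both splice sites
# annotated, pair absent from the two annotated transcripts.
NOVEL_JUNCTION_LABELS = {
    "Exon 1 (120 bp)-Exon 3", "Exon 1 (120 bp)-Exon 4", "Exon 1 (120 bp)-Exon 5",
    "Exon 1 (120 bp)-Exon 7", "Exon 1 (120 bp)-Exon 8", "Exon 1 (234 bp)-Exon 3",
    "Exon 2-Exon 4", "Exon 2-Exon 8", "Exon 2-Exon 9",
    "Exon 3-Exon 5", "Exon 3-Exon 7", "Exon 3-Exon 8",
    "Exon 4-Exon 8", "Exon 5-Exon 7", "Exon 7-Exon 9",
}
ANNOTATED_JUNCTION_LABELS = {
    "Exon 1 (120 bp)-Exon 2", "Exon 1 (234 bp)-Exon 2", "Exon 2-Exon 3",
    "Exon 3-Exon 4", "Exon 4-Exon 5", "Exon 5-Exon 6", "Exon 6-Exon 7",
    "Exon 7-Exon 8", "Exon 8-Exon 9",
}


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _sam(tmp_path, body, ln=10000):
    path = tmp_path / "mini.sam"
    path.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:%d\n%s" % (ln, body))
    return path


def test_gapped_op_yields_one_junction(tmp_path):
    body = "r1\t0\tchr1\t101\t60\t100M500N80M\t*\t0\t0\t%s\t*\n" % ("A" * 180)
    chains = extract_read_chains(_sam(tmp_path, body))
    assert len(chains) == 1
    assert chains[0].blocks == [(100, 200), (700, 780)]
    assert chains[0].junctions == [(200, 700)]


def test_deletions_do_not_create_junctions(tmp_path):
    body = "r1\t0\tchr1\t101\t60\t50M5D50M\t*\t0\t0\t%s\t*\n" % ("A" * 100)
    chains = extract_read_chains(_sam(tmp_path, body))
    assert chains[0].junctions == []
    assert chains[0].blocks == [(100, 205)]


def test_secondary_supplementary_unmapped_skipped(tmp_path):
    rows = "".join(
        f"r{i}\t{flag}\tchr1\t101\t60\t10M\t*\t0\t0\t{'A' * 10}\t*\n"
        for i, flag in enumerate([0, 256, 2048])
    ) + "r9\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
    chains = extract_read_chains(_sam(tmp_path, rows))
    assert [c.read_id for c in chains] == ["r0"]


def test_unmapped_only_gives_empty_result(tmp_path):
    chains = extract_read_chains(_sam(tmp_path, "r9\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"))
    assert chains == []


def test_missing_header_rejected(tmp_path):
    path = tmp_path / "naked.sam"
    path.write_text("r1\t0\tchr1\t101\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n")
    with pytest.raises(ValueError, match="header|no sequences"):
        extract_read_chains(path)


# ---------------------------------------------------------------------------
# snapping
# ---------------------------------------------------------------------------

def _true_junctions(model, chain_ids):
    by = model.exons_by_id
    return [(by[a].end, by[b].start) for a, b in zip(chain_ids, chain_ids[1:])]


def test_snap_is_fixed_point_on_exact_junctions(locus, catalogue):
    model, _ = locus
    blocks = []
    pos_pairs = _true_junctions(model, catalogue["v.1"])
    by = model.exons_by_id
    blocks = [(by[e].start, by[e].end) for e in catalogue["v.1"]]
    chain = ReadChain("r", blocks)
    snapped = snap_junctions([chain], model, w=12)[0]
    assert snapped.blocks == blocks
    assert snapped.junctions == pos_pairs


@settings(derandomize=True, max_examples=60)
@given(dd=st.integers(-12, 12), da=st.integers(-12, 12))
def test_snap_recovers_any_displacement_within_window(locus, catalogue, dd, da):
    model, _ = locus
    by = model.exons_by_id
    blocks = [(by[e].start, by[e].end) for e in catalogue["v.1"]]
    i = 3  # displace the E4-E5 junction
    noisy = list(blocks)
    noisy[i] = (noisy[i][0], noisy[i][1] + dd)
    noisy[i + 1] = (noisy[i + 1][0] + da, noisy[i + 1][1])
    snapped = snap_junctions([ReadChain("r", noisy)], model, w=12)[0]
    assert snapped.blocks == blocks


def test_displacement_beyond_window_left_untouched(locus, catalogue):
    model, _ = locus
    by = model.exons_by_id
    blocks = [(by[e].start, by[e].end) for e in catalogue["v.1"]]
    noisy = list(blocks)
    noisy[3] = (noisy[3][0], noisy[3][1] + 40)
    snapped = snap_junctions([ReadChain("r", noisy)], model, w=12)[0]
    assert snapped.blocks[3][1] == blocks[3][1] + 40


@pytest.mark.parametrize("gt_at, expected_donor", [(20, 20), (24, 24)])
def test_equidistant_donors_resolved_toward_gt_ag(gt_at, expected_donor):
    """Two annotated donors 4 nt apart; the junction is equidistant, so the
    donor whose intron starts with GT (ending AG) must win the tie."""
    model = GeneModel(
        gene="g", contig="m", strand="+",
        exons=[Exon("A1", "m", 0, 20), Exon("A2", "m", 0, 24), Exon("B", "m", 40, 60)],
        transcripts={"t1": ["A1", "B"], "t2": ["A2", "B"]},
    )
    seq = ["C"] * 60
    seq[gt_at:gt_at + 2] = "GT"
    seq[38:40] = "AG"
    genome = {"m": "".join(seq)}
    chain = ReadChain("r", [(0, 22), (50, 60)])
    snapped = snap_junctions([chain], model, w=12, genome=genome)[0]
    assert snapped.junctions == [(expected_donor, 40)]


def test_snapping_exact_on_noiseless_and_near_exact_on_noisy(noiseless_run, noisy_run, locus):
    model, _ = locus
    by = model.exons_by_id
    for run, required in ((noiseless_run, 1.0), (noisy_run, 0.99)):
        truth = {
            r.read_id: set(_true_junctions(model, r.chain)) for r in run.reads
        }
        total = exact = 0
        for chain in run.chains:
            expected = truth[chain.read_id]
            for j in chain.junctions:
                total += 1
                exact += j in expected
        assert total > 0
        assert exact / total >= required


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def test_annotated_only_reads_give_annotated_rows(locus, catalogue, tmp_path):
    model, genome = locus
    run = make_run(
        model, genome,
        {n: (catalogue[n], 1.0) for n in ("v.1", "v.2")},
        200, tmp_path, seed=21,
    )
    assert set(run.table["status"]) == {"annotated"}
    assert set(run.table["label"]) == ANNOTATED_JUNCTION_LABELS


def test_skipping_chain_yields_novel_combination_row(locus, catalogue, tmp_path):
    model, genome = locus
    run = make_run(
        model, genome,
        {"v.1": (catalogue["v.1"], 0.7), "v.3": (catalogue["v.3"], 0.3)},
        200, tmp_path, seed=22,
    )
    row = run.table[run.table["label"] == "Exon 5-Exon 7"]
    assert len(row) == 1
    assert row["status"].iloc[0] == "novel_combination"


def test_full_catalogue_yields_the_fifteen_novel_junctions(noisy_run):
    novel = noisy_run.table[noisy_run.table["status"] == "novel_combination"]
    assert set(novel["label"]) == NOVEL_JUNCTION_LABELS


def test_support_conservation_on_noiseless_reads(noiseless_run, locus):
    model, _ = locus
    expected = Counter()
    for r in noiseless_run.reads:
        for j in _true_junctions(model, r.chain):
            expected[j] += 1
    table = tabulate_junctions(noiseless_run.chains, model, min_support=1, min_fraction=0)
    observed = {
        (int(r["donor"]), int(r["acceptor"])): int(r["support"])
        for _, r in table.iterrows()
    }
    assert observed == {j: n for j, n in expected.items()}


def test_raising_min_support_only_removes_rows(noisy_run, locus):
    model, _ = locus
    previous = None
    for threshold in (1, 3, 10, 50, 200, 1000):
        table = tabulate_junctions(noisy_run.chains, model, min_support=threshold)
        rows = {(int(r["donor"]), int(r["acceptor"])) for _, r in table.iterrows()}
        if previous is not None:
            assert rows <= previous
        previous = rows


# ---------------------------------------------------------------------------
# novel exons
# ---------------------------------------------------------------------------

def test_n1_recovered_at_exact_boundaries(locus, catalogue, tmp_path):
    model, genome = locus
    run = make_run(
        model, genome, {"v.15": (catalogue["v.15"], 1.0)}, 100, tmp_path,
        seed=23, p_sub=0.0, p_ins=0.0, p_del=0.0,
    )
    calls = discover_novel_exons(run.chains, model, min_support=1)
    assert len(calls) == 1
    call = calls[0]
    assert (call.length, call.flank_left, call.flank_right) == (156, "E7", "E8")
    assert (call.start, call.end) == (
        model.exons_by_id["N1"].start, model.exons_by_id["N1"].end,
    )


def test_n2_recovered_from_v14_reads(locus, catalogue, tmp_path):
    model, genome = locus
    run = make_run(
        model, genome, {"v.14": (catalogue["v.14"], 1.0)}, 100, tmp_path, seed=24,
    )
    calls = discover_novel_exons(run.chains, model)
    assert [(c.length, c.flank_left, c.flank_right) for c in calls] == [(92, "E8", "E9")]


def test_annotated_reads_give_no_novel_exons(noiseless_run, locus):
    model, _ = locus
    only_annotated = [
        c for c, r in zip(noiseless_run.chains, noiseless_run.reads)
        if not any(e.startswith("N") for e in r.chain)
    ]
    assert discover_novel_exons(only_annotated, model) == []
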