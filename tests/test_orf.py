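"""ORF calling, premature-stop / NMD classification and domain presence.

The expected protein lengths and domain patterns below are the engineered
values of the synthetic locus, which mirror the text-determined properties
of the corresponding human ELF3 variants (reference 371 aa; exon-6 skip
341 aa; exon-4 skip 340 aa; the N2 frameshift isoform 476 aa; etc.).
"""

from __future__ import annotations

import pytest

from nanosplice.orf import (
    Anchor,
    StartAnchors,
    classify_nmd,
    derive_anchors,
    domain_presence,
    predict_orf,
    reference_protein,
)

DOMAINS = ["PNT", "TAD", "SAR", "AT_hook", "ETS"]

# variant -> (start origin, protein aa)
EXPECTED_ORFS = {
    "v.1": ("annotated_exon2", 371),
    "v.3": ("annotated_exon2", 341),
    "v.4": ("annotated_exon2", 340),
    "v.5": ("annotated_exon2", 297),
    "v.7": ("annotated_exon2", 340),
    "v.8": ("annotated_exon2", 310),
    "v.10": ("annotated_exon2", 262),
    "v.14": ("annotated_exon2", 476),
    "v.16": ("alt_exon3", 311),
    "v.17": ("alt_exon3", 311),
    "v.24": ("alt_exon4", 232),
}

# domain-presence pattern (PNT, TAD, SAR, AT_hook, ETS) per variant; these
# are the rows whose exon chains are fully determined by the variant
# descriptions, plus the two annotated isoforms.
EXPECTED_DOMAINS = {
    "v.1": (1, 1, 1, 1, 1),
    "v.2": (1, 1, 1, 1, 1),
    "v.3": (1, 1, 0, 1, 1),
    "v.4": (1, 0, 1, 1, 1),
    "v.5": (0, 1, 1, 1, 1),
    "v.6": (1, 1, 1, 1, 0),
    "v.7": (1, 0, 1, 1, 1),
    "v.8": (1, 0, 0, 1, 1),
    "v.9": (1, 0, 1, 1, 0),
    "v.14": (1, 1, 1, 1, 0),
    "v.16": (0, 1, 1, 1, 1),
    "v.17": (0, 1, 1, 1, 1),
    "v.18": (0, 0, 1, 1, 1),
    "v.19": (0, 1, 0, 1, 1),
}

# exons whose coding sequence carries each domain in the synthetic locus
DOMAIN_EXONS = {
    "PNT": {"E2", "E3"},
    "TAD": {"E4"},
    "SAR": {"E6"},
    "AT_hook": {"E7"},
    "ETS": {"E8", "E9"},
}


@pytest.fixture(scope="module")
def anchors(locus):
    model, genome = locus
    return derive_anchors(model, genome)


@pytest.fixture(scope="module")
def cdnas(locus, catalogue):
    model, genome = locus
    return {n: model.chain_sequence(genome, c) for n, c in catalogue.items()}


@pytest.fixture(scope="module")
def ref_protein(locus):
    model, genome = locus
    return reference_protein(model, genome)


@pytest.mark.parametrize("variant", sorted(EXPECTED_ORFS))
def test_predicted_start_origin_and_protein_length(anchors, cdnas, variant):
    origin, aa = EXPECTED_ORFS[variant]
    orf = predict_orf(cdnas[variant], anchors, variant=variant)
    assert orf.has_orf
    assert orf.start_origin == origin
    assert orf.protein_length == aa
    assert (orf.stop - orf.start) % 3 == 0
    assert orf.protein_length == (orf.stop - orf.start) // 3 - 1


def test_cdna_without_atg_has_no_orf(anchors, cdnas):
    # v.25-v.27 lack every start-codon-bearing exon, and the locus plants no
    # other ATG, so the scan finds nothing
    for variant in ("v.25", "v.26", "v.27"):
        orf = predict_orf(cdnas[variant], anchors, variant=variant)
        assert orf.start_origin == "none" and not orf.has_orf
    plain = predict_orf("CCGA" * 40, anchors)
    assert not plain.has_orf


def test_anchor_found_despite_one_mismatch(anchors, cdnas):
    cdna = cdnas["v.1"]
    exact = predict_orf(cdna, anchors, variant="v.1")
    # corrupt one base in the anchor context upstream of the ATG
    p = exact.start - 10
    mutated = cdna[:p] + ("C" if cdna[p] != "C" else "G") + cdna[p + 1:]
    orf = predict_orf(mutated, anchors, variant="v.1")
    assert orf.start_origin == "annotated_exon2"
    assert orf.protein_length == exact.protein_length


def test_scan_refinds_the_annotated_orf(anchors, cdnas):
    """With anchors disabled, the longest-ORF scan lands on the same start
    and stop as the anchored call (idempotence of the two routes)."""
    blind = StartAnchors(
        annotated=Anchor("annotated_exon2", "X" * 40, 20),
        alternatives=[],
        stop=anchors.stop,
    )
    anchored = predict_orf(cdnas["v.1"], anchors)
    scanned = predict_orf(cdnas["v.1"], blind)
    assert scanned.start_origin == "scan"
    assert (scanned.start, scanned.stop) == (anchored.start, anchored.stop)


class TestPtcAndNmd:
    def test_n1_insertion_creates_ptc_and_nmd_candidate(self, locus, catalogue, anchors, cdnas):
        model, _ = locus
        orf = predict_orf(cdnas["v.15"], anchors, variant="v.15")
        assert orf.has_orf and orf.ptc
        orf = classify_nmd(orf, catalogue["v.15"], model)
        assert orf.nmd_candidate

    def test_stop_in_final_exon_is_never_nmd(self, locus, catalogue, anchors, cdnas):
        model, _ = locus
        for variant in ("v.6", "v.14"):  # both terminate inside E9
            orf = predict_orf(cdnas[variant], anchors, variant=variant)
            assert not orf.ptc
            orf = classify_nmd(orf, catalogue[variant], model)
            assert not orf.nmd_candidate

    @pytest.mark.parametrize("gap, expected", [(51, True), (50, False), (0, False)])
    def test_last_junction_distance_rule_is_strict(self, locus, catalogue, anchors, cdnas, gap, expected):
        """A stop exactly d_nmd nt upstream of the last junction is not a
        candidate; one nt further upstream is."""
        model, _ = locus
        chain = catalogue["v.15"]
        orf = predict_orf(cdnas["v.15"], anchors, variant="v.15")
        by = model.exons_by_id
        last_junction = sum(by[e].length for e in chain[:-1])
        orf.stop = last_junction - gap
        orf = classify_nmd(orf, chain, model, d_nmd=50)
        assert orf.nmd_candidate is expected

    def test_catalogue_coding_and_noncoding_counts(self, locus, catalogue, anchors, cdnas):
        """21 of the 25 novel chains are protein-coding; four are non-coding
        (one via a premature stop triggering NMD, three lacking any ORF)."""
        model, _ = locus
        coding = non_coding = 0
        for name, chain in catalogue.items():
            if name in ("v.1", "v.2"):
                continue
            orf = classify_nmd(
                predict_orf(cdnas[name], anchors, variant=name), chain, model
            )
            if orf.has_orf and not orf.nmd_candidate:
                coding += 1
            else:
                non_coding += 1
        assert (coding, non_coding) == (21, 4)


class TestDomainPresence:
    @pytest.mark.parametrize("variant", sorted(EXPECTED_DOMAINS))
    def test_text_determined_patterns(self, locus, anchors, cdnas, ref_protein, variant):
        model, _ = locus
        orf = predict_orf(cdnas[variant], anchors, variant=variant)
        dp = domain_presence(orf.protein, ref_protein, model.domain_defs, variant)
        assert tuple(int(dp.presence[d]) for d in DOMAINS) == EXPECTED_DOMAINS[variant]

    def test_empty_protein_has_no_domains(self, locus, ref_protein):
        model, _ = locus
        dp = domain_presence("", ref_protein, model.domain_defs)
        assert set(dp.presence) == set(DOMAINS)
        assert not any(dp.presence.values())

    def test_domain_presence_implies_coding_exons_in_chain(
        self, locus, catalogue, anchors, cdnas, ref_protein
    ):
        model, _ = locus
        for name, chain in catalogue.items():
            orf = predict_orf(cdnas[name], anchors, variant=name)
            dp = domain_presence(orf.protein, ref_protein, model.domain_defs, name)
            for domain, present in dp.presence.items():
                if present:
                    assert DOMAIN_EXONS[domain] <= set(chain), (name, domain)
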