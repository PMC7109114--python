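import itertools
import os.path
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsascan.sequence_effect import (
    CONSEQ_FRAMESHIFT,
    CONSEQ_INFRAME,
    CONSEQ_MISSENSE,
    CONSEQ_NONCODING,
    apply_interval_deletion,
    classify_clone_haplotypes,
    effect_report,
    fpkm,
    translate_orf,
)
from bsascan.synthetic_data import make_causal_cds
from bsascan.variant_io import ValidationError

NONSTOP = [c for c in ("".join(b) for b in itertools.product("ACGT", repeat=3))
           if c not in ("TAA", "TAG", "TGA")]


def random_orf(rng, n_codons):
    """ATG + random non-stop codons + TAA."""
    body = [rng.choice(NONSTOP) for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def test_apply_interval_deletion_examples():
    seq = "ABCDEFGHIJ"
    assert apply_interval_deletion(seq, 3, 5) == "ABFGHIJ"
    assert apply_interval_deletion(seq, 4, 4) == "ABCEFGHIJ"
    # inverse: re-inserting the removed substring restores the original
    removed = seq[2:5]
    cut = apply_interval_deletion(seq, 3, 5)
    assert cut[:2] + removed + cut[2:] == seq
    with pytest.raises(ValidationError):
        apply_interval_deletion(seq, 0, 3)
    with pytest.raises(ValidationError):
        apply_interval_deletion(seq, 5, 11)


def test_deletion_interval_length():
    seq = "A" * 720
    assert len(seq) - len(apply_interval_deletion(seq, 568, 581)) == 14


@pytest.mark.parametrize(
    "cds,protein,stop",
    [("ATGTAA", "M", True), ("ATGAAATAG", "MK", True), ("ATGAAA", "MK", False),
     ("AT", "", False)],
)
def test_translate_orf_examples(cds, protein, stop):
    assert translate_orf(cds) == (protein, stop)


def test_720nt_orf_translates_to_239aa():
    rng = random.Random(42)
    orf = random_orf(rng, 240)
    assert len(orf) == 720
    protein, stop = translate_orf(orf)
    assert stop and len(protein) == 239


def test_causal_cds_effect_report():
    """The engineered candidate CDS: 720 nt / 239 aa wild type; the 14-nt
    deletion at 568..581 frameshifts, truncating to 205 aa with a 189-aa
    shared prefix (= floor((568-1)/3)); domains beyond aa 189 are lost."""
    cds = make_causal_cds(np.random.default_rng(0))
    domains = [("B-box 1", 6, 48), ("VP", 217, 222), ("NLS", 225, 239)]
    rep = effect_report(cds, (568, 581), domains)
    assert rep.consequence == CONSEQ_FRAMESHIFT
    assert rep.wt_length_aa == 239
    assert rep.mut_length_aa == 205
    assert rep.shared_prefix_aa == 189 == (568 - 1) // 3
    assert rep.lost_domains == ("VP", "NLS")


def test_effect_report_outside_cds():
    rep = effect_report("ATGAAATAA", None)
    assert rep.consequence == CONSEQ_NONCODING
    assert rep.wt_length_aa == rep.mut_length_aa


def test_effect_report_missense():
    rep = effect_report("ATGAAATAA", None, mut_cds="ATGACATAA")
    assert rep.consequence == CONSEQ_MISSENSE
    assert rep.shared_prefix_aa == 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_inframe_codon_deletion_law(data):
    """Deleting k whole codons (no stop created) is in-frame and shortens the
    protein by exactly k."""
    rng = random.Random(data.draw(st.integers(0, 10_000)))
    n_codons = data.draw(st.integers(10, 60))
    orf = random_orf(rng, n_codons)
    k = data.draw(st.integers(1, 4))
    first = data.draw(st.integers(2, n_codons - 1 - k))  # keep ATG and stop
    start = (first - 1) * 3 + 1
    end = start + 3 * k - 1
    rep = effect_report(orf, (start, end))
    assert rep.consequence == CONSEQ_INFRAME
    assert rep.mut_length_aa == rep.wt_length_aa - k


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_frameshift_shared_prefix_law(data):
    """Whenever the first frameshifted codon changes the amino acid, the
    shared prefix is floor((deletion_start - 1)/3).  Oracle: direct
    translation comparison."""
    rng = random.Random(data.draw(st.integers(0, 10_000)))
    n_codons = data.draw(st.integers(20, 80))
    orf = random_orf(rng, n_codons)
    start = data.draw(st.integers(4, 3 * (n_codons - 5)))
    length = data.draw(st.sampled_from([1, 2, 4, 5, 14]))
    end = start + length - 1
    rep = effect_report(orf, (start, end))
    wt_protein, _ = translate_orf(orf)
    mut_protein, _ = translate_orf(apply_interval_deletion(orf, start, end))
    expected_prefix = len(os.path.commonprefix([wt_protein, mut_protein]))
    assert rep.shared_prefix_aa == expected_prefix
    # the frameshift cannot preserve anything before the first shifted codon
    assert rep.shared_prefix_aa >= (start - 1) // 3


def test_clone_classification_matches_reported_percentages():
    rng = random.Random(1)
    reference = "".join(rng.choice("ACGT") for _ in range(140))
    deletion = (61, 74)  # 14 nt
    full_read = reference
    del_read = reference[:60] + reference[74:]
    reads = [full_read] * 29 + [del_read] * 39
    counts = classify_clone_haplotypes(reads, reference, deletion)
    assert (counts.full, counts.deleted) == (29, 39)
    assert counts.pct_full == 42.65
    assert counts.pct_deleted == 57.35


def test_clone_classification_edge_cases():
    reference = "ACGTACGTACGTACGTACGT"
    deletion = (9, 11)
    full = reference
    non_spanning = "TTTTTTT"
    counts = classify_clone_haplotypes([full, full, non_spanning], reference, deletion)
    assert counts.full == 2 and counts.unclassified == 1
    assert counts.pct_full == 100.0
    counts2 = classify_clone_haplotypes(
        [full, reference[:8] + reference[11:], reference[:8] + reference[11:]],
        reference, deletion,
    )
    assert counts2.pct_full == 33.33


def test_amplicon_size_discrepancy_equals_deletion_length():
    """Full- and del-type amplicons differ by exactly the deletion length."""
    rng = random.Random(5)
    reference = "".join(rng.choice("ACGT") for _ in range(400))
    start, end = 200, 213
    del_amplicon = reference[: start - 1] + reference[end:]
    assert len(reference) - len(del_amplicon) == 14


@pytest.mark.parametrize(
    "frags,millions,kb,expected",
    [(10, 1, 1, 10.0), (0, 3, 2, 0.0), (100, 2, 0.5, 100.0)],
)
def test_fpkm(frags, millions, kb, expected):
    assert fpkm(frags, millions, kb) == pytest.approx(expected)


def test_fpkm_zero_denominator():
    with pytest.raises(ValidationError):
        fpkm(10, 0, 1)
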