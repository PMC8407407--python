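"""Degenerate-primer matching and virtual PCR.

The matching semantics (anchored edit-style alignment with separate
substitution and indel budgets) are pinned by an independent brute-force
oracle implemented here from scratch.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rpodprofiler as rp
from rpodprofiler.iupac_pcr import IUPAC_CODES

from conftest import random_dna

# --------------------------------------------------------------------------
# independent oracle: recursive anchored alignment over expansions

_ORACLE_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_ORACLE_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _oracle_aligns(primer, template, pos, mm_left, ind_left):
    """Can the (concrete) primer align anchored at pos within budgets,
    consuming at least one template base?"""
    def rec(i, j, mm, ind):
        if i == len(primer):
            return j > pos
        ok = False
        if j < len(template):
            cost = 0 if template[j] == primer[i] else 1
            if cost <= mm:
                ok = ok or rec(i + 1, j + 1, mm - cost, ind)
        if ind > 0:
            ok = ok or rec(i + 1, j, mm, ind - 1)          # deletion
            if j < len(template):
                ok = ok or rec(i, j + 1, mm, ind - 1)      # insertion
        return ok

    return rec(0, pos, mm_left, ind_left)


def oracle_positions(primer_seq, template, max_mm, max_ind):
    """Set of (start, strand) where some expansion aligns within budget."""
    expansions = ["".join(p) for p in itertools.product(
        *(_ORACLE_CODES[c] for c in primer_seq))]
    hits = set()
    for strand, tpl in (("+", template),
                        ("-", "".join(_ORACLE_RC[b] for b in template[::-1]))):
        for p in range(len(tpl)):
            if any(_oracle_aligns(e, tpl, p, max_mm, max_ind)
                   for e in expansions):
                if strand == "+":
                    hits.add((p, "+"))
                else:
                    # the scanner reports reverse-strand matches by their
                    # forward-strand start, which depends on the match end;
                    # compare by RC-coordinate start instead
                    hits.add((p, "-"))
    return hits


def scanner_positions(primer, template, max_mm, max_ind):
    n = len(template)
    out = set()
    for m in rp.scan_template(primer, template, max_mm, max_ind,
                              dedupe=False):
        if m.strand == "+":
            out.add((m.start, "+"))
        else:
            out.add((n - m.end, "-"))
    return out


# --------------------------------------------------------------------------
# expand_iupac


@pytest.mark.parametrize("seq,n", [
    ("ACGT", 1),
    ("ATYGAAATCGCCAARCG", 4),       # PsEG30F: Y x R
    ("GGGAACWKGCGCAGGAARTC", 8),    # PsJL628R: W x K x R
])
def test_expand_iupac_counts(seq, n):
    exp = rp.expand_iupac(seq)
    assert len(exp) == n
    assert all(set(e) <= set("ACGT") for e in exp)


def test_expand_iupac_rejects_bad_character():
    with pytest.raises(ValueError, match="position 2"):
        rp.expand_iupac("ACXGT")


@given(st.text(alphabet=sorted(IUPAC_CODES), min_size=1, max_size=12))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_degeneracy_is_product_of_code_sizes(seq):
    expected = 1
    for c in seq:
        expected *= len(IUPAC_CODES[c])
    assert len(rp.expand_iupac(seq)) == expected
    assert rp.Primer("p", seq, "forward").degeneracy == expected


# --------------------------------------------------------------------------
# iupac_match_at


def test_degenerate_code_covers_base():
    m = rp.iupac_match_at(rp.Primer("p", "ATYG", "forward"), "ATCG", 0)
    assert (m.mismatches, m.indels, m.start, m.end) == (0, 0, 0, 4)


def test_single_substitution_within_budget():
    m = rp.iupac_match_at(rp.Primer("p", "ATCG", "forward"), "ATGG", 0)
    assert (m.mismatches, m.indels) == (1, 0)


def test_two_substitutions_need_indel_assist():
    # ATCG vs AGGG: no alignment with <=1 substitution alone, but deleting
    # T leaves ACG vs AGG = 1 substitution -- within separate budgets
    primer = rp.Primer("p", "ATCG", "forward")
    assert rp.iupac_match_at(primer, "AGGG", 0, max_indel=0) is None
    m = rp.iupac_match_at(primer, "AGGG", 0, max_mismatch=1, max_indel=1)
    assert (m.mismatches, m.indels) == (1, 1)
    assert _oracle_aligns("ATCG", "AGGG", 0, 1, 1)


def test_no_match_when_budget_truly_exceeded():
    primer = rp.Primer("p", "ATCG", "forward")
    assert rp.iupac_match_at(primer, "GGGG", 0) is None


def test_template_ambiguity_counts_as_mismatch():
    primer = rp.Primer("p", "ACGT", "forward")
    m = rp.iupac_match_at(primer, "ACGN", 0, max_indel=0)
    assert m.mismatches == 1
    assert rp.iupac_match_at(primer, "ANNT", 0, max_indel=0) is None


# --------------------------------------------------------------------------
# scan_template


def test_scan_no_occurrence_and_empty_template():
    primer = rp.Primer("p", "ACGTACGTAC", "forward")
    assert rp.scan_template(primer, "G" * 50) == []
    assert rp.scan_template(primer, "") == []


def test_scan_exact_expansion_single_forward_hit():
    rng = np.random.default_rng(1)
    primer = rp.known_primer("PsEG30F")
    site = sorted(rp.expand_iupac(primer.sequence))[0]
    template = random_dna(rng, 60) + site + random_dna(rng, 60)
    hits = rp.scan_template(primer, template)
    fwd = [h for h in hits if h.strand == "+" and h.edits == 0]
    assert len(fwd) == 1
    assert (fwd[0].start, fwd[0].end) == (60, 60 + len(site))


def test_scan_two_sites_sorted_ascending():
    rng = np.random.default_rng(2)
    primer = rp.known_primer("PsEG790R")
    site = sorted(rp.expand_iupac(primer.sequence))[0]
    template = site + random_dna(rng, 100) + site + random_dna(rng, 30)
    starts = [h.start for h in rp.scan_template(primer, template)
              if h.strand == "+" and h.edits == 0]
    assert starts == [0, 116]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_scan_equals_bruteforce_oracle(seed):
    """Hit set identical to exhaustive enumeration over positions x
    expansions x in-budget edit variants, on both strands."""
    rng = np.random.default_rng(seed)
    primer_seq = "ATYGACRTGCAT"[:10 + seed]
    template = random_dna(rng, 2000)
    # implant a clean site and a mutated site so hits certainly exist
    site = sorted(rp.expand_iupac(primer_seq))[0]
    mutated = site[:4] + ("A" if site[4] != "A" else "C") + site[5:]
    template = template[:500] + site + template[500:1500] + mutated \
        + template[1500:]
    primer = rp.Primer("p", primer_seq, "forward")
    for max_mm, max_ind in ((0, 0), (1, 0), (1, 1)):
        assert (scanner_positions(primer, template, max_mm, max_ind)
                == oracle_positions(primer_seq, template, max_mm, max_ind))


def test_budget_monotonicity():
    rng = np.random.default_rng(7)
    primer = rp.Primer("p", "ACGTWCGTAC", "forward")
    template = random_dna(rng, 800)
    prev: set = set()
    for budgets in ((0, 0), (1, 0), (1, 1)):
        cur = scanner_positions(primer, template, *budgets)
        assert prev <= cur
        prev = cur


# --------------------------------------------------------------------------
# amplify


def test_amplify_expected_736_product(rpod_pair):
    """A template carrying both rpoD primer sites around a 703 nt insert
    yields the expected 736 nt product (both footprints included)."""
    fwd, rev = rpod_pair
    rng = np.random.default_rng(4)
    record = rp.AmpliconRecord("r1", rp.TaxonomyRecord("sp"),
                               random_dna(rng, 703))
    template = rp.implant_primer_sites(record, rpod_pair, flank=200, seed=4)
    amps = rp.amplify(rpod_pair, template)
    assert len(amps) == 1
    assert amps[0].length == 736
    assert amps[0].trimmed_sequence == record.sequence
    # zero flanks: the product spans the whole template
    bare = rp.implant_primer_sites(record, rpod_pair, flank=0, seed=4)
    amps0 = rp.amplify(rpod_pair, bare)
    assert len(amps0) == 1 and amps0[0].sequence == bare


def test_amplify_requires_reverse_site(rpod_pair):
    fwd, _ = rpod_pair
    rng = np.random.default_rng(5)
    site = sorted(rp.expand_iupac(fwd.sequence))[0]
    template = random_dna(rng, 100) + site + random_dna(rng, 400)
    assert rp.amplify(rpod_pair, template) == []


def test_two_forward_sites_one_reverse(rpod_pair):
    fwd, rev = rpod_pair
    rng = np.random.default_rng(6)
    f = sorted(rp.expand_iupac(fwd.sequence))[0]
    r = rp.reverse_complement(sorted(rp.expand_iupac(rev.sequence))[0])
    template = (f + random_dna(rng, 100) + f + random_dna(rng, 100) + r)
    amps = rp.amplify(rpod_pair, template)
    assert len(amps) == 2
    lengths = sorted(a.length for a in amps)
    assert lengths[1] - lengths[0] == 100 + len(f)


def test_strand_symmetry(rpod_pair):
    rng = np.random.default_rng(8)
    record = rp.AmpliconRecord("r", rp.TaxonomyRecord("sp"),
                               random_dna(rng, 300))
    template = rp.implant_primer_sites(record, rpod_pair, flank=150, seed=8)
    fwd_lengths = sorted(a.length for a in rp.amplify(rpod_pair, template))
    rc_lengths = sorted(a.length for a in
                        rp.amplify(rpod_pair,
                                   rp.reverse_complement(template)))
    assert fwd_lengths == rc_lengths == [300 + 17 + 16]


def test_max_len_caps_products(rpod_pair):
    rng = np.random.default_rng(9)
    record = rp.AmpliconRecord("r", rp.TaxonomyRecord("sp"),
                               random_dna(rng, 703))
    template = rp.implant_primer_sites(record, rpod_pair, flank=10, seed=9)
    assert rp.amplify(rpod_pair, template, max_len=500) == []


# --------------------------------------------------------------------------
# evaluate_primer_pair


def test_evaluate_primer_pair_fractions(rpod_pair):
    rng = np.random.default_rng(10)
    targets = {}
    for i in range(4):
        rec = rp.AmpliconRecord(f"t{i}", rp.TaxonomyRecord("sp"),
                                random_dna(rng, 400))
        targets[f"t{i}"] = rp.implant_primer_sites(
            rec, rpod_pair, flank=50, seed=100 + i,
            ablate_forward=(i == 3))
    negatives = {f"n{i}": random_dna(rng, 600) for i in range(3)}
    m = rp.evaluate_primer_pair(rpod_pair, targets, negatives,
                                expected_length_window=(400, 500))
    assert m.n_templates == 4 and m.n_amplified == 3
    assert m.fraction_amplified == pytest.approx(0.75)
    assert m.n_negative_amplified == 0 and m.fraction_negative == 0.0
    assert m.length_anomalies == []


def test_evaluate_flags_length_anomalies(rpod_pair):
    rng = np.random.default_rng(12)
    rec = rp.AmpliconRecord("t0", rp.TaxonomyRecord("sp"),
                            random_dna(rng, 703))
    template = rp.implant_primer_sites(rec, rpod_pair, flank=20, seed=12)
    m = rp.evaluate_primer_pair(rpod_pair, {"t0": template},
                                expected_length_window=(100, 500))
    assert m.length_anomalies == [("t0", 736)]


def test_evaluate_rejects_empty_targets(rpod_pair):
    with pytest.raises(ValueError):
        rp.evaluate_primer_pair(rpod_pair, {}, {})
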