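"""Seed-site grammar, hybridization alignment and target calling."""

import functools
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtfnet.errors import InputError
from mirtfnet.seq import reverse_complement
from mirtfnet.targets import (
    MiRNARecord,
    TargetSite,
    call_targets,
    context_like_score,
    find_seed_sites,
    hybrid_align_score,
    perfect_duplex_score,
    scan_gene,
    score_sites,
)

MIR = MiRNARecord("let-7-like", "UGAGGUAGUAGGUUGUAUAGUU")  # 22 nt

rna = st.text(alphabet="ACGU", min_size=0, max_size=60)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


# ---------------------------------------------------------------- seed grammar

def oracle_seed_sites(utr: str, mirna: MiRNARecord):
    """Regex-based scan: anchor every 6mer core, classify by neighbors."""
    core = reverse_complement(mirna.mature_seq[1:7])
    m8c = reverse_complement(mirna.mature_seq[7])
    out = []
    for m in re.finditer(f"(?={re.escape(core)})", utr):
        q = m.start()
        left = q > 0 and utr[q - 1] == m8c
        right = q + 6 < len(utr) and utr[q + 6] == "A"
        if left and right:
            out.append((q - 1, "8mer"))
        elif left:
            out.append((q - 1, "7mer-m8"))
        elif right:
            out.append((q, "7mer-A1"))
        else:
            out.append((q, "6mer"))
    return out


def test_constructed_8mer_site():
    utr = "G" * 10 + reverse_complement(MIR.mature_seq[1:8]) + "A" + "G" * 10
    sites = find_seed_sites(utr, MIR, gene_id="g1")
    assert [(s.utr_start, s.site_type) for s in sites] == [(10, "8mer")]
    assert sites[0].utr_end <= len(utr)


@pytest.mark.parametrize(
    "left, right, expected_type, expected_start",
    [
        (True, True, "8mer", 9),
        (True, False, "7mer-m8", 9),
        (False, True, "7mer-A1", 10),
        (False, False, "6mer", 10),
    ],
)
def test_site_type_classification(left, right, expected_type, expected_start):
    core = reverse_complement(MIR.mature_seq[1:7])
    m8c = reverse_complement(MIR.mature_seq[7])
    not_m8 = next(b for b in "ACGU" if b != m8c)
    utr = "C" * 9 + (m8c if left else not_m8) + core + ("A" if right else "C") + "C" * 9
    sites = find_seed_sites(utr, MIR)
    assert [(s.utr_start, s.site_type) for s in sites] == [(expected_start, expected_type)]


def test_no_complementary_core_gives_no_sites():
    # the let-7 core complement contains CUAC; a poly-G UTR cannot match
    assert find_seed_sites("G" * 100, MIR) == []


def test_grammar_matches_regex_oracle_on_random_sequences():
    rng = np.random.default_rng(11)
    mirnas = [MiRNARecord(f"m{i}", random_rna(rng, 21)) for i in range(10)]
    for _ in range(150):
        utr = random_rna(rng, 300)
        for mirna in mirnas:
            got = [(s.utr_start, s.site_type) for s in find_seed_sites(utr, mirna)]
            assert got == oracle_seed_sites(utr, mirna)


def test_non_nucleotide_character_reported_with_position():
    with pytest.raises(InputError, match="position 3"):
        find_seed_sites("ACGXACG", MIR)


# ---------------------------------------------------------- alignment scoring

def oracle_align(mirna: MiRNARecord, window: str) -> float:
    """Independent affine-gap local DP, top-down memoized."""
    a = mirna.mature_seq[::-1]
    b = window
    L = len(a)

    def sub(i, j):
        x, y = a[i], b[j]
        if (x, y) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
            s = 5.0
        elif (x, y) in {("G", "U"), ("U", "G")}:
            s = 2.0
        else:
            s = -4.0
        return 2.0 * s if 2 <= L - i <= 8 else s

    @functools.lru_cache(maxsize=None)
    def score(i, j, state):
        # state: 0 = last was a pair, 1 = gap consuming miRNA, 2 = gap consuming window
        if state == 0:
            if i == 0 or j == 0:
                return 0.0
            prev = max(score(i - 1, j - 1, 0), score(i - 1, j - 1, 1), score(i - 1, j - 1, 2), 0.0)
            return max(0.0, prev + sub(i - 1, j - 1))
        if state == 1:
            if i == 0:
                return -1e18
            return max(score(i - 1, j, 0) - 8.0, score(i - 1, j, 1) - 2.0)
        if j == 0:
            return -1e18
        return max(score(i, j - 1, 0) - 8.0, score(i, j - 1, 2) - 2.0)

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            best = max(best, score(i, j, 0))
    return best


def test_empty_window_scores_zero():
    assert hybrid_align_score(MIR, "") == 0.0


def test_perfect_duplex_score_arithmetic():
    # 22-nt duplex: 7 seed positions at +10, 15 others at +5
    assert perfect_duplex_score(MIR) == pytest.approx(5 * 15 + 10 * 7)


def test_window_length_limit():
    with pytest.raises(InputError, match="window"):
        hybrid_align_score(MIR, "A" * 81)


def test_alignment_matches_independent_dp_oracle():
    rng = np.random.default_rng(5)
    for _ in range(60):
        mirna = MiRNARecord("m", random_rna(rng, int(rng.integers(19, 24))))
        window = random_rna(rng, int(rng.integers(0, 31)))
        assert hybrid_align_score(mirna, window) == pytest.approx(
            oracle_align(mirna, window)
        )


@given(window=rna, extra=st.integers(1, 6))
@settings(max_examples=40, deadline=None)
def test_alignment_monotone_under_appending_matched_bases(window, extra):
    base = hybrid_align_score(MIR, window)
    grown = window + reverse_complement(MIR.mature_seq)[:extra]
    assert hybrid_align_score(MIR, grown) >= base - 1e-9


# ------------------------------------------------------------- context score

def test_context_centered_6mer_in_gc_utr():
    utr = "GC" * 100  # no A/U anywhere, so AU30 = 0
    site = TargetSite("g", MIR.id, 97, "6mer")  # center of a 200-nt UTR: (200-6)/2 = 97
    assert context_like_score(site, utr) == pytest.approx(-0.03)


def test_context_8mer_at_utr_end_in_au_context():
    utr = "AU" * 20 + "GCGCGCGC"  # 48 nt, 8mer occupying the 3' end
    site = TargetSite("g", MIR.id, 40, "8mer")
    assert context_like_score(site, utr) == pytest.approx(-0.31 - 0.1 * 1.0 - 0.1 * 1.0)


def test_context_matches_direct_recomputation():
    rng = np.random.default_rng(3)
    for _ in range(50):
        L = int(rng.integers(40, 400))
        utr = random_rna(rng, L)
        site_type = rng.choice(["6mer", "7mer-A1", "7mer-m8", "8mer"])
        length = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[site_type]
        start = int(rng.integers(0, L - length + 1))
        site = TargetSite("g", "m", start, site_type)
        flank = utr[max(0, start - 30) : start] + utr[start + length : start + length + 30]
        au = (flank.count("A") + flank.count("U")) / len(flank) if flank else 0.0
        half = (L - length) / 2
        prox = 1.0 if half <= 0 else max(0.0, 1 - min(start, L - start - length) / half)
        base = {"8mer": -0.31, "7mer-m8": -0.16, "7mer-A1": -0.10, "6mer": -0.03}[site_type]
        assert context_like_score(site, utr) == pytest.approx(base - 0.1 * au - 0.1 * prox)


def test_context_invalid_coordinates_error():
    with pytest.raises(InputError, match="outside"):
        context_like_score(TargetSite("g", "m", 95, "8mer"), "ACGU" * 25)


# ------------------------------------------------------------- target calls

def test_no_sites_no_pass():
    call = call_targets("g", MIR, [])
    assert call.n_sites == 0 and not call.passes


def test_overlapping_sites_resolved_by_align_score():
    s1 = TargetSite("g", MIR.id, 10, "7mer-m8", align_score=50.0, context_score=-0.2)
    s2 = TargetSite("g", MIR.id, 12, "6mer", align_score=80.0, context_score=-0.05)
    call = call_targets("g", MIR, [s1, s2], align_min=1e9)
    assert call.n_sites == 1
    assert call.total_align_score == 80.0  # the higher-scoring site wins


def test_call_pass_via_alignment_branch():
    site = TargetSite("g", MIR.id, 0, "6mer", align_score=100.0, context_score=0.5)
    assert call_targets("g", MIR, [site], align_min=90.0).passes
    assert not call_targets("g", MIR, [site], align_min=110.0).passes


def test_call_context_branch_requires_seven_or_better():
    weak = TargetSite("g", MIR.id, 0, "6mer", align_score=10.0, context_score=-0.1)
    assert not call_targets("g", MIR, [weak], align_min=1e9).passes
    strong = TargetSite("g", MIR.id, 0, "7mer-m8", align_score=10.0, context_score=-0.1)
    assert call_targets("g", MIR, [strong], align_min=1e9).passes


def test_call_mixed_ids_rejected():
    site = TargetSite("other", MIR.id, 0, "6mer", align_score=1.0, context_score=0.0)
    with pytest.raises(InputError, match="mixed"):
        call_targets("g", MIR, [site])


def test_pass_set_monotone_in_align_min():
    rng = np.random.default_rng(9)
    mirnas = [MiRNARecord(f"m{i}", random_rna(rng, 21)) for i in range(5)]
    utrs = {f"g{i}": random_rna(rng, 400) for i in range(20)}
    for frac_loose, frac_tight in [(0.5, 0.9)]:
        loose, tight = set(), set()
        for mirna in mirnas:
            for gid, utr in utrs.items():
                _, c1 = scan_gene(gid, utr, mirna, align_min_frac=frac_loose)
                _, c2 = scan_gene(gid, utr, mirna, align_min_frac=frac_tight)
                if c1.passes:
                    loose.add((gid, mirna.id))
                if c2.passes:
                    tight.add((gid, mirna.id))
        assert tight <= loose


def test_planted_sites_all_recovered(tiny_cohort):
    """Every planted 8mer is rediscovered and its gene-level call passes."""
    truth = tiny_cohort["truth"]
    utrs = {g.gene_id: g.utr_seq for g in tiny_cohort["genes"]}
    by_id = {m.id: m for m in tiny_cohort["mirnas"]}
    n_checked = 0
    for mirna_id, entries in truth.target_map.items():
        mirna = by_id[mirna_id]
        for gene_id, pos in entries:
            sites = find_seed_sites(utrs[gene_id], mirna, gene_id=gene_id)
            assert (pos, "8mer") in {(s.utr_start, s.site_type) for s in sites}
            score_sites(sites, utrs[gene_id], mirna)
            call = call_targets(gene_id, mirna, sites)
            assert call.passes  # via the context branch at worst
            n_checked += 1
    assert n_checked > 0
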