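"""Promoter extraction, PWM scanning, alignment and conservation classes."""

import math

import numpy as np
import pytest

from chapvar.io import PWM, GeneRecord
from chapvar.motifs import (CONSERVED, CONSERVED_WITH_VARIATION, NON_CONSERVED,
                            align_promoters, classify_conservation,
                            extract_promoter, motif_support_fraction, revcomp,
                            scan_promoter, scan_promoter_set, score_window)

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _loop_score(pwm, window):
    return sum(pwm.loglik[_IDX[b], j] for j, b in enumerate(window))


def _oracle_scan(pwm, promoter):
    """Exhaustive window enumeration on both strands."""
    hits = []
    L = pwm.length
    for i in range(len(promoter) - L + 1):
        w = promoter[i:i + L]
        if "N" in w:
            continue
        for strand, seq in (("+", w), ("-", revcomp(w))):
            s = _loop_score(pwm, seq)
            if s > pwm.cutoff:
                hits.append((i, strand, round(s, 9)))
    return sorted(hits)


def _hitset(hits):
    return sorted((h.pos, h.strand_rel, round(h.score, 9)) for h in hits)


# --------------------------------------------------------------------------
# extract_promoter


def _contig(rng, n=1000):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_extract_promoter_plus_strand_exact_fit():
    rng = np.random.default_rng(0)
    contig = _contig(rng)
    gene = GeneRecord("g", "chr1", 501, 530, "+")
    prom = extract_promoter({"chr1": contig}, gene, 500)
    assert prom.seq == contig[:500] and not prom.truncated


def test_extract_promoter_minus_strand_reverse_complement():
    rng = np.random.default_rng(1)
    contig = _contig(rng)
    gene = GeneRecord("g", "chr1", 471, 500, "-")
    prom = extract_promoter({"chr1": contig}, gene, 500)
    assert prom.seq == revcomp(contig[500:1000]) and not prom.truncated


def test_extract_promoter_truncation_flagged():
    rng = np.random.default_rng(2)
    contig = _contig(rng)
    gene = GeneRecord("g", "chr1", 300, 330, "+")
    prom = extract_promoter({"chr1": contig}, gene, 500)
    assert len(prom.seq) == 299 and prom.truncated
    assert prom.seq == contig[:299]


def test_extract_promoter_zero_upstream_empty_and_flagged():
    gene = GeneRecord("g", "chr1", 1, 30, "+")
    prom = extract_promoter({"chr1": "A" * 100}, gene, 500)
    assert prom.seq == "" and prom.truncated


def test_extract_promoter_missing_contig_rejected():
    gene = GeneRecord("g", "chrX", 501, 530, "+")
    with pytest.raises(ValueError, match="chrX"):
        extract_promoter({"chr1": "A" * 1000}, gene)


# --------------------------------------------------------------------------
# score_window / scan_promoter


def test_score_window_zero_matrix():
    pwm = PWM("z", np.zeros((4, 5)), 0.0)
    assert score_window(pwm, "ACGTA") == 0.0


def test_score_window_direct_sum():
    ll = np.zeros((4, 2))
    ll[0] = [1.0, 0.5]
    pwm = PWM("a", ll, 0.0)
    assert score_window(pwm, "AA") == pytest.approx(1.5)


def test_score_window_n_returns_nan():
    pwm = PWM("z", np.ones((4, 3)), 0.0)
    assert math.isnan(score_window(pwm, "ANT"))


def test_score_window_matches_loop_oracle():
    rng = np.random.default_rng(3)
    for _ in range(30):
        L = int(rng.integers(1, 12))
        pwm = PWM("t", rng.normal(size=(4, L)), 0.0)
        window = "".join(rng.choice(list("ACGT"), size=L))
        assert score_window(pwm, window) == pytest.approx(_loop_score(pwm, window))


def test_scan_planted_consensus_single_hit():
    rng = np.random.default_rng(4)
    L = 10
    consensus = "".join(rng.choice(list("ACGT"), size=L))
    ll = np.full((4, L), -2.0)
    for j, b in enumerate(consensus):
        ll[_IDX[b], j] = 1.0
    background = "".join(rng.choice(list("ACGT"), size=80))
    promoter = background[:40] + consensus + background[40:]
    pwm = PWM("t", ll, L * 1.0 - 0.5)  # only the exact consensus clears this
    hits = scan_promoter(pwm, promoter)
    assert len(hits) == 1
    h = hits[0]
    assert h.pos == 40 and h.site_seq == consensus and h.strand_rel == "+"
    assert h.upstream_offset == len(promoter) - (40 + L - 1)


def test_scan_matches_enumeration_oracle_random():
    rng = np.random.default_rng(5)
    for _ in range(40):
        L = int(rng.integers(3, 9))
        pwm = PWM("t", rng.normal(size=(4, L)), float(rng.normal(0, 2)))
        promoter = "".join(rng.choice(list("ACGTN"), size=50,
                                      p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        assert _hitset(scan_promoter(pwm, promoter)) == _oracle_scan(pwm, promoter)


def test_scan_strand_involution():
    """Scanning the reverse complement mirrors positions and swaps strands."""
    rng = np.random.default_rng(6)
    for _ in range(20):
        L = int(rng.integers(3, 8))
        pwm = PWM("t", rng.normal(size=(4, L)), float(rng.normal(0, 2)))
        promoter = "".join(rng.choice(list("ACGT"), size=60))
        fwd = scan_promoter(pwm, promoter)
        rev = scan_promoter(pwm, revcomp(promoter))
        mirrored = sorted((len(promoter) - h.pos - L,
                           "+" if h.strand_rel == "-" else "-",
                           round(h.score, 9)) for h in rev)
        assert _hitset(fwd) == mirrored


def test_scan_short_promoter_warns_and_returns_empty():
    pwm = PWM("t", np.zeros((4, 10)), -1.0)
    with pytest.warns(UserWarning):
        assert scan_promoter(pwm, "ACGT") == []


def test_scan_promoter_set_equals_per_promoter_scans():
    rng = np.random.default_rng(7)
    pwms = [PWM(f"T{k}", rng.normal(size=(4, int(rng.integers(3, 8)))),
                float(rng.normal(0, 2))) for k in range(5)]
    promoters = {f"g{i}": "".join(rng.choice(list("ACGT"), size=70)) for i in range(20)}
    batch = scan_promoter_set(pwms, promoters, strain="S")
    for g, seq in promoters.items():
        for pwm in pwms:
            expected = _hitset(scan_promoter(pwm, seq))
            got = _hitset(batch.get((g, pwm.tf_name), []))
            assert got == expected


# --------------------------------------------------------------------------
# Alignment


def test_align_identical_promoters_gap_free():
    aln = align_promoters({"A": "ACGTACGT", "B": "ACGTACGT", "C": "ACGTACGT"})
    assert all(row == "ACGTACGT" for row in aln.rows.values())


def test_align_single_deletion_one_gap_block():
    rng = np.random.default_rng(8)
    base = "".join(rng.choice(list("ACGT"), size=120))
    deleted = base[:50] + base[53:]
    aln = align_promoters({"A": base, "B": deleted})
    assert aln.rows["A"] == base
    row_b = aln.rows["B"]
    assert row_b.count("-") == 3
    gap_start = row_b.index("-")
    assert set(row_b[gap_start:gap_start + 3]) == {"-"}
    assert "-" not in row_b[:gap_start] and "-" not in row_b[gap_start + 3:]


def test_align_degapping_recovers_inputs():
    rng = np.random.default_rng(9)
    for _ in range(5):
        base = rng.choice(list("ACGT"), size=100)
        seqs = {}
        for s in ("A", "B", "C", "D"):
            arr = list(base)
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(0, len(arr)))
                op = rng.random()
                if op < 0.4 and len(arr) > 5:
                    del arr[i:i + int(rng.integers(1, 4))]
                elif op < 0.8:
                    arr[i:i] = list(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                else:
                    arr[i] = str(rng.choice(list("ACGT")))
            seqs[s] = "".join(arr)
        aln = align_promoters(seqs)
        lengths = {len(r) for r in aln.rows.values()}
        assert len(lengths) == 1
        for s in seqs:
            assert aln.rows[s].replace("-", "") == seqs[s]


def test_align_empty_promoter_reported_absent():
    aln = align_promoters({"A": "ACGT", "B": "ACGT", "C": ""})
    assert aln.absent == ["C"] and set(aln.rows) == {"A", "B"}


# --------------------------------------------------------------------------
# Conservation classification


def _planted_setup(site_b=None, drop_b=False):
    """Three strains with a planted site; strain B optionally varied/lost."""
    rng = np.random.default_rng(10)
    L = 8
    consensus = "ACGTTGCA"
    ll = np.full((4, L), -2.0)
    for j, b in enumerate(consensus):
        ll[_IDX[b], j] = 1.0
    pwm = PWM("tf1", ll, L - 3.5)  # one mismatch (cost 3) tolerated, two rejected
    background = "".join(rng.choice(list("ACGT"), size=60))
    seqs = {}
    for s in ("A", "B", "C"):
        site = consensus
        if s == "B" and site_b is not None:
            site = site_b
        seqs[s] = background[:30] + site + background[30:]
    if drop_b:
        seqs["B"] = background[:30] + "T" * L + background[30:]
    hits = {s: scan_promoter(pwm, seqs[s]) for s in seqs}
    aln = align_promoters(seqs)
    return hits, aln


def test_classify_identical_sites_conserved():
    hits, aln = _planted_setup()
    recs = classify_conservation(hits, aln, gene_id="g")
    planted = [r for r in recs if r.status == CONSERVED]
    assert len(planted) >= 1
    assert all(r.status == CONSERVED for r in recs)


def test_classify_substituted_site_conserved_with_variation():
    hits, aln = _planted_setup(site_b="ACGTTGCC")  # one substitution, above cutoff
    recs = classify_conservation(hits, aln, gene_id="g")
    assert any(r.status == CONSERVED_WITH_VARIATION for r in recs)
    assert not any(r.status == NON_CONSERVED for r in recs)


def test_classify_scrambled_site_non_conserved():
    hits, aln = _planted_setup(drop_b=True)
    recs = classify_conservation(hits, aln, gene_id="g")
    assert all(r.status == NON_CONSERVED for r in recs)


def test_classify_groups_partition_hits():
    rng = np.random.default_rng(11)
    L = 6
    pwm_hits = {}
    seqs = {}
    base = "".join(rng.choice(list("ACGT"), size=80))
    for s in ("A", "B"):
        seqs[s] = base
    ll = rng.normal(size=(4, L))
    pwm = PWM("tfX", ll, float(np.sort(ll, axis=0)[-1].sum() - 3.0))
    for s in seqs:
        pwm_hits[s] = scan_promoter(pwm, seqs[s])
    aln = align_promoters(seqs)
    recs = classify_conservation(pwm_hits, aln, gene_id="g")
    n_hits = sum(len(h) for h in pwm_hits.values())
    n_grouped = sum(sum(1 for h in r.hits.values() if h is not None) for r in recs)
    assert n_grouped == n_hits
    assert all(r.status in (CONSERVED, CONSERVED_WITH_VARIATION, NON_CONSERVED)
               for r in recs)


def test_motif_support_fraction_counting():
    targets = {"tf1": {"g1", "g2"}, "tf2": {"g1", "g2"}, "tf3": {"g1", "g2"}}
    hit_genes = {"tf1": {"g1", "g2", "g9"}, "tf2": set(), "tf3": {"g2"}}
    frac = motif_support_fraction(targets, hit_genes)
    assert frac == {"tf1": 1.0, "tf2": 0.0, "tf3": 0.5}


def test_motif_support_fraction_missing_pwm_warns():
    with pytest.warns(UserWarning, match="tf9"):
        out = motif_support_fraction({"tf9": {"g1"}}, {})
    assert out == {}
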