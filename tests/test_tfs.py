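"""Target-set construction, the rank-test cascade, labels and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chapvar.motifs import (CONSERVED, CONSERVED_WITH_VARIATION, NON_CONSERVED,
                            ConservationRecord)
from chapvar.stats import hypergeometric_ge
from chapvar.tfs import (TFResult, build_target_sets, client_enrichment,
                         cluster_tfs, exclude_small_tfs, go_enrichment,
                         kw_screen, label_tfs, pair_enrichment,
                         pairwise_wilcoxon)


def _rec(gene, tf, status):
    return ConservationRecord(gene_id=gene, tf_name=tf, anchor_offset=10,
                              status=status)


# --------------------------------------------------------------------------
# Target sets


def test_build_target_sets_conserved_and_expressed_only():
    records = [_rec("g1", "tf1", CONSERVED),
               _rec("g2", "tf1", CONSERVED_WITH_VARIATION),
               _rec("g3", "tf1", NON_CONSERVED),
               _rec("g4", "tf2", CONSERVED)]
    expressed = {"A": {"g1", "g2", "g4"}, "B": {"g1", "g4"}}
    ts = build_target_sets(records, expressed)
    assert ts["tf1"] == {"A": {"g1", "g2"}, "B": {"g1"}}
    assert ts["tf2"] == {"A": {"g4"}, "B": {"g4"}}


def test_build_target_sets_variant_flag():
    records = [_rec("g1", "tf1", CONSERVED),
               _rec("g2", "tf1", CONSERVED_WITH_VARIATION)]
    expressed = {"A": {"g1", "g2"}}
    ts = build_target_sets(records, expressed, include_variant=False)
    assert ts["tf1"]["A"] == {"g1"}


def test_build_target_sets_filtered_gene_absent_everywhere():
    records = [_rec("g1", "tf1", CONSERVED)]
    expressed = {"A": set(), "B": set()}
    ts = build_target_sets(records, expressed)
    assert all(not s for s in ts["tf1"].values())


def test_exclude_small_tfs_boundary():
    ts = {
        "ok": {s: {f"g{i}" for i in range(3)} for s in "ABCDE"},
        "small": {s: ({"g1", "g2"} if s == "C" else {"g1", "g2", "g3"})
                  for s in "ABCDE"},
    }
    kept, excluded = exclude_small_tfs(ts, min_targets=3)
    assert set(kept) == {"ok"} and set(excluded) == {"small"}


def test_exclude_small_tfs_arithmetic():
    """Kept count equals total minus excluded (6 TFs, 2 below threshold)."""
    ts = {}
    for i in range(6):
        n = 2 if i < 2 else 4
        ts[f"tf{i}"] = {s: {f"g{j}" for j in range(n)} for s in "AB"}
    kept, excluded = exclude_small_tfs(ts)
    assert len(kept) == 6 - len(excluded) == 4


# --------------------------------------------------------------------------
# Cascade on constructed fold changes


def _de_tables(shift_strain=None, shift_genes=(), delta=1.5, n=40, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    out = {}
    for s in ("A", "B", "C"):
        lfc = rng.normal(0, 0.2, size=n)
        if s == shift_strain:
            for g in shift_genes:
                lfc[genes.index(g)] += delta
        out[s] = pd.DataFrame({
            "base_mean_untreated": 100.0,
            "base_mean_treated": 100.0 * 2 ** lfc,
            "log2fc": lfc, "p": 0.5, "adj_p": 0.5,
            "is_de": np.abs(lfc) > 1.0,
        }, index=genes)
    return out


def test_kw_screen_flags_shifted_regulon():
    targets = {f"g{i}" for i in range(12)}
    de = _de_tables(shift_strain="A", shift_genes=targets)
    ts = {"tfS": {s: targets for s in "ABC"},
          "tfN": {s: {f"g{i}" for i in range(20, 32)} for s in "ABC"}}
    res = kw_screen(ts, de)
    assert res["tfS"].is_candidate
    assert not res["tfN"].is_candidate
    assert res["tfS"].kw_adj_p >= res["tfS"].kw_p


def test_kw_screen_identical_values_p_one():
    genes = [f"g{i}" for i in range(5)]
    de = {s: pd.DataFrame({"log2fc": 0.7, "base_mean_untreated": 1.0,
                           "base_mean_treated": 1.0, "p": 1.0, "adj_p": 1.0,
                           "is_de": False}, index=genes) for s in "AB"}
    res = kw_screen({"tf": {s: set(genes) for s in "AB"}}, de)
    assert res["tf"].kw_p == 1.0


def test_pairwise_wilcoxon_localizes_shifted_pairs():
    targets = {f"g{i}" for i in range(12)}
    de = _de_tables(shift_strain="A", shift_genes=targets)
    ts = {"tfS": {s: targets for s in "ABC"}}
    res = kw_screen(ts, de)
    pairwise_wilcoxon(res, ts, de)
    ps = res["tfS"].pair_wilcoxon_adj_p
    assert ps[("A", "B")] < 0.05 and ps[("A", "C")] < 0.05
    assert ps[("B", "C")] > 0.05


def test_pairwise_wilcoxon_adjusted_dominates_raw():
    targets = {f"g{i}" for i in range(12)}
    de = _de_tables(shift_strain="A", shift_genes=targets)
    ts = {"tfS": {s: targets for s in "ABC"}}
    res = kw_screen(ts, de)
    pairwise_wilcoxon(res, ts, de)
    from chapvar.stats import wilcoxon_ranksum
    for (a, b), adj in res["tfS"].pair_wilcoxon_adj_p.items():
        raw = wilcoxon_ranksum(list(de[a].loc[sorted(targets), "log2fc"]),
                               list(de[b].loc[sorted(targets), "log2fc"])).p
        assert adj >= raw - 1e-15


def _pair_records(genes, specific):
    return pd.DataFrame({
        "fc_ratio": 1.0,
        "is_pair_specific": [g in specific for g in genes],
        "bp_class": "none",
    }, index=genes)


def test_pair_enrichment_extreme_targets_all_specific():
    genes = [f"g{i}" for i in range(200)]
    targets = set(genes[:12])
    de = _de_tables(n=200)
    ts = {"tf": {s: targets for s in "ABC"}}
    res = {"tf": TFResult("tf", {s: len(targets) for s in "ABC"},
                          kw_adj_p=0.001, is_candidate=True)}
    pairs = {p: _pair_records(genes, targets) for p in
             itertools.combinations("ABC", 2)}
    pair_enrichment(res, ts, pairs, set(genes))
    assert res["tf"].is_high_confidence
    assert all(p < 0.05 for p in res["tf"].pair_enrich_adj_p.values())


def test_pair_enrichment_background_rate_not_enriched():
    genes = [f"g{i}" for i in range(200)]
    targets = set(genes[:40])
    specific = {g for i, g in enumerate(genes) if i % 5 == 0}  # 20% everywhere
    ts = {"tf": {s: targets for s in "AB"}}
    res = {"tf": TFResult("tf", {s: len(targets) for s in "AB"},
                          kw_adj_p=0.001, is_candidate=True)}
    pairs = {("A", "B"): _pair_records(genes, specific)}
    pair_enrichment(res, ts, pairs, set(genes), continuity=False)
    assert not res["tf"].is_high_confidence
    assert res["tf"].pair_enrich_adj_p[("A", "B")] > 0.4


# --------------------------------------------------------------------------
# Labels and clustering


def test_label_rule_table():
    pairs = [("A", "B"), ("A", "C"), ("B", "C")]
    results = {
        "tf0": TFResult("tf0", {}, kw_adj_p=0.2),
        "tf1": TFResult("tf1", {}, kw_adj_p=0.01,
                        pair_wilcoxon_adj_p={p: 0.3 for p in pairs}),
        "tf2": TFResult("tf2", {}, kw_adj_p=0.01,
                        pair_wilcoxon_adj_p={("A", "B"): 0.01, ("A", "C"): 0.3,
                                             ("B", "C"): 0.06}),
    }
    mat = label_tfs(results, pairs)
    assert list(mat.loc["tf0"]) == [0, 0, 0]
    assert list(mat.loc["tf1"]) == [1, 1, 1]
    assert list(mat.loc["tf2"]) == [2, 1, 1]
    assert set(np.unique(mat.to_numpy())) <= {0, 1, 2}


def test_cluster_tfs_identical_rows_merge_first():
    mat = pd.DataFrame([[0, 0, 0], [2, 2, 2], [0, 0, 0]],
                       index=["x", "y", "z"], columns=["p1", "p2", "p3"])
    dend = cluster_tfs(mat)
    assert dend.merges[0, 2] == 0.0
    first = {dend.labels[int(dend.merges[0, 0])], dend.labels[int(dend.merges[0, 1])]}
    assert first == {"x", "z"}
    # all-zero vs all-two rows over k pairs are 2*sqrt(k) apart
    assert dend.merges[-1, 2] == pytest.approx(2 * np.sqrt(3))


# --------------------------------------------------------------------------
# Client and GO enrichment


def test_client_enrichment_study_counts():
    universe = {f"tf{i}" for i in range(187)}
    clients = {f"tf{i}" for i in range(23)}
    candidates = {f"tf{i}" for i in range(16, 37)}  # 21 candidates, 7 clients
    row = client_enrichment(candidates, clients, universe)
    assert (row.k, row.K, row.n, row.N) == (7, 23, 21, 187)
    assert row.p == pytest.approx(0.0011, abs=5e-5)


def test_client_enrichment_inclusive_tail_saturates_at_one():
    universe = {"a", "b", "c"}
    row = client_enrichment({"a", "b"}, universe, universe, include_observed=True)
    assert row.p == 1.0


def test_client_enrichment_matches_inclusive_tail_shift():
    universe = {f"t{i}" for i in range(30)}
    clients = {f"t{i}" for i in range(8)}
    candidates = {f"t{i}" for i in range(5, 15)}
    k = len(candidates & clients)
    row = client_enrichment(candidates, clients, universe)
    assert row.p == pytest.approx(hypergeometric_ge(k + 1, 8, 10, 30))


def test_go_enrichment_bookkeeping_matches_brute_force():
    rng = np.random.default_rng(3)
    universe = {f"g{i}" for i in range(60)}
    go_map = {g: set(rng.choice([f"GO:{t}" for t in range(8)],
                                size=int(rng.integers(1, 4)), replace=False))
              for g in universe}
    gene_set = set(rng.choice(sorted(universe), size=15, replace=False))
    rows = go_enrichment(gene_set, go_map, universe)
    for row in rows:
        term_genes = {g for g in universe if row.term_id in go_map.get(g, ())}
        assert row.K == len(term_genes)
        assert row.k == len(gene_set & term_genes)
        assert row.n == len(gene_set) and row.N == len(universe)
        assert row.p == pytest.approx(
            hypergeometric_ge(row.k, row.K, row.n, row.N))
        assert row.adj_p >= row.p


def test_go_enrichment_planted_term_found():
    universe = {f"g{i}" for i in range(100)}
    go_map = {g: {"GO:common"} for g in universe}
    rare = {f"g{i}" for i in range(10)}
    for g in rare:
        go_map[g].add("GO:rare")
    rows = go_enrichment(rare, go_map, universe)
    sig = [r.term_id for r in rows if r.adj_p < 0.05]
    assert sig == ["GO:rare"]


def test_go_enrichment_uniform_draw_rarely_significant():
    rng = np.random.default_rng(5)
    universe = {f"g{i}" for i in range(200)}
    go_map = {g: set(rng.choice([f"GO:{t}" for t in range(10)], size=2,
                                replace=False)) for g in universe}
    n_sig = 0
    for _ in range(20):
        gene_set = set(rng.choice(sorted(universe), size=30, replace=False))
        rows = go_enrichment(gene_set, go_map, universe)
        n_sig += sum(r.adj_p < 0.05 for r in rows)
    # FWER <= 0.05 per draw: expectation <= 1 over 20 draws; allow ~4 sd
    assert n_sig <= 4


def test_go_enrichment_empty_set_warns():
    with pytest.warns(UserWarning):
        assert go_enrichment(set(), {}, {"g1"}) == []
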