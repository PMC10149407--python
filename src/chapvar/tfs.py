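"""The TF-inference cascade: from conserved motifs to candidate regulators.

Target sets are genes carrying a conserved (optionally
conserved-with-variation) predicted binding site for a TF and expression
data in a strain.  TFs with fewer than three targets in any strain are
excluded.  The cascade then asks, per TF:

1. Kruskal-Wallis: do the targets' treated/untreated log2 fold changes
   differ among strains?  (Bonferroni across TFs; candidates pass at 0.05.)
2. Pairwise Wilcoxon rank-sum: which strain pairs differ?  (Bonferroni
   across all candidate-TF x pair tests.)
3. Two-proportion enrichment: are strain-pair-specific genes over-represented
   among the targets relative to all analysed genes?  (Bonferroni across
   candidate-TF x pair tests; a TF enriched in at least one pair is
   high-confidence.)

Each (TF, pair) gets a label — 0: no strain dependence, 1: Kruskal-Wallis
only, 2: Kruskal-Wallis and pairwise Wilcoxon — and the label matrix is
clustered (Euclidean, complete linkage) for heatmap-style reporting.
Candidate lists can be tested for enrichment of chaperone-client TFs and
target sets for GO-term over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import CONSERVED, CONSERVED_WITH_VARIATION, ConservationRecord
from .stats import (Dendrogram, adjust, hclust_complete, hypergeometric_ge,
                    kruskal_wallis, two_proportion_greater, wilcoxon_ranksum)

Pair = tuple[str, str]


@dataclass
class TFResult:
    tf_name: str
    n_targets: dict[str, int]
    kw_p: float = float("nan")
    kw_adj_p: float = float("nan")
    pair_wilcoxon_adj_p: dict[Pair, float] = field(default_factory=dict)
    pair_enrich_adj_p: dict[Pair, float] = field(default_factory=dict)
    labels: dict[Pair, int] = field(default_factory=dict)
    is_candidate: bool = False
    is_high_confidence: bool = False
    is_client: bool | None = None


@dataclass
class EnrichmentRow:
    term_id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    adj_p: float = float("nan")


def build_target_sets(records: list[ConservationRecord],
                      expressed: dict[str, set[str]],
                      include_variant: bool = True) -> dict[str, dict[str, set[str]]]:
    """tf -> strain -> set of target genes.

    A gene is a target of a TF in a strain when it carries a qualifying
    conserved hit (conserved, plus conserved-with-variation when
    ``include_variant``) and the gene has expression data in that strain.
    """
    allowed = {CONSERVED}
    if include_variant:
        allowed.add(CONSERVED_WITH_VARIATION)
    out: dict[str, dict[str, set[str]]] = {}
    for rec in records:
        if rec.status not in allowed:
            continue
        per_strain = out.setdefault(rec.tf_name, {s: set() for s in expressed})
        for strain, genes in expressed.items():
            if rec.gene_id in genes:
                per_strain[strain].add(rec.gene_id)
    return out


def exclude_small_tfs(target_sets: dict[str, dict[str, set[str]]],
                      min_targets: int = 3):
    """Split TFs into (kept, excluded): excluded iff the TF has fewer than
    ``min_targets`` targets in at least one strain."""
    kept, excluded = {}, {}
    for tf, per_strain in target_sets.items():
        if any(len(g) < min_targets for g in per_strain.values()):
            excluded[tf] = per_strain
        else:
            kept[tf] = per_strain
    return kept, excluded


def kw_screen(target_sets: dict[str, dict[str, set[str]]],
              de: dict[str, pd.DataFrame], alpha: float = 0.05) -> dict[str, TFResult]:
    """Kruskal-Wallis on per-strain target log2 fold changes, Bonferroni
    across tested TFs; candidates pass adjusted p < alpha."""
    results: dict[str, TFResult] = {}
    raw: list[float] = []
    tfs = sorted(target_sets)
    for tf in tfs:
        groups = []
        for strain in sorted(de):
            genes = sorted(target_sets[tf].get(strain, set()))
            groups.append(list(de[strain].loc[genes, "log2fc"]))
        res = kruskal_wallis(groups)
        results[tf] = TFResult(tf, {s: len(target_sets[tf].get(s, set()))
                                    for s in sorted(de)}, kw_p=res.p)
        raw.append(res.p)
    for tf, adj_p in zip(tfs, adjust(raw, "bonferroni")):
        results[tf].kw_adj_p = adj_p
        results[tf].is_candidate = adj_p < alpha
    return results


def pairwise_wilcoxon(results: dict[str, TFResult],
                      target_sets: dict[str, dict[str, set[str]]],
                      de: dict[str, pd.DataFrame], alpha: float = 0.05) -> None:
    """Two-sided Wilcoxon rank-sum on every strain pair for each candidate
    TF; Bonferroni family = all (candidate TF, pair) tests performed."""
    strains = sorted(de)
    tests: list[tuple[str, Pair, float]] = []
    for tf, res in sorted(results.items()):
        if not res.is_candidate:
            continue
        for i, a in enumerate(strains):
            for b in strains[i + 1:]:
                ga = sorted(target_sets[tf].get(a, set()))
                gb = sorted(target_sets[tf].get(b, set()))
                w = wilcoxon_ranksum(list(de[a].loc[ga, "log2fc"]),
                                     list(de[b].loc[gb, "log2fc"]))
                tests.append((tf, (a, b), w.p))
    adj = adjust([t[2] for t in tests], "bonferroni")
    for (tf, pair, _), a_p in zip(tests, adj):
        results[tf].pair_wilcoxon_adj_p[pair] = a_p


def pair_enrichment(results: dict[str, TFResult],
                    target_sets: dict[str, dict[str, set[str]]],
                    pair_records: dict[Pair, pd.DataFrame],
                    analyzed_genes: set[str],
                    alpha: float = 0.05,
                    continuity: bool = True) -> None:
    """One-sided two-proportion test: pair-specific genes among a candidate
    TF's targets vs among all analysed genes; Bonferroni across
    (candidate TF, pair) tests.  A TF enriched (adjusted p < alpha) in at
    least one pair is flagged high-confidence."""
    tests: list[tuple[str, Pair, float]] = []
    for tf, res in sorted(results.items()):
        if not res.is_candidate:
            continue
        for pair, recs in sorted(pair_records.items()):
            a, b = pair
            targets = (target_sets[tf].get(a, set()) & target_sets[tf].get(b, set())
                       & analyzed_genes)
            n1 = len(targets)
            if n1 == 0:
                continue
            spec = set(recs.index[recs["is_pair_specific"]])
            x1 = len(targets & spec)
            x2 = len(spec & analyzed_genes)
            n2 = len(analyzed_genes)
            t = two_proportion_greater(x1, n1, x2, n2, continuity=continuity)
            tests.append((tf, pair, t.p))
    adj = adjust([t[2] for t in tests], "bonferroni")
    for (tf, pair, _), a_p in zip(tests, adj):
        results[tf].pair_enrich_adj_p[pair] = a_p
        if a_p < alpha:
            results[tf].is_high_confidence = True


def label_tfs(results: dict[str, TFResult], pairs: list[Pair],
              alpha: float = 0.05) -> pd.DataFrame:
    """Per-(TF, pair) labels: 0 when the TF's Kruskal-Wallis adjusted p is
    >= alpha; 1 when it passes but the pair's Wilcoxon adjusted p does not;
    2 when both pass.  Returned as a TF x pair integer matrix."""
    mat = {}
    for tf, res in sorted(results.items()):
        row = {}
        for pair in pairs:
            if not (res.kw_adj_p < alpha):
                row[pair] = 0
            elif res.pair_wilcoxon_adj_p.get(pair, 1.0) < alpha:
                row[pair] = 2
            else:
                row[pair] = 1
            res.labels[pair] = row[pair]
        mat[tf] = row
    df = pd.DataFrame.from_dict(mat, orient="index")
    df.columns = [f"{a}|{b}" for a, b in pairs]
    return df.astype(int)


def cluster_tfs(label_matrix: pd.DataFrame) -> Dendrogram:
    """Complete-linkage clustering of TFs on Euclidean distances between
    label rows, for heatmap-style reporting."""
    if label_matrix.shape[0] < 2:
        raise ValueError("cluster_tfs: need >= 2 TFs")
    x = label_matrix.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return hclust_complete(d, list(label_matrix.index))


def client_enrichment(candidates: set[str], clients: set[str],
                      universe: set[str], include_observed: bool = False) -> EnrichmentRow:
    """Hypergeometric enrichment of chaperone-client TFs among candidates.

    The default tail is strict — P(X > k), the convention of R's upper-tail
    ``phyper`` — matching how such enrichments are conventionally reported;
    ``include_observed=True`` gives the inclusive tail P(X >= k).
    """
    if not universe:
        raise ValueError("client_enrichment: empty universe")
    if not candidates <= universe or not clients <= universe:
        raise ValueError("client_enrichment: candidates and clients must lie in universe")
    k = len(candidates & clients)
    K, n, N = len(clients), len(candidates), len(universe)
    if include_observed:
        p = hypergeometric_ge(k, K, n, N)
    else:
        p = hypergeometric_ge(k + 1, K, n, N) if k < min(K, n) else 0.0
    return EnrichmentRow("clients", k, K, n, N, p, p)


def go_enrichment(gene_set: set[str], go_map: dict[str, set[str]],
                  universe: set[str], alpha: float = 0.05) -> list[EnrichmentRow]:
    """Per-GO-term hypergeometric over-representation with Bonferroni
    correction over terms represented in the universe."""
    if not gene_set:
        import warnings
        warnings.warn("go_enrichment: empty gene set")
        return []
    if not gene_set <= universe:
        raise ValueError("go_enrichment: gene_set must lie within universe")
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in go_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(gene_set & term_genes[term])
        rows.append(EnrichmentRow(term, k, K, len(gene_set), len(universe),
                                  hypergeometric_ge(k, K, len(gene_set), len(universe))))
    adj = adjust([r.p for r in rows], "bonferroni")
    for row, a in zip(rows, adj):
        row.adj_p = a
    return sorted(rows, key=lambda r: (r.adj_p, r.term_id))
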