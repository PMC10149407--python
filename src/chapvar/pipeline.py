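"""End-to-end orchestration: simulate -> scan -> DE -> pairs -> TF cascade
-> trees -> GO, with a machine-readable run report.

`run_all` executes the full workflow on synthetic data (or on data loaded
through :mod:`chapvar.io`), writes every intermediate as TSV when an output
directory is given, and returns a report whose counts are internally
consistent (pair-specific = buffered + potentiated + tie; conservation
classes partition the grouped hits).  Reruns with the same config and seed
are bit-identical.

`recovery_experiment` and `null_calibration` are the calibration drivers:
the former scores planted-regulon recovery (precision/recall of the
high-confidence TF list) over fresh simulations, the latter measures the
family-wise error of the cascade and the DE test level under a null
configuration, redrawing counts over many seeds against one fixed genome.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .diffexpr import de_test, filter_genes, pair_specific, size_factors, strain_pairs, tpm
from .motifs import (CLASSES, Promoter, align_promoters, classify_conservation,
                     extract_promoter, scan_promoter_set)
from .synthetic import GroundTruth, SimConfig, simulate_counts, simulate_go_map, simulate_promoters
from .tfs import (build_target_sets, cluster_tfs, exclude_small_tfs, go_enrichment,
                  kw_screen, label_tfs, pair_enrichment, pairwise_wilcoxon, client_enrichment)
from .trees import bionj, compare_matrices, expression_distance, tn93_distance


@dataclass
class PipelineConfig:
    """All knobs of the workflow; cutoffs follow the study design defaults."""

    sim: SimConfig = field(default_factory=SimConfig)
    alpha: float = 0.05
    fc_cutoff: float = 2.0
    ratio_cutoff: float = 2.0
    min_count: int = 5
    min_targets: int = 3
    conservation_window: int = 20
    include_variant_motifs: bool = True
    require_de_for_pairs: bool = True
    filter_mode: str = "max"
    dispersion_mode: str = "pooled"
    client_tfs: list[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("fc_cutoff", "ratio_cutoff"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must exceed 1")
        if self.min_count < 0 or self.min_targets < 0 or self.conservation_window < 0:
            raise ValueError("counts and windows must be non-negative")

    @property
    def seed(self) -> int:
        return self.sim.seed


@dataclass
class MotifStage:
    fasta_map: dict
    gene_table: list
    pwms: list
    truth: GroundTruth
    promoters: dict[str, dict[str, Promoter]]
    hits: dict[str, dict]  # strain -> {(gene, tf) -> [TFBSHit]}
    records: list
    n_hits: int
    class_counts: dict[str, int]


def run_motif_stage(config: PipelineConfig) -> MotifStage:
    """Simulate genomes, extract promoters, scan, align and classify."""
    cfg = config.sim
    fasta_map, gene_table, pwms, truth = simulate_promoters(cfg)
    promoters: dict[str, dict[str, Promoter]] = {}
    hits: dict[str, dict] = {}
    for strain, genome in fasta_map.items():
        proms = {g.gene_id: extract_promoter(genome, g, cfg.promoter_len)
                 for g in gene_table}
        promoters[strain] = proms
        hits[strain] = scan_promoter_set(pwms, {g: p.seq for g, p in proms.items()},
                                         strain=strain)
    per_gene: dict[str, dict[str, list]] = {}
    for strain, hmap in hits.items():
        for (gene, _tf), hl in hmap.items():
            per_gene.setdefault(gene, {s: [] for s in promoters})[strain].extend(hl)
    records = []
    for gene in sorted(per_gene):
        aln = align_promoters({s: promoters[s][gene].seq for s in promoters})
        records.extend(classify_conservation(per_gene[gene], aln,
                                             window_bp=config.conservation_window,
                                             gene_id=gene))
    n_hits = sum(len(hl) for h in hits.values() for hl in h.values())
    class_counts = {c: sum(1 for r in records if r.status == c) for c in CLASSES}
    return MotifStage(fasta_map, gene_table, pwms, truth, promoters, hits,
                      records, n_hits, class_counts)


@dataclass
class ExpressionStage:
    expt: cio.CountExperiment
    filtered: cio.CountExperiment
    factors: pd.Series
    de: dict[str, pd.DataFrame]
    pairs: dict[tuple[str, str], pd.DataFrame]


def run_expression_stage(config: PipelineConfig, expt: cio.CountExperiment,
                         fc_cutoff: float | None = None) -> ExpressionStage:
    filtered = filter_genes(expt, min_count=config.min_count, mode=config.filter_mode)
    factors = size_factors(filtered)
    fc = config.fc_cutoff if fc_cutoff is None else fc_cutoff
    de = {s: de_test(filtered, s, alpha=config.alpha, fc_cut=fc, factors=factors,
                     dispersion_mode=config.dispersion_mode)
          for s in filtered.strains}
    pairs = {(a, b): pair_specific(de[a], de[b], ratio_cut=config.ratio_cutoff,
                                   require_de=config.require_de_for_pairs)
             for a, b in strain_pairs(filtered.strains)}
    return ExpressionStage(expt, filtered, factors, de, pairs)


@dataclass
class TFStage:
    target_sets: dict
    excluded: dict
    results: dict
    label_matrix: pd.DataFrame
    candidates: list[str]
    high_confidence: list[str]
    dendrogram: object = None


def run_tf_stage(config: PipelineConfig, records, expr: ExpressionStage) -> TFStage:
    analyzed = set(expr.filtered.genes)
    expressed = {s: analyzed for s in expr.filtered.strains}
    target_sets = build_target_sets(records, expressed,
                                    include_variant=config.include_variant_motifs)
    kept, excluded = exclude_small_tfs(target_sets, min_targets=config.min_targets)
    results = kw_screen(kept, expr.de, alpha=config.alpha)
    pairwise_wilcoxon(results, kept, expr.de, alpha=config.alpha)
    pair_enrichment(results, kept, expr.pairs, analyzed, alpha=config.alpha)
    pairs = strain_pairs(expr.filtered.strains)
    labels = label_tfs(results, pairs, alpha=config.alpha)
    stage = TFStage(target_sets=kept, excluded=excluded, results=results,
                    label_matrix=labels,
                    candidates=sorted(t for t, r in results.items() if r.is_candidate),
                    high_confidence=sorted(t for t, r in results.items()
                                           if r.is_high_confidence))
    if labels.shape[0] >= 2:
        stage.dendrogram = cluster_tfs(labels)
    return stage


def _concat_promoters(motif: MotifStage) -> dict[str, str]:
    genes = sorted(next(iter(motif.promoters.values())))
    return {s: "".join(motif.promoters[s][g].seq for g in genes)
            for s in motif.promoters}


def run_all(config: PipelineConfig, outdir: str | Path | None = None,
            with_trees: bool = True, with_go: bool = True) -> dict:
    """Execute every stage on a fresh simulation and return the run report."""
    motif = run_motif_stage(config)
    expt = simulate_counts(config.sim, motif.truth)
    go_map = simulate_go_map(config.sim, motif.truth)
    expr = run_expression_stage(config, expt)
    tf = run_tf_stage(config, motif.records, expr)

    report: dict = {
        "config": _config_dict(config),
        "seed": config.seed,
        "versions": _versions(),
        "n_genes_simulated": config.sim.n_genes,
        "n_genes_analyzed": len(expr.filtered.genes),
        "n_tfbs_hits": motif.n_hits,
        "conservation_classes": motif.class_counts,
        "de_genes": {s: int(expr.de[s]["is_de"].sum()) for s in sorted(expr.de)},
        "pair_specific": {},
        "n_tfs_tested": len(tf.target_sets),
        "n_tfs_excluded": len(tf.excluded),
        "candidate_tfs": tf.candidates,
        "high_confidence_tfs": tf.high_confidence,
        "planted_tfs": sorted({t for t, _, _ in config.sim.planted_tfs}),
    }
    for (a, b), recs in sorted(expr.pairs.items()):
        spec = recs[recs["is_pair_specific"]]
        report["pair_specific"][f"{a}|{b}"] = {
            "n": int(len(spec)),
            "buffered": int((spec["bp_class"] == "buffered").sum()),
            "potentiated": int((spec["bp_class"] == "potentiated").sum()),
            "tie": int((spec["bp_class"] == "tie").sum()),
        }

    if config.client_tfs is not None:
        universe = set(tf.target_sets) | set(tf.excluded)
        row = client_enrichment(set(tf.candidates), set(config.client_tfs) & universe,
                                universe)
        report["client_enrichment_p"] = row.p

    if with_go:
        hc_targets = set()
        for t in tf.high_confidence:
            for genes in tf.target_sets[t].values():
                hc_targets |= genes
        universe = set(expr.filtered.genes)
        rows = go_enrichment(hc_targets, go_map, universe, alpha=config.alpha) \
            if hc_targets else []
        report["go_enriched_terms"] = [r.term_id for r in rows if r.adj_p < config.alpha]

    if with_trees:
        genetic = tn93_distance(_concat_promoters(motif))
        lengths = {g.gene_id: float(g.end - g.start + 1) for g in motif.gene_table}
        tpm_mat = tpm(expr.filtered, {g: lengths[g] for g in expr.filtered.genes})
        expr_unt = expression_distance(tpm_mat, expr.filtered.samples, "untreated")
        expr_trt = expression_distance(tpm_mat, expr.filtered.samples, "treated")
        report["trees"] = {
            "genetic_newick": cio.write_newick(bionj(genetic)),
            "expression_untreated_newick": cio.write_newick(bionj(expr_unt)),
            "expression_treated_newick": cio.write_newick(bionj(expr_trt)),
            "rho_genetic_vs_untreated": compare_matrices(genetic, expr_unt),
            "rho_genetic_vs_treated": compare_matrices(genetic, expr_trt),
        }

    if outdir is not None:
        _write_outputs(Path(outdir), config, motif, expt, go_map, expr, tf, report)
    return report


def sweep_fc_cutoffs(config: PipelineConfig,
                     cutoffs: tuple[float, ...] = (1.5, 2.0, 2.5)) -> dict:
    """Re-run the DE -> TF stages at several fold-change cutoffs.

    Reports per-cutoff DE/pair counts and high-confidence TF lists, the
    pairwise symmetric differences of those lists, and whether the DE gene
    sets nest (higher cutoff implies a subset)."""
    motif = run_motif_stage(config)
    expt = simulate_counts(config.sim, motif.truth)
    per_cutoff: dict[float, dict] = {}
    de_sets: dict[float, dict[str, set[str]]] = {}
    for fc in cutoffs:
        expr = run_expression_stage(config, expt, fc_cutoff=fc)
        tf = run_tf_stage(config, motif.records, expr)
        de_sets[fc] = {s: set(d.index[d["is_de"]]) for s, d in expr.de.items()}
        per_cutoff[fc] = {
            "de_genes": {s: len(g) for s, g in de_sets[fc].items()},
            "high_confidence_tfs": tf.high_confidence,
            "candidate_tfs": tf.candidates,
        }
    ordered = sorted(cutoffs, reverse=True)
    nested = all(
        de_sets[hi][s] <= de_sets[lo][s]
        for hi, lo in zip(ordered, ordered[1:])
        for s in de_sets[hi])
    diffs = {}
    for i, a in enumerate(cutoffs):
        for b in cutoffs[i + 1:]:
            sa = set(per_cutoff[a]["high_confidence_tfs"])
            sb = set(per_cutoff[b]["high_confidence_tfs"])
            diffs[f"{a}|{b}"] = sorted(sa ^ sb)
    return {"per_cutoff": {str(k): v for k, v in per_cutoff.items()},
            "de_sets_nested": nested,
            "high_confidence_symmetric_difference": diffs}


# --------------------------------------------------------------------------
# Calibration drivers


def _derive_seed(base: int, i: int) -> int:
    return int((base * 1_000_003 + 7919 * i + 1) % (2 ** 31))


def recovery_experiment(config: PipelineConfig, n_seeds: int = 20,
                        base_seed: int | None = None) -> dict:
    """Precision/recall of the high-confidence TF list against planted TFs,
    pooled over fresh full-pipeline simulations."""
    base = config.seed if base_seed is None else base_seed
    tp = fp = fn = 0
    per_seed = []
    for i in range(n_seeds):
        sim = dataclasses.replace(config.sim, seed=_derive_seed(base, i))
        cfg = dataclasses.replace(config, sim=sim)
        rep = run_all(cfg, with_trees=False, with_go=False)
        planted = set(rep["planted_tfs"])
        hc = set(rep["high_confidence_tfs"])
        tp += len(hc & planted)
        fp += len(hc - planted)
        fn += len(planted - hc)
        per_seed.append({"seed": cfg.seed, "high_confidence": sorted(hc)})
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {"precision": precision, "recall": recall,
            "tp": tp, "fp": fp, "fn": fn,
            "n_seeds": n_seeds, "per_seed": per_seed}


def null_calibration(config: PipelineConfig, n_seeds: int = 200,
                     base_seed: int | None = None) -> dict:
    """Family-wise error of the cascade and DE test level under the null.

    The genome/motif stage is simulated once (no planted effects); each seed
    redraws the count matrix — the stochastic layer that generates false
    positives — and replays the DE -> TF stages."""
    sim = dataclasses.replace(config.sim, planted_tfs=[])
    cfg = dataclasses.replace(config, sim=sim)
    motif = run_motif_stage(cfg)
    base = cfg.seed if base_seed is None else base_seed
    n_false = 0
    type1_num = 0
    type1_den = 0
    for i in range(n_seeds):
        expt = simulate_counts(sim, motif.truth, seed=_derive_seed(base, i))
        expr = run_expression_stage(cfg, expt)
        tf = run_tf_stage(cfg, motif.records, expr)
        if tf.high_confidence:
            n_false += 1
        for s, d in expr.de.items():
            type1_num += int((d["p"] < 0.05).sum())
            type1_den += len(d)
    return {"fwer": n_false / n_seeds,
            "de_type1": type1_num / type1_den,
            "n_seeds": n_seeds}


# --------------------------------------------------------------------------
# Reporting helpers


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["planted_tfs"] = [list(t) for t in config.sim.planted_tfs]
    return d


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"chapvar": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


def _write_outputs(outdir: Path, config, motif: MotifStage, expt, go_map,
                   expr: ExpressionStage, tf: TFStage, report: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for strain, contigs in motif.fasta_map.items():
        cio.write_fasta(contigs, outdir / f"genome_{strain}.fa")
    cio.write_gene_table(motif.gene_table, outdir / "genes.tsv")
    cio.write_pwm_library(motif.pwms, outdir / "pwms.txt")
    cio.write_counts(expt, outdir / "counts.tsv", outdir / "samples.tsv")
    cio.write_go_map(go_map, outdir / "go_map.tsv")
    for s, d in expr.de.items():
        d.rename_axis("gene_id").to_csv(outdir / f"de_{s}.tsv", sep="\t")
    for (a, b), d in expr.pairs.items():
        d.rename_axis("gene_id").to_csv(outdir / f"pairs_{a}_{b}.tsv", sep="\t")
    hit_rows = []
    for strain, hmap in motif.hits.items():
        for (gene, tfname), hl in hmap.items():
            for h in hl:
                hit_rows.append({"gene_id": gene, "strain": strain, "tf": tfname,
                                 "offset": h.upstream_offset, "strand": h.strand_rel,
                                 "score": h.score, "site_seq": h.site_seq})
    pd.DataFrame(hit_rows).to_csv(outdir / "tfbs_hits.tsv", sep="\t", index=False)
    cons_rows = [{"gene_id": r.gene_id, "tf": r.tf_name, "anchor_offset": r.anchor_offset,
                  "class": r.status} for r in motif.records]
    pd.DataFrame(cons_rows).to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    tf_rows = []
    for name, res in sorted(tf.results.items()):
        tf_rows.append({"tf": name, "kw_p": res.kw_p, "kw_adj_p": res.kw_adj_p,
                        "is_candidate": res.is_candidate,
                        "is_high_confidence": res.is_high_confidence,
                        **{f"wilcoxon_{a}|{b}": p for (a, b), p in res.pair_wilcoxon_adj_p.items()},
                        **{f"enrich_{a}|{b}": p for (a, b), p in res.pair_enrich_adj_p.items()}})
    pd.DataFrame(tf_rows).to_csv(outdir / "tf_results.tsv", sep="\t", index=False)
    tf.label_matrix.rename_axis("tf").to_csv(outdir / "tf_labels.tsv", sep="\t")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
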