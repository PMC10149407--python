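"""Joint genome + transcriptome simulator with known ground truth.

Emulates the study design the pipeline targets: several diverged strains,
two conditions (chaperone inhibitor treated / untreated), a few biological
replicates, negative-binomially distributed gene counts, planted TF
regulons whose treated-condition effect is strain-specific, and promoter
sequences carrying planted motif instances that are conserved, carry a
variant, or are lost across strains.

Strains are related by a random strain tree; background SNPs and small
per-gene baseline expression offsets both accumulate along its branches, so
genetic and (untreated) expression distances share phylogenetic signal.
Planted motif footprints are shielded from background SNPs — variant and
loss events are planted explicitly — so ground-truth conservation classes
are exact rather than probabilistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PWM, CountExperiment, GeneRecord
from .motifs import revcomp, score_window
from .trees import Node, DistanceMatrix, cophenetic

_BASES = np.array(list("ACGT"))

# log-likelihood ratios of a sharp consensus PWM: 85% consensus base vs 5%
# each alternative, against a uniform background
_LL_HI = math.log(0.85 / 0.25)
_LL_LO = math.log(0.05 / 0.25)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated design: 5 strains x 2 conditions x 3
    biological replicates, 2000 genes, 20 TFs with 30 targets each, and 5
    planted responsive (TF, strain) pairs at a log2 treatment effect of 1.5.
    """

    n_strains: int = 5
    n_genes: int = 2000
    n_replicates: int = 3
    n_tfs: int = 20
    targets_per_tf: int = 30
    promoter_len: int = 500
    motif_len: int = 12
    snp_rate: float = 0.005
    motif_variant_rate: float = 0.02
    motif_loss_rate: float = 0.02
    base_mean_log_mu: float = math.log(100.0)
    base_mean_log_sd: float = 1.2
    dispersion: float = 0.05
    planted_tfs: list[tuple[str, str, float]] | None = None
    expression_bm_sd: float = 0.25
    libsize_log_sd: float = 0.15
    cds_len: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strains", "n_genes", "n_replicates", "n_tfs",
                     "targets_per_tf", "promoter_len", "motif_len", "cds_len"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        for name in ("snp_rate", "motif_variant_rate", "motif_loss_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.motif_variant_rate + self.motif_loss_rate > 1.0:
            raise ConfigError("motif_variant_rate + motif_loss_rate must be <= 1")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.motif_len >= self.promoter_len:
            raise ConfigError("motif_len must be smaller than promoter_len")
        if self.n_tfs * self.targets_per_tf > self.n_genes:
            raise ConfigError("disjoint regulons need n_tfs * targets_per_tf <= n_genes")
        if self.planted_tfs is None:
            n = min(5, self.n_tfs)
            self.planted_tfs = [
                (self.tf_names[i], self.strain_names[i % self.n_strains], 1.5)
                for i in range(n)]
        tfs, strains = set(self.tf_names), set(self.strain_names)
        for tf, strain, _ in self.planted_tfs:
            if tf not in tfs or strain not in strains:
                raise ConfigError(f"planted pair ({tf}, {strain}) outside config")

    @property
    def strain_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_strains)]

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tfs)]

    @property
    def gene_names(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    tf_targets: dict[str, set[str]]
    responsive: set[tuple[str, str]]
    effects: dict[tuple[str, str], float]  # (gene, strain) -> log2 treated effect
    motif_positions: dict[tuple[str, str, str], int | None]  # (gene, strain, tf) -> pos
    motif_status: dict[tuple[str, str], tuple[str, str | None]]  # (gene, tf) -> (class, strain)
    consensus: dict[str, str]
    strain_tree: Node
    baseline_log2: pd.DataFrame  # genes x strains baseline log2 offsets
    size_factors: dict[str, float] = field(default_factory=dict)


def _random_tree(names: list[str], rng: np.random.Generator,
                 blen_lo: float = 0.2, blen_hi: float = 1.0) -> Node:
    """Random binary rooted tree by sequential attachment; branch lengths
    uniform and rescaled to mean root-to-leaf depth 1."""
    nodes = [Node(name=n) for n in names]
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(blen_lo, blen_hi))
        b.length = float(rng.uniform(blen_lo, blen_hi))
        parent = Node(children=[b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    if len(names) > 1:
        depths = []

        def _depth(node: Node, d: float) -> None:
            if node.is_leaf:
                depths.append(d)
            for c in node.children:
                _depth(c, d + c.length)

        _depth(root, 0.0)
        scale = 1.0 / (sum(depths) / len(depths))

        def _scale(node: Node) -> None:
            node.length *= scale
            for c in node.children:
                _scale(c)

        for c in root.children:
            _scale(c)
    return root


def _consensus_pwm(tf: str, consensus: str, cutoff_margin: float = 0.25) -> PWM:
    """Sharp PWM for a consensus: the cutoff admits the consensus and any
    single-substitution variant, and rejects two or more substitutions."""
    L = len(consensus)
    ll = np.full((4, L), _LL_LO)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, b in enumerate(consensus):
        ll[idx[b], j] = _LL_HI
    cutoff = L * _LL_HI - (_LL_HI - _LL_LO) - cutoff_margin
    return PWM(tf, ll, cutoff)


def simulate_promoters(cfg: SimConfig):
    """Simulate per-strain genomes with planted, SNP-shielded motif instances.

    Returns ``(fasta_map, gene_table, pwms, truth)`` where ``fasta_map`` maps
    strain -> {contig -> sequence}.  Genes alternate between the + and -
    strand so promoter extraction is exercised in both orientations.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    strains, genes, tfs = cfg.strain_names, cfg.gene_names, cfg.tf_names
    plen, L = cfg.promoter_len, cfg.motif_len

    tree = _random_tree(strains, rng)

    # distinct, non-self-reverse-complementary consensus motifs
    consensus: dict[str, str] = {}
    seen: set[str] = set()
    for tf in tfs:
        while True:
            cand = "".join(rng.choice(_BASES, size=L))
            if cand != revcomp(cand) and cand not in seen:
                break
        seen.add(cand)
        consensus[tf] = cand
    pwms = [_consensus_pwm(tf, consensus[tf]) for tf in tfs]
    pwm_by_tf = {p.tf_name: p for p in pwms}

    # disjoint regulons
    order = rng.permutation(cfg.n_genes)
    tf_targets: dict[str, set[str]] = {}
    plant_pos: dict[str, tuple[str, int]] = {}  # gene -> (tf, pos)
    k = 0
    for tf in tfs:
        members = {genes[i] for i in order[k:k + cfg.targets_per_tf]}
        tf_targets[tf] = members
        k += cfg.targets_per_tf
        for g in members:
            plant_pos[g] = (tf, int(rng.integers(0, plen - L + 1)))

    # ancestral promoters with planted consensus, then evolution along the tree
    anc = rng.integers(0, 4, size=(cfg.n_genes, plen), dtype=np.int8)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    protected = np.zeros((cfg.n_genes, plen), dtype=bool)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, (tf, pos) in plant_pos.items():
        gi = gene_index[g]
        anc[gi, pos:pos + L] = [code[b] for b in consensus[tf]]
        protected[gi, pos:pos + L] = True

    leaf_seqs: dict[str, np.ndarray] = {}
    leaf_expr: dict[str, np.ndarray] = {}

    def _evolve(node: Node, seqs: np.ndarray, expr: np.ndarray) -> None:
        for child in node.children:
            s = seqs.copy()
            if cfg.snp_rate > 0 and child.length > 0:
                p = min(1.0, cfg.snp_rate * child.length)
                mask = (rng.random(s.shape) < p) & ~protected
                n_mut = int(mask.sum())
                if n_mut:
                    shift = rng.integers(1, 4, size=n_mut).astype(np.int8)
                    s[mask] = (s[mask] + shift) % 4
            e = expr + rng.normal(0.0, cfg.expression_bm_sd * math.sqrt(max(child.length, 0.0)),
                                  size=expr.shape)
            if child.is_leaf:
                leaf_seqs[child.name] = s
                leaf_expr[child.name] = e
            else:
                _evolve(child, s, e)

    if tree.is_leaf:  # single strain
        leaf_seqs[tree.name] = anc.copy()
        leaf_expr[tree.name] = np.zeros(cfg.n_genes)
    else:
        _evolve(tree, anc, np.zeros(cfg.n_genes))

    # planted variant / loss events (mutually exclusive per target gene)
    motif_positions: dict[tuple[str, str, str], int | None] = {}
    motif_status: dict[tuple[str, str], tuple[str, str | None]] = {}
    for g, (tf, pos) in sorted(plant_pos.items()):
        gi = gene_index[g]
        for s in strains:
            motif_positions[(g, s, tf)] = pos
        u = float(rng.random())
        hit_strain = strains[int(rng.integers(0, len(strains)))]
        pwm = pwm_by_tf[tf]
        if u < cfg.motif_loss_rate and len(strains) > 1:
            arr = leaf_seqs[hit_strain]
            while True:
                repl = rng.integers(0, 4, size=L, dtype=np.int8)
                site = "".join(_BASES[repl])
                if (score_window(pwm, site) <= pwm.cutoff
                        and score_window(pwm, revcomp(site)) <= pwm.cutoff):
                    break
            arr[gi, pos:pos + L] = repl
            motif_positions[(g, hit_strain, tf)] = None
            motif_status[(g, tf)] = ("lost", hit_strain)
        elif u < cfg.motif_loss_rate + cfg.motif_variant_rate and len(strains) > 1:
            arr = leaf_seqs[hit_strain]
            j = int(rng.integers(0, L))
            arr[gi, pos + j] = (arr[gi, pos + j] + rng.integers(1, 4)) % 4
            motif_status[(g, tf)] = ("variant", hit_strain)
        else:
            motif_status[(g, tf)] = ("conserved", None)

    # assemble one contig per strain; genes alternate strands
    cds = rng.integers(0, 4, size=(cfg.n_genes, cfg.cds_len - 3), dtype=np.int8)
    atg = np.array([code["A"], code["T"], code["G"]], dtype=np.int8)
    gene_table: list[GeneRecord] = []
    fasta_map: dict[str, dict[str, str]] = {}
    for s in strains:
        parts: list[np.ndarray] = []
        offset = 0
        for gi, g in enumerate(genes):
            prom = leaf_seqs[s][gi]
            body = np.concatenate([atg, cds[gi]])
            if gi % 2 == 0:  # + strand: [promoter][cds]
                parts.extend([prom, body])
                start = offset + plen + 1
                end = start + cfg.cds_len - 1
                strand = "+"
            else:  # - strand: [revcomp(cds)][revcomp(promoter)]
                parts.extend([3 - body[::-1], 3 - prom[::-1]])
                start = offset + 1
                end = offset + cfg.cds_len
                strand = "-"
            offset += plen + cfg.cds_len
            if s == strains[0]:
                gene_table.append(GeneRecord(g, "chr1", start, end, strand))
        contig = "".join(_BASES[np.concatenate(parts)])
        fasta_map[s] = {"chr1": contig}

    responsive = {(tf, s) for tf, s, _ in cfg.planted_tfs}
    effects: dict[tuple[str, str], float] = {}
    for tf, s, eff in cfg.planted_tfs:
        for g in tf_targets[tf]:
            effects[(g, s)] = effects.get((g, s), 0.0) + eff

    baseline = pd.DataFrame({s: leaf_expr[s] for s in strains}, index=genes)
    truth = GroundTruth(tf_targets=tf_targets, responsive=responsive,
                        effects=effects, motif_positions=motif_positions,
                        motif_status=motif_status, consensus=consensus,
                        strain_tree=tree, baseline_log2=baseline)
    return fasta_map, gene_table, pwms, truth


def simulate_counts(cfg: SimConfig, truth: GroundTruth,
                    seed: int | None = None) -> CountExperiment:
    """Negative-binomial counts for the design in ``cfg``.

    mean(gene, strain, treated) / mean(gene, strain, untreated) = 2**effect
    for planted responsive regulons, 1 otherwise; variance = mu + alpha mu^2
    with the single shared dispersion alpha; per-sample library-size factors
    are log-normal and recorded in ``truth.size_factors``.
    """
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 1])
    genes, strains = cfg.gene_names, cfg.strain_names
    mu = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, size=cfg.n_genes)
    log2mu = np.log2(mu)

    eff = np.zeros((cfg.n_genes, len(strains)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for (g, s), e in truth.effects.items():
        eff[gene_index[g], strains.index(s)] += e

    cols: dict[str, np.ndarray] = {}
    meta = []
    truth.size_factors.clear()
    for si, s in enumerate(strains):
        base = log2mu + truth.baseline_log2[s].to_numpy()
        for cond in ("untreated", "treated"):
            lam = 2.0 ** (base + (eff[:, si] if cond == "treated" else 0.0))
            for rep in range(1, cfg.n_replicates + 1):
                sf = float(rng.lognormal(0.0, cfg.libsize_log_sd))
                sid = f"{s}_{cond}_{rep}"
                m = lam * sf
                if cfg.dispersion < 1e-8:
                    counts = rng.poisson(m)
                else:
                    r = 1.0 / cfg.dispersion
                    counts = rng.negative_binomial(r, r / (r + m))
                cols[sid] = counts.astype(np.int64)
                meta.append({"sample_id": sid, "strain": s, "condition": cond,
                             "replicate": rep})
                truth.size_factors[sid] = sf
    counts = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return CountExperiment(counts, samples)


def simulate_go_map(cfg: SimConfig, truth: GroundTruth,
                    n_background_terms: int = 20) -> dict[str, set[str]]:
    """Random gene -> GO assignment with one dedicated term per planted
    regulon, so GO enrichment on recovered regulons has a planted positive."""
    rng = np.random.default_rng([cfg.seed, 2])
    terms = [f"GO:B{i + 1:03d}" for i in range(n_background_terms)]
    out: dict[str, set[str]] = {}
    for g in cfg.gene_names:
        n = int(rng.integers(1, 4))
        out[g] = set(rng.choice(terms, size=n, replace=False))
    for tf, targets in truth.tf_targets.items():
        term = f"GO:R_{tf}"
        for g in targets:
            out[g].add(term)
    return out


def simulate_distance_fixture(n_taxa: int, seed: int, seq_len: int = 2000):
    """A random additive metric from a random tree, plus sequences evolved on
    it (Jukes-Cantor per branch).  Returns (sequences, DistanceMatrix, tree)."""
    if n_taxa < 3:
        raise ValueError("simulate_distance_fixture: need n_taxa >= 3")
    rng = np.random.default_rng([seed, 3])
    names = [f"T{i + 1}" for i in range(n_taxa)]
    tree = _random_tree(names, rng, blen_lo=0.02, blen_hi=0.25)

    root_seq = rng.integers(0, 4, size=seq_len, dtype=np.int8)
    seqs: dict[str, str] = {}

    def _evolve(node: Node, seq: np.ndarray) -> None:
        for child in node.children:
            s = seq.copy()
            p = 0.75 * (1.0 - math.exp(-4.0 * child.length / 3.0))
            mask = rng.random(seq_len) < p
            n_mut = int(mask.sum())
            if n_mut:
                s[mask] = rng.integers(0, 4, size=n_mut, dtype=np.int8)
            if child.is_leaf:
                seqs[child.name] = "".join(_BASES[s])
            else:
                _evolve(child, s)

    _evolve(tree, root_seq)
    return seqs, cophenetic(tree), tree
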