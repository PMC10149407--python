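"""Generate a synthetic multi-strain fixture and inspect its ground truth.

Builds the default study design — 5 strains x {treated, untreated} x 3
replicates, 2000 genes, 20 TF regulons of 30 genes, 5 responsive (TF,
strain) pairs at log2 effect 1.5 — and prints what was planted.
"""

from chapvar import SimConfig, simulate_counts, simulate_promoters

cfg = SimConfig(seed=7)
fasta_map, gene_table, pwms, truth = simulate_promoters(cfg)
expt = simulate_counts(cfg, truth)

print(f"strains: {cfg.strain_names}")
print(f"genome per strain: 1 contig of {len(fasta_map['S1']['chr1']):,} bp, "
      f"{len(gene_table)} genes (+/- strands alternating)")
print(f"PWM library: {len(pwms)} motifs of length {pwms[0].length}, "
      f"cutoff {pwms[0].cutoff:.2f}")
print(f"count matrix: {expt.counts.shape[0]} genes x {expt.counts.shape[1]} samples")

print("\nplanted responsive regulons (TF, strain, log2 effect):")
for tf, strain, eff in cfg.planted_tfs:
    print(f"  {tf} in {strain}: {len(truth.tf_targets[tf])} targets, "
          f"treated means shifted by 2^{eff} = {2**eff:.2f}x")

status = [v[0] for v in truth.motif_status.values()]
print(f"\nplanted motif instances: {len(status)} "
      f"({status.count('conserved')} conserved, "
      f"{status.count('variant')} with a variant in one strain, "
      f"{status.count('lost')} lost in one strain)")
print("Every quantity above is recorded in the GroundTruth object, so "
      "downstream stages can be scored against what was actually planted.")
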