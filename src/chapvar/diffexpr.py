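"""Count filtering, normalization, fold changes and DE / pair classification.

The DE test is a deliberately simple negative-binomial Wald test: counts are
normalized with median-of-ratios size factors, per-condition means get a 0.5
pseudocount, the log2 fold change (treated over untreated) is tested against
a delta-method variance using a method-of-moments NB dispersion, and p-values
are Benjamini-Hochberg adjusted.  A gene is differentially expressed when
the adjusted p-value is below ``alpha`` and the fold change exceeds
``fc_cut`` or falls below ``1/fc_cut``.

Strain-pair comparisons follow: a gene is strain-pair specific when the
ratio of its fold changes between two strains exceeds ``ratio_cut`` (or its
reciprocal), and pair-specific genes are classified *buffered* when the
between-strain expression difference is larger under treatment and
*potentiated* when it is larger untreated.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import CountExperiment
from .stats import adjust

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 0.01

BUFFERED = "buffered"
POTENTIATED = "potentiated"
TIE = "tie"


def filter_genes(expt: CountExperiment, min_count: int = 5,
                 mode: str = "max") -> CountExperiment:
    """Drop genes too weakly observed to analyse.

    ``mode="max"`` (default) removes a gene only when its count is below
    ``min_count`` in every sample; ``mode="min"`` applies the literal
    smallest-count reading and removes a gene when any sample falls below
    the threshold.  Genes with missing values are always removed.
    """
    counts = expt.counts
    keep = ~counts.isna().any(axis=1)
    counts = counts[keep]
    if mode == "max":
        keep = counts.max(axis=1) >= min_count
    elif mode == "min":
        keep = counts.min(axis=1) >= min_count
    else:
        raise ValueError(f"filter_genes: unknown mode {mode!r}")
    counts = counts[keep]
    if counts.shape[0] == 0:
        raise ValueError(
            "filter_genes removed every gene; review min_count / filter mode")
    return CountExperiment(counts, expt.samples)


def size_factors(expt: CountExperiment) -> pd.Series:
    """Median-of-ratios normalization factors (one per sample).

    Each sample's factor is the median, over genes expressed in every
    sample, of the ratio of its count to the gene's geometric mean.
    """
    counts = expt.counts.to_numpy(dtype=float)
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError("size_factors: no gene has nonzero counts in every sample")
    sub = counts[usable]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return pd.Series(factors, index=expt.counts.columns, name="size_factor")


def _moments_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Gene-wise method-of-moments NB dispersion, averaged over conditions."""
    ests = []
    for cols in groups:
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        ests.append(a)
    est = np.nanmean(np.stack(ests), axis=0)
    return est


def _pooled_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> float:
    """Bias-corrected pooled moments dispersion.

    Solves sum(v - m) = alpha * sum(mu^2) across genes and conditions, with
    E[m^2] = mu^2 + (mu + alpha mu^2)/n corrected via the denominator
    m^2 - v/n.  Far less biased than the median of gene-wise estimates at
    small replicate counts.
    """
    num = 0.0
    den = 0.0
    for cols in groups:
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float((v - m).sum())
        den += float((np.square(m) - v / len(cols)).sum())
    if den <= 0:
        return DISPERSION_FLOOR
    return num / den


def de_test(expt: CountExperiment, strain: str, alpha: float = 0.05,
            fc_cut: float = 2.0, factors: pd.Series | None = None,
            dispersion_mode: str = "pooled") -> pd.DataFrame:
    """Per-gene treated/untreated Wald test for one strain.

    ``dispersion_mode="pooled"`` (default) uses the median of gene-wise
    method-of-moments dispersions across all genes of the strain — with
    only a few replicates, gene-wise estimates are too noisy to hold the
    nominal test level.  ``"genewise"`` keeps per-gene estimates.  Both are
    floored at 0.01.

    Returns a DataFrame indexed by gene with columns base_mean_untreated,
    base_mean_treated, log2fc, p, adj_p, is_de.
    """
    treated = expt.sample_ids(strain=strain, condition="treated")
    untreated = expt.sample_ids(strain=strain, condition="untreated")
    if len(treated) < 2 or len(untreated) < 2:
        raise ValueError(f"de_test: strain {strain} needs >= 2 replicates per condition")
    if factors is None:
        factors = size_factors(expt)
    cols = treated + untreated
    norm = expt.counts[cols].to_numpy(dtype=float) / factors[cols].to_numpy()
    t_idx = np.arange(len(treated))
    u_idx = np.arange(len(treated), len(cols))

    m_t = norm[:, t_idx].mean(axis=1)
    m_u = norm[:, u_idx].mean(axis=1)
    log2fc = np.log2(m_t + PSEUDOCOUNT) - np.log2(m_u + PSEUDOCOUNT)

    if dispersion_mode == "pooled":
        pooled = _pooled_dispersion(norm, [t_idx, u_idx])
        disp = np.full(norm.shape[0], max(pooled, DISPERSION_FLOOR))
    elif dispersion_mode == "genewise":
        disp = _moments_dispersion(norm, [t_idx, u_idx])
        disp = np.where(np.isfinite(disp), disp, DISPERSION_FLOOR)
        disp = np.maximum(disp, DISPERSION_FLOOR)
    else:
        raise ValueError(f"de_test: unknown dispersion_mode {dispersion_mode!r}")

    ln2sq = math.log(2.0) ** 2
    var_t = (m_t + disp * m_t ** 2) / len(t_idx)
    var_u = (m_u + disp * m_u ** 2) / len(u_idx)
    var_log2fc = (var_t / np.square(m_t + PSEUDOCOUNT)
                  + var_u / np.square(m_u + PSEUDOCOUNT)) / ln2sq
    sd = np.sqrt(np.maximum(var_log2fc, 1e-300))
    z = log2fc / sd
    p = 2.0 * _sps.norm.sf(np.abs(z))
    adj = np.array(adjust(list(p), "bh"))
    fc = np.exp2(log2fc)
    is_de = (adj < alpha) & ((fc > fc_cut) | (fc < 1.0 / fc_cut))
    return pd.DataFrame({
        "base_mean_untreated": m_u,
        "base_mean_treated": m_t,
        "log2fc": log2fc,
        "p": p,
        "adj_p": adj,
        "is_de": is_de,
    }, index=expt.counts.index)


def tpm(expt: CountExperiment, lengths: dict[str, float] | pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to sum 1e6."""
    lens = pd.Series(lengths).reindex(expt.counts.index)
    if lens.isna().any() or (lens <= 0).any():
        raise ValueError("tpm: every gene needs a positive length")
    rate = expt.counts.div(lens / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("tpm: zero total rate in a sample")
    return rate.div(totals, axis=1) * 1e6


def classify_buffered_potentiated(gene: str, de_a: pd.DataFrame,
                                  de_b: pd.DataFrame) -> str:
    """Buffered / potentiated / tie for one pair-specific gene.

    D+ = |log2 treated-mean difference| between the strains, D- likewise
    untreated; buffered when D+ > D- (divergence released under chaperone
    inhibition), potentiated when D+ < D-.
    """
    ra, rb = de_a.loc[gene], de_b.loc[gene]
    d_plus = abs(math.log2(ra["base_mean_treated"] + PSEUDOCOUNT)
                 - math.log2(rb["base_mean_treated"] + PSEUDOCOUNT))
    d_minus = abs(math.log2(ra["base_mean_untreated"] + PSEUDOCOUNT)
                  - math.log2(rb["base_mean_untreated"] + PSEUDOCOUNT))
    if d_plus > d_minus:
        return BUFFERED
    if d_plus < d_minus:
        return POTENTIATED
    return TIE


def pair_specific(de_a: pd.DataFrame, de_b: pd.DataFrame,
                  ratio_cut: float = 2.0, require_de: bool = True) -> pd.DataFrame:
    """Strain-pair-specific genes for one unordered strain pair.

    fc_ratio is the linear fold-change ratio FC_A / FC_B (both with the DE
    pseudocount); a gene is pair-specific when the ratio exceeds
    ``ratio_cut`` or falls below its reciprocal.  With ``require_de`` only
    genes DE in at least one strain of the pair are eligible.  Genes present
    in only one strain are skipped.
    """
    common = de_a.index.intersection(de_b.index)
    a = de_a.loc[common]
    b = de_b.loc[common]
    ratio = np.exp2(a["log2fc"] - b["log2fc"])
    specific = (ratio > ratio_cut) | (ratio < 1.0 / ratio_cut)
    if require_de:
        specific &= a["is_de"] | b["is_de"]
    d_plus = np.abs(np.log2(a["base_mean_treated"] + PSEUDOCOUNT)
                    - np.log2(b["base_mean_treated"] + PSEUDOCOUNT))
    d_minus = np.abs(np.log2(a["base_mean_untreated"] + PSEUDOCOUNT)
                     - np.log2(b["base_mean_untreated"] + PSEUDOCOUNT))
    bp = np.where(d_plus > d_minus, BUFFERED,
                  np.where(d_plus < d_minus, POTENTIATED, TIE))
    return pd.DataFrame({
        "fc_ratio": ratio,
        "is_pair_specific": specific,
        "bp_class": np.where(specific, bp, "none"),
    }, index=common)


def strain_pairs(strains: list[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(strains), 2))
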