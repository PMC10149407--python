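"""Promoter extraction, PWM scanning and cross-strain motif conservation.

Promoters are the 500 bp immediately 5' of the translation start on the
coding strand.  Each PWM is slid one base at a time over the promoter on
both strands; a window whose summed log-likelihood exceeds the PWM's cutoff
(strictly) is a putative TFBS.  Hits are compared across strains on a
multiple sequence alignment of the orthologous promoters: hits of the same
TF falling within a 20-column window of each other are grouped, and a group
is *conserved* (hit in every strain, identical site sequence),
*conserved_with_variation* (hit in every strain, sequence differs) or
*non_conserved* (gained/lost in at least one strain).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .io import PWM, GeneRecord

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

CONSERVED = "conserved"
CONSERVED_WITH_VARIATION = "conserved_with_variation"
NON_CONSERVED = "non_conserved"
CLASSES = (CONSERVED, CONSERVED_WITH_VARIATION, NON_CONSERVED)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3; anything else (N) becomes -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class TFBSHit:
    """One scored motif occurrence on a promoter.

    ``pos`` is the 0-based index of the window start within the promoter
    string (coding-strand orientation); ``upstream_offset`` is the 1-based
    distance from the translation start to the hit base nearest it, the
    convention used when reporting sites as "N bp upstream".
    """

    tf_name: str
    pos: int
    upstream_offset: int
    strand_rel: str
    score: float
    site_seq: str
    gene_id: str = ""
    strain: str = ""


@dataclass
class Promoter:
    gene_id: str
    seq: str
    truncated: bool = False


@dataclass
class ConservationRecord:
    gene_id: str
    tf_name: str
    anchor_offset: int
    status: str
    hits: dict[str, TFBSHit | None] = field(default_factory=dict)


def extract_promoter(genome: dict[str, str], gene: GeneRecord,
                     promoter_len: int = 500) -> Promoter:
    """The ``promoter_len`` bases immediately 5' of the translation start on
    the coding strand (reverse-complemented for --strand genes).  Genes with
    fewer upstream bases yield a shorter promoter flagged truncated."""
    if gene.seq_id not in genome:
        raise ValueError(f"gene {gene.gene_id}: sequence {gene.seq_id} not in genome")
    contig = genome[gene.seq_id]
    if gene.strand == "+":
        lo = max(0, gene.start - 1 - promoter_len)
        seq = contig[lo:gene.start - 1]
    else:
        seq = revcomp(contig[gene.end:gene.end + promoter_len])
    return Promoter(gene.gene_id, seq, truncated=len(seq) < promoter_len)


def score_window(pwm: PWM, window: str) -> float:
    """Summed log-likelihood of one window; NaN when the window contains a
    base the PWM cannot score (the caller skips such windows)."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    enc = encode(window)
    if (enc < 0).any():
        return math.nan
    return float(pwm.loglik[enc, np.arange(pwm.length)].sum())


def scan_promoter(pwm: PWM, promoter: str) -> list[TFBSHit]:
    """All windows on both strands scoring strictly above the PWM cutoff.

    Reverse-strand windows are scored on the reverse complement but reported
    at the coding-strand coordinates they cover, with ``site_seq`` in coding
    orientation.  Windows containing N are skipped.  Hits are sorted by
    ascending upstream offset (nearest the translation start first).
    """
    plen = len(promoter)
    L = pwm.length
    if plen < L:
        warnings.warn(f"promoter shorter than motif ({plen} < {L}); no windows scanned")
        return []
    enc = encode(promoter)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows >= 0).all(axis=1)
    cols = np.arange(L)
    fwd = pwm.loglik[windows, cols].sum(axis=1)
    rc = pwm.reverse_complement()
    rev = rc.loglik[windows, cols].sum(axis=1)
    hits: list[TFBSHit] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        for i in np.nonzero(valid & (scores > pwm.cutoff))[0]:
            i = int(i)
            hits.append(TFBSHit(
                tf_name=pwm.tf_name,
                pos=i,
                upstream_offset=plen - (i + L - 1),
                strand_rel=strand,
                score=float(scores[i]),
                site_seq=promoter[i:i + L],
            ))
    hits.sort(key=lambda h: (h.upstream_offset, h.strand_rel))
    return hits


def scan_promoter_set(pwms: list[PWM], promoters: dict[str, str],
                      strain: str = "") -> dict[tuple[str, str], list[TFBSHit]]:
    """Scan every promoter with every PWM in one vectorised pass.

    Equal-length promoters are stacked, one-hot encoded once, and scored for
    all PWMs (both strands) with a single matrix product per length group.
    Returns {(gene_id, tf_name): hits}; genes/TF pairs without hits are absent.
    """
    out: dict[tuple[str, str], list[TFBSHit]] = {}
    if not pwms or not promoters:
        return out
    by_len: dict[int, list[str]] = {}
    for g, seq in promoters.items():
        by_len.setdefault(len(seq), []).append(g)
    max_l = max(p.length for p in pwms)
    for plen, genes in by_len.items():
        usable = [p for p in pwms if p.length <= plen]
        if not usable:
            continue
        enc = np.stack([encode(promoters[g]) for g in genes])  # (G, plen)
        for L in sorted({p.length for p in usable}):
            group = [p for p in usable if p.length == L]
            wins = np.lib.stride_tricks.sliding_window_view(enc, L, axis=1)  # (G, W, L)
            G, W, _ = wins.shape
            flat = wins.reshape(-1, L)
            valid = (flat >= 0).all(axis=1)
            eye = np.eye(4, dtype=np.float32)
            onehot = eye[np.maximum(flat, 0)].reshape(flat.shape[0], 4 * L)
            # weight matrix: per PWM two columns (forward, reverse-complement)
            wmat = np.zeros((4 * L, 2 * len(group)), dtype=np.float32)
            for k, pwm in enumerate(group):
                wmat[:, 2 * k] = pwm.loglik.T.ravel()
                wmat[:, 2 * k + 1] = pwm.reverse_complement().loglik.T.ravel()
            scores = onehot @ wmat  # (G*W, 2*n_pwm)
            scores[~valid] = -np.inf
            for k, pwm in enumerate(group):
                for strand, col in (("+", 2 * k), ("-", 2 * k + 1)):
                    sc = scores[:, col]
                    # float32 scoring is screened with a small guard band and
                    # confirmed in float64 so cutoff ties behave exactly
                    for flat_i in np.nonzero(sc > pwm.cutoff - 1e-4)[0]:
                        gi, wi = divmod(int(flat_i), W)
                        gene = genes[gi]
                        site = promoters[gene][wi:wi + L]
                        window = site if strand == "+" else revcomp(site)
                        exact = score_window(pwm, window)
                        if not (exact > pwm.cutoff):
                            continue
                        out.setdefault((gene, pwm.tf_name), []).append(TFBSHit(
                            tf_name=pwm.tf_name, pos=wi,
                            upstream_offset=plen - (wi + L - 1),
                            strand_rel=strand, score=exact, site_seq=site,
                            gene_id=gene, strain=strain))
    for hits in out.values():
        hits.sort(key=lambda h: (h.upstream_offset, h.strand_rel))
    return out


# --------------------------------------------------------------------------
# Promoter alignment (center star, Needleman-Wunsch pairwise)


@dataclass
class PromoterAlignment:
    """Gapped promoter rows of equal length plus strains absent (empty input)."""

    rows: dict[str, str]
    absent: list[str] = field(default_factory=list)

    def columns_of(self, strain: str) -> np.ndarray:
        """Map ungapped sequence position -> 0-based alignment column."""
        row = np.frombuffer(self.rows[strain].encode("ascii"), dtype=np.uint8)
        return np.nonzero(row != ord("-"))[0]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -2.0
    return a


def align_promoters(promoters: dict[str, str]) -> PromoterAlignment:
    """Center-star multiple alignment of orthologous promoters.

    The center is the strain minimising the summed pairwise Needleman-Wunsch
    distance (match +1, mismatch -1, gap -2); the other strains' pairwise
    alignments to the center are merged with the usual "once a gap, always a
    gap" rule.  Strains with empty promoters are excluded and reported absent.
    """
    absent = sorted(s for s, seq in promoters.items() if not seq)
    present = {s: seq for s, seq in promoters.items() if seq}
    if len(present) < 2:
        raise ValueError("align_promoters: need >= 2 non-empty promoters")
    strains = sorted(present)
    if len(set(present.values())) == 1:
        return PromoterAlignment({s: present[s] for s in strains}, absent)

    aligner = _aligner()
    totals = {s: 0.0 for s in strains}
    for i, a in enumerate(strains):
        for b in strains[i + 1:]:
            sc = aligner.score(present[a], present[b])
            totals[a] += sc
            totals[b] += sc
    center = max(strains, key=lambda s: (totals[s], s))
    cseq = present[center]
    n = len(cseq)

    # pairwise alignments decomposed against center positions:
    # ins[s][k] = bases of s inserted before center position k; sub[s][k] =
    # the base of s aligned to center position k ('-' for deletion)
    ins: dict[str, list[str]] = {}
    sub: dict[str, list[str]] = {}
    for s in strains:
        if s == center:
            continue
        aln = aligner.align(cseq, present[s])[0]
        gc, gs = str(aln[0]), str(aln[1])
        ins_s: list[str] = [""] * (n + 1)
        sub_s: list[str] = []
        k = 0
        for cc, sc_ in zip(gc, gs):
            if cc == "-":
                ins_s[k] += sc_
            else:
                sub_s.append(sc_)
                k += 1
        ins[s], sub[s] = ins_s, sub_s

    master = [0] * (n + 1)
    for s in ins:
        for k in range(n + 1):
            master[k] = max(master[k], len(ins[s][k]))

    rows: dict[str, str] = {}
    crow = []
    for k in range(n):
        crow.append("-" * master[k] + cseq[k])
    crow.append("-" * master[n])
    rows[center] = "".join(crow)
    for s in strains:
        if s == center:
            continue
        parts = []
        for k in range(n):
            block = ins[s][k]
            parts.append(block + "-" * (master[k] - len(block)) + sub[s][k])
        block = ins[s][n]
        parts.append(block + "-" * (master[n] - len(block)))
        rows[s] = "".join(parts)
    return PromoterAlignment(rows, absent)


# --------------------------------------------------------------------------
# Conservation classification


def classify_conservation(hits_by_strain: dict[str, list[TFBSHit]],
                          alignment: PromoterAlignment,
                          window_bp: int = 20,
                          gene_id: str = "") -> list[ConservationRecord]:
    """Group hits of one gene across strains and classify each group.

    Hits of the same TF whose alignment columns differ by at most
    ``window_bp`` columns are grouped greedily left to right (anchor = the
    leftmost ungrouped hit; nearest-column candidate per strain, ties going
    to the higher score).  A group with a hit in every aligned strain is
    conserved (identical site sequence) or conserved-with-variation;
    a missing strain (including strains absent from the alignment) makes the
    group non-conserved.
    """
    all_strains = sorted(set(alignment.rows) | set(alignment.absent) | set(hits_by_strain))
    colmaps = {s: alignment.columns_of(s) for s in alignment.rows}
    # flatten: (column, strain, hit), per tf
    by_tf: dict[str, list[tuple[int, str, TFBSHit]]] = {}
    for strain, hits in hits_by_strain.items():
        if strain not in colmaps:
            continue  # absent strain cannot carry hits into the alignment
        for h in hits:
            col = int(colmaps[strain][h.pos])
            by_tf.setdefault(h.tf_name, []).append((col, strain, h))

    records: list[ConservationRecord] = []
    for tf in sorted(by_tf):
        pool = sorted(by_tf[tf], key=lambda t: (t[0], -t[2].score, t[1]))
        used = [False] * len(pool)
        for a_i, (a_col, a_strain, a_hit) in enumerate(pool):
            if used[a_i]:
                continue
            used[a_i] = True
            group: dict[str, TFBSHit] = {a_strain: a_hit}
            for s in all_strains:
                if s == a_strain or s in alignment.absent:
                    continue
                best = None
                for c_i, (col, strain, hit) in enumerate(pool):
                    if used[c_i] or strain != s or abs(col - a_col) > window_bp:
                        continue
                    key = (abs(col - a_col), -hit.score)
                    if best is None or key < best[0]:
                        best = (key, c_i, hit)
                if best is not None:
                    used[best[1]] = True
                    group[s] = best[2]
            if set(group) == set(all_strains):
                seqs = {h.site_seq for h in group.values()}
                status = CONSERVED if len(seqs) == 1 else CONSERVED_WITH_VARIATION
            else:
                status = NON_CONSERVED
            records.append(ConservationRecord(
                gene_id=gene_id or a_hit.gene_id, tf_name=tf,
                anchor_offset=a_hit.upstream_offset, status=status,
                hits={s: group.get(s) for s in all_strains}))
    return records


def motif_support_fraction(target_sets: dict[str, set[str]],
                           hit_genes: dict[str, set[str]]) -> dict[str, float]:
    """Per TF, the fraction of externally supplied target genes whose promoter
    carries at least one predicted hit for that TF."""
    out: dict[str, float] = {}
    for tf, targets in target_sets.items():
        if not targets:
            raise ValueError(f"motif_support_fraction: empty target set for {tf}")
        if tf not in hit_genes:
            warnings.warn(f"TF {tf} has no scanned motif; skipped")
            continue
        out[tf] = len(targets & hit_genes[tf]) / len(targets)
    return out
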