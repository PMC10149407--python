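"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (80-column wrap on write), a PWM library dialect
(``>NAME cutoff=<float>`` followed by four ``A:/C:/G:/T:`` rows of
log-likelihoods), gene-coordinate tables (TSV, 1-based inclusive
coordinates), count matrices with a sample sheet, gene -> GO mappings, and
newick trees with branch lengths.

Readers validate aggressively and never silently drop records: malformed
input raises :class:`FormatError` naming the offending record, and
counts/sample-sheet mismatches raise :class:`ConsistencyError`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .trees import Node

DNA_ALPHABET = set("ACGTN")
CONDITIONS = ("treated", "untreated")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (e.g. counts and sample sheet) do not."""


@dataclass(frozen=True)
class GeneRecord:
    """Gene coordinates, 1-based inclusive; the translation start sits at
    ``start`` for +-strand genes and at ``end`` for --strand genes."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates are 1-based")


_PWM_BASES = ("A", "C", "G", "T")


@dataclass
class PWM:
    """Position weight matrix of per-position log-likelihoods.

    ``loglik`` has 4 rows in A, C, G, T order and one column per motif
    position; a window scores above ``cutoff`` to be called a putative TFBS.
    """

    tf_name: str
    loglik: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.loglik = np.asarray(self.loglik, dtype=float)
        if self.loglik.ndim != 2 or self.loglik.shape[0] != 4 or self.loglik.shape[1] < 1:
            raise ValueError(f"PWM {self.tf_name}: loglik must be 4 x L with L >= 1")
        if not np.all(np.isfinite(self.loglik)) or not math.isfinite(self.cutoff):
            raise ValueError(f"PWM {self.tf_name}: non-finite values")

    @property
    def length(self) -> int:
        return self.loglik.shape[1]

    def reverse_complement(self) -> "PWM":
        """PWM scoring the reverse complement: rows swapped A<->T, C<->G and
        columns reversed."""
        return PWM(self.tf_name, self.loglik[::-1, ::-1], self.cutoff)


class CountExperiment:
    """Gene x sample raw-count matrix plus its sample sheet.

    ``counts`` is a genes x samples integer DataFrame; ``samples`` is indexed
    by sample id with columns strain, condition and replicate.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        counts = counts.copy()
        samples = samples.copy()
        if counts.index.duplicated().any():
            counts = counts[~counts.index.duplicated(keep="first")]
        if counts.columns.duplicated().any():
            counts = counts.loc[:, ~counts.columns.duplicated(keep="first")]
        missing = [c for c in counts.columns if c not in samples.index]
        if missing:
            raise ConsistencyError(
                f"samples in counts absent from sample sheet: {', '.join(missing)}")
        samples = samples.loc[list(counts.columns)]
        bad = samples.index[~samples["condition"].isin(CONDITIONS)]
        if len(bad):
            raise FormatError(f"sample {bad[0]}: condition must be treated/untreated")
        self.counts = counts
        self.samples = samples

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def strains(self) -> list[str]:
        return sorted(self.samples["strain"].unique())

    def sample_ids(self, strain: str | None = None, condition: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if strain is not None:
            mask &= self.samples["strain"] == strain
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def subset_genes(self, genes) -> "CountExperiment":
        return CountExperiment(self.counts.loc[list(genes)], self.samples)


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence map (upper-cased A/C/G/T/N)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {rec.id}: illegal character(s) {''.join(sorted(bad))}")
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id}")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --------------------------------------------------------------------------
# PWM library dialect

_PWM_HEADER = re.compile(r">(\S+)\s+cutoff=([-+0-9.eE]+)\s*$")


def read_pwm_library(path) -> list[PWM]:
    """Parse the PWM library dialect, one ``>NAME cutoff=<float>`` block per TF
    followed by exactly four ``A:/C:/G:/T:`` rows of log-likelihoods."""
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        m = _PWM_HEADER.match(lines[i])
        if not m:
            if lines[i].startswith(">"):
                raise FormatError(f"PWM header missing cutoff: {lines[i]!r}")
            raise FormatError(f"expected PWM header, got {lines[i]!r}")
        name, cutoff = m.group(1), float(m.group(2))
        rows = []
        for base in _PWM_BASES:
            if i + 1 + len(rows) >= len(lines):
                raise FormatError(f"PWM {name}: missing {base} row")
            ln = lines[i + 1 + len(rows)]
            if not ln.startswith(f"{base}:"):
                raise FormatError(f"PWM {name}: expected '{base}:' row, got {ln!r}")
            try:
                rows.append([float(v) for v in ln.split(":", 1)[1].split()])
            except ValueError as e:
                raise FormatError(f"PWM {name}: bad value in {base} row") from e
        if len({len(r) for r in rows}) != 1:
            raise FormatError(f"PWM {name}: rows of unequal length")
        pwms.append(PWM(name, np.array(rows), cutoff))
        i += 5
    if not pwms:
        raise FormatError(f"{path}: no PWM blocks found")
    return pwms


def write_pwm_library(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name} cutoff={pwm.cutoff:g}\n")
            for base, row in zip(_PWM_BASES, pwm.loglik):
                fh.write(f"{base}: " + " ".join(f"{v:.6g}" for v in row) + "\n")


# --------------------------------------------------------------------------
# Counts + sample sheet


def read_counts(counts_path, samples_path) -> CountExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.shape[1] == 0:
        raise FormatError(f"{counts_path}: no sample columns")
    for col in counts.columns:
        vals = counts[col]
        if vals.isna().any():
            raise FormatError(f"count matrix: missing value in sample {col}")
        arr = vals.to_numpy()
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FormatError(f"count matrix: non-integer count in sample {col}")
        if (arr < 0).any():
            raise FormatError(f"count matrix: negative count in sample {col}")
    counts = counts.astype(np.int64)
    samples = read_sample_sheet(samples_path)
    return CountExperiment(counts, samples)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str})
    required = {"sample_id", "strain", "condition", "replicate"}
    if not required.issubset(sheet.columns):
        raise FormatError(f"sample sheet missing columns: {required - set(sheet.columns)}")
    if sheet["sample_id"].duplicated().any():
        raise FormatError("sample sheet: duplicate sample_id")
    if (sheet["replicate"] < 1).any():
        raise FormatError("sample sheet: replicate must be >= 1")
    if not sheet["condition"].isin(CONDITIONS).all():
        raise FormatError("sample sheet: condition must be treated/untreated")
    return sheet.set_index("sample_id")


def write_counts(expt: CountExperiment, counts_path, samples_path) -> None:
    expt.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    expt.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")


# --------------------------------------------------------------------------
# Gene table


def read_gene_table(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "seq_id": str, "strand": str})
    required = {"gene_id", "seq_id", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"gene table missing columns: {required - set(df.columns)}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise FormatError(f"gene table: duplicate gene_id {dup}")
    out = []
    for row in df.itertuples(index=False):
        try:
            out.append(GeneRecord(row.gene_id, row.seq_id, int(row.start),
                                  int(row.end), row.strand))
        except ValueError as e:
            raise FormatError(str(e)) from e
    if not out:
        raise FormatError(f"{path}: empty gene table")
    return out


def write_gene_table(genes: list[GeneRecord], path) -> None:
    pd.DataFrame([g.__dict__ for g in genes]).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# GO map


def read_go_map(path) -> dict[str, set[str]]:
    """Read a gene -> GO-term mapping from a TSV with >= 2 columns
    (gene id, term id); extra columns are ignored and duplicate pairs collapse."""
    out: dict[str, set[str]] = {}
    n_rows = 0
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                continue
            if parts[0] == "gene_id":  # optional header
                continue
            out.setdefault(parts[0], set()).add(parts[1])
            n_rows += 1
    if n_rows == 0:
        raise FormatError(f"{path}: no parsable gene/GO rows")
    return out


def write_go_map(go_map: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_id\n")
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


# --------------------------------------------------------------------------
# Newick


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: Node) -> str:
    """Serialize a tree to newick with branch lengths, ';'-terminated."""
    if len(tree.leaves()) < 2:
        raise ValueError("write_newick: tree must have >= 2 leaves")

    def _rec(node: Node, top: bool) -> str:
        if node.is_leaf:
            if not node.name:
                raise ValueError("write_newick: unnamed leaf")
            return f"{node.name}:{_fmt_len(node.length)}"
        inner = ",".join(_rec(c, False) for c in node.children)
        if top:
            return f"({inner})"
        label = node.name or ""
        return f"({inner}){label}:{_fmt_len(node.length)}"

    return _rec(tree, True) + ";"
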