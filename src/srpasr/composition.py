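"""Amino-acid chronology statistics and alignment summaries.

The chronology orders amino acids by their inferred time of entry into the
canonical genetic code; the consensus ordering used here runs Gly/Ala first
through Trp last, with the late set {Cys, His, Phe, Met, Tyr, Trp}.  Ancestral
sequences reconstructed for very old nodes are scored for their usage of the
late residues and compared against a WAG-simulation null distribution with an
empirical (add-one) one-sided p-value.

Also provided: BLOSUM62 pairwise identity/positive statistics for whole
alignments and the variance-then-means support comparison (F-test followed by
a pooled-variance one-tailed t-test, plus a cumulative support-fraction
table) used to contrast posterior supports between alternative trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .errors import DomainError
from .seqio import AA_ORDER, GAP, MISSING_CODE, Alignment, parse_label, ungapped_length
from .simulate import NullDistribution

__all__ = [
    "Chronology", "DomainAnnotation", "DEFAULT_CHRONOLOGY", "count_residues",
    "composition_summary", "depletion_test", "pairwise_identity_stats",
    "support_comparison", "read_domain_annotation",
]


@dataclass(frozen=True)
class Chronology:
    """Ordered entry of amino acids into the genetic code, earliest first."""

    groups: tuple[tuple[str, ...], ...]
    late_set: frozenset[str]

    def __post_init__(self):
        flat = [a for g in self.groups for a in g]
        if sorted(flat) != sorted(AA_ORDER):
            raise DomainError("chronology must cover each of the 20 residues exactly once")
        if not self.late_set <= set(flat):
            raise DomainError("late_set must be a subset of the chronology residues")


#: Consensus chronology: Gly/Ala, Val/Asp, Pro, Ser, Glu/Leu, Thr, Arg, Asn,
#: Lys, Gln, Ile, Cys, His, Phe, Met, Tyr, Trp ("Try" in some sources = Tyr).
DEFAULT_CHRONOLOGY = Chronology(
    groups=(("G", "A"), ("V", "D"), ("P",), ("S",), ("E", "L"), ("T",),
            ("R",), ("N",), ("K",), ("Q",), ("I",), ("C",), ("H",), ("F",),
            ("M",), ("Y",), ("W",)),
    late_set=frozenset("CHFMYW"),
)


@dataclass
class DomainAnnotation:
    """Named half-open [start, end) intervals on master alignment columns."""

    intervals: dict[str, tuple[int, int]]

    def validate(self, n_columns: int) -> None:
        for name, (start, end) in self.intervals.items():
            if not (0 <= start < end <= n_columns):
                raise DomainError(f"domain {name!r}: interval [{start}, {end}) "
                                  f"invalid for {n_columns} columns")


def read_domain_annotation(path) -> DomainAnnotation:
    """TSV with columns name, start, end (0-based half-open master columns)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "start", "end"],
                     comment="#")
    intervals = {str(r.name_): (int(r.start), int(r.end))
                 for r in df.rename(columns={"name": "name_"}).itertuples()}
    if len(intervals) != len(df):
        raise DomainError("duplicate domain names")
    return DomainAnnotation(intervals=intervals)


def count_residues(seq: str, residues: Sequence[str] | set[str],
                   interval: Optional[tuple[int, int]] = None) -> int:
    """Count positions in ``residues`` (gaps never count), optionally within
    a half-open column interval."""
    if interval is not None:
        start, end = interval
        if not (0 <= start <= end <= len(seq)):
            raise DomainError(f"interval [{start}, {end}) out of bounds for length {len(seq)}")
        seq = seq[start:end]
    rset = set(residues) - {GAP}
    return sum(1 for c in seq if c in rset)


def composition_summary(seqs: Sequence[tuple[str, str]],
                        chronology: Chronology = DEFAULT_CHRONOLOGY,
                        groupby: str = "sequence",
                        domains: Optional[DomainAnnotation] = None) -> pd.DataFrame:
    """Late-residue count table per sequence/gene/taxon group and per domain.

    Returns a tidy frame with one row per (group, residue, region) holding
    count statistics (n, mean, median, quartiles, min, max) over the member
    sequences.  With ``groupby="sequence"`` each row describes one sequence
    (mean == count).
    """
    if groupby not in ("sequence", "gene", "taxon_group"):
        raise DomainError(f"unknown groupby {groupby!r}")
    regions: dict[str, Optional[tuple[int, int]]] = {"whole": None}
    if domains is not None:
        regions.update(domains.intervals)

    rows = []
    for header, seq in seqs:
        if groupby == "sequence":
            group = header
        else:
            label = parse_label(header)
            group = label.gene if groupby == "gene" else label.taxon_group
        for residue in sorted(chronology.late_set):
            for region, interval in regions.items():
                rows.append({"group": group, "residue": residue, "region": region,
                             "count": count_residues(seq, {residue}, interval),
                             "ungapped_length": ungapped_length(seq)})
    raw = pd.DataFrame(rows)
    agg = (raw.groupby(["group", "residue", "region"])["count"]
              .agg(n="size", mean="mean", median="median",
                   q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75),
                   min="min", max="max")
              .reset_index())
    return agg


def depletion_test(observed: int, null: NullDistribution) -> tuple[float, Optional[float]]:
    """One-sided empirical test that ``observed`` is low relative to the null.

    p = (1 + #{null <= observed}) / (n_sims + 1); the z-score is
    (observed - mean)/SD, absent when the null is degenerate (zero variance).
    """
    if null.n_sims < 20:
        raise DomainError("null distribution needs at least 20 simulations")
    counts = null.counts
    p = (1 + int((counts <= observed).sum())) / (null.n_sims + 1)
    sd = counts.std(ddof=1)
    z = float((observed - counts.mean()) / sd) if sd > 0 else None
    return p, z


def pairwise_identity_stats(alignment: Alignment,
                            scoring: str = "BLOSUM62") -> tuple[float, float]:
    """Mean percent identity and percent positives over all unordered pairs.

    Per pair the denominator is the number of columns where at least one
    member holds a residue (gap-gap columns excluded; residue-gap columns are
    mismatches); "positive" pairs are residue pairs whose substitution score
    is strictly > 0.
    """
    if len(alignment) < 2:
        raise DomainError("need at least 2 records")
    mat = substitution_matrices.load(scoring)
    score = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            score[i, j] = mat[a][b]
    positive = score > 0

    enc = alignment.encoded()
    n = enc.shape[0]
    ids, poss = [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[i], enc[j]
            either = (a != MISSING_CODE) | (b != MISSING_CODE)
            denom = int(either.sum())
            if denom == 0:
                continue
            both = (a != MISSING_CODE) & (b != MISSING_CODE)
            same = int(((a == b) & both).sum())
            pos = int(positive[a[both], b[both]].sum())
            ids.append(100.0 * same / denom)
            poss.append(100.0 * pos / denom)
    return float(np.mean(ids)), float(np.mean(poss))


@dataclass
class SupportComparison:
    f_statistic: float
    f_p: float
    t_statistic: Optional[float]
    t_p: Optional[float]
    degenerate: bool
    mean_a: float
    mean_b: float
    cumulative: pd.DataFrame  # support level x, fraction of nodes >= x, per list


def support_comparison(supports_a: Sequence[float],
                       supports_b: Sequence[float]) -> SupportComparison:
    """Compare two sets of node supports: F-test on variances, then a
    pooled-variance one-tailed t-test (alternative: mean_a > mean_b), plus a
    cumulative support-fraction table on a 0.01 grid."""
    a = np.asarray(supports_a, dtype=float)
    b = np.asarray(supports_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise DomainError("each support list needs at least 3 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    degenerate = va == 0 or vb == 0
    if degenerate:
        f_stat, f_p, t_stat, t_p = np.nan, np.nan, None, None
    else:
        f_stat = va / vb
        # two-sided F-test for variance equality
        f_p = 2 * min(stats.f.cdf(f_stat, len(a) - 1, len(b) - 1),
                      stats.f.sf(f_stat, len(a) - 1, len(b) - 1))
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
        t_stat, t_p = float(t_stat), float(t_p)
    grid = np.round(np.arange(0, 1.01, 0.01), 2)
    cumulative = pd.DataFrame({
        "support": grid,
        "fraction_a": [(a >= x).mean() for x in grid],
        "fraction_b": [(b >= x).mean() for x in grid],
    })
    return SupportComparison(f_statistic=float(f_stat) if f_stat == f_stat else np.nan,
                             f_p=f_p, t_statistic=t_stat, t_p=t_p,
                             degenerate=degenerate,
                             mean_a=float(a.mean()), mean_b=float(b.mean()),
                             cumulative=cumulative)


def gene_mean_count(alignment: Alignment, residue: str,
                    genes: tuple[str, ...] = ("Ffh", "FtsY")) -> tuple[float, int, int]:
    """Mean/min/max per-sequence count of one residue over records of the
    given genes (used for extant-protein baselines)."""
    counts = [count_residues(seq, {residue}) for header, seq in alignment
              if parse_label(header).gene in genes]
    if not counts:
        raise DomainError(f"no records with gene in {genes}")
    return float(np.mean(counts)), int(np.min(counts)), int(np.max(counts))
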