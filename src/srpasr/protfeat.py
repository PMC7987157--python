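"""Physicochemical sequence features: isoelectric point, hydropathy,
localization heuristic, MTS-region extraction.

The isoelectric point uses the Henderson-Hasselbalch net-charge sum with the
Bjellqvist pK constants (the set used by the common web calculators) and
bisection on pH in [0, 14]; net charge is strictly decreasing in pH, so the
bisection always converges when the endpoint charges have opposite signs.

The localization call is a deliberately simple heuristic on mean
Kyte-Doolittle hydropathy: it approximates the qualitative cytoplasmic vs
membrane distinction made by dedicated classifiers but is not equivalent to
any of them, and should be read as a sign/ordering indicator only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import DomainError
from .seqio import GAP

__all__ = [
    "PKSet", "BJELLQVIST", "net_charge", "isoelectric_point",
    "mean_hydropathy", "classify_localization", "extract_mts", "MtsResult",
]


@dataclass(frozen=True)
class PKSet:
    """pK values for the ionizable side chains and the termini."""

    d: float
    e: float
    c: float
    y: float
    h: float
    k: float
    r: float
    n_term: float
    c_term: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not 0 < v < 14:
                raise DomainError(f"pK {name}={v} outside (0, 14)")


#: Bjellqvist constants (single N-terminal value; the per-residue N-terminal
#: refinements of the original tables shift pI by < 0.1 for typical proteins).
BJELLQVIST = PKSet(d=4.05, e=4.45, c=9.0, y=10.0, h=5.98, k=10.0, r=12.0,
                   n_term=7.5, c_term=3.55)

_POSITIVE = {"K": "k", "R": "r", "H": "h"}
_NEGATIVE = {"D": "d", "E": "e", "C": "c", "Y": "y"}


def net_charge(seq: str, pH: float, pks: PKSet = BJELLQVIST) -> float:
    """Henderson-Hasselbalch net charge at the given pH."""
    if not seq:
        raise DomainError("empty sequence")
    if GAP in seq:
        raise DomainError("gapped input; degap before computing charge")
    charge = 1.0 / (1.0 + 10 ** (pH - pks.n_term))
    charge -= 1.0 / (1.0 + 10 ** (pks.c_term - pH))
    for ch in seq:
        if ch in _POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (pH - getattr(pks, _POSITIVE[ch])))
        elif ch in _NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (getattr(pks, _NEGATIVE[ch]) - pH))
    return charge


def isoelectric_point(seq: str, pks: PKSet = BJELLQVIST,
                      tol: float = 1e-3) -> tuple[float, bool]:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Returns ``(pI, converged)``; when the charge does not change sign on the
    interval the nearer boundary is returned with ``converged=False``.
    """
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(seq, lo, pks), net_charge(seq, hi, pks)
    if c_lo < 0:  # all-acidic edge case: negative everywhere
        return lo, False
    if c_hi > 0:
        return hi, False
    while hi - lo > tol / 10:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pks) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), True


def mean_hydropathy(seq: str, scale: Optional[dict[str, float]] = None) -> float:
    """Arithmetic mean of the hydropathy scale over residues (default
    Kyte-Doolittle); X is excluded from numerator and denominator."""
    scale = KYTE_DOOLITTLE if scale is None else scale
    seq = seq.replace(GAP, "")
    vals = [scale[c] for c in seq if c in scale]
    if not vals:
        raise DomainError("no scorable residues in sequence")
    return sum(vals) / len(vals)


def classify_localization(h: float, threshold: float = 0.6) -> str:
    """'transmembrane_like' iff mean hydropathy >= threshold, else
    'cytoplasmic'.  Heuristic approximation of hydrophobicity-based
    localization classifiers; the boundary itself classifies as
    transmembrane_like."""
    return "transmembrane_like" if h >= threshold else "cytoplasmic"


@dataclass(frozen=True)
class MtsResult:
    found: bool
    interval: Optional[tuple[int, int]] = None   # half-open on the degapped query
    subsequence: Optional[str] = None
    pI: Optional[float] = None
    score: Optional[float] = None


def extract_mts(seq: str, reference_mts: str,
                score_floor_fraction: float = 0.3,
                open_gap: float = -11.0, extend_gap: float = -1.0) -> MtsResult:
    """Locate the membrane-targeting-sequence region by global alignment of a
    reference MTS to the (degapped) query and report its isoelectric point.

    The hit is rejected (``found=False``) when the alignment score falls
    below ``score_floor_fraction`` x the reference self-alignment score.
    """
    seq = seq.replace(GAP, "")
    if not seq or not reference_mts:
        raise DomainError("empty sequence or reference")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    # do not penalise the reference landing inside a longer query
    try:
        aligner.end_insertion_score = 0.0
    except AttributeError:  # older Bio.Align naming
        aligner.target_end_gap_score = 0.0

    self_score = aligner.score(reference_mts, reference_mts)
    aln = aligner.align(seq, reference_mts)[0]
    if aln.score < score_floor_fraction * self_score:
        return MtsResult(found=False, score=float(aln.score))
    blocks = aln.aligned[0]
    start, end = int(blocks[0][0]), int(blocks[-1][1])
    sub = seq[start:end]
    pi, _ = isoelectric_point(sub)
    return MtsResult(found=True, interval=(start, end), subsequence=sub,
                     pI=pi, score=float(aln.score))
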