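"""Female-enrichment interval scan over sex-pooled depth tracks.

The scan proceeds in four stages:

1. *Valid-base masking.* A base is valid iff its pooled depths satisfy
   ``(C_f < max_f and C_m < max_m) and (C_f > min_f or C_m > min_m)``; the
   upper limits skip collapsed repeats, the lower limits skip bases with too
   few reads in both sexes to be informative.
2. *Interval construction.* Scanning left to right within each scaffold, an
   interval closes once it has accumulated ``V`` valid bases (default 1000);
   the scaffold end closes a final, possibly shorter interval. Boundaries
   are trimmed to the first/last valid base, and intervals partition the
   valid bases of a scaffold exactly.
3. *Scoring.* Each interval gets an enrichment score
   ``log2(mean_f / (adjustment * mean_m))`` with means taken over valid bases.
   When the male mean is exactly zero it is replaced by the depth equivalent
   of half of one aligned read, ``(read_length / 2) / span``, and the interval
   is flagged ``zero_male``.
4. *Filtering and calling.* Intervals spanning fewer than 500 bp or holding
   fewer than 200 valid bases are dropped; of the rest, those with score
   strictly greater than 2 are called W-candidates and aggregated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .covprof import Limits, SexCoverageProfile

__all__ = [
    "ValidBaseMask",
    "CandidateInterval",
    "CandidateReport",
    "valid_mask",
    "scan_intervals",
    "score_interval",
    "score_intervals",
    "filter_intervals",
    "call_candidates",
    "run_scan",
    "write_candidate_bed",
    "write_interval_tsv",
]

#: scaffold -> boolean array, True where the base is valid
ValidBaseMask = Dict[str, np.ndarray]


def valid_mask(profile: SexCoverageProfile, limits: Limits) -> ValidBaseMask:
    """Boolean mask of valid bases (strict inequalities on raw pooled depth)."""
    mask: ValidBaseMask = {}
    for name in profile.female_track.scaffolds():
        cf = profile.female_track[name]
        cm = profile.male_track[name]
        mask[name] = (
            (cf < limits.max_f)
            & (cm < limits.max_m)
            & ((cf > limits.min_f) | (cm > limits.min_m))
        )
    return mask


@dataclass
class CandidateInterval:
    """A scanned interval with its valid-base summary and enrichment score.

    ``mean_m`` is the raw pooled male mean over valid bases; ``mean_m_adj``
    (set at scoring) is that mean after the male-coverage adjustment and,
    when ``zero_male``, after the half-read substitution.
    """

    scaffold: str
    start: int
    end: int
    n_valid: int
    mean_f: float
    mean_m: float
    mean_m_adj: Optional[float] = None
    score: Optional[float] = None
    zero_male: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("interval must have start < end")
        if self.n_valid > self.span:
            raise ValueError("n_valid cannot exceed span")

    @property
    def span(self) -> int:
        return self.end - self.start


def scan_intervals(
    profile: SexCoverageProfile,
    mask: ValidBaseMask,
    V: int = 1000,
    means_over: str = "valid",
) -> List[CandidateInterval]:
    """Partition each scaffold's valid bases into consecutive runs of V.

    Returns unscored intervals (means filled in), trimmed to their
    first/last valid base; the terminal interval of a scaffold may hold
    fewer than V valid bases. Scaffolds with no valid base yield nothing.
    ``means_over`` selects whether interval means average the valid bases
    only (default) or every base of the trimmed span (``"all"``).
    """
    if V < 1:
        raise ValueError("V must be >= 1")
    if means_over not in ("valid", "all"):
        raise ValueError("means_over must be 'valid' or 'all'")
    out: List[CandidateInterval] = []
    for name in profile.female_track.scaffolds():
        m = mask[name]
        idx = np.flatnonzero(m)
        if idx.size == 0:
            continue
        cf = profile.female_track[name]
        cm = profile.male_track[name]
        vf = cf[idx].astype(np.float64)
        vm = cm[idx].astype(np.float64)
        for lo in range(0, idx.size, V):
            hi = min(lo + V, idx.size)
            start = int(idx[lo])
            end = int(idx[hi - 1]) + 1
            n_valid = hi - lo
            if means_over == "valid":
                mean_f = float(vf[lo:hi].mean())
                mean_m = float(vm[lo:hi].mean())
            else:
                mean_f = float(cf[start:end].mean())
                mean_m = float(cm[start:end].mean())
            out.append(
                CandidateInterval(
                    scaffold=name,
                    start=start,
                    end=end,
                    n_valid=n_valid,
                    mean_f=mean_f,
                    mean_m=mean_m,
                )
            )
    return out


def score_interval(
    iv: CandidateInterval, adjustment: float, read_length: int = 125
) -> CandidateInterval:
    """Return a scored copy of ``iv``.

    ``score = log2(mean_f / (adjustment * mean_m))``. A zero male mean is
    substituted with the coverage of half of one read over the interval,
    ``(read_length / 2) / span``, and flagged. A valid interval cannot have
    both means zero (every valid base exceeds a lower limit in one sex).
    """
    if adjustment <= 0:
        raise ValueError("adjustment must be positive")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    mean_m = iv.mean_m
    zero_male = mean_m == 0.0
    if zero_male:
        if iv.mean_f == 0.0:
            raise AssertionError(
                "interval with zero coverage in both sexes cannot contain valid bases"
            )
        mean_m = (read_length / 2.0) / iv.span
    mean_m_adj = adjustment * mean_m
    score = math.log2(iv.mean_f / mean_m_adj)
    return replace(iv, mean_m_adj=mean_m_adj, score=score, zero_male=zero_male)


def score_intervals(
    intervals: Sequence[CandidateInterval], adjustment: float, read_length: int = 125
) -> List[CandidateInterval]:
    return [score_interval(iv, adjustment, read_length) for iv in intervals]


def filter_intervals(
    intervals: Sequence[CandidateInterval],
    min_span: int = 500,
    min_valid: int = 200,
) -> List[CandidateInterval]:
    """Drop short or information-poor intervals.

    Keeps intervals with span >= ``min_span`` and n_valid >= ``min_valid``
    (both bounds inclusive: the exclusion rule is 'fewer than').
    """
    return [iv for iv in intervals if iv.span >= min_span and iv.n_valid >= min_valid]


@dataclass
class CandidateReport:
    """Aggregate of intervals whose enrichment score exceeds the threshold."""

    intervals: List[CandidateInterval]
    threshold: float
    per_scaffold: Dict[str, int] = field(init=False)
    n_intervals: int = field(init=False)
    n_scaffolds: int = field(init=False)
    n_scaffolds_multi: int = field(init=False)
    n_zero_male: int = field(init=False)
    total_span: int = field(init=False)

    def __post_init__(self) -> None:
        per: Dict[str, int] = {}
        for iv in self.intervals:
            per[iv.scaffold] = per.get(iv.scaffold, 0) + 1
        self.per_scaffold = per
        self.n_intervals = len(self.intervals)
        self.n_scaffolds = len(per)
        self.n_scaffolds_multi = sum(1 for c in per.values() if c >= 2)
        self.n_zero_male = sum(1 for iv in self.intervals if iv.zero_male)
        self.total_span = sum(iv.span for iv in self.intervals)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_intervals": self.n_intervals,
            "n_scaffolds": self.n_scaffolds,
            "n_scaffolds_multi": self.n_scaffolds_multi,
            "n_zero_male": self.n_zero_male,
            "total_span": self.total_span,
            "per_scaffold": self.per_scaffold,
        }


def call_candidates(
    intervals: Sequence[CandidateInterval], threshold: float = 2.0
) -> CandidateReport:
    """Keep intervals with score strictly greater than ``threshold`` and
    aggregate per-scaffold counts, total span and zero-male counts."""
    for iv in intervals:
        if iv.score is None:
            raise ValueError("intervals must be scored before calling")
    called = [iv for iv in intervals if iv.score > threshold]
    return CandidateReport(called, threshold)


def run_scan(
    profile: SexCoverageProfile,
    limits: Limits,
    V: int = 1000,
    read_length: int = 125,
    min_span: int = 500,
    min_valid: int = 200,
    threshold: float = 2.0,
) -> tuple[List[CandidateInterval], CandidateReport]:
    """Full scan: mask, build, score, filter, call.

    Returns (all scored unfiltered intervals, candidate report).
    """
    mask = valid_mask(profile, limits)
    intervals = scan_intervals(profile, mask, V=V)
    scored = score_intervals(intervals, profile.adjustment, read_length=read_length)
    kept = filter_intervals(scored, min_span=min_span, min_valid=min_valid)
    report = call_candidates(kept, threshold=threshold)
    return scored, report


def write_candidate_bed(report: CandidateReport, path) -> None:
    """Candidate intervals as BED, enrichment score in column 5."""
    with open(path, "w") as fh:
        for iv in report.intervals:
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\tcandidate\t{iv.score:.4f}\n")


def write_interval_tsv(intervals: Sequence[CandidateInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tspan\tn_valid\tmean_f\tmean_m\tmean_m_adj\tscore\tzero_male\n")
        for iv in intervals:
            adj = "" if iv.mean_m_adj is None else f"{iv.mean_m_adj:.6g}"
            sc = "" if iv.score is None else f"{iv.score:.6g}"
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.span}\t{iv.n_valid}\t"
                f"{iv.mean_f:.6g}\t{iv.mean_m:.6g}\t{adj}\t{sc}\t{int(iv.zero_male)}\n"
            )


def write_report_json(report: CandidateReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
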