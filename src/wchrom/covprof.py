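"""Depth extraction, sex pooling, modal coverage, validity limits.

Per-base depth is computed from coordinate-sorted SAM/BAM with the filters
the downstream scan assumes: unmapped, secondary and supplementary records
are dropped (jointly SAM flag mask 2308), as are alignments clipped at both
ends of the read. Depth counts aligned reference-consuming positions only
(standard pileup semantics — no insertions or soft-clipped bases).

Pooled female and male tracks are summarised by their modal (most frequent
non-zero) depth, which anchors both the valid-base limits — lower limit one
third of the mode (floored), upper limit three times the mode — and the
male-coverage adjustment factor modal_f / modal_m applied before ratio
formation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .tracks import DepthTrack

__all__ = [
    "FILTER_FLAG_MASK",
    "Limits",
    "SexCoverageProfile",
    "depth_from_alignments",
    "merge_by_sex",
    "modal_coverage",
    "derive_limits",
    "adjustment_factor",
    "write_profile_tsv",
]

#: unmapped (4) + secondary (256) + supplementary (2048)
FILTER_FLAG_MASK = 2308

_CLIP_OPS = {4, 5}  # soft, hard


def _is_both_side_clipped(read: pysam.AlignedSegment) -> bool:
    cig = read.cigartuples
    if not cig or len(cig) < 2:
        return False
    return cig[0][0] in _CLIP_OPS and cig[-1][0] in _CLIP_OPS


def depth_from_alignments(path, apply_filters: bool = True) -> DepthTrack:
    """Per-base depth from a coordinate-sorted SAM/BAM file.

    With ``apply_filters`` set, records that are unmapped, secondary or
    supplementary, or soft/hard-clipped at both ends, do not contribute.
    Raises ``ValueError`` for headerless or non-coordinate-sorted input.
    """
    with pysam.AlignmentFile(str(path), check_sq=True) as af:
        header = af.header.to_dict()
        if not header.get("SQ"):
            raise ValueError(f"{path}: no sequence header")
        so = header.get("HD", {}).get("SO")
        if so != "coordinate":
            raise ValueError(f"{path}: alignment file must be coordinate-sorted (SO={so!r})")
        lengths = {sq["SN"]: sq["LN"] for sq in header["SQ"]}
        diffs = {name: np.zeros(n + 1, dtype=np.int64) for name, n in lengths.items()}
        for read in af:
            if read.is_unmapped:
                continue
            if apply_filters:
                if read.flag & FILTER_FLAG_MASK:
                    continue
                if _is_both_side_clipped(read):
                    continue
            d = diffs[read.reference_name]
            for start, end in read.get_blocks():
                d[start] += 1
                d[end] -= 1
    return DepthTrack({name: np.cumsum(d[:-1]) for name, d in diffs.items()})


def merge_by_sex(
    tracks: Sequence[Tuple[DepthTrack, str]]
) -> Tuple[DepthTrack, DepthTrack, int, int]:
    """Pool per-individual tracks by sex (per-base sum).

    Returns (female_track, male_track, n_females, n_males); raises if the
    scaffold sets/lengths disagree or either sex is absent (no coverage
    ratio can be formed).
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    ref_lengths = tracks[0][0].lengths()
    pooled: Dict[str, Optional[DepthTrack]] = {"female": None, "male": None}
    counts = {"female": 0, "male": 0}
    for track, sex in tracks:
        if sex not in pooled:
            raise ValueError(f"unknown sex label {sex!r}")
        if track.lengths() != ref_lengths:
            raise ValueError("tracks cover different scaffold sets/lengths")
        if pooled[sex] is None:
            pooled[sex] = DepthTrack({k: v.copy() for k, v in track.depths.items()})
        else:
            pooled[sex].iadd(track)
        counts[sex] += 1
    if counts["female"] == 0 or counts["male"] == 0:
        raise ValueError("both sexes required to form a coverage ratio")
    return pooled["female"], pooled["male"], counts["female"], counts["male"]


def modal_coverage(track: DepthTrack) -> int:
    """Most frequent non-zero depth; ties break toward the smaller depth."""
    max_depth = max((int(arr.max()) if len(arr) else 0) for arr in track.depths.values())
    if max_depth == 0:
        raise ValueError("track has no covered bases")
    counts = np.zeros(max_depth + 1, dtype=np.int64)
    for arr in track.depths.values():
        counts += np.bincount(arr, minlength=max_depth + 1)
    # exclude depth 0; argmax returns the first (smallest) maximal depth
    return int(np.argmax(counts[1:]) + 1)


@dataclass(frozen=True)
class Limits:
    """Valid-base depth limits per sex (lower exclusive, upper exclusive)."""

    min_f: int
    min_m: int
    max_f: int
    max_m: int

    def __post_init__(self) -> None:
        if not (self.min_f < self.max_f and self.min_m < self.max_m):
            raise ValueError("lower limit must be below upper limit for each sex")
        if min(self.min_f, self.min_m) < 0:
            raise ValueError("limits must be non-negative")


def derive_limits(
    modal_f: int,
    modal_m: int,
    lower_frac: float = 1.0 / 3.0,
    upper_mult: float = 3.0,
) -> Limits:
    """Limits from modal coverages: lower = floor(lower_frac * mode),
    upper = upper_mult * mode.

    Flooring the lower limit reproduces the canonical pairs (mode 25 -> 8/75,
    mode 29 -> 9/87); nearest-rounding would not.
    """
    if modal_f < 1 or modal_m < 1:
        raise ValueError("modal coverages must be >= 1")
    eps = 1e-9
    return Limits(
        min_f=math.floor(lower_frac * modal_f + eps),
        min_m=math.floor(lower_frac * modal_m + eps),
        max_f=math.floor(upper_mult * modal_f + eps),
        max_m=math.floor(upper_mult * modal_m + eps),
    )


@dataclass
class SexCoverageProfile:
    """Pooled female/male depth with modal summaries and adjustment factor."""

    female_track: DepthTrack
    male_track: DepthTrack
    modal_f: int
    modal_m: int
    n_females: int
    n_males: int
    adjustment: float

    def __post_init__(self) -> None:
        if self.modal_f < 1 or self.modal_m < 1:
            raise ValueError("modal coverages must be >= 1")
        if self.adjustment <= 0:
            raise ValueError("adjustment must be positive")
        if self.female_track.lengths() != self.male_track.lengths():
            raise ValueError("female and male tracks disagree on scaffolds")

    @classmethod
    def from_tracks(
        cls,
        tracks: Sequence[Tuple[DepthTrack, str]],
        adjustment_method: str = "modal",
    ) -> "SexCoverageProfile":
        """Pool per-individual tracks and summarise."""
        f, m, n_f, n_m = merge_by_sex(tracks)
        return cls.from_pooled(f, m, n_f, n_m, adjustment_method)

    @classmethod
    def from_pooled(
        cls,
        female_track: DepthTrack,
        male_track: DepthTrack,
        n_females: int,
        n_males: int,
        adjustment_method: str = "modal",
    ) -> "SexCoverageProfile":
        modal_f = modal_coverage(female_track)
        modal_m = modal_coverage(male_track)
        profile = cls(female_track, male_track, modal_f, modal_m, n_females, n_males, 1.0)
        profile.adjustment = adjustment_factor(profile, adjustment_method)
        return profile


def adjustment_factor(profile: SexCoverageProfile, method: str = "modal") -> float:
    """Factor multiplying male coverage before forming the female:male ratio.

    ``modal`` (default): modal_f / modal_m, anchoring the correction to the
    same statistic as the validity limits. ``throughput``: total female bases
    over total male bases, correcting for sequencing yield instead.
    """
    if method == "modal":
        return profile.modal_f / profile.modal_m
    if method == "throughput":
        tot_m = profile.male_track.total()
        if tot_m == 0:
            raise ValueError("male track has no coverage")
        return profile.female_track.total() / tot_m
    raise ValueError(f"unknown adjustment method {method!r}")


def write_profile_tsv(profile: SexCoverageProfile, limits: Limits, path) -> None:
    with open(path, "w") as fh:
        fh.write("modal_f\tmodal_m\tn_females\tn_males\tadjustment\tmin_f\tmin_m\tmax_f\tmax_m\n")
        fh.write(
            f"{profile.modal_f}\t{profile.modal_m}\t{profile.n_females}\t{profile.n_males}\t"
            f"{profile.adjustment:.6g}\t{limits.min_f}\t{limits.min_m}\t{limits.max_f}\t{limits.max_m}\n"
        )
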