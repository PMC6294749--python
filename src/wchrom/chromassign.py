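"""Scaffold-to-chromosome assignment by physical coverage of perfect pairs.

Reads from a laser-captured chromosome library, aligned to the assembly as
pairs, tie a scaffold to that chromosome when enough of it is spanned by
concordant, mismatch-free read pairs. "Physical" coverage counts the outer
span of each pair (the sequenced fragment), not per-base read depth; a
scaffold is assigned when at least 5% of its bases fall under the union of
such fragments. A marker-representation QC summarises how many known
linkage-group markers received any reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import pysam

__all__ = [
    "FragmentSet",
    "AssignmentResult",
    "filter_perfect_pairs",
    "physical_fraction",
    "fractions_from_fragments",
    "assign",
    "marker_representation",
    "write_assignment_tsv",
]

#: scaffold -> list of (start, end) fragment outer spans, 0-based half-open
FragmentSet = Dict[str, List[Tuple[int, int]]]


def _edit_distance(read: pysam.AlignedSegment):
    try:
        return read.get_tag("NM")
    except KeyError:
        return None


def filter_perfect_pairs(path) -> FragmentSet:
    """Fragments from concordant, mismatch-free read pairs.

    Keeps primary, mapped, properly-paired records whose edit distance (NM
    tag) is 0 for *both* mates and whose mates map to the same scaffold; each
    surviving pair contributes one fragment spanning the pair's outermost
    coordinates. Records lacking the NM tag are excluded (conservative).
    Unpaired records raise a format error.
    """
    pending: Dict[str, Tuple[str, int, int, bool]] = {}
    frags: FragmentSet = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if not read.is_paired:
                raise ValueError(f"{path}: record {read.query_name!r} lacks mate-pairing flags")
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_proper_pair:
                continue
            nm = _edit_distance(read)
            ok = nm == 0
            key = read.query_name
            if key not in pending:
                pending[key] = (read.reference_name, read.reference_start, read.reference_end, ok)
            else:
                ref2, s2, e2, ok2 = pending.pop(key)
                if not (ok and ok2):
                    continue
                if read.reference_name != ref2:
                    continue  # discordant: mates on different scaffolds
                frag = (min(read.reference_start, s2), max(read.reference_end, e2))
                frags.setdefault(read.reference_name, []).append(frag)
    return frags


def physical_fraction(fragments: Sequence[Tuple[int, int]], scaffold_length: int) -> float:
    """Fraction of a scaffold under the union of fragment spans."""
    if scaffold_length <= 0:
        raise ValueError("scaffold_length must be positive")
    if not fragments:
        return 0.0
    covered = 0
    cur_s = cur_e = None
    for s, e in sorted(fragments):
        if not (0 <= s < e <= scaffold_length):
            raise ValueError(f"fragment ({s}, {e}) outside scaffold of length {scaffold_length}")
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return covered / scaffold_length


def fractions_from_fragments(
    frags: FragmentSet, lengths: Mapping[str, int]
) -> Dict[str, float]:
    """Physical-coverage fraction for every scaffold in ``lengths``."""
    return {
        name: physical_fraction(frags.get(name, []), length)
        for name, length in lengths.items()
    }


@dataclass
class AssignmentResult:
    """Per-scaffold physical-coverage fraction and assignment call."""

    fractions: Dict[str, float]
    assigned: Dict[str, bool]
    threshold: float

    def assigned_scaffolds(self) -> List[str]:
        return [name for name, flag in self.assigned.items() if flag]


def assign(fractions: Mapping[str, float], threshold: float = 0.05) -> AssignmentResult:
    """Assign scaffolds whose covered fraction is at least ``threshold``
    (inclusive boundary)."""
    for name, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction for {name!r} outside [0, 1]")
    assigned = {name: f >= threshold for name, f in fractions.items()}
    return AssignmentResult(dict(fractions), assigned, threshold)


def marker_representation(
    hit_counts: Mapping[str, int], markers: Sequence[str]
) -> Tuple[float, Dict[str, int]]:
    """Library QC: fraction of known markers with at least one mapped read.

    Returns (fraction hit, per-marker read counts over the full marker list);
    hits to markers outside the list are ignored.
    """
    if not markers:
        raise ValueError("marker list must be non-empty")
    counts = {m: int(hit_counts.get(m, 0)) for m in markers}
    hit = sum(1 for c in counts.values() if c >= 1)
    return hit / len(markers), counts


def write_assignment_tsv(
    result: AssignmentResult, lengths: Mapping[str, int], path
) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tlength\tfraction_covered\tassigned\n")
        for name, frac in result.fractions.items():
            fh.write(f"{name}\t{lengths.get(name, '')}\t{frac:.6g}\t{int(result.assigned[name])}\n")
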