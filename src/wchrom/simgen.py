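"""Synthetic genomes and sex-structured coverage for a ZW system.

Emulates the coverage structure of a pooled male/female resequencing panel
over a homomorphic-sex-chromosome genome: a diploid background, hemizygous
W-specific segments (1 copy in ZW females, 0 in ZZ males), Z-hemizygous
segments (1 copy in females, 2 in males), collapsed high-copy repeats that
inflate depth in both sexes, and sex-independent segregating deletion
polymorphisms. Per-base depth is drawn as an independent Poisson counting
process with mean proportional to copy number; an optional alignment-emission
path writes placed reads so the alignment-filtering code can be exercised
end to end.

Defaults mirror the study design this package targets: 22 females and 26
males at ~1X per-individual depth, with on the order of 0.4% of a 10-Mb
synthetic genome planted as W-specific sequence in 2-kb segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .tracks import DepthTrack, write_bedgraph

__all__ = [
    "SegmentClass",
    "AUTOSOMAL",
    "SHARED_SEX",
    "W_SPECIFIC",
    "Z_HEMIZYGOUS",
    "repeat_class",
    "GenomeModel",
    "IndividualSpec",
    "SimConfig",
    "build_genome_model",
    "make_panel",
    "individual_seed",
    "simulate_depth",
    "simulate_pooled",
    "emit_alignments",
    "write_truth_bed",
    "write_reference_fasta",
    "write_panel_tsv",
    "run_simulation",
]

SEGMENT_LABELS = {"autosomal", "shared_sex", "w_specific", "z_hemizygous", "repeat"}


@dataclass(frozen=True)
class SegmentClass:
    """Copy-number class of a genomic segment in each sex.

    ``repeat_multiplier`` models a collapsed repeat family: reads from many
    near-identical genomic copies pile onto a single reference locus, so the
    apparent depth is the diploid depth times the family size.
    """

    label: str
    copy_female: int
    copy_male: int
    repeat_multiplier: float = 1.0

    def __post_init__(self) -> None:
        # labels outside the canonical set are allowed (e.g. mirrored classes
        # in symmetry checks) but carry no enforced copy structure
        if self.copy_female < 0 or self.copy_male < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.repeat_multiplier < 1:
            raise ValueError("repeat_multiplier must be >= 1")
        expected = {
            "w_specific": (1, 0),
            "z_hemizygous": (1, 2),
            "autosomal": (2, 2),
            "shared_sex": (2, 2),
        }
        if self.label in expected and (self.copy_female, self.copy_male) != expected[self.label]:
            raise ValueError(
                f"{self.label} segments must have copies {expected[self.label]}"
            )
        if self.label in expected and self.repeat_multiplier != 1.0:
            raise ValueError("repeat_multiplier != 1 only allowed for repeat segments")

    def mean_copy(self, sex: str) -> float:
        copy = self.copy_female if sex == "female" else self.copy_male
        return copy * self.repeat_multiplier


AUTOSOMAL = SegmentClass("autosomal", 2, 2)
SHARED_SEX = SegmentClass("shared_sex", 2, 2)
W_SPECIFIC = SegmentClass("w_specific", 1, 0)
Z_HEMIZYGOUS = SegmentClass("z_hemizygous", 1, 2)


def repeat_class(multiplier: float) -> SegmentClass:
    """A collapsed repeat present in both sexes at ``multiplier`` diploid copies."""
    return SegmentClass("repeat", 2, 2, repeat_multiplier=float(multiplier))


Segment = Tuple[int, int, SegmentClass]


@dataclass
class GenomeModel:
    """Truth model: scaffolds tiled by copy-number segments.

    ``scaffolds`` is an ordered list of (name, length, segments); segments are
    (start, end, SegmentClass) in 0-based half-open coordinates, sorted,
    non-overlapping and tiling each scaffold exactly.

    ``indel_loci`` lists sex-independent segregating deletions as
    (scaffold, start, end, deletion_allele_frequency); each individual draws
    its diploid copy number at these loci independently of sex.
    """

    scaffolds: List[Tuple[str, int, List[Segment]]]
    indel_loci: List[Tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, length, segments in self.scaffolds:
            if length <= 0:
                raise ValueError(f"scaffold {name!r} has non-positive length")
            pos = 0
            for start, end, cls in segments:
                if start != pos or end <= start:
                    raise ValueError(
                        f"segments on {name!r} must be sorted, positive-length "
                        "and tile the scaffold exactly"
                    )
                pos = end
            if pos != length:
                raise ValueError(f"segments on {name!r} do not tile to its length")

    def lengths(self) -> Dict[str, int]:
        return {name: length for name, length, _ in self.scaffolds}

    def total_length(self) -> int:
        return sum(length for _, length, _ in self.scaffolds)

    def truth_intervals(self, label: str) -> List[Tuple[str, int, int]]:
        """All (scaffold, start, end) segments of a given class label."""
        out = []
        for name, _, segments in self.scaffolds:
            for start, end, cls in segments:
                if cls.label == label:
                    out.append((name, start, end))
        return out

    def planted_total(self, label: str) -> int:
        return sum(e - s for _, s, e in self.truth_intervals(label))


@dataclass(frozen=True)
class IndividualSpec:
    """One sequenced animal: sex, expected diploid depth and its RNG seed."""

    id: str
    sex: str
    target_depth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")


@dataclass
class SimConfig:
    """Parameters of a synthetic panel.

    Defaults encode the study conditions the package is tested against:
    a 10-Mb genome in 50 scaffolds, 20 W-specific and 20 Z-hemizygous
    segments of 2 kb each, 10 collapsed repeats at 10x the diploid copy
    number, 20 sex-independent deletion polymorphisms segregating at
    frequency 0.3, and a 22-female / 26-male panel at ~1X each.
    """

    n_scaffolds: int = 50
    scaffold_length: int = 200_000
    n_w_segments: int = 20
    w_segment_length: int = 2_000
    n_z_segments: int = 20
    z_segment_length: int = 2_000
    n_repeat_segments: int = 10
    repeat_segment_length: int = 2_000
    repeat_multiplier: float = 10.0
    n_indel_segments: int = 20
    indel_segment_length: int = 2_000
    indel_deletion_freq: float = 0.3
    n_females: int = 22
    n_males: int = 26
    target_depth: float = 1.0
    seed: int = 0


def build_genome_model(config: SimConfig) -> GenomeModel:
    """Plant W-specific, Z-hemizygous, repeat and indel segments at random
    non-overlapping positions, filling the rest with autosomal sequence.

    Deterministic for a fixed ``config.seed``. Raises if the planted total
    exceeds the genome or any scaffold has zero length.
    """
    if config.scaffold_length <= 0 or config.n_scaffolds <= 0:
        raise ValueError("scaffolds must have positive count and length")
    rng = np.random.default_rng(config.seed)

    planted: List[Tuple[str, int]] = []  # (kind, length)
    planted += [("w_specific", config.w_segment_length)] * config.n_w_segments
    planted += [("z_hemizygous", config.z_segment_length)] * config.n_z_segments
    planted += [("repeat", config.repeat_segment_length)] * config.n_repeat_segments
    planted += [("indel", config.indel_segment_length)] * config.n_indel_segments
    if any(length <= 0 for _, length in planted):
        raise ValueError("planted segment lengths must be positive")

    total = config.n_scaffolds * config.scaffold_length
    if sum(length for _, length in planted) > total:
        raise ValueError("total planted length exceeds total scaffold length")

    # Assign each planted segment to a scaffold; retry if a scaffold overflows.
    names = [f"scaffold_{i}" for i in range(config.n_scaffolds)]
    per_scaffold: Dict[str, List[Tuple[str, int]]] = {n: [] for n in names}
    order = rng.permutation(len(planted))
    for idx in order:
        kind, length = planted[idx]
        for _ in range(1000):
            name = names[int(rng.integers(config.n_scaffolds))]
            used = sum(l for _, l in per_scaffold[name])
            if used + length <= config.scaffold_length:
                per_scaffold[name].append((kind, length))
                break
        else:
            raise ValueError("could not place planted segments (genome too full)")

    scaffolds: List[Tuple[str, int, List[Segment]]] = []
    indel_loci: List[Tuple[str, int, int, float]] = []
    for name in names:
        items = per_scaffold[name]
        L = config.scaffold_length
        free = L - sum(l for _, l in items)
        # random non-overlapping placement: sorted starts within the free space,
        # then offset by cumulative planted length
        offsets = np.sort(rng.integers(0, free + 1, size=len(items)))
        segments: List[Segment] = []
        pos = 0
        cum = 0
        for (kind, length), off in zip(items, offsets):
            start = int(off) + cum
            if start > pos:
                segments.append((pos, start, AUTOSOMAL))
            end = start + length
            if kind == "w_specific":
                segments.append((start, end, W_SPECIFIC))
            elif kind == "z_hemizygous":
                segments.append((start, end, Z_HEMIZYGOUS))
            elif kind == "repeat":
                segments.append((start, end, repeat_class(config.repeat_multiplier)))
            else:  # indel polymorphism: autosomal segment + locus entry
                segments.append((start, end, AUTOSOMAL))
                indel_loci.append((name, start, end, config.indel_deletion_freq))
            pos = end
            cum += length
        if pos < L:
            segments.append((pos, L, AUTOSOMAL))
        # merge adjacent autosomal runs for tidiness
        merged: List[Segment] = []
        for seg in segments:
            if merged and merged[-1][2] is AUTOSOMAL and seg[2] is AUTOSOMAL and merged[-1][1] == seg[0]:
                merged[-1] = (merged[-1][0], seg[1], AUTOSOMAL)
            else:
                merged.append(seg)
        scaffolds.append((name, L, merged))
    return GenomeModel(scaffolds, indel_loci)


def individual_seed(master_seed: int, index: int) -> int:
    """Deterministic per-individual seed schedule from one master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % 2**31)


def make_panel(
    n_females: int,
    n_males: int,
    target_depth: float = 1.0,
    master_seed: int = 0,
) -> List[IndividualSpec]:
    """Build a sexed panel with per-individual seeds expanded from one master."""
    panel = []
    for i in range(n_females):
        panel.append(
            IndividualSpec(f"F{i:02d}", "female", target_depth, individual_seed(master_seed, i))
        )
    for j in range(n_males):
        panel.append(
            IndividualSpec(
                f"M{j:02d}", "male", target_depth, individual_seed(master_seed, n_females + j)
            )
        )
    return panel


def _lambda_array(model: GenomeModel, ind: IndividualSpec, copies: np.ndarray) -> Dict[str, np.ndarray]:
    """Per-base Poisson mean for one individual (copies = indel genotypes)."""
    lams: Dict[str, np.ndarray] = {}
    for name, length, segments in model.scaffolds:
        lam = np.empty(length, dtype=np.float64)
        for start, end, cls in segments:
            lam[start:end] = ind.target_depth * cls.mean_copy(ind.sex) / 2.0
        lams[name] = lam
    for (name, start, end, _freq), copy in zip(model.indel_loci, copies):
        lams[name][start:end] *= copy / 2.0
    return lams


def _indel_copies(model: GenomeModel, rng: np.random.Generator) -> np.ndarray:
    """Diploid copy numbers at each indel locus: Binomial(2, 1 - del_freq)."""
    freqs = np.array([f for _, _, _, f in model.indel_loci], dtype=float)
    if len(freqs) == 0:
        return np.empty(0, dtype=np.int64)
    return rng.binomial(2, 1.0 - freqs)


def simulate_depth(model: GenomeModel, ind: IndividualSpec) -> DepthTrack:
    """Per-base depth for one individual.

    Depth at each base is an independent Poisson draw with mean
    ``target_depth * copy_number(sex) / 2 * repeat_multiplier``; indel-locus
    genotypes scale the mean by the individual's diploid copy there.
    Deterministic given ``ind.seed``.
    """
    rng = np.random.default_rng(ind.seed)
    copies = _indel_copies(model, rng)
    lams = _lambda_array(model, ind, copies)
    return DepthTrack({name: rng.poisson(lam) for name, lam in lams.items()})


def simulate_pooled(
    model: GenomeModel, panel: Sequence[IndividualSpec]
) -> Tuple[DepthTrack, DepthTrack, int, int]:
    """Simulate the whole panel, pooling depth by sex without keeping
    per-individual tracks in memory.

    Returns (female_track, male_track, n_females, n_males).
    """
    lengths = model.lengths()
    pooled = {
        "female": DepthTrack.zeros(lengths),
        "male": DepthTrack.zeros(lengths),
    }
    counts = {"female": 0, "male": 0}
    for ind in panel:
        pooled[ind.sex].iadd(simulate_depth(model, ind))
        counts[ind.sex] += 1
    return pooled["female"], pooled["male"], counts["female"], counts["male"]


def emit_alignments(
    model: GenomeModel,
    ind: IndividualSpec,
    read_length: int,
    path,
    secondary_frac: float = 0.0,
    clipped_frac: float = 0.0,
    n_reads: Optional[int] = None,
) -> int:
    """Write a coordinate-sorted SAM file of placed single-end reads.

    Reads are placed (not aligned): per segment the read count is Poisson
    with mean ``segment depth * length / read_length`` so that depth
    recomputed from the file matches :func:`simulate_depth` in expectation.
    A deterministic fraction of records is flagged secondary
    (``secondary_frac``) and another fraction is soft-clipped on both ends
    (``clipped_frac``) to exercise downstream alignment filters. With
    ``n_reads`` the total count is fixed and placement is uniform over
    copy-weighted segments.

    Returns the number of records written.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    rng = np.random.default_rng(ind.seed)
    copies = _indel_copies(model, rng)
    lams = _lambda_array(model, ind, copies)

    placements: List[Tuple[str, int]] = []  # (scaffold, start)
    if n_reads is None:
        for name, length, segments in model.scaffolds:
            lam = lams[name]
            for start, end, _cls in segments:
                mean_reads = float(lam[start:end].sum()) / read_length
                k = int(rng.poisson(mean_reads))
                if k == 0:
                    continue
                starts = rng.integers(start, end, size=k)
                starts = np.minimum(starts, length - read_length)
                starts = np.maximum(starts, 0)
                placements += [(name, int(s)) for s in starts]
    else:
        # fixed total: sample scaffolds/positions weighted by per-base mean
        weights = np.array([lams[name].sum() for name, _, _ in model.scaffolds])
        if weights.sum() == 0:
            weights = np.array([length for _, length, _ in model.scaffolds], dtype=float)
        weights = weights / weights.sum()
        which = rng.choice(len(model.scaffolds), size=n_reads, p=weights)
        for w in which:
            name, length, _ = model.scaffolds[int(w)]
            lam = lams[name]
            p = lam / lam.sum() if lam.sum() > 0 else None
            pos = int(rng.choice(length, p=p))
            pos = min(max(pos, 0), length - read_length)
            placements.append((name, pos))

    placements.sort()
    n = len(placements)
    n_secondary = int(round(secondary_frac * n))
    n_clipped = int(round(clipped_frac * n))
    # deterministic choice of which records get flags/clips: evenly spread
    secondary_idx = set(np.linspace(0, n - 1, n_secondary, dtype=int)) if n_secondary else set()
    clip_pool = [i for i in range(n) if i not in secondary_idx]
    clipped_idx = set(clip_pool[:n_clipped])

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length, _ in model.scaffolds],
    }
    tid = {name: i for i, (name, _, _) in enumerate(model.scaffolds)}
    clip = max(1, read_length // 10) if read_length >= 3 else 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, (name, pos) in enumerate(placements):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{ind.id}_read{i}"
            a.reference_id = tid[name]
            a.reference_start = pos
            a.mapping_quality = 60
            flag = 0
            if i in secondary_idx:
                flag |= 256
            a.flag = flag
            if i in clipped_idx and clip > 0:
                mlen = read_length - 2 * clip
                a.cigarstring = f"{clip}S{mlen}M{clip}S"
            else:
                a.cigarstring = f"{read_length}M"
            a.query_sequence = "A" * read_length
            out.write(a)
    return n


# -- file outputs -----------------------------------------------------------

def write_truth_bed(model: GenomeModel, path, labels: Sequence[str] = ("w_specific", "z_hemizygous", "repeat")) -> None:
    """BED of planted non-autosomal segments (name column = class label)."""
    rows = []
    for label in labels:
        rows += [(name, s, e, label) for name, s, e in model.truth_intervals(label)]
    rows.sort()
    with open(path, "w") as fh:
        for name, s, e, label in rows:
            fh.write(f"{name}\t{s}\t{e}\t{label}\n")


def write_reference_fasta(model: GenomeModel, path, seed: int = 0, width: int = 80) -> None:
    """Random-nucleotide reference matching the model's scaffold lengths."""
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for name, length, _ in model.scaffolds:
            seq = rng.choice(alphabet, size=length).tobytes().decode()
            fh.write(f">{name}\n")
            for i in range(0, length, width):
                fh.write(seq[i : i + width] + "\n")


def write_panel_tsv(panel: Sequence[IndividualSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsex\ttarget_depth\tseed\n")
        for ind in panel:
            fh.write(f"{ind.id}\t{ind.sex}\t{ind.target_depth}\t{ind.seed}\n")


def run_simulation(config: SimConfig, outdir, write_fasta: bool = True) -> GenomeModel:
    """Generate a full synthetic dataset under ``outdir``.

    Writes truth BED, panel TSV, per-individual BedGraphs and (optionally)
    the reference FASTA; returns the genome model.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_genome_model(config)
    panel = make_panel(config.n_females, config.n_males, config.target_depth, config.seed)
    write_truth_bed(model, outdir / "truth.bed")
    write_panel_tsv(panel, outdir / "panel.tsv")
    if write_fasta:
        write_reference_fasta(model, outdir / "reference.fasta", seed=config.seed)
    for ind in panel:
        write_bedgraph(simulate_depth(model, ind), outdir / f"{ind.id}.bedgraph")
    return model
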