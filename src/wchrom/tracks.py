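"""Per-base depth tracks and BedGraph round-tripping.

A :class:`DepthTrack` holds one non-negative integer per reference base for
every scaffold — the read depth of a single individual or of a sex-pooled
alignment. All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

import numpy as np

__all__ = ["DepthTrack", "read_bedgraph", "write_bedgraph"]


@dataclass
class DepthTrack:
    """Read depth per base, keyed by scaffold name.

    Arrays are integer-valued and length equals the scaffold length.
    """

    depths: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.depths.items():
            arr = np.asarray(arr)
            if arr.ndim != 1:
                raise ValueError(f"depth array for {name!r} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative depth on scaffold {name!r}")
            self.depths[name] = arr

    @classmethod
    def zeros(cls, lengths: Mapping[str, int], dtype=np.int64) -> "DepthTrack":
        return cls({name: np.zeros(int(n), dtype=dtype) for name, n in lengths.items()})

    # -- mapping-ish access -------------------------------------------------
    def __getitem__(self, scaffold: str) -> np.ndarray:
        return self.depths[scaffold]

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.depths

    def __iter__(self) -> Iterator[str]:
        return iter(self.depths)

    def scaffolds(self) -> list[str]:
        return list(self.depths)

    def lengths(self) -> Dict[str, int]:
        return {name: len(arr) for name, arr in self.depths.items()}

    def total(self) -> int:
        """Sum of depth over every base of every scaffold."""
        return int(sum(int(arr.sum()) for arr in self.depths.values()))

    def iadd(self, other: "DepthTrack") -> "DepthTrack":
        """In-place per-base addition; scaffold sets and lengths must agree."""
        if self.lengths() != other.lengths():
            raise ValueError("scaffold sets/lengths differ between tracks")
        for name in self.depths:
            self.depths[name] += other.depths[name]
        return self

    def __add__(self, other: "DepthTrack") -> "DepthTrack":
        out = DepthTrack({k: v.copy() for k, v in self.depths.items()})
        return out.iadd(other)


def write_bedgraph(track: DepthTrack, path) -> None:
    """Write a track as BedGraph (0-based half-open), including zero runs."""
    with open(path, "w") as fh:
        for name in track.scaffolds():
            arr = track[name]
            if len(arr) == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                fh.write(f"{name}\t{s}\t{e}\t{int(arr[s])}\n")


def read_bedgraph(path, lengths: Mapping[str, int]) -> DepthTrack:
    """Read a BedGraph file into a DepthTrack.

    ``lengths`` gives the full scaffold lengths so positions absent from the
    file are depth 0.
    """
    track = DepthTrack.zeros(lengths)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            name, s, e, v = line.split("\t")[:4]
            if name not in track:
                raise ValueError(f"scaffold {name!r} not in provided lengths")
            track[name][int(s) : int(e)] = int(float(v))
    return track
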