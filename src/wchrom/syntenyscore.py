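"""Homolog calling from tabular alignments and per-chromosome enrichment.

Protein-level hits between a focal gene set (e.g. genes on a candidate sex
chromosome) and an annotated reference genome are filtered by alignment
length and percent identity, reduced to one best hit per query, and then
summarised per reference chromosome as observed homologs divided by total
annotated genes — an enrichment score whose excess on one chromosome points
at the conserved synteny of the focal set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import pandas as pd

__all__ = ["HomologCall", "call_homologs", "enrichment", "read_annotation_counts"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomologCall:
    """One retained query-target homolog call."""

    query: str
    target: str
    length: int  # aligned amino acids
    identity: float  # percent, 0-100
    chromosome: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("alignment length must be non-negative")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("percent identity must lie in [0, 100]")


def _iter_lines(records: Union[str, Path, Iterable[str]]) -> Iterable[str]:
    if isinstance(records, (str, Path)):
        with open(records) as fh:
            yield from fh
    else:
        yield from records


def call_homologs(
    records: Union[str, Path, Iterable[str]],
    gene_chromosome: Optional[Mapping[str, str]] = None,
    min_len: int = 50,
    min_ident: float = 60.0,
    best_per_query: bool = True,
) -> List[HomologCall]:
    """Filter 12-column tabular alignment records into homolog calls.

    Columns follow the standard BLAST tabular layout (query, target,
    percent identity, alignment length, ...). Records with alignment length
    >= ``min_len`` amino acids and identity >= ``min_ident`` percent are
    kept (both bounds inclusive). With ``best_per_query`` only the best
    target per query survives — highest identity, then longest alignment,
    first-seen on ties — to avoid double counting in the enrichment table.
    Malformed rows are skipped with a warning; if every row is malformed the
    input is rejected.
    """
    calls: List[HomologCall] = []
    n_rows = n_bad = 0
    for line in _iter_lines(records):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n_rows += 1
        parts = line.split("\t")
        try:
            if len(parts) < 12:
                raise ValueError("fewer than 12 columns")
            query, target = parts[0], parts[1]
            identity = float(parts[2])
            length = int(parts[3])
            call = HomologCall(
                query=query,
                target=target,
                length=length,
                identity=identity,
                chromosome=gene_chromosome.get(target) if gene_chromosome else None,
            )
        except (ValueError, IndexError) as exc:
            n_bad += 1
            logger.warning("skipping malformed alignment row (%s): %r", exc, line)
            continue
        if call.length >= min_len and call.identity >= min_ident:
            calls.append(call)
    if n_rows > 0 and n_bad == n_rows:
        raise ValueError("all alignment rows were malformed")

    if not best_per_query:
        return calls
    best: Dict[str, HomologCall] = {}
    for call in calls:
        prev = best.get(call.query)
        if prev is None or (call.identity, call.length) > (prev.identity, prev.length):
            best[call.query] = call
    # preserve first-seen query order
    seen = set()
    ordered = []
    for call in calls:
        if call.query not in seen:
            seen.add(call.query)
            ordered.append(best[call.query])
    return ordered


def enrichment(
    calls: Iterable[HomologCall], annotation_counts: Mapping[str, int]
) -> pd.DataFrame:
    """Per-chromosome enrichment: observed homologs / total annotated genes.

    Chromosomes with zero annotated genes, or calls placed on chromosomes
    absent from the annotation table, are errors. Duplicate identical calls
    are counted once.
    """
    observed: Dict[str, int] = {chrom: 0 for chrom in annotation_counts}
    for call in set(calls):
        if call.chromosome is None:
            continue
        if call.chromosome not in annotation_counts:
            raise ValueError(f"call on unannotated chromosome {call.chromosome!r}")
        observed[call.chromosome] += 1
    rows = []
    for chrom, total in annotation_counts.items():
        if total <= 0:
            raise ValueError(f"chromosome {chrom!r} has no annotated genes")
        rows.append((chrom, observed[chrom], total, observed[chrom] / total))
    return pd.DataFrame(rows, columns=["chromosome", "observed", "total", "enrichment"])


def read_annotation_counts(path) -> Dict[str, int]:
    """Two-column TSV: chromosome, annotated gene count."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "total"], comment="#")
    return dict(zip(df["chromosome"].astype(str), df["total"].astype(int)))
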