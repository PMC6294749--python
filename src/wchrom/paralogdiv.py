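"""Derived-substitution attribution between recent paralogs, via outgroups.

Given a codon alignment holding two focal paralogs (e.g. an autosomal gene
and its young sex-linked duplicate) plus one or more outgroups, each
variable site is polarised against the outgroup consensus: a substitution is
attributed to the paralog that differs from the consensus while the other
paralog retains it. Sites where both paralogs differ from the consensus are
unresolvable under this parsimony rule and reported rather than guessed;
sites where both paralogs share a non-consensus state are ancestral
(pre-duplication) changes and attributed to neither. Attributed nucleotide
substitutions are also translated in codon context to count how many codons
changed their amino acid.

Also provides plain pairwise identity over comparable (gap-free in both
sequences) columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CodonAlignment",
    "BranchCounts",
    "attribute_derived",
    "pairwise_identity",
    "read_alignment_fasta",
    "read_roles_tsv",
]

GAP_CHARS = {"-", ".", "~"}
_BASES = {"A", "C", "G", "T", "U"}


@dataclass
class CodonAlignment:
    """Aligned coding nucleotide sequences with paralog/outgroup roles."""

    sequences: Dict[str, str]
    paralog_a: str
    paralog_b: str
    outgroups: List[str]

    def __post_init__(self) -> None:
        self.sequences = {k: v.upper().replace("U", "T") for k, v in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("all aligned sequences must have the same length")
        (self.length,) = lengths
        if self.length % 3 != 0:
            raise ValueError("aligned length must be divisible by 3 (codon alignment)")
        if not self.outgroups:
            raise ValueError("at least one outgroup is required")
        for sid in [self.paralog_a, self.paralog_b, *self.outgroups]:
            if sid not in self.sequences:
                raise ValueError(f"sequence {sid!r} missing from alignment")


@dataclass
class BranchCounts:
    """Per-paralog derived substitution counts and site bookkeeping."""

    nt_substitutions: Dict[str, int]
    aa_changes: Dict[str, int]
    attributed_sites: Dict[str, List[int]] = field(default_factory=dict)
    sites_excluded: int = 0  # gap in a focal paralog (or no outgroup base)
    sites_unresolvable: int = 0  # no outgroup majority, or both paralogs derived
    sites_ancestral: int = 0  # both paralogs share a non-consensus base


def _outgroup_consensus(chars: Sequence[str]) -> Optional[str]:
    """Strict-majority base among non-gap outgroup characters, else None."""
    bases = [c for c in chars if c in _BASES]
    if not bases:
        return None
    (base, count), *rest = Counter(bases).most_common()
    if count * 2 > len(bases):
        return base
    return None


def attribute_derived(aln: CodonAlignment) -> BranchCounts:
    """Attribute derived substitutions to each paralog by outgroup parsimony.

    Columns with a gap in either focal paralog are excluded. At each
    remaining column the outgroup consensus (strict majority of non-gap
    outgroup bases) defines the ancestral state; a paralog differing from it
    while the other matches it carries one attributed substitution. Columns
    with no consensus, no outgroup base, or both paralogs derived are
    counted unresolvable/excluded. Amino-acid changes: for every codon
    holding attributed sites of a paralog, the paralog's codon is compared
    with the same codon with those sites reverted to the ancestral base;
    a differing translation counts one changed amino acid.
    """
    a = aln.sequences[aln.paralog_a]
    b = aln.sequences[aln.paralog_b]
    outs = [aln.sequences[o] for o in aln.outgroups]

    counts = BranchCounts(
        nt_substitutions={aln.paralog_a: 0, aln.paralog_b: 0},
        aa_changes={aln.paralog_a: 0, aln.paralog_b: 0},
        attributed_sites={aln.paralog_a: [], aln.paralog_b: []},
    )
    ancestral_base: Dict[int, str] = {}
    for i in range(aln.length):
        ca, cb = a[i], b[i]
        if ca in GAP_CHARS or cb in GAP_CHARS or ca not in _BASES or cb not in _BASES:
            counts.sites_excluded += 1
            continue
        o = _outgroup_consensus([s[i] for s in outs])
        if o is None:
            counts.sites_unresolvable += 1
            continue
        ancestral_base[i] = o
        if ca == o and cb == o:
            continue
        if ca != o and cb != o:
            if ca == cb:
                counts.sites_ancestral += 1  # change on the pre-duplication branch
            else:
                counts.sites_unresolvable += 1
            continue
        derived = aln.paralog_a if ca != o else aln.paralog_b
        counts.nt_substitutions[derived] += 1
        counts.attributed_sites[derived].append(i)

    table = standard_dna_table.forward_table

    def translate(codon: str) -> Optional[str]:
        if any(c not in _BASES for c in codon):
            return None
        return table.get(codon, "*")

    for paralog, seq in ((aln.paralog_a, a), (aln.paralog_b, b)):
        by_codon: Dict[int, List[int]] = {}
        for i in counts.attributed_sites[paralog]:
            by_codon.setdefault(i // 3, []).append(i)
        for ci, sites in by_codon.items():
            codon = list(seq[3 * ci : 3 * ci + 3])
            anc = codon.copy()
            for i in sites:
                anc[i % 3] = ancestral_base[i]
            aa_new, aa_old = translate("".join(codon)), translate("".join(anc))
            if aa_new is not None and aa_old is not None and aa_new != aa_old:
                counts.aa_changes[paralog] += 1
    return counts


def pairwise_identity(a: str, b: str) -> Tuple[float, int]:
    """Percent identity over columns where neither sequence has a gap.

    Returns (identity %, number of comparable columns); errors when no
    column is comparable.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    a, b = a.upper(), b.upper()
    comparable = matches = 0
    for ca, cb in zip(a, b):
        if ca in GAP_CHARS or cb in GAP_CHARS:
            continue
        comparable += 1
        if ca == cb:
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns")
    return 100.0 * matches / comparable, comparable


def read_alignment_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_roles_tsv(path) -> Dict[str, str]:
    """Two-column TSV: sequence id, role in {paralog_a, paralog_b, outgroup}."""
    roles: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, role = line.split("\t")[:2]
            roles[sid] = role
    return roles
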