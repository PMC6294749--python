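"""Sex-marker panel statistics and ZW-cross Mendelian expectations.

Candidate female-specific markers are validated by PCR presence/absence
across a sexed panel. A marker present in every female and no male is
sex-specific; under a sex-independent null in which a segregating marker is
present in any animal with probability p = 1/2, the chance of that perfect
pattern arising in a panel of six females and six males is 2^-12 ≈ 2e-4 —
the panel's false-positive probability.

The cross model enumerates Z/W gamete combinations to predict offspring sex
ratios: a ZW (sex-reversed) male crossed to a ZW female yields 3:1
female:male when WW is viable, and a WW female yields all-female spawns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "MarkerClass",
    "classify_panel",
    "panel_fpr",
    "CrossModel",
    "expected_sex_ratio",
    "biplex_call",
    "FEMALE_BAND",
    "CONTROL_BAND",
]


class MarkerClass:
    SEX_SPECIFIC = "sex_specific"
    NEAR_SPECIFIC = "near_specific"
    POLYMORPHIC = "polymorphic"
    NON_SPECIFIC = "non_specific"
    FAILED = "failed"


def classify_panel(presence: Sequence[bool], sexes: Sequence[str]) -> str:
    """Classify one marker's presence/absence pattern across a sexed panel.

    - ``sex_specific``: present in all females and no males.
    - ``near_specific``: exactly one animal discordant from that pattern
      (one male with the band, or one female without it).
    - ``non_specific``: present in every animal.
    - ``failed``: absent from every animal.
    - ``polymorphic``: any other partial pattern (no clean sex trend).

    The call is invariant to animal ordering and requires both sexes.
    """
    if len(presence) != len(sexes):
        raise ValueError("presence vector and sex labels differ in length")
    for s in sexes:
        if s not in ("female", "male"):
            raise ValueError(f"unknown sex label {s!r}")
    n_f = sum(1 for s in sexes if s == "female")
    n_m = len(sexes) - n_f
    if n_f == 0 or n_m == 0:
        raise ValueError("panel must contain both sexes")
    f_present = sum(1 for p, s in zip(presence, sexes) if s == "female" and p)
    m_present = sum(1 for p, s in zip(presence, sexes) if s == "male" and p)
    if f_present == 0 and m_present == 0:
        return MarkerClass.FAILED
    if f_present == n_f and m_present == n_m:
        return MarkerClass.NON_SPECIFIC
    if f_present == n_f and m_present == 0:
        return MarkerClass.SEX_SPECIFIC
    discordant = (n_f - f_present) + m_present
    if discordant == 1:
        return MarkerClass.NEAR_SPECIFIC
    return MarkerClass.POLYMORPHIC


def panel_fpr(n_f: int, n_m: int, p: float = 0.5) -> float:
    """Probability a sex-independent marker mimics perfect female-specificity.

    Under the null a segregating marker is present in each animal
    independently with probability ``p``; the perfect pattern (present in
    all ``n_f`` females, absent in all ``n_m`` males) then has probability
    ``p**n_f * (1 - p)**n_m`` — 2**-(n_f + n_m) for p = 1/2.
    """
    if n_f < 0 or n_m < 0:
        raise ValueError("panel sizes must be non-negative")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    return p**n_f * (1.0 - p) ** n_m


def _canonical(genotype: Iterable[str]) -> str:
    g = "".join(sorted(genotype))
    if sorted(g) not in (["W", "W"], ["W", "Z"], ["Z", "Z"]):
        raise ValueError(f"genotype must be a pair over {{Z, W}}, got {genotype!r}")
    return g


@dataclass
class CrossModel:
    """A cross between two Z/W genotypes with a viability map and sex rule.

    ``sex_rule`` maps each diploid genotype to 'male' or 'female'; the
    default scores ZZ male and both W-bearing genotypes (ZW, WW) female.
    """

    parent1: str
    parent2: str
    viability: Optional[Mapping[str, bool]] = None
    sex_rule: Mapping[str, str] = field(
        default_factory=lambda: {"ZZ": "male", "WZ": "female", "WW": "female"}
    )

    def __post_init__(self) -> None:
        self.parent1 = _canonical(self.parent1)
        self.parent2 = _canonical(self.parent2)
        if self.viability is not None:
            self.viability = {_canonical(k): bool(v) for k, v in self.viability.items()}

    def offspring_distribution(self) -> Dict[str, float]:
        """Probabilities of viable offspring genotypes (renormalised)."""
        raw: Dict[str, float] = {}
        for g1, g2 in product(self.parent1, self.parent2):
            geno = _canonical(g1 + g2)
            raw[geno] = raw.get(geno, 0.0) + 0.25
        viable = {
            g: p
            for g, p in raw.items()
            if self.viability is None or self.viability.get(g, True)
        }
        total = sum(viable.values())
        if total == 0:
            raise ValueError("no viable offspring genotype in this cross")
        return {g: p / total for g, p in viable.items()}


def expected_sex_ratio(cross: CrossModel) -> Tuple[float, float, float]:
    """(P(female), P(male), female:male ratio) by gamete enumeration.

    The ratio is ``math.inf`` for all-female spawns.
    """
    dist = cross.offspring_distribution()
    p_f = sum(p for g, p in dist.items() if cross.sex_rule[g] == "female")
    p_m = 1.0 - p_f
    ratio = math.inf if p_m == 0 else p_f / p_m
    return p_f, p_m, ratio


FEMALE_BAND = 219  # bp, amplified from W-specific sequence
CONTROL_BAND = 486  # bp, internal control present in both sexes


def biplex_call(bands: Iterable[float], tolerance: float = 10.0) -> str:
    """Call sex from a biplex PCR band pattern.

    The 486-bp internal control must be present for any call (otherwise the
    reaction failed); the 219-bp female-specific band then separates females
    from males. Band sizes match within ``tolerance`` bp (gel resolution).
    """
    bands = list(bands)

    def has(size: float) -> bool:
        return any(abs(b - size) <= tolerance for b in bands)

    if not has(CONTROL_BAND):
        return "fail"
    return "female" if has(FEMALE_BAND) else "male"
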