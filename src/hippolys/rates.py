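"""Poisson-corrected substitution rates and partner concordance.

For every cross-species pair of family members the proportion of differing
aligned sites p (pairwise gap deletion) is corrected for multiple hits with
the Poisson model, d = -ln(1 - p), and converted to a rate by dividing by
twice the pairwise divergence time — both lineages accumulate substitutions
since their split.  The family rate is the arithmetic mean of the pair rates,
in substitutions per residue per billion years.

Two interacting proteins are *discordant* when their family rates differ by
more than a fold threshold (default 2), read as evidence of distinct
selective constraints.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .core_io import (
    GAP,
    AlignedFamily,
    HippolysError,
    MemberKey,
    SaturationError,
    SpeciesRegistry,
    round_half_away,
)

PAIRWISE = "pairwise"
COMPLETE = "complete"


@dataclass
class PairwiseDistance:
    """Observed and corrected distance between two aligned sequences."""

    member_a: MemberKey | None
    member_b: MemberKey | None
    sites_compared: int
    differences: int
    p: float
    d: float | None = None  # Poisson-corrected; filled by poisson_correct


@dataclass
class FamilyRate:
    """Overall family substitution rate with its per-pair breakdown."""

    family_name: str
    rate: float  # substitutions per residue per billion years (unrounded)
    pair_rates: list[tuple[tuple[MemberKey, MemberKey], float]]

    @property
    def rate_rounded(self) -> float:
        return round_half_away(self.rate, 3)


def p_distance(
    seq_a: str,
    seq_b: str,
    member_a: MemberKey | None = None,
    member_b: MemberKey | None = None,
) -> PairwiseDistance:
    """Proportion of differing sites under pairwise gap deletion."""
    if len(seq_a) != len(seq_b):
        raise HippolysError(
            f"sequences of unequal length ({len(seq_a)} vs {len(seq_b)})"
        )
    sites = differences = 0
    for a, b in zip(seq_a, seq_b):
        if a == GAP or b == GAP:
            continue
        sites += 1
        if a != b:
            differences += 1
    if sites == 0:
        raise HippolysError("no comparable (gap-free) sites between sequences")
    return PairwiseDistance(
        member_a=member_a,
        member_b=member_b,
        sites_compared=sites,
        differences=differences,
        p=differences / sites,
    )


def poisson_correct(p: float) -> float:
    """Multiple-hit correction d = -ln(1 - p)."""
    if p < 0:
        raise HippolysError(f"p-distance {p} is negative")
    if p >= 1:
        raise SaturationError(f"p-distance {p} saturated; Poisson correction undefined")
    return -math.log1p(-p)


def _strip_shared_gap_columns(family: AlignedFamily) -> dict[MemberKey, str]:
    """Complete deletion: drop every column gapped in any member."""
    keep = [
        col
        for col in range(family.alignment_length)
        if all(seq[col] != GAP for seq in family.members.values())
    ]
    return {k: "".join(seq[col] for col in keep) for k, seq in family.members.items()}


def family_rate(
    family: AlignedFamily,
    registry: SpeciesRegistry,
    gap_mode: str = PAIRWISE,
) -> FamilyRate:
    """Mean over cross-species pair rates d / (2 T).

    Same-species (paralog) pairs are excluded: paralog divergence predates the
    speciation time that would be used to normalize them.  ``gap_mode`` is
    ``pairwise`` (default) or ``complete`` deletion.
    """
    if gap_mode == COMPLETE:
        sequences = _strip_shared_gap_columns(family)
    elif gap_mode == PAIRWISE:
        sequences = dict(family.members)
    else:
        raise HippolysError(f"unknown gap mode {gap_mode!r}")

    species_present = {sp for sp, _ in family.members}
    if len(species_present) < 2:
        raise HippolysError(
            f"family {family.family_name!r}: need members from >= 2 species"
        )

    pair_rates: list[tuple[tuple[MemberKey, MemberKey], float]] = []
    for key_a, key_b in itertools.combinations(family.members, 2):
        if key_a[0] == key_b[0]:
            continue  # within-species paralog pair
        dist = p_distance(sequences[key_a], sequences[key_b], key_a, key_b)
        dist.d = poisson_correct(dist.p)
        t = registry.divergence_time(key_a[0], key_b[0])
        if t <= 0:
            raise HippolysError(
                f"nonpositive divergence time for ({key_a[0]}, {key_b[0]})"
            )
        pair_rates.append(((key_a, key_b), dist.d / (2.0 * t)))

    rate = sum(r for _, r in pair_rates) / len(pair_rates)
    return FamilyRate(family_name=family.family_name, rate=rate, pair_rates=pair_rates)


def pathway_summary(rates: list[float | FamilyRate]) -> tuple[float, float, float]:
    """(min, max, mean) of family rates, each rounded half-away to 3 decimals."""
    if not rates:
        raise HippolysError("pathway summary of an empty rate list")
    values = [r.rate if isinstance(r, FamilyRate) else float(r) for r in rates]
    return (
        round_half_away(min(values), 3),
        round_half_away(max(values), 3),
        round_half_away(sum(values) / len(values), 3),
    )


def concordance(rate_a: float, rate_b: float, fold_threshold: float = 2.0) -> str:
    """``"discordant"`` iff the rates differ by strictly more than the fold
    threshold, else ``"concordant"``."""
    if rate_a <= 0 or rate_b <= 0:
        raise HippolysError("concordance requires strictly positive rates")
    ratio = max(rate_a, rate_b) / min(rate_a, rate_b)
    return "discordant" if ratio > fold_threshold else "concordant"
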