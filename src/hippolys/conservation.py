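"""Conserved-lysine scanning and context-pattern extraction.

A lysine is *conserved* over a scope group (all species, or vertebrates only)
when every member of the scope carries a lysine in the same alignment column;
a gap anywhere in the scope disqualifies the column.  Around each conserved
lysine a *context pattern* is grown outward while the flanking columns stay
nearly invariant; patterns render in the conventional dash/slash notation,
e.g. ``I/L/M-K-S/T`` (slash = variable position, listing the residues seen).

The upstream-hydrophobic rule asks whether every scope member individually
has an I, L, V or M one or two residues upstream of its own lysine — the
satisfying offset may differ between members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .core_io import (
    GAP,
    HYDROPHOBIC,
    AlignedFamily,
    HippolysError,
    MemberKey,
    SpeciesRegistry,
    UndefinedFractionError,
)

ALL_SPECIES = "all_species"
VERTEBRATES = "vertebrates"
CUSTOM = "custom"


class EmptyScopeError(HippolysError):
    """A scope group resolved to zero members."""


@dataclass(frozen=True)
class ScopeGroup:
    """The set of family members over which conservation is assessed."""

    label: str
    members: tuple[MemberKey, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise EmptyScopeError(f"scope {self.label!r} has no members")

    @classmethod
    def all_species(cls, family: AlignedFamily) -> "ScopeGroup":
        return cls(ALL_SPECIES, tuple(family.members))

    @classmethod
    def vertebrates(cls, family: AlignedFamily, registry: SpeciesRegistry) -> "ScopeGroup":
        members = tuple(
            key for key in family.members if registry.is_member(key[0], "vertebrate")
        )
        return cls(VERTEBRATES, members)

    @classmethod
    def custom(cls, members: tuple[MemberKey, ...]) -> "ScopeGroup":
        return cls(CUSTOM, members)

    def validate_against(self, family: AlignedFamily) -> None:
        missing = [m for m in self.members if m not in family.members]
        if missing:
            raise EmptyScopeError(
                f"scope {self.label!r}: member(s) {missing} not in family "
                f"{family.family_name!r}"
            )


@dataclass(frozen=True)
class ContextPattern:
    """Residue sets observed at each offset around a conserved lysine.

    Offsets form a contiguous window ``-u..+v`` including 0 (the lysine, whose
    set is always ``{K}``).  ``hydrophobic_flags[o]`` is true when the set at
    offset ``o`` lies entirely within {I, L, V, M}.
    """

    residue_sets: dict[int, frozenset[str]]
    hydrophobic_flags: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        offsets = sorted(self.residue_sets)
        if 0 not in self.residue_sets:
            raise ValueError("context pattern must include offset 0")
        if offsets != list(range(offsets[0], offsets[-1] + 1)):
            raise ValueError("context offsets must be contiguous")
        for off, residues in self.residue_sets.items():
            if not residues:
                raise ValueError(f"empty residue set at offset {off}")
        object.__setattr__(
            self,
            "hydrophobic_flags",
            {o: s <= HYDROPHOBIC for o, s in self.residue_sets.items()},
        )

    @property
    def offsets(self) -> range:
        lo, hi = min(self.residue_sets), max(self.residue_sets)
        return range(lo, hi + 1)

    def render(self) -> str:
        """Dash/slash notation, variable positions sorted alphabetically."""
        return "-".join(
            "/".join(sorted(self.residue_sets[o])) for o in self.offsets
        )


def parse_context(text: str, center: int | None = None) -> ContextPattern:
    """Parse dash/slash notation back into a pattern.

    ``center`` gives the index (0-based, within the dash-separated fields) of
    the candidate lysine; by default the first field whose residue set is
    exactly ``{K}`` is taken, which is unambiguous unless a flanking position
    is itself an invariant lysine left of the candidate.
    """
    fields = [frozenset(tok.split("/")) for tok in text.split("-") if tok]
    if center is None:
        center = next(
            (i for i, s in enumerate(fields) if s == frozenset("K")), None
        )
        if center is None:
            raise ValueError(f"no invariant-K field in context {text!r}")
    sets = {i - center: s for i, s in enumerate(fields)}
    return ContextPattern(residue_sets=sets)


@dataclass
class ConservedLysine:
    """An alignment column that is lysine across an entire scope group."""

    family_name: str
    alignment_column: int
    scope: ScopeGroup
    reference_position: int | None  # None (flagged) when the reference is gapped
    per_member_position: dict[MemberKey, int]
    context: ContextPattern | None = None

    @property
    def reference_gapped(self) -> bool:
        return self.reference_position is None


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def find_conserved_lysines(
    family: AlignedFamily,
    scope: ScopeGroup,
    max_variants: int = 3,
    max_window: int = 5,
) -> list[ConservedLysine]:
    """All alignment columns where every scope member has 'K'.

    Results are ordered by reference position; columns where the reference is
    gapped come last with ``reference_position=None``.  Each site carries its
    extracted context pattern.
    """
    scope.validate_against(family)
    sites: list[ConservedLysine] = []
    seqs = [family.members[m] for m in scope.members]
    for col in range(family.alignment_length):
        if all(seq[col] == "K" for seq in seqs):
            per_member = {
                m: family.ungapped_position(m, col) for m in scope.members
            }
            site = ConservedLysine(
                family_name=family.family_name,
                alignment_column=col,
                scope=scope,
                reference_position=(
                    family.ungapped_position(family.reference, col)
                    if family.reference in family.members
                    else None
                ),
                per_member_position={m: p for m, p in per_member.items() if p is not None},
            )
            site.context = extract_context(
                family, site, scope, max_variants=max_variants, max_window=max_window
            )
            sites.append(site)
    sites.sort(
        key=lambda s: (s.reference_position is None, s.reference_position or 0, s.alignment_column)
    )
    return sites


def count_reference_lysines(family: AlignedFamily) -> int:
    """Number of lysines in the ungapped reference sequence."""
    return family.ungapped(family.reference).count("K")


def conserved_fraction(n_conserved: int, n_total_reference_lysines: int) -> str:
    """Percentage of reference lysines that are conserved, rendered for reports.

    100*n/total rounded half-away-from-zero to one decimal, with a trailing
    ``.0`` dropped: (18, 36) -> ``"50%"``, (14, 64) -> ``"21.9%"``.
    """
    if n_total_reference_lysines < 1:
        raise UndefinedFractionError("conserved fraction undefined with zero lysines")
    if not 0 <= n_conserved <= n_total_reference_lysines:
        raise ValueError(
            f"n_conserved {n_conserved} outside 0..{n_total_reference_lysines}"
        )
    value = (
        Decimal(100) * Decimal(n_conserved) / Decimal(n_total_reference_lysines)
    ).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    text = format(value, "f")
    if text.endswith(".0"):
        text = text[:-2]
    return f"{text}%"


def extract_context(
    family: AlignedFamily,
    site: ConservedLysine,
    scope: ScopeGroup,
    max_variants: int = 3,
    max_window: int = 5,
) -> ContextPattern:
    """Grow the conserved context outward from the lysine column.

    Each side extends one column at a time while the scope's residue set at
    that column is gap-free and holds at most ``max_variants`` distinct
    residues, stopping independently per side at the first failing column or
    at ``max_window`` offsets.  The window rule is a reconstruction of how
    published context strings behave (printed windows range from -1..+1 to
    -2..+4); see the methods note.
    """
    scope.validate_against(family)
    seqs = [family.members[m] for m in scope.members]
    col0 = site.alignment_column
    length = family.alignment_length

    def column_set(col: int) -> frozenset[str] | None:
        residues = {seq[col] for seq in seqs}
        if GAP in residues:
            return None
        return frozenset(residues)

    sets: dict[int, frozenset[str]] = {0: frozenset("K")}
    for direction in (-1, +1):
        for step in range(1, max_window + 1):
            col = col0 + direction * step
            if not 0 <= col < length:
                break
            residues = column_set(col)
            if residues is None or len(residues) > max_variants:
                break
            sets[direction * step] = residues
    return ContextPattern(residue_sets=sets)


def hydrophobic_upstream(
    family: AlignedFamily, site: ConservedLysine, scope: ScopeGroup
) -> tuple[bool, set[int]]:
    """Does every scope member have I/L/V/M at its own -1 or -2 residue?

    Offsets are counted on each member's ungapped sequence relative to its own
    lysine, so different members may satisfy the rule at different offsets.
    Returns the overall verdict and the union of satisfying offsets.  A lysine
    within the first two residues treats out-of-range offsets as
    non-hydrophobic.
    """
    scope.validate_against(family)
    satisfied_offsets: set[int] = set()
    for member in scope.members:
        pos = site.per_member_position.get(member)
        if pos is None:
            return False, set()
        ungapped = family.ungapped(member)
        member_ok = False
        for offset in (-1, -2):
            idx = pos - 1 + offset
            if idx >= 0 and ungapped[idx] in HYDROPHOBIC:
                member_ok = True
                satisfied_offsets.add(offset)
        if not member_ok:
            return False, set()
    return True, satisfied_offsets
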