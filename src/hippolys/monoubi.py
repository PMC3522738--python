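"""Monoubiquitylation candidate classification.

Each conserved lysine is scored against the evidence criteria for a
monoubiquitylation site: conservation across the full species set, a
conserved context with an upstream hydrophobic residue (I/L/V/M at -1 or -2),
no structural role for the lysine, and corroboration — residency in or near a
binding/interaction domain, being the protein's sole universally conserved
lysine, or support from an external ubiquitylation predictor.

The strong/modest/none call is a deterministic cascade:

1. structural lysine                -> none
2. upstream-hydrophobic rule fails  -> none
3. universally conserved, affirmatively non-structural, with at least one
   corroborating line of evidence   -> strong
4. anything else (vertebrate-limited conservation, unknown structural
   status, or no corroboration)     -> modest

The published strength calls are narrative; this cascade is the minimal rule
set consistent with all of them and is documented as a reconstruction in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .conservation import (
    ALL_SPECIES,
    VERTEBRATES,
    ConservedLysine,
    ScopeGroup,
    conserved_fraction,
    count_reference_lysines,
    find_conserved_lysines,
    hydrophobic_upstream,
)
from .core_io import (
    AlignedFamily,
    HippolysError,
    ResidueAnnotation,
    SpeciesRegistry,
    TableFormatError,
)

NONSTRUCTURAL = "nonstructural"
STRUCTURAL = "structural"
UNKNOWN = "unknown"

STRENGTH_ORDER = {"none": 0, "modest": 1, "strong": 2}


@dataclass(frozen=True)
class EvidenceFlags:
    """Boolean evidence underlying one candidate call."""

    universal_scope: bool
    hydrophobic_ok: bool
    structural_status: str  # nonstructural | structural | unknown
    in_or_adjacent_interaction_domain: bool
    sole_conserved_lysine: bool
    predictor_support: bool

    def __post_init__(self) -> None:
        if self.structural_status not in (NONSTRUCTURAL, STRUCTURAL, UNKNOWN):
            raise ValueError(f"bad structural_status {self.structural_status!r}")


@dataclass
class CandidateCall:
    site: ConservedLysine
    flags: EvidenceFlags
    strength: str  # strong | modest | none
    rationale: list[str]


def gather_evidence(
    site: ConservedLysine,
    family: AlignedFamily,
    annotation: ResidueAnnotation,
    all_sites: Sequence[ConservedLysine],
    adjacency_margin: int = 10,
) -> EvidenceFlags:
    """Derive the evidence flags for one conserved lysine.

    ``annotation`` must describe the family reference member.  Domain
    adjacency means the reference position falls inside a listed interval or
    within ``adjacency_margin`` residues of its boundary ("just upstream of
    the dimerization domain" style evidence).  ``sole_conserved_lysine`` is
    true when this site is the family's only universally conserved lysine.
    """
    if annotation.member != family.reference:
        raise TableFormatError(
            f"annotation is for {annotation.member}, family reference is "
            f"{family.reference}"
        )
    annotation.validate_against(family)
    pos = site.reference_position
    universal = site.scope.label == ALL_SPECIES
    hydro_ok, _ = hydrophobic_upstream(family, site, site.scope)

    if pos is None:
        structural_status = UNKNOWN
        in_domain = False
        predictor = False
    else:
        if annotation.structural_lysines is None:
            structural_status = UNKNOWN
        elif pos in annotation.structural_lysines:
            structural_status = STRUCTURAL
        else:
            structural_status = NONSTRUCTURAL
        in_domain = any(
            dom.start - adjacency_margin <= pos <= dom.end + adjacency_margin
            for dom in annotation.domains
        )
        predictor = pos in annotation.predictor_hits

    universal_sites = [s for s in all_sites if s.scope.label == ALL_SPECIES]
    sole = universal and len(universal_sites) == 1

    return EvidenceFlags(
        universal_scope=universal,
        hydrophobic_ok=hydro_ok,
        structural_status=structural_status,
        in_or_adjacent_interaction_domain=in_domain,
        sole_conserved_lysine=sole,
        predictor_support=predictor,
    )


def classify_candidate(flags: EvidenceFlags) -> tuple[str, list[str]]:
    """Apply the rule cascade; returns (strength, ordered rule labels fired)."""
    if flags.structural_status == STRUCTURAL:
        return "none", ["structural-lysine"]
    if not flags.hydrophobic_ok:
        return "none", ["no-upstream-hydrophobic"]
    if flags.universal_scope and flags.structural_status == NONSTRUCTURAL:
        corroboration = []
        if flags.in_or_adjacent_interaction_domain:
            corroboration.append("interaction-domain")
        if flags.sole_conserved_lysine:
            corroboration.append("sole-conserved-lysine")
        if flags.predictor_support:
            corroboration.append("predictor-support")
        if corroboration:
            return "strong", ["universal", "nonstructural", *corroboration]
    reasons = []
    if not flags.universal_scope:
        reasons.append("vertebrate-limited-scope")
    if flags.structural_status == UNKNOWN:
        reasons.append("unknown-structural-status")
    if not reasons:
        reasons.append("no-corroborating-evidence")
    return "modest", reasons


@dataclass
class FamilySummary:
    """One summary row per family, mirroring the published per-family table."""

    family_name: str
    total_lysines: int
    n_conserved_universal: int
    fraction: str
    best_call: CandidateCall | None

    @property
    def best_context(self) -> str:
        if self.best_call is None or self.best_call.site.context is None:
            return ""
        return self.best_call.site.context.render()


def scan_family(
    family: AlignedFamily,
    annotations: Iterable[ResidueAnnotation],
    registry: SpeciesRegistry,
    scopes: Sequence[str] = (ALL_SPECIES, VERTEBRATES),
    max_variants: int = 3,
    max_window: int = 5,
    adjacency_margin: int = 10,
) -> tuple[list[CandidateCall], FamilySummary]:
    """Full per-family pipeline: scan, gather evidence, classify, summarize.

    Each lysine is reported once, at the widest scope in which it is
    conserved.  When no annotation row matches the family reference, the
    structural status defaults to unknown (capping strength at modest).
    """
    scope_objs: list[ScopeGroup] = []
    for label in scopes:
        if label == ALL_SPECIES:
            scope_objs.append(ScopeGroup.all_species(family))
        elif label == VERTEBRATES:
            scope_objs.append(ScopeGroup.vertebrates(family, registry))
        else:
            raise HippolysError(f"unknown scope label {label!r}")
    # widest scope first: a site conserved at a wider scope is not re-reported
    scope_objs.sort(key=lambda s: -len(s.members))

    sites: list[ConservedLysine] = []
    seen_columns: set[int] = set()
    for scope in scope_objs:
        for site in find_conserved_lysines(
            family, scope, max_variants=max_variants, max_window=max_window
        ):
            if site.alignment_column not in seen_columns:
                seen_columns.add(site.alignment_column)
                sites.append(site)
    sites.sort(
        key=lambda s: (s.reference_position is None, s.reference_position or 0, s.alignment_column)
    )

    annotation = next(
        (a for a in annotations if a.member == family.reference), None
    )
    if annotation is None:
        annotation = ResidueAnnotation(member=family.reference, structural_lysines=None)

    calls: list[CandidateCall] = []
    for site in sites:
        flags = gather_evidence(
            site, family, annotation, sites, adjacency_margin=adjacency_margin
        )
        strength, rationale = classify_candidate(flags)
        calls.append(CandidateCall(site=site, flags=flags, strength=strength, rationale=rationale))

    total = count_reference_lysines(family)
    n_universal = sum(1 for s in sites if s.scope.label == ALL_SPECIES)
    fraction = conserved_fraction(n_universal, total) if total else "0%"
    best = max(
        calls,
        key=lambda c: (
            STRENGTH_ORDER[c.strength],
            -(c.site.reference_position or 10**9),
        ),
        default=None,
    )
    if best is not None and best.strength == "none":
        best = None
    return calls, FamilySummary(
        family_name=family.family_name,
        total_lysines=total,
        n_conserved_universal=n_universal,
        fraction=fraction,
        best_call=best,
    )
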