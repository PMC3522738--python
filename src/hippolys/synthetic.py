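"""Synthetic protein-family generator with known ground truth.

Families are evolved down the ultrametric ladder tree implied by the species
registry's divergence times under an equal-rates substitution model: per
branch of duration t, each site receives Poisson(rate * t) substitution
events, each replacing the residue with a uniformly chosen different one
(multiple hits therefore occur and partly revert, exactly the regime the
Poisson distance correction targets).

Ground truth is made exactly recoverable by two constructions:

* *planted* conserved-lysine sites: the columns of a planted context string
  are frozen to that pattern in the designated scope (and free to evolve
  outside it), so conservation scanning must find precisely the planted
  columns;
* lysine is excluded from ancestral draws and from substitution targets at
  all non-planted columns, so no conserved lysine can arise by chance at any
  rate (including rate 0, where every sequence equals the ancestor).

Structural/predictor flags and binding-domain intervals for planted sites are
emitted as a residue-annotation table; a copy-number profile is emitted as an
observed-count table with its implied event total.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .conservation import ALL_SPECIES, VERTEBRATES, parse_context
from .copynumber import FLY_BASELINE, LineageModel, count_events
from .core_io import (
    AMINO_ACIDS,
    GAP,
    HYDROPHOBIC,
    AlignedFamily,
    DomainInterval,
    HippolysError,
    ResidueAnnotation,
    SpeciesRegistry,
    write_alignment,
    write_annotations,
    write_copy_table,
)
from .monoubi import NONSTRUCTURAL, STRUCTURAL, UNKNOWN, EvidenceFlags, classify_candidate

_K_INDEX = AMINO_ACIDS.index("K")
_NON_K = [i for i in range(len(AMINO_ACIDS)) if i != _K_INDEX]


@dataclass(frozen=True)
class PlantedSite:
    """One conserved lysine planted into a synthetic family.

    ``position`` is the 1-based residue position of the lysine on the
    (ungapped) reference; ``context`` is a dash/slash pattern whose sole
    invariant-K field marks the lysine (e.g. ``"M-K-E-L-E"``).  For the truth
    strength label to be deterministic the context should settle the upstream
    hydrophobic rule itself — cover offset -1 or -2 with a purely hydrophobic
    set, or cover both with non-hydrophobic sets.
    """

    position: int
    context: str
    scope: str = ALL_SPECIES
    structural: bool = False
    predictor: bool = False
    in_domain: bool = False

    def __post_init__(self) -> None:
        if self.scope not in (ALL_SPECIES, VERTEBRATES):
            raise HippolysError(f"planted site scope must be {ALL_SPECIES} or {VERTEBRATES}")
        parse_context(self.context)  # validates the pattern now


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic family.

    Defaults emulate the real inputs: the nine-species coelomate registry,
    a mid-length signalling-protein alignment, and a substitution rate in the
    middle of the range observed for Hippo-pathway families (0.151-1.379
    substitutions per residue per billion years).
    """

    seed: int
    family_name: str = "SynthFamily"
    registry: SpeciesRegistry = field(default_factory=SpeciesRegistry.default)
    sequence_length: int = 500
    true_rate: float = 0.5
    planted_sites: tuple[PlantedSite, ...] = ()
    structural_status_known: bool = True
    copy_profile: Mapping[str, int] | None = None
    copy_model: LineageModel = field(
        default_factory=lambda: LineageModel(FLY_BASELINE, 1)
    )
    #: terminal-branch rate multipliers, species -> factor (discordance hook)
    rate_multipliers: Mapping[str, float] = field(default_factory=dict)
    gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.true_rate < 0:
            raise HippolysError("true_rate must be non-negative")
        if self.sequence_length < 1:
            raise HippolysError("sequence_length must be positive")
        positions = [s.position for s in self.planted_sites]
        if len(positions) != len(set(positions)):
            raise HippolysError("planted positions must be distinct")
        if not 0 <= self.gap_fraction < 1:
            raise HippolysError("gap_fraction must be in [0, 1)")


@dataclass
class PlantedTruth:
    position: int
    scope: str
    context: str
    expected_strength: str


@dataclass
class SyntheticTruth:
    """What the generator guarantees about its own output."""

    planted: list[PlantedTruth]
    conserved_universal_positions: list[int]
    conserved_vertebrate_positions: list[int]
    total_reference_lysines: int
    true_rate: float
    copy_events: float | None = None
    copy_model: str | None = None

    def to_json(self) -> str:
        payload = {
            "planted": [vars(p) for p in self.planted],
            "conserved_universal_positions": self.conserved_universal_positions,
            "conserved_vertebrate_positions": self.conserved_vertebrate_positions,
            "total_reference_lysines": self.total_reference_lysines,
            "true_rate": self.true_rate,
            "copy_events": self.copy_events,
            "copy_model": self.copy_model,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _evolve(seq: np.ndarray, duration: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One branch: Poisson(rate*duration) jumps per site, uniform targets.

    Lysine is never a target (planted columns are overwritten afterwards), so
    chance all-species lysine columns cannot arise.
    """
    out = seq.copy()
    lam = rate * duration
    if lam <= 0:
        return out
    hits = rng.poisson(lam, size=out.shape[0])
    for site in np.nonzero(hits)[0]:
        state = int(out[site])
        for _ in range(int(hits[site])):
            choices = [i for i in _NON_K if i != state]
            state = int(rng.choice(choices))
        out[site] = state
    return out


def _ladder_order(registry: SpeciesRegistry) -> list[tuple[str, float]]:
    depths = registry.ladder_depths
    return sorted(depths.items(), key=lambda kv: (-kv[1], kv[0]))


def _simulate_tips(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve an ancestral sequence to every tip of the ladder tree."""
    length = config.sequence_length
    ancestral = np.array(rng.choice(_NON_K, size=length), dtype=np.int64)
    order = _ladder_order(config.registry)
    root_depth = order[0][1]
    spine = ancestral
    spine_depth = root_depth
    tips: dict[str, np.ndarray] = {}
    for species, depth in order:
        spine = _evolve(spine, spine_depth - depth, config.true_rate, rng)
        spine_depth = depth
        mult = float(config.rate_multipliers.get(species, 1.0))
        tips[species] = _evolve(spine, depth, config.true_rate * mult, rng)
    return tips


# ---------------------------------------------------------------------------
# Planting and truth
# ---------------------------------------------------------------------------


def _truth_hydrophobic(residue_sets: Mapping[int, frozenset]) -> bool:
    return any(
        off in residue_sets and residue_sets[off] <= HYDROPHOBIC for off in (-1, -2)
    )


def generate_family(
    config: SimulationConfig,
) -> tuple[AlignedFamily, list[ResidueAnnotation], SyntheticTruth]:
    """Generate one aligned family plus annotations and ground truth."""
    rng = np.random.default_rng(config.seed)
    tips = _simulate_tips(config, rng)
    registry = config.registry
    length = config.sequence_length

    vertebrates = registry.clade("vertebrate")
    reference_species = (
        "Homo_sapiens" if "Homo_sapiens" in registry.species else registry.species[-1]
    )
    member_order = [sp for sp, _ in _ladder_order(registry)]

    # plant the conserved contexts
    frozen_columns: set[int] = set()
    universal_k_cols: set[int] = set()
    vertebrate_k_cols: set[int] = set()
    for site in config.planted_sites:
        pattern = parse_context(site.context)
        scope_species = (
            list(member_order)
            if site.scope == ALL_SPECIES
            else [sp for sp in member_order if sp in vertebrates]
        )
        for offset in pattern.offsets:
            col = site.position - 1 + offset
            if not 0 <= col < length:
                raise HippolysError(
                    f"context {site.context!r} at position {site.position} "
                    f"overruns sequence bounds"
                )
            residues = sorted(pattern.residue_sets[offset])
            for i, sp in enumerate(scope_species):
                tips[sp][col] = AMINO_ACIDS.index(residues[i % len(residues)])
            frozen_columns.add(col)
            if residues == ["K"]:
                if site.scope == ALL_SPECIES:
                    universal_k_cols.add(col)
                else:
                    vertebrate_k_cols.add(col)

    members = {
        (sp, config.family_name): "".join(AMINO_ACIDS[i] for i in tips[sp])
        for sp in member_order
    }

    # optional gap injection (reference and frozen columns stay gap-free)
    if config.gap_fraction > 0:
        for key in list(members):
            if key[0] == reference_species:
                continue
            chars = list(members[key])
            mask = rng.random(length) < config.gap_fraction
            for col in np.nonzero(mask)[0]:
                if int(col) not in frozen_columns:
                    chars[int(col)] = GAP
            members[key] = "".join(chars)

    family = AlignedFamily(
        family_name=config.family_name,
        members=members,
        reference=(reference_species, config.family_name),
    )

    # annotations for the reference member
    structural = {s.position for s in config.planted_sites if s.structural}
    annotation = ResidueAnnotation(
        member=family.reference,
        structural_lysines=structural if config.structural_status_known else None,
        domains=[
            DomainInterval("binding", max(1, s.position - 5), min(length, s.position + 10))
            for s in config.planted_sites
            if s.in_domain
        ],
        predictor_hits={s.position for s in config.planted_sites if s.predictor},
    )

    # ground truth, including the strength label the classifier should emit
    n_universal = len(universal_k_cols)
    planted_truth = []
    for site in config.planted_sites:
        pattern = parse_context(site.context)
        if site.structural:
            status = STRUCTURAL
        elif config.structural_status_known:
            status = NONSTRUCTURAL
        else:
            status = UNKNOWN
        flags = EvidenceFlags(
            universal_scope=site.scope == ALL_SPECIES,
            hydrophobic_ok=_truth_hydrophobic(pattern.residue_sets),
            structural_status=status,
            in_or_adjacent_interaction_domain=site.in_domain,
            sole_conserved_lysine=site.scope == ALL_SPECIES and n_universal == 1,
            predictor_support=site.predictor,
        )
        strength, _ = classify_candidate(flags)
        planted_truth.append(
            PlantedTruth(
                position=site.position,
                scope=site.scope,
                context=site.context,
                expected_strength=strength,
            )
        )

    copy_events = copy_model = None
    if config.copy_profile is not None:
        copy_events = count_events(config.copy_model, config.copy_profile, registry).total_events
        copy_model = config.copy_model.describe()

    truth = SyntheticTruth(
        planted=planted_truth,
        conserved_universal_positions=sorted(c + 1 for c in universal_k_cols),
        conserved_vertebrate_positions=sorted(c + 1 for c in vertebrate_k_cols),
        total_reference_lysines=family.ungapped(family.reference).count("K"),
        true_rate=config.true_rate,
        copy_events=copy_events,
        copy_model=copy_model,
    )
    return family, [annotation], truth


def generate_copy_table(config: SimulationConfig) -> tuple[dict[str, dict[str, int]], float]:
    """Observed copy table for the configured profile and its implied event total."""
    if config.copy_profile is None:
        raise HippolysError("config has no copy_profile")
    table = {config.family_name: dict(config.copy_profile)}
    events = count_events(config.copy_model, config.copy_profile, config.registry).total_events
    return table, events


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write alignment + annotations + truth (+ copy table) for one config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    family, annotations, truth = generate_family(config)
    paths = {
        "alignment": outdir / f"{config.family_name}.fasta",
        "annotations": outdir / f"{config.family_name}.annotations.tsv",
        "truth": outdir / f"{config.family_name}.truth.json",
    }
    write_alignment(family, paths["alignment"])
    write_annotations(annotations, paths["annotations"])
    paths["truth"].write_text(truth.to_json() + "\n")
    if config.copy_profile is not None:
        table, _ = generate_copy_table(config)
        paths["copies"] = outdir / f"{config.family_name}.copies.tsv"
        write_copy_table(table, paths["copies"])
    return paths
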