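"""Whole-genome-duplication-aware gene copy-number accounting.

Vertebrates experienced a whole-genome duplication on their stem lineage (the
2R doubling, modeled as a single x2 because the observed expectation is two
amniote copies per single-copy fly gene), and teleost fish a further
lineage-specific duplication (3R, another x2).  A ``LineageModel`` fixes a
baseline — the fly/bilaterian baseline or a hypothesized ancestral-vertebrate
count — and predicts the expected copy number at each terminal species.

Observed counts are then explained by per-tip gain/loss events:
``losses = max(expected - observed, 0)`` and ``gains = max(observed -
expected, 0)`` copies per species.  Event totals weight a gained copy heavier
than a lost one (default gain cost 2 vs loss cost 1): a loss is a single
deletion, while a gain invokes a duplication outside the WGD framework, and
duplications are conventionally costed above losses in gene-content
parsimony.  Unit costs are available for a plain L1 count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import HippolysError, SpeciesRegistry

FLY_BASELINE = "fly_baseline"
VERTEBRATE_ANCESTOR = "vertebrate_ancestor"

DEFAULT_LOSS_COST = 1.0
DEFAULT_GAIN_COST = 2.0


@dataclass(frozen=True)
class LineageModel:
    """Expected copy numbers under a WGD history hypothesis.

    ``fly_baseline`` counts from the single pre-duplication bilaterian gene
    complement (vertebrates x2, teleosts an additional x2);
    ``vertebrate_ancestor`` fixes the post-2R vertebrate count directly, so
    only the teleost doubling applies and non-vertebrates are out of scope.
    """

    baseline_node: str
    baseline_count: int
    wgd_multipliers: Mapping[str, int] = field(
        default_factory=lambda: {"vertebrate": 2, "teleost": 2}
    )

    def __post_init__(self) -> None:
        if self.baseline_node not in (FLY_BASELINE, VERTEBRATE_ANCESTOR):
            raise HippolysError(f"unknown baseline node {self.baseline_node!r}")
        if self.baseline_count < 1:
            raise HippolysError("baseline count must be a positive integer")
        for clade, factor in self.wgd_multipliers.items():
            if not (isinstance(factor, int) and factor > 0):
                raise HippolysError(f"WGD multiplier for {clade!r} must be a positive integer")

    def describe(self) -> str:
        return f"{self.baseline_node}:{self.baseline_count}"


def expected_copies(model: LineageModel, species: str, registry: SpeciesRegistry) -> int:
    """Expected copy number at one terminal species under the model."""
    if species not in registry.species:
        raise HippolysError(f"unknown species {species!r}")
    is_vertebrate = registry.is_member(species, "vertebrate")
    is_teleost = registry.is_member(species, "teleost")
    count = model.baseline_count
    if model.baseline_node == FLY_BASELINE:
        if is_vertebrate:
            count *= model.wgd_multipliers.get("vertebrate", 1)
            if is_teleost:
                count *= model.wgd_multipliers.get("teleost", 1)
    else:  # vertebrate_ancestor: post-2R baseline
        if not is_vertebrate:
            raise HippolysError(
                f"vertebrate-ancestor baseline queried for non-vertebrate {species!r}"
            )
        if is_teleost:
            count *= model.wgd_multipliers.get("teleost", 1)
    return count


@dataclass
class EventCount:
    """Per-species gain/loss copies and the weighted event total."""

    per_species: dict[str, tuple[int, int]]  # species -> (losses, gains) in copies
    total_events: float
    loss_cost: float = DEFAULT_LOSS_COST
    gain_cost: float = DEFAULT_GAIN_COST

    @property
    def total_copies_changed(self) -> int:
        """Unweighted count of gained plus lost copies."""
        return sum(l + g for l, g in self.per_species.values())


def count_events(
    model: LineageModel,
    observed: Mapping[str, int],
    registry: SpeciesRegistry,
    loss_cost: float = DEFAULT_LOSS_COST,
    gain_cost: float = DEFAULT_GAIN_COST,
) -> EventCount:
    """Tip-based gain/loss accounting of observed counts against the model.

    Only species present in ``observed`` contribute.  A species' copy losses
    and gains are weighted by ``loss_cost`` and ``gain_cost`` in the total.
    """
    if not observed:
        raise HippolysError("no observed counts supplied")
    per_species: dict[str, tuple[int, int]] = {}
    total = 0.0
    for species, count in observed.items():
        if count < 0:
            raise HippolysError(f"negative observed count for {species!r}")
        expected = expected_copies(model, species, registry)
        losses = max(expected - count, 0)
        gains = max(count - expected, 0)
        per_species[species] = (losses, gains)
        total += loss_cost * losses + gain_cost * gains
    return EventCount(
        per_species=per_species,
        total_events=total,
        loss_cost=loss_cost,
        gain_cost=gain_cost,
    )


@dataclass
class RankedHypothesis:
    model: LineageModel
    total_events: float
    tied: bool


def compare_hypotheses(
    observed: Mapping[str, int],
    models: Sequence[LineageModel],
    registry: SpeciesRegistry,
    loss_cost: float = DEFAULT_LOSS_COST,
    gain_cost: float = DEFAULT_GAIN_COST,
) -> list[RankedHypothesis]:
    """Rank models by ascending event total; ties keep input order, flagged."""
    if len(models) < 2:
        raise HippolysError("hypothesis comparison needs at least two models")
    totals = [
        count_events(model, observed, registry, loss_cost, gain_cost).total_events
        for model in models
    ]
    order = sorted(range(len(models)), key=lambda i: (totals[i], i))
    ranked = []
    for rank, i in enumerate(order):
        tied = any(
            totals[j] == totals[i] for j in order if j != i
        )
        ranked.append(RankedHypothesis(model=models[i], total_events=totals[i], tied=tied))
    return ranked
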