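import pytest

from hippolys import (
    AlignedFamily,
    PlantedSite,
    SimulationConfig,
    SpeciesRegistry,
    generate_family,
)

NINE_SPECIES = (
    "Drosophila_melanogaster",
    "Strongylocentrotus_purpuratus",
    "Saccoglossus_kowalevskii",
    "Branchiostoma_floridae",
    "Ciona_intestinalis",
    "Danio_rerio",
    "Gallus_gallus",
    "Mus_musculus",
    "Homo_sapiens",
)


@pytest.fixture(scope="session")
def registry() -> SpeciesRegistry:
    return SpeciesRegistry.default()


def family_from_sequences(seqs: dict[str, str], reference_species: str = "Homo_sapiens",
                          name: str = "Fam") -> AlignedFamily:
    """Build a one-paralog-per-species family from raw aligned strings."""
    return AlignedFamily(
        family_name=name,
        members={(sp, name): seq for sp, seq in seqs.items()},
        reference=(reference_species, name),
    )


def uniform_family(sequence: str, name: str = "Fam") -> AlignedFamily:
    """Nine identical copies of one aligned sequence, one per species."""
    return family_from_sequences({sp: sequence for sp in NINE_SPECIES}, name=name)


@pytest.fixture(scope="session")
def salvador_like_bundle():
    """A synthetic family with one planted universal, in-domain, sole
    conserved lysine in an M-K-E-L-E context — the strongest candidate
    configuration."""
    config = SimulationConfig(
        seed=11,
        family_name="SavLike",
        sequence_length=400,
        true_rate=0.3,
        planted_sites=(PlantedSite(position=120, context="M-K-E-L-E", in_domain=True),),
    )
    family, annotations, truth = generate_family(config)
    return config, family, annotations, truth
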