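import pytest

from hippolys import (
    DomainInterval,
    EvidenceFlags,
    PlantedSite,
    ResidueAnnotation,
    ScopeGroup,
    SimulationConfig,
    classify_candidate,
    find_conserved_lysines,
    gather_evidence,
    generate_family,
    scan_family,
)
from hippolys.core_io import TableFormatError

from conftest import NINE_SPECIES, family_from_sequences, uniform_family


def make_flags(**overrides):
    base = dict(
        universal_scope=True,
        hydrophobic_ok=True,
        structural_status="nonstructural",
        in_or_adjacent_interaction_domain=False,
        sole_conserved_lysine=False,
        predictor_support=False,
    )
    base.update(overrides)
    return EvidenceFlags(**base)


class TestClassifyCandidate:
    def test_universal_nonstructural_corroborated_is_strong(self):
        strength, rationale = classify_candidate(
            make_flags(in_or_adjacent_interaction_domain=True, sole_conserved_lysine=True)
        )
        assert strength == "strong"
        assert "interaction-domain" in rationale and "sole-conserved-lysine" in rationale

    def test_universal_without_corroboration_is_modest(self):
        strength, rationale = classify_candidate(make_flags())
        assert strength == "modest"
        assert rationale == ["no-corroborating-evidence"]

    def test_vertebrate_scope_with_unknown_structure_is_modest(self):
        strength, rationale = classify_candidate(
            make_flags(universal_scope=False, structural_status="unknown")
        )
        assert strength == "modest"
        assert "vertebrate-limited-scope" in rationale

    def test_structural_lysine_is_never_a_candidate(self):
        strength, rationale = classify_candidate(
            make_flags(structural_status="structural", in_or_adjacent_interaction_domain=True)
        )
        assert (strength, rationale) == ("none", ["structural-lysine"])

    def test_failed_hydrophobic_rule_disqualifies(self):
        strength, _ = classify_candidate(make_flags(hydrophobic_ok=False, sole_conserved_lysine=True))
        assert strength == "none"

    def test_unknown_structural_status_caps_at_modest(self):
        strength, rationale = classify_candidate(
            make_flags(structural_status="unknown", predictor_support=True)
        )
        assert strength == "modest"
        assert "unknown-structural-status" in rationale


class TestGatherEvidence:
    @pytest.fixture()
    def family(self):
        # one universally conserved K at reference position 3 (L at -1)
        return uniform_family("ALKE" + "A" * 36)

    def _site_and_all(self, family):
        sites = find_conserved_lysines(family, ScopeGroup.all_species(family))
        return sites[0], sites

    @pytest.mark.parametrize(
        "interval, margin, expected",
        [((2, 5), 10, True), ((20, 30), 10, False), ((10, 30), 10, True), ((15, 30), 10, False)],
    )
    def test_domain_adjacency_margin(self, family, interval, margin, expected):
        site, sites = self._site_and_all(family)
        ann = ResidueAnnotation(
            member=family.reference,
            structural_lysines=set(),
            domains=[DomainInterval("binding", *interval)],
        )
        flags = gather_evidence(site, family, ann, sites, adjacency_margin=margin)
        assert flags.in_or_adjacent_interaction_domain is expected

    def test_sole_universal_lysine_flagged(self, family):
        site, sites = self._site_and_all(family)
        ann = ResidueAnnotation(member=family.reference, structural_lysines=set())
        assert gather_evidence(site, family, ann, sites).sole_conserved_lysine

    def test_not_sole_with_two_universal_sites(self):
        family = uniform_family("ALKEALKEAA")
        sites = find_conserved_lysines(family, ScopeGroup.all_species(family))
        ann = ResidueAnnotation(member=family.reference, structural_lysines=set())
        assert len(sites) == 2
        assert not gather_evidence(sites[0], family, ann, sites).sole_conserved_lysine

    def test_structural_and_unknown_status(self, family):
        site, sites = self._site_and_all(family)
        structural = ResidueAnnotation(member=family.reference, structural_lysines={3})
        unknown = ResidueAnnotation(member=family.reference, structural_lysines=None)
        assert gather_evidence(site, family, structural, sites).structural_status == "structural"
        assert gather_evidence(site, family, unknown, sites).structural_status == "unknown"

    def test_predictor_hits(self, family):
        site, sites = self._site_and_all(family)
        ann = ResidueAnnotation(
            member=family.reference, structural_lysines=set(), predictor_hits={3}
        )
        assert gather_evidence(site, family, ann, sites).predictor_support

    def test_annotation_family_mismatch_rejected(self, family):
        site, sites = self._site_and_all(family)
        ann = ResidueAnnotation(member=("Danio_rerio", "Fam"), structural_lysines=set())
        with pytest.raises(TableFormatError):
            gather_evidence(site, family, ann, sites)


class TestScanFamily:
    def test_planted_salvador_like_site_yields_one_strong_call(
        self, registry, salvador_like_bundle
    ):
        config, family, annotations, truth = salvador_like_bundle
        calls, summary = scan_family(family, annotations, registry)
        strong = [c for c in calls if c.strength == "strong"]
        assert len(strong) == 1
        assert strong[0].site.reference_position == truth.planted[0].position
        assert strong[0].strength == truth.planted[0].expected_strength
        assert summary.total_lysines == truth.total_reference_lysines
        assert summary.fraction == "100%"

    def test_family_without_conserved_lysines(self, registry):
        seqs = {sp: "MAKE" for sp in NINE_SPECIES}
        seqs["Danio_rerio"] = "MARE"
        family = family_from_sequences(seqs)
        calls, summary = scan_family(family, [], registry)
        assert calls == []
        assert summary.fraction == "0%"
        assert summary.best_call is None

    def test_structural_only_sites_all_classified_none(self, registry):
        config = SimulationConfig(
            seed=5,
            sequence_length=200,
            true_rate=0.3,
            planted_sites=(
                PlantedSite(position=50, context="L-K-E", structural=True),
                PlantedSite(position=90, context="I-K-P", structural=True),
            ),
        )
        family, annotations, _ = generate_family(config)
        calls, summary = scan_family(family, annotations, registry)
        assert calls and all(c.strength == "none" for c in calls)
        assert summary.best_call is None

    def test_vertebrate_site_reported_at_vertebrate_scope(self, registry):
        config = SimulationConfig(
            seed=9,
            sequence_length=200,
            true_rate=0.4,
            planted_sites=(
                PlantedSite(position=40, context="M-K-E-L-E"),
                PlantedSite(position=120, context="L-T-K-P", scope="vertebrates"),
            ),
        )
        family, annotations, truth = generate_family(config)
        calls, _ = scan_family(family, annotations, registry)
        by_pos = {c.site.reference_position: c for c in calls}
        assert by_pos[40].site.scope.label == "all_species"
        assert by_pos[120].site.scope.label == "vertebrates"
        assert by_pos[120].strength == "modest"  # vertebrate-limited scope caps strength

    def test_evidence_monotonicity_never_lowers_strength(self):
        order = {"none": 0, "modest": 1, "strong": 2}
        statuses = ["structural", "unknown", "nonstructural"]
        bools = [False, True]
        for universal in bools:
            for hydro in bools:
                for status in statuses:
                    for domain in bools:
                        for sole in bools:
                            for predictor in bools:
                                flags = make_flags(
                                    universal_scope=universal,
                                    hydrophobic_ok=hydro,
                                    structural_status=status,
                                    in_or_adjacent_interaction_domain=domain,
                                    sole_conserved_lysine=sole,
                                    predictor_support=predictor,
                                )
                                base, _ = classify_candidate(flags)
                                # single-step improvements along the evidence lattice
                                upgrades = []
                                if not universal:
                                    upgrades.append(make_flags(
                                        universal_scope=True, hydrophobic_ok=hydro,
                                        structural_status=status,
                                        in_or_adjacent_interaction_domain=domain,
                                        sole_conserved_lysine=sole, predictor_support=predictor))
                                if status != "nonstructural":
                                    upgrades.append(make_flags(
                                        universal_scope=universal, hydrophobic_ok=hydro,
                                        structural_status="nonstructural",
                                        in_or_adjacent_interaction_domain=domain,
                                        sole_conserved_lysine=sole, predictor_support=predictor))
                                if not predictor:
                                    upgrades.append(make_flags(
                                        universal_scope=universal, hydrophobic_ok=hydro,
                                        structural_status=status,
                                        in_or_adjacent_interaction_domain=domain,
                                        sole_conserved_lysine=sole, predictor_support=True))
                                for upgraded in upgrades:
                                    better, _ = classify_candidate(upgraded)
                                    assert order[better] >= order[base]
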