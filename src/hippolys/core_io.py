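"""Shared containers, coordinate conventions and file I/O.

Everything downstream (conservation scanning, candidate classification,
substitution rates, copy-number accounting) works on three kinds of input:

* aligned protein families (aligned FASTA, one family per file, records named
  ``>Genus_species|ParalogName``),
* a species registry carrying clade memberships and pairwise divergence
  times in billions of years,
* small tab-separated metadata tables (residue annotations per reference
  protein, observed gene copy counts per family).

Coordinates are 1-based and inclusive on the *ungapped* sequence of a member,
matching the way sites are reported in the literature ("K345" is the 345th
residue of the human protein, gaps ignored).  Alignment columns are 0-based
internally and never appear in reports.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Constants and error hierarchy
# ---------------------------------------------------------------------------

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Residues counted as hydrophobic for the upstream (-1/-2) context rule.
HYDROPHOBIC = frozenset("ILVM")

#: Clade labels understood by the registry.
CLADE_LABELS = frozenset(
    {
        "protostome",
        "deuterostome",
        "echinoderm",
        "hemichordate",
        "cephalochordate",
        "urochordate",
        "vertebrate",
        "teleost",
        "amniote",
        "mammal",
    }
)

#: Canonical FASTA line wrap used on output.
FASTA_WRAP = 60


class HippolysError(Exception):
    """Base class for all package errors."""


class AlignmentParseError(HippolysError):
    """A FASTA record contains an illegal character or unparseable header."""


class RaggedAlignmentError(HippolysError):
    """Member sequences of one family differ in aligned length."""


class MissingReferenceError(HippolysError):
    """The designated reference member is absent from the family."""


class RegistryError(HippolysError):
    """The species registry violates an invariant (asymmetry, unknown species...)."""


class TableFormatError(HippolysError):
    """A TSV metadata table is missing columns or malformed."""


class UndefinedFractionError(HippolysError):
    """Conserved fraction requested with zero total lysines."""


class SaturationError(HippolysError):
    """Poisson correction undefined: observed proportion of differences >= 1."""


# ---------------------------------------------------------------------------
# Rounding convention
# ---------------------------------------------------------------------------


def round_half_away(value: float, ndigits: int) -> float:
    """Round with ties going away from zero (so 21.875 -> 21.88 at 2 digits).

    Python's built-in ``round`` uses banker's rounding; printed percentages
    and rates in this package follow the half-away-from-zero convention
    instead (21.875% prints as 21.9%).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Species registry
# ---------------------------------------------------------------------------

# The default registry: nine coelomate species (eight deuterostomes and one
# protostome) spanning protostome/deuterostome, echinoderm, hemichordate,
# cephalochordate, urochordate and vertebrate lineages.  Divergence times are
# the fossil-calibrated estimates used throughout: protostomes split from
# deuterostomes 1.1 billion years ago (By); echinoderms and hemichordates
# split from chordates 0.99 and 0.90 By; cephalochordates and urochordates
# from vertebrates 0.75 and 0.72 By; teleosts from amniotes 0.46 By; birds
# from mammals 0.33 By; mouse from human 0.093 By.  The species tree is a
# ladder, so the pairwise time of two species is the split depth of whichever
# lineage leaves the backbone earlier.
_DEFAULT_SPLIT_DEPTH: dict[str, float] = {
    "Drosophila_melanogaster": 1.1,
    "Strongylocentrotus_purpuratus": 0.99,
    "Saccoglossus_kowalevskii": 0.90,
    "Branchiostoma_floridae": 0.75,
    "Ciona_intestinalis": 0.72,
    "Danio_rerio": 0.46,
    "Gallus_gallus": 0.33,
    "Mus_musculus": 0.093,
    "Homo_sapiens": 0.093,
}

_DEFAULT_CLADES: dict[str, frozenset[str]] = {
    "Drosophila_melanogaster": frozenset({"protostome"}),
    "Strongylocentrotus_purpuratus": frozenset({"deuterostome", "echinoderm"}),
    "Saccoglossus_kowalevskii": frozenset({"deuterostome", "hemichordate"}),
    "Branchiostoma_floridae": frozenset({"deuterostome", "cephalochordate"}),
    "Ciona_intestinalis": frozenset({"deuterostome", "urochordate"}),
    "Danio_rerio": frozenset({"deuterostome", "vertebrate", "teleost"}),
    "Gallus_gallus": frozenset({"deuterostome", "vertebrate", "amniote"}),
    "Mus_musculus": frozenset({"deuterostome", "vertebrate", "amniote", "mammal"}),
    "Homo_sapiens": frozenset({"deuterostome", "vertebrate", "amniote", "mammal"}),
}


@dataclass(frozen=True)
class SpeciesRegistry:
    """Species set with clade memberships and pairwise divergence times (By)."""

    species: tuple[str, ...]
    clade_membership: Mapping[str, frozenset[str]]
    _times: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for sp in self.species:
            clades = self.clade_membership.get(sp)
            if not clades:
                raise RegistryError(f"species {sp!r} belongs to no clade")
            unknown = clades - CLADE_LABELS
            if unknown:
                raise RegistryError(f"unknown clade label(s) {sorted(unknown)} for {sp!r}")
        # clade hierarchy: mammal <= amniote <= vertebrate; teleost <= vertebrate
        for narrow, wide in (("mammal", "amniote"), ("amniote", "vertebrate"), ("teleost", "vertebrate")):
            bad = self.clade(narrow) - self.clade(wide)
            if bad:
                raise RegistryError(f"clade hierarchy violated: {sorted(bad)} in {narrow} but not {wide}")
        for (a, b), t in self._times.items():
            if a not in self.species or b not in self.species:
                raise RegistryError(f"divergence time given for unknown species pair ({a}, {b})")
            other = self._times.get((b, a))
            if other is None or abs(other - t) > 1e-12:
                raise RegistryError(f"divergence time asymmetric for ({a}, {b}): {t} vs {other}")
            if a == b and t != 0.0:
                raise RegistryError(f"nonzero self-divergence for {a}")
            if t < 0:
                raise RegistryError(f"negative divergence time for ({a}, {b})")

    def divergence_time(self, a: str, b: str) -> float:
        """Pairwise divergence time in billions of years; 0 on the diagonal."""
        if a not in self.species or b not in self.species:
            raise RegistryError(f"unknown species in pair ({a!r}, {b!r})")
        if a == b:
            return 0.0
        try:
            return self._times[(a, b)]
        except KeyError:
            raise RegistryError(f"no divergence time for ({a!r}, {b!r})") from None

    def clade(self, label: str) -> frozenset[str]:
        """Species carrying a clade label."""
        return frozenset(sp for sp in self.species if label in self.clade_membership[sp])

    def is_member(self, sp: str, label: str) -> bool:
        return sp in self.species and label in self.clade_membership[sp]

    @classmethod
    def from_tables(
        cls,
        clades: Mapping[str, Iterable[str]],
        times: Mapping[tuple[str, str], float],
    ) -> "SpeciesRegistry":
        """Build a registry from a clade map and an upper- or full-triangle time map."""
        species = tuple(clades)
        full: dict[tuple[str, str], float] = {}
        for (a, b), t in times.items():
            full[(a, b)] = t
            full.setdefault((b, a), times.get((b, a), t))
        for sp in species:
            full[(sp, sp)] = 0.0
        membership = {sp: frozenset(cl) for sp, cl in clades.items()}
        return cls(species=species, clade_membership=membership, _times=full)

    @classmethod
    def default(cls) -> "SpeciesRegistry":
        """The bundled nine-species coelomate registry (ladder topology)."""
        times = {
            (a, b): max(_DEFAULT_SPLIT_DEPTH[a], _DEFAULT_SPLIT_DEPTH[b])
            for a in _DEFAULT_SPLIT_DEPTH
            for b in _DEFAULT_SPLIT_DEPTH
            if a != b
        }
        return cls.from_tables(_DEFAULT_CLADES, times)

    @property
    def ladder_depths(self) -> dict[str, float]:
        """Split depth of each species from the backbone, deepest first.

        Only meaningful for ladder-shaped registries such as the default;
        derived as each species' maximum pairwise time against the others is
        not unique, so we store the canonical depths for the default set and
        recompute for custom registries as min over partners of T(sp, other)
        ... which for a ladder equals the species' own split depth.
        """
        depths: dict[str, float] = {}
        for sp in self.species:
            others = [o for o in self.species if o != sp]
            depths[sp] = min(self.divergence_time(sp, o) for o in others)
        return depths


# ---------------------------------------------------------------------------
# Aligned families
# ---------------------------------------------------------------------------

MemberKey = tuple[str, str]  # (species, paralog_name)


def _format_key(key: MemberKey) -> str:
    return f"{key[0]}|{key[1]}"


def parse_member_header(header: str, default_paralog: str) -> MemberKey:
    """Parse ``Genus_species|Paralog`` (paralog optional) into a member key."""
    parts = header.split("|")
    if len(parts) == 1:
        species, paralog = parts[0], default_paralog
    elif len(parts) == 2:
        species, paralog = parts
    else:
        raise AlignmentParseError(f"cannot parse record header {header!r}")
    if not species or "_" not in species:
        raise AlignmentParseError(
            f"record header {header!r}: species must be in Genus_species form"
        )
    if not paralog:
        raise AlignmentParseError(f"record header {header!r}: empty paralog name")
    return (species, paralog)


@dataclass
class AlignedFamily:
    """One protein family's aligned members, keyed by (species, paralog).

    ``reference`` designates the member on whose ungapped sequence residues
    are counted and reported (conventionally the human paralog).
    """

    family_name: str
    members: dict[MemberKey, str]
    reference: MemberKey

    def __post_init__(self) -> None:
        if not self.members:
            raise RaggedAlignmentError(f"family {self.family_name!r} has no members")
        lengths = {len(s) for s in self.members.values()}
        if len(lengths) != 1 or 0 in lengths:
            detail = ", ".join(
                f"{_format_key(k)}:{len(s)}" for k, s in self.members.items()
            )
            raise RaggedAlignmentError(
                f"family {self.family_name!r}: unequal aligned lengths ({detail})"
            )
        for key, seq in self.members.items():
            for col, ch in enumerate(seq):
                if ch not in AMINO_ACIDS and ch != GAP:
                    raise AlignmentParseError(
                        f"family {self.family_name!r}, record {_format_key(key)}, "
                        f"column {col}: illegal character {ch!r}"
                    )
        if self.reference not in self.members:
            raise MissingReferenceError(
                f"family {self.family_name!r}: reference {_format_key(self.reference)} "
                f"not among members"
            )
        if not self.ungapped(self.reference):
            raise MissingReferenceError(
                f"family {self.family_name!r}: reference sequence is all gaps"
            )

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.members.values())))

    def sequence(self, member: MemberKey) -> str:
        try:
            return self.members[member]
        except KeyError:
            raise MissingReferenceError(
                f"family {self.family_name!r}: unknown member {_format_key(member)}"
            ) from None

    def ungapped(self, member: MemberKey) -> str:
        return self.sequence(member).replace(GAP, "")

    def ungapped_position(self, member: MemberKey, column: int) -> int | None:
        """1-based residue position of ``column`` in ``member``; None on a gap."""
        seq = self.sequence(member)
        if not 0 <= column < len(seq):
            raise IndexError(
                f"column {column} out of range for family {self.family_name!r}"
            )
        if seq[column] == GAP:
            return None
        return column + 1 - seq.count(GAP, 0, column + 1)

    def column_of(self, member: MemberKey, position: int) -> int:
        """Alignment column (0-based) of the 1-based ungapped ``position``."""
        seq = self.sequence(member)
        count = 0
        for col, ch in enumerate(seq):
            if ch != GAP:
                count += 1
                if count == position:
                    return col
        raise IndexError(
            f"position {position} beyond ungapped length of {_format_key(member)}"
        )


def read_alignment(
    path: str | Path, reference_key: MemberKey | str, family_name: str | None = None
) -> AlignedFamily:
    """Read one family from aligned FASTA.

    Headers are ``>Genus_species|ParalogName``; when the paralog part is
    absent it defaults to the family name (the file stem unless given).
    ``reference_key`` may be a (species, paralog) tuple or a ``"species|paralog"``
    string.
    """
    path = Path(path)
    name = family_name or path.stem
    if isinstance(reference_key, str):
        reference_key = parse_member_header(reference_key, name)
    members: dict[MemberKey, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        key = parse_member_header(record.id, name)
        if key in members:
            raise AlignmentParseError(
                f"family {name!r}: duplicate record {_format_key(key)}"
            )
        members[key] = str(record.seq).upper()
    return AlignedFamily(family_name=name, members=members, reference=reference_key)


def write_alignment(family: AlignedFamily, path: str | Path) -> None:
    """Write aligned FASTA with the canonical 60-column wrap, member order kept."""
    records = [
        SeqRecord(Seq(seq), id=_format_key(key), description="")
        for key, seq in family.members.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Residue annotations
# ---------------------------------------------------------------------------


@dataclass
class DomainInterval:
    """A named interval on the ungapped reference, 1-based inclusive.

    Only binding/interaction domains belong in the annotation table: the
    candidate classifier treats residency in (or adjacency to) any listed
    interval as interaction evidence, so catalytic domains with no partner
    surface should be omitted.
    """

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise TableFormatError(
                f"domain {self.label!r}: start {self.start} > end {self.end}"
            )


@dataclass
class ResidueAnnotation:
    """Curated per-protein residue facts consumed, never derived, here.

    ``structural_lysines`` is ``None`` when no structural information exists
    for the protein — deliberately distinct from an empty set (no known
    structural lysines), because unknown status caps candidate strength.
    ``predictor_hits`` holds positions supported by an external
    sequence-based ubiquitylation predictor, consumed as a flag only.
    """

    member: MemberKey
    structural_lysines: set[int] | None
    domains: list[DomainInterval] = field(default_factory=list)
    predictor_hits: set[int] = field(default_factory=set)

    def validate_against(self, family: AlignedFamily) -> None:
        if self.member not in family.members:
            raise TableFormatError(
                f"annotation member {_format_key(self.member)} not in family "
                f"{family.family_name!r}"
            )
        n = len(family.ungapped(self.member))
        positions = set(self.predictor_hits) | (self.structural_lysines or set())
        for dom in self.domains:
            positions.update((dom.start, dom.end))
        bad = [p for p in positions if not 1 <= p <= n]
        if bad:
            raise TableFormatError(
                f"annotation positions {sorted(bad)} outside 1..{n} for "
                f"{_format_key(self.member)}"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise TableFormatError(f"{path}: missing column(s) {missing}")
        return list(reader)


def read_species_registry(path: str | Path) -> SpeciesRegistry:
    """Read a registry TSV.

    Columns: ``species``, ``clades`` (comma-separated labels), then one column
    per species holding the divergence time in billions of years (a full
    symmetric matrix with zeros on the diagonal).
    """
    rows = _read_tsv(path, ["species", "clades"])
    species = [r["species"] for r in rows]
    clades = {r["species"]: [c for c in r["clades"].split(",") if c] for r in rows}
    times: dict[tuple[str, str], float] = {}
    for r in rows:
        for other in species:
            if other not in r:
                raise TableFormatError(f"{path}: missing time column {other!r}")
            times[(r["species"], other)] = float(r[other])
    return SpeciesRegistry.from_tables(clades, times)


def write_species_registry(registry: SpeciesRegistry, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["species", "clades", *registry.species])
        for sp in registry.species:
            clades = ",".join(sorted(registry.clade_membership[sp]))
            row = [sp, clades] + [
                format(registry.divergence_time(sp, o), "g") for o in registry.species
            ]
            writer.writerow(row)


_ANNOTATION_COLUMNS = ["species", "paralog", "structural_lysines", "domains", "predictor_hits"]


def _parse_positions(cell: str) -> set[int]:
    return {int(tok) for tok in cell.split(",") if tok.strip()}


def read_annotations(path: str | Path) -> list[ResidueAnnotation]:
    """Read residue annotations.

    Columns: ``species``, ``paralog``, ``structural_lysines`` (comma list,
    empty for none, the literal ``unknown`` when no structural data exists),
    ``domains`` (``label:start-end`` items joined by ``;``),
    ``predictor_hits`` (comma list).
    """
    out = []
    for row in _read_tsv(path, _ANNOTATION_COLUMNS):
        raw = row["structural_lysines"].strip()
        structural = None if raw.lower() == "unknown" else _parse_positions(raw)
        domains = []
        for item in row["domains"].split(";"):
            item = item.strip()
            if not item:
                continue
            try:
                label, span = item.rsplit(":", 1)
                start, end = span.split("-")
                domains.append(DomainInterval(label, int(start), int(end)))
            except ValueError as exc:
                raise TableFormatError(f"{path}: bad domain spec {item!r}") from exc
        out.append(
            ResidueAnnotation(
                member=(row["species"], row["paralog"]),
                structural_lysines=structural,
                domains=domains,
                predictor_hits=_parse_positions(row["predictor_hits"]),
            )
        )
    return out


def write_annotations(annotations: Iterable[ResidueAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for ann in annotations:
            structural = (
                "unknown"
                if ann.structural_lysines is None
                else ",".join(map(str, sorted(ann.structural_lysines)))
            )
            domains = ";".join(f"{d.label}:{d.start}-{d.end}" for d in ann.domains)
            hits = ",".join(map(str, sorted(ann.predictor_hits)))
            writer.writerow([ann.member[0], ann.member[1], structural, domains, hits])


def read_copy_table(path: str | Path) -> dict[str, dict[str, int]]:
    """Read observed gene copy counts: columns ``family``, ``species``, ``count``."""
    table: dict[str, dict[str, int]] = {}
    for row in _read_tsv(path, ["family", "species", "count"]):
        count = int(row["count"])
        if count < 0:
            raise TableFormatError(
                f"{path}: negative copy count for {row['family']}/{row['species']}"
            )
        table.setdefault(row["family"], {})[row["species"]] = count
    return table


def write_copy_table(table: Mapping[str, Mapping[str, int]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["family", "species", "count"])
        for family in table:
            for species, count in table[family].items():
                writer.writerow([family, species, count])
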