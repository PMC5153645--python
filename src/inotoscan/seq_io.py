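"""Sequence and metadata I/O.

Reads and writes the formats the mining pipeline touches (FASTA sequence
collections, TSV species manifests), provides six-frame translation for
translated homology searches against nucleotide assemblies, and ships the
packaged reference table of oxytocin/vasopressin/inotocin mature peptides
with their observed frequencies across arthropod precursor sequences.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "SpeciesMeta",
    "PeptideFixtureRow",
    "FastaFormatError",
    "SequenceValidationError",
    "read_fasta",
    "write_fasta",
    "read_species_manifest",
    "write_species_manifest",
    "six_frame_translate",
    "load_table1_fixture",
    "load_order_tree_newick",
    "INSECT_FIXTURE_GROUPS",
    "ARTEFACT_FIXTURE_SPECIES",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
NUCLEOTIDE_ALPHABET = frozenset("ACGTUN")


class FastaFormatError(ValueError):
    """Structural problem in a FASTA file (empty entry, missing header...)."""


class SequenceValidationError(ValueError):
    """Residues outside the declared alphabet, or inconsistent metadata."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence bound to a species and source dataset.

    ``residues`` are stored upper-case and validated against the declared
    alphabet (amino acids plus ``X``/``*``, or nucleotides plus ``N``).
    """

    identifier: str
    residues: str
    molecule_type: str = "protein"
    species: str = ""
    source_dataset: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise SequenceValidationError("record identifier must be non-empty")
        if self.molecule_type not in ("protein", "nucleotide"):
            raise SequenceValidationError(
                f"unknown molecule_type {self.molecule_type!r}"
            )
        residues = self.residues.upper()
        if not residues:
            raise SequenceValidationError(
                f"record {self.identifier!r} has an empty sequence"
            )
        alphabet = (
            PROTEIN_ALPHABET if self.molecule_type == "protein" else NUCLEOTIDE_ALPHABET
        )
        bad = set(residues) - alphabet
        if bad:
            raise SequenceValidationError(
                f"record {self.identifier!r} contains illegal "
                f"{self.molecule_type} characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SpeciesMeta:
    """Taxonomic placement of one sampled species."""

    species: str
    order: str
    subphylum: str
    group_label: str = ""
    source_dataset: str = ""

    def __post_init__(self) -> None:
        if not self.species or not self.order or not self.subphylum:
            raise SequenceValidationError(
                f"species manifest row incomplete: {self!r}"
            )
        if not self.group_label:
            object.__setattr__(self, "group_label", self.order)


@dataclass(frozen=True)
class PeptideFixtureRow:
    """One row of the packaged mature-peptide reference table."""

    sequence: str
    amidated: bool
    frequency: int
    name: str
    group_or_species: str

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise SequenceValidationError("frequency must be >= 0")
        if not (self.sequence.startswith("C") and len(self.sequence) >= 6
                and self.sequence[5] == "C"):
            raise SequenceValidationError(
                f"peptide {self.sequence!r} lacks the ring cysteines at "
                "positions 1 and 6"
            )

    @property
    def is_arthropod(self) -> bool:
        """Reference vertebrate peptides carry frequency 0."""
        return self.frequency > 0


def _iter_fasta_entries(path: Path) -> Iterator[tuple[str, str, str]]:
    header = None
    chunks: list[str] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header[0], header[1], "".join(chunks)
                desc = line[1:].strip()
                if not desc:
                    raise FastaFormatError(
                        f"{path}:{lineno}: header with no identifier"
                    )
                first, _, rest = desc.partition(" ")
                header = (first, rest)
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
        if header is not None:
            yield header[0], header[1], "".join(chunks)


def read_fasta(
    path: str | Path,
    molecule_type: str = "protein",
    species: str = "",
    source_dataset: str = "",
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    The first whitespace-separated token of each description line is the
    identifier; the remainder is kept as free-text description. Blank lines
    are ignored; an entry with an empty sequence or a duplicate identifier
    is an error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for identifier, description, residues in _iter_fasta_entries(path):
        if not residues:
            raise FastaFormatError(
                f"{path}: entry {identifier!r} has no sequence data"
            )
        if identifier in seen:
            raise FastaFormatError(
                f"{path}: duplicate identifier {identifier!r}"
            )
        seen.add(identifier)
        records.append(
            SequenceRecord(
                identifier=identifier,
                residues=residues,
                molecule_type=molecule_type,
                species=species,
                source_dataset=source_dataset,
                description=description,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            handle.write(f">{rec.identifier}{desc}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def read_species_manifest(path: str | Path) -> list[SpeciesMeta]:
    """Read the canonical 4/5-column species manifest TSV.

    Columns: species, order, subphylum, and optionally group_label and
    dataset. Species names must be unique.
    """
    rows: list[SpeciesMeta] = []
    seen: set[str] = set()
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            meta = SpeciesMeta(
                species=row["species"],
                order=row["order"],
                subphylum=row["subphylum"],
                group_label=row.get("group_label") or "",
                source_dataset=row.get("dataset") or "",
            )
            if meta.species in seen:
                raise SequenceValidationError(
                    f"duplicate species in manifest: {meta.species!r}"
                )
            seen.add(meta.species)
            rows.append(meta)
    return rows


def write_species_manifest(manifest: Iterable[SpeciesMeta],
                           path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["species", "order", "subphylum", "group_label",
                         "dataset"])
        for meta in manifest:
            writer.writerow([meta.species, meta.order, meta.subphylum,
                             meta.group_label, meta.source_dataset])


def assign_species_from_identifier(
    records: Iterable[SequenceRecord],
    manifest: Iterable[SpeciesMeta],
) -> list[SequenceRecord]:
    """Bind records to manifest species via the ``Species|rest`` id prefix.

    FASTA files carry no species column; dataset exports in this package
    prefix identifiers with the species name. Records whose prefix is not
    in the manifest keep their existing (possibly empty) species.
    """
    known = {m.species for m in manifest}
    out: list[SequenceRecord] = []
    for rec in records:
        prefix = rec.identifier.partition("|")[0]
        if not rec.species and prefix in known:
            rec = replace(rec, species=prefix)
        out.append(rec)
    return out


def convert_supplementary_manifest(path: str | Path) -> list[SpeciesMeta]:
    """Converter stub for externally formatted species lists.

    Assumes one precursor/receptor per species with sequence text in a
    per-study supplementary layout; since no machine-readable layout is
    standardised, this currently just delegates to the canonical TSV
    reader and exists as the extension point for custom layouts.
    """
    return read_species_manifest(path)


def six_frame_translate(record: SequenceRecord) -> list[SequenceRecord]:
    """Translate a nucleotide record in all six reading frames.

    Frames +1/+2/+3 read the forward strand at offsets 0/1/2; -1/-2/-3 read
    the reverse complement likewise. Stop codons become ``*``; trailing
    partial codons are dropped. The frame is appended to the identifier as
    ``|frame=+1`` etc.
    """
    if record.molecule_type != "nucleotide":
        raise TypeError(
            f"six_frame_translate requires a nucleotide record, got "
            f"{record.molecule_type!r} for {record.identifier!r}"
        )
    out: list[SequenceRecord] = []
    forward = Seq(record.residues.replace("U", "T"))
    reverse = forward.reverse_complement()
    for strand, seq in ((1, forward), (-1, reverse)):
        for offset in range(3):
            frame = strand * (offset + 1)
            sub = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
            if len(sub) == 0:
                continue
            protein = str(sub.translate())
            if not protein:
                continue
            out.append(
                SequenceRecord(
                    identifier=f"{record.identifier}|frame={frame:+d}",
                    residues=protein,
                    molecule_type="protein",
                    species=record.species,
                    source_dataset=record.source_dataset,
                    description=record.description,
                )
            )
    return out


# Fixture rows whose group/species column places them inside the class
# Insecta (subphylum Hexapoda); used for the insect-only ring consensus.
INSECT_FIXTURE_GROUPS = frozenset(
    {
        "insects",
        "Athalia rosae, Neodiprion lecontei",
        "Haploembia palaui, Leptinotarsa decemlineata",
        "Gryllotalpa sp., Teleogryllus commodus",
        "Camponotus floridanus",
        "Dinoponera quadriceps",
        "Arachnocampa luminosa",
        "Pachypsylla venusta",
        "Diaphorina citri",
    }
)

# The Arachnocampa luminosa peptide is attributed to cross-dataset
# contamination and excluded from consensus statistics by default.
ARTEFACT_FIXTURE_SPECIES = frozenset({"Arachnocampa luminosa"})


def load_table1_fixture() -> list[PeptideFixtureRow]:
    """Load the packaged mature-peptide table.

    Returns 24 rows: 3 vertebrate reference peptides (oxytocin, vasopressin,
    vasotocin; frequency 0) and 21 distinct arthropod peptides with their
    observed precursor frequencies. ``amidated`` marks peptides whose
    precursor carries a canonical C-terminal amidation signal.
    """
    text = (
        resources.files("inotoscan.data").joinpath("table1_peptides.tsv").read_text()
    )
    rows: list[PeptideFixtureRow] = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        rows.append(
            PeptideFixtureRow(
                sequence=row["sequence"],
                amidated=row["amidated"] == "true",
                frequency=int(row["frequency"]),
                name=row["name"],
                group_or_species=row["group_or_species"],
            )
        )
    return rows


def load_order_tree_newick() -> str:
    """Newick text of the packaged arthropod order-level taxonomy tree."""
    return (
        resources.files("inotoscan.data")
        .joinpath("arthropod_orders.nwk")
        .read_text()
        .strip()
    )
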