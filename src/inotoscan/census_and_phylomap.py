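"""Peptide census, consensus statistics, and presence/absence mapping.

Aggregates annotated precursors into a deduplicated mature-peptide census,
position frequency matrices (logo data) and consensus patterns; summarises
neurophysin inter-cysteine segment lengths; tabulates per-species presence
of precursor and receptor; infers losses of the signalling system on a
user-supplied taxonomy tree under Dollo parsimony (one gain, any number of
losses); and flags likely cross-dataset contamination.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .precursor_annotation import (
    NeurophysinFramework,
    PrecursorAnnotation,
    NEUROPHYSIN_COMPLETE_CYS,
)
from .receptor_classification import ReceptorCall
from .seq_io import SpeciesMeta

__all__ = [
    "PeptideCensus",
    "PositionFrequencyMatrix",
    "ConsensusResult",
    "PresenceTable",
    "TaxonSummary",
    "DolloResult",
    "SegmentStats",
    "build_census",
    "build_pfm",
    "derive_consensus",
    "neurophysin_stats",
    "build_presence_table",
    "dollo_losses",
    "flag_contamination",
]


@dataclass(frozen=True)
class PeptideCensus:
    """Deduplicated mature-peptide counts over complete precursors."""

    counts: dict[str, int]
    species_of: dict[str, frozenset[str]]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def unique_count(self) -> int:
        return len(self.counts)

    def sorted_items(self) -> list[tuple[str, int]]:
        """Descending count, then lexicographic — the serialisation order."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def build_census(annotations: Iterable[PrecursorAnnotation]) -> PeptideCensus:
    """Count mature peptides across complete annotations.

    The census counts precursors, not species: a species with two
    precursors encoding different peptides contributes twice.
    """
    counts: Counter[str] = Counter()
    species: dict[str, set[str]] = defaultdict(set)
    for ann in annotations:
        if ann.completeness != "complete" or ann.mature is None:
            continue
        counts[ann.mature.residues] += 1
        if ann.species:
            species[ann.mature.residues].add(ann.species)
    return PeptideCensus(
        counts=dict(counts),
        species_of={k: frozenset(v) for k, v in species.items()},
    )


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position residue frequencies over equal-length peptides."""

    length: int
    frequencies: tuple[dict[str, float], ...]
    support: tuple[int, ...]

    def top_residue(self, position: int) -> tuple[str, float]:
        """Highest-frequency residue at a 0-based position (ties: lexical)."""
        col = self.frequencies[position]
        best = max(col.items(), key=lambda kv: (kv[1], kv[0]))
        # Deterministic tie-break: highest frequency, then alphabetical.
        top_f = max(col.values())
        candidates = sorted(r for r, f in col.items() if f == top_f)
        return candidates[0], top_f

    def to_json(self) -> str:
        return json.dumps(
            {
                "length": self.length,
                "support": list(self.support),
                "frequencies": [dict(sorted(c.items())) for c in self.frequencies],
            },
            indent=2,
        )


def build_pfm(peptides: Sequence[str]) -> PositionFrequencyMatrix:
    """Column-wise residue frequencies; one count per occurrence.

    All peptides must share one length; offenders are listed in the error.
    """
    if not peptides:
        raise ValueError("build_pfm requires at least one peptide")
    length = len(peptides[0])
    bad = [p for p in peptides if len(p) != length]
    if bad:
        raise ValueError(
            f"peptides of mixed length (expected {length}): {sorted(set(bad))}"
        )
    n = len(peptides)
    columns: list[dict[str, float]] = []
    for i in range(length):
        col = Counter(p[i] for p in peptides)
        columns.append({res: cnt / n for res, cnt in sorted(col.items())})
    return PositionFrequencyMatrix(
        length=length,
        frequencies=tuple(columns),
        support=tuple(n for _ in range(length)),
    )


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus pattern: invariant positions upper-case, majority
    positions lower-case, others ``X``."""

    pattern: str
    invariant_positions: frozenset[int]  # 1-based

    @property
    def strict_pattern(self) -> str:
        """Upper-case at invariant positions, ``X`` everywhere else."""
        return "".join(
            c.upper() if (i + 1) in self.invariant_positions else "X"
            for i, c in enumerate(self.pattern)
        )


def derive_consensus(pfm: PositionFrequencyMatrix,
                     majority_threshold: float = 0.5) -> ConsensusResult:
    pattern: list[str] = []
    invariant: set[int] = set()
    for i in range(pfm.length):
        residue, freq = pfm.top_residue(i)
        if freq >= 1.0 - 1e-9:
            pattern.append(residue.upper())
            invariant.add(i + 1)
        elif freq > majority_threshold:
            pattern.append(residue.lower())
        else:
            pattern.append("X")
    return ConsensusResult(
        pattern="".join(pattern), invariant_positions=frozenset(invariant)
    )


@dataclass(frozen=True)
class SegmentStats:
    """Mean/SD of one inter-cysteine segment length across frameworks."""

    segment_index: int  # 0-based, between framework cysteines i and i+1
    mean: float
    sd: float
    n: int
    flags: frozenset[str] = frozenset()


def neurophysin_stats(
    frameworks: Iterable[NeurophysinFramework],
) -> tuple[list[SegmentStats], int]:
    """Per-segment (mean, SD, n) over complete frameworks.

    Only complete frameworks (14 cysteines, hence 13 aligned segments)
    contribute; the count of incomplete frameworks is returned for
    bookkeeping. SD uses the n-1 denominator; with n = 1 it is reported
    as 0 with the ``single_observation`` flag.
    """
    frameworks = list(frameworks)
    if not frameworks:
        raise ValueError("neurophysin_stats requires at least one framework")
    complete = [f for f in frameworks if f.complete]
    n_partial = len(frameworks) - len(complete)
    if not complete:
        raise ValueError("no complete frameworks to summarise")
    n_segments = NEUROPHYSIN_COMPLETE_CYS - 1
    stats: list[SegmentStats] = []
    for k in range(n_segments):
        values = [f.segment_lengths[k] for f in complete]
        n = len(values)
        mean = sum(values) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            flags: frozenset[str] = frozenset()
        else:
            sd = 0.0
            flags = frozenset({"single_observation"})
        stats.append(SegmentStats(segment_index=k, mean=mean, sd=sd, n=n,
                                  flags=flags))
    return stats, n_partial


@dataclass(frozen=True)
class SpeciesStatus:
    precursor_status: str  # present | partial | absent
    receptor_status: str

    @property
    def any_evidence(self) -> bool:
        return self.precursor_status != "absent" or self.receptor_status != "absent"


@dataclass(frozen=True)
class PresenceTable:
    statuses: dict[str, SpeciesStatus]  # species -> status pair

    def present_species(self) -> frozenset[str]:
        return frozenset(
            s for s, st in self.statuses.items() if st.any_evidence
        )


@dataclass(frozen=True)
class TaxonSummary:
    """Per-group tally: species with the system (INT) of species sampled (T)."""

    group_label: str
    n_present: int  # INT
    n_sampled: int  # T


def build_presence_table(
    precursor_annotations: Sequence[PrecursorAnnotation],
    receptor_calls: Sequence[ReceptorCall],
    manifest: Sequence[SpeciesMeta],
) -> tuple[PresenceTable, list[TaxonSummary]]:
    """Per-species presence statuses and per-group INT/T summaries.

    A species counts towards INT when precursor or receptor evidence is
    present or partial. Species sampled in the manifest with no hits are
    ``absent``. Receptor evidence counts only for inotocin-like calls;
    CCAP-like and unclassified calls do not establish presence.
    """
    known = {m.species for m in manifest}
    unknown = sorted(
        ({a.species for a in precursor_annotations if a.species}
         | {c.species for c in receptor_calls if c.species}) - known
    )
    if unknown:
        raise ValueError(f"species missing from manifest: {unknown}")

    prec: dict[str, set[str]] = defaultdict(set)
    for ann in precursor_annotations:
        if ann.completeness == "complete":
            prec[ann.species].add("present")
        elif ann.completeness == "partial_neurophysin_only":
            prec[ann.species].add("partial")
    rec: dict[str, set[str]] = defaultdict(set)
    for call in receptor_calls:
        if call.label == "inotocin_like":
            rec[call.species].add("partial" if call.partial else "present")

    def _status(levels: set[str]) -> str:
        if "present" in levels:
            return "present"
        if "partial" in levels:
            return "partial"
        return "absent"

    statuses = {
        m.species: SpeciesStatus(
            precursor_status=_status(prec.get(m.species, set())),
            receptor_status=_status(rec.get(m.species, set())),
        )
        for m in manifest
    }
    table = PresenceTable(statuses=statuses)

    by_group: dict[str, list[str]] = defaultdict(list)
    for m in manifest:
        by_group[m.group_label].append(m.species)
    summaries = [
        TaxonSummary(
            group_label=group,
            n_present=sum(1 for s in members if statuses[s].any_evidence),
            n_sampled=len(members),
        )
        for group, members in sorted(by_group.items())
    ]
    return table, summaries


@dataclass(frozen=True)
class DolloResult:
    """Single-gain / multiple-loss reconstruction on a rooted tree.

    ``gain_clade`` is the leaf set of the most recent common ancestor of
    all present leaves; each entry of ``loss_clades`` is the leaf set of
    one maximal subtree (inside the gain clade) containing no present
    leaf — the stem edge of that subtree carries the loss.
    """

    gain_clade: frozenset[str]
    loss_clades: tuple[frozenset[str], ...]

    @property
    def n_losses(self) -> int:
        return len(self.loss_clades)


def dollo_losses(tree: dendropy.Tree | str,
                 presence: Mapping[str, bool]) -> DolloResult:
    """Minimal Dollo loss set for a presence/absence character.

    The gain is placed on the most recent common ancestor of all present
    leaves; losses are the maximal absent subtrees below it, which is the
    unique minimal loss set closest to the root. Every tree leaf must have
    a presence value.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    tree.is_rooted = True
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = sorted(set(leaves) - set(presence))
    if missing:
        raise ValueError(f"leaves without presence values: {missing}")
    present = [label for label in leaves if presence[label]]
    if not present:
        return DolloResult(gain_clade=frozenset(), loss_clades=())
    gain = tree.mrca(taxa=[leaves[p].taxon for p in present])

    def leaf_labels(node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    losses: list[frozenset[str]] = []

    def descend(node) -> None:
        for child in node.child_nodes():
            labels = leaf_labels(child)
            if not any(presence[l] for l in labels):
                losses.append(labels)  # maximal absent subtree: stop here
            else:
                descend(child)

    descend(gain)
    losses.sort(key=lambda s: sorted(s))
    return DolloResult(gain_clade=leaf_labels(gain), loss_clades=tuple(losses))


def flag_contamination(
    presence: PresenceTable,
    census: PeptideCensus,
    manifest: Sequence[SpeciesMeta],
    min_absent_peers: int = 3,
    cross_level: str = "subphylum",
) -> list[str]:
    """Species whose hits look like cross-dataset contamination.

    A species is flagged when (a) it is the only sampled member of its
    order with the system while at least ``min_absent_peers`` other
    members lack it, and (b) it shares a byte-identical mature peptide
    with a species from a different subphylum (``cross_level='order'``
    relaxes this to a different order).
    """
    if cross_level not in ("subphylum", "order"):
        raise ValueError("cross_level must be 'subphylum' or 'order'")
    meta = {m.species: m for m in manifest}
    by_order: dict[str, list[str]] = defaultdict(list)
    for m in manifest:
        by_order[m.order].append(m.species)

    flagged: list[str] = []
    for species, status in sorted(presence.statuses.items()):
        if not status.any_evidence or species not in meta:
            continue
        order_members = by_order[meta[species].order]
        others = [s for s in order_members if s != species]
        others_absent = [
            s for s in others if not presence.statuses[s].any_evidence
        ]
        lone = len(others_absent) == len(others) and len(others) >= min_absent_peers
        if not lone:
            continue
        shares_distant = False
        for peptide, carriers in census.species_of.items():
            if species not in carriers:
                continue
            for other in carriers - {species}:
                if other not in meta:
                    continue
                if cross_level == "subphylum":
                    distant = meta[other].subphylum != meta[species].subphylum
                else:
                    distant = meta[other].order != meta[species].order
                if distant:
                    shares_distant = True
                    break
            if shares_distant:
                break
        if shares_distant:
            flagged.append(species)
    return flagged


def write_census_tsv(census: PeptideCensus, path) -> None:
    with open(path, "w") as handle:
        handle.write("peptide\tcount\tspecies\n")
        for peptide, count in census.sorted_items():
            species = ",".join(sorted(census.species_of.get(peptide, ())))
            handle.write(f"{peptide}\t{count}\t{species}\n")


def write_presence_tsv(table: PresenceTable, summaries: Sequence[TaxonSummary],
                       path) -> None:
    with open(path, "w") as handle:
        handle.write("species\tprecursor_status\treceptor_status\n")
        for species in sorted(table.statuses):
            st = table.statuses[species]
            handle.write(
                f"{species}\t{st.precursor_status}\t{st.receptor_status}\n"
            )
        handle.write("\n#group\tINT\tT\n")
        for s in summaries:
            handle.write(f"#{s.group_label}\t{s.n_present}\t{s.n_sampled}\n")
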