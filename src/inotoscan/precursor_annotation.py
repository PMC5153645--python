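"""Precursor architecture parsing.

Oxytocin/vasopressin-family prohormones share one architecture: a signal
region, a mature peptide with a disulfide-bonded 6-residue ring (cysteines
at positions 1 and 6) and a short C-terminal tail, an amidation signal
(glycine amide donor followed by a dibasic convertase site such as GKR),
and a cysteine-rich neurophysin domain with 14 conserved cysteines. This
module parses candidate proteins into that architecture and classifies
each as complete, neurophysin-only partial, or rejected.

The grammar, concretely:

* ring: ``C X4 C`` anywhere in the sequence;
* tail: 3 residues (nonapeptide, canonical) or 4 (decapeptide);
* amidation signal: ``G`` immediately after the mature peptide, then a
  dibasic pair from {KR, RK, KK} (RR tolerated but flagged);
* neurophysin: a run of >= 6 cysteines downstream, consecutive cysteines
  at most 30 residues apart; complete at exactly 14.

Peptides whose terminal residue is A or S instead of G can still be
amidated (the donor glycine follows them) and are flagged
``non_canonical_terminal``. A ring with no processing signal at all is
still reported (``no_processing_site``) so unprocessed precursors remain
representable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seq_io import SequenceRecord, SpeciesMeta

__all__ = [
    "MaturePeptide",
    "NeurophysinFramework",
    "PrecursorAnnotation",
    "BatchSummary",
    "find_mature_peptides",
    "find_neurophysin",
    "annotate_precursor",
    "batch_annotate",
]

DIBASIC_PAIRS = ("KR", "RK", "KK")
UNUSUAL_DIBASIC = ("RR",)
AMIDE_DONOR = "G"
NEUROPHYSIN_MAX_GAP = 30
NEUROPHYSIN_MIN_CYS = 6
NEUROPHYSIN_COMPLETE_CYS = 14
# Maximum mature-end to framework-start distance used when no candidate
# carries an amidation signal.
NEUROPHYSIN_LINK_WINDOW = 150
# Kyte-Doolittle hydropathy, used only for the advisory weak-signal flag.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class MaturePeptide:
    """A candidate mature peptide anchored at a C-X4-C ring.

    ``start`` is the 0-based offset of the ring's first cysteine in the
    precursor; ``amidation_signal`` is the donor+dibasic triplet ("" when
    absent).
    """

    residues: str
    start: int
    amidated: bool
    amidation_signal: str = ""
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.residues) < 6 or self.residues[0] != "C" or self.residues[5] != "C":
            raise ValueError(
                f"mature peptide {self.residues!r} lacks ring cysteines at "
                "positions 1 and 6"
            )
        if self.amidated and not self.amidation_signal.startswith(AMIDE_DONOR):
            raise ValueError("amidated peptide requires a glycine amide donor")

    @property
    def end(self) -> int:
        return self.start + len(self.residues)

    @property
    def ring(self) -> str:
        return self.residues[:6]

    @property
    def tail(self) -> str:
        return self.residues[6:]

    @property
    def terminal_residue(self) -> str:
        return self.residues[-1]

    @property
    def length_class(self) -> str:
        return {9: "nonapeptide", 10: "decapeptide"}.get(
            len(self.residues), "other"
        )


@dataclass(frozen=True)
class NeurophysinFramework:
    """A cysteine framework downstream of the mature domain."""

    interval: tuple[int, int]
    cysteine_positions: tuple[int, ...]
    complete: bool

    @property
    def cysteine_count(self) -> int:
        return len(self.cysteine_positions)

    @property
    def segment_lengths(self) -> tuple[int, ...]:
        """Residue counts between consecutive framework cysteines."""
        pos = self.cysteine_positions
        return tuple(pos[i + 1] - pos[i] - 1 for i in range(len(pos) - 1))

    @property
    def found(self) -> bool:
        return bool(self.cysteine_positions)


_EMPTY_FRAMEWORK = NeurophysinFramework(interval=(0, 0), cysteine_positions=(),
                                        complete=False)


@dataclass(frozen=True)
class PrecursorAnnotation:
    record_id: str
    species: str
    completeness: str  # complete | partial_neurophysin_only | rejected
    signal_region: tuple[int, int]
    mature: MaturePeptide | None
    neurophysin: NeurophysinFramework
    flags: frozenset[str] = frozenset()


def _signal_at(seq: str, pos: int) -> tuple[str, frozenset[str]] | None:
    """Amidation signal (donor + dibasic) starting at ``pos``, if any."""
    if pos + 3 > len(seq) or seq[pos] != AMIDE_DONOR:
        return None
    pair = seq[pos + 1 : pos + 3]
    if pair in DIBASIC_PAIRS:
        return seq[pos : pos + 3], frozenset()
    if pair in UNUSUAL_DIBASIC:
        return seq[pos : pos + 3], frozenset({"unusual_dibasic"})
    return None


def find_mature_peptides(precursor: str | SequenceRecord) -> list[MaturePeptide]:
    """All C-X4-C-anchored mature-peptide candidates, in sequence order.

    For each ring the nonapeptide reading (3-residue tail) is tried first,
    then the decapeptide reading (4-residue tail); the first reading whose
    amidation signal validates wins. Rings with no valid signal are still
    reported as unamidated nonapeptide-length candidates.
    """
    seq = precursor.residues if isinstance(precursor, SequenceRecord) else str(precursor).upper()
    if not seq:
        raise ValueError("find_mature_peptides requires a non-empty sequence")
    out: list[MaturePeptide] = []
    for i in range(len(seq) - 5):
        if seq[i] != "C" or seq[i + 5] != "C":
            continue
        candidate: MaturePeptide | None = None
        for tail_len, extra_flags in ((3, frozenset()),
                                      (4, frozenset({"decapeptide"}))):
            end = i + 6 + tail_len
            if end > len(seq):
                continue
            sig = _signal_at(seq, end)
            if sig is None:
                continue
            signal, sig_flags = sig
            flags = set(extra_flags | sig_flags)
            if seq[end - 1] in ("A", "S"):
                flags.add("non_canonical_terminal")
            candidate = MaturePeptide(
                residues=seq[i:end],
                start=i,
                amidated=True,
                amidation_signal=signal,
                flags=frozenset(flags),
            )
            break
        if candidate is None:
            end = min(i + 9, len(seq))
            candidate = MaturePeptide(
                residues=seq[i:end] if end - i >= 6 else seq[i : i + 6],
                start=i,
                amidated=False,
                flags=frozenset({"no_processing_site"}),
            )
        out.append(candidate)
    return out


def find_neurophysin(precursor: str | SequenceRecord,
                     downstream_of: int = 0,
                     max_gap: int = NEUROPHYSIN_MAX_GAP,
                     min_cysteines: int = NEUROPHYSIN_MIN_CYS) -> NeurophysinFramework:
    """Locate the cysteine framework downstream of ``downstream_of``.

    Cysteine positions are chained into runs whose consecutive members are
    at most ``max_gap`` residues apart; the run with the most cysteines
    (ties: first) is the framework, if it has at least ``min_cysteines``.
    """
    seq = precursor.residues if isinstance(precursor, SequenceRecord) else str(precursor).upper()
    if downstream_of < 0 or downstream_of > len(seq):
        raise ValueError(f"downstream_of {downstream_of} out of bounds")
    positions = [i for i in range(downstream_of, len(seq)) if seq[i] == "C"]
    if not positions:
        return _EMPTY_FRAMEWORK
    runs: list[list[int]] = [[positions[0]]]
    for pos in positions[1:]:
        if pos - runs[-1][-1] - 1 <= max_gap:
            runs[-1].append(pos)
        else:
            runs.append([pos])
    best = max(runs, key=len)
    if len(best) < min_cysteines:
        return _EMPTY_FRAMEWORK
    return NeurophysinFramework(
        interval=(best[0], best[-1] + 1),
        cysteine_positions=tuple(best),
        complete=len(best) == NEUROPHYSIN_COMPLETE_CYS,
    )


def _weak_signal_like(prefix: str) -> bool:
    """True when the first 30 residues lack an 8-residue hydrophobic window."""
    window = 8
    region = prefix[:30]
    if len(region) < window:
        return True
    for i in range(len(region) - window + 1):
        mean = sum(_KD.get(c, 0.0) for c in region[i : i + window]) / window
        if mean > 1.5:
            return False
    return True


def annotate_precursor(record: SequenceRecord) -> PrecursorAnnotation:
    """Parse one candidate protein into the precursor architecture.

    Candidate selection when several rings occur: the first ring with a
    valid amidation signal wins; failing that, the first ring followed
    within :data:`NEUROPHYSIN_LINK_WINDOW` residues by a cysteine
    framework. A complete annotation requires both a mature peptide and a
    detected neurophysin framework.
    """
    if record.molecule_type != "protein":
        raise ValueError(f"annotate_precursor requires protein, got {record.molecule_type!r}")
    seq = record.residues
    candidates = find_mature_peptides(seq)
    flags: set[str] = set()

    mature: MaturePeptide | None = None
    amidated = [c for c in candidates if c.amidated]
    if amidated:
        mature = amidated[0]
    else:
        for cand in candidates:
            fw = find_neurophysin(seq, downstream_of=cand.end)
            if fw.found and fw.interval[0] - cand.end <= NEUROPHYSIN_LINK_WINDOW:
                mature = cand
                break
    if len(candidates) > 1 and mature is not None:
        flags.add("multiple_mature_candidates")

    if mature is not None:
        search_from = mature.end + len(mature.amidation_signal)
        neurophysin = find_neurophysin(seq, downstream_of=search_from)
    else:
        neurophysin = find_neurophysin(seq, downstream_of=0)

    if mature is not None and neurophysin.found:
        completeness = "complete"
        flags |= mature.flags
        signal_region = (0, mature.start)
        if _weak_signal_like(seq[: mature.start]):
            flags.add("weak_signal_like")
    elif mature is None and neurophysin.found:
        completeness = "partial_neurophysin_only"
        signal_region = (0, 0)
    else:
        completeness = "rejected"
        signal_region = (0, 0)
        if mature is not None:
            flags.add("no_neurophysin")
            mature = None

    return PrecursorAnnotation(
        record_id=record.identifier,
        species=record.species,
        completeness=completeness,
        signal_region=signal_region,
        mature=mature,
        neurophysin=neurophysin,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class BatchSummary:
    """Dataset-level counts over a batch of precursor annotations."""

    n_records: int
    n_complete: int
    n_partial: int
    n_rejected: int
    n_amidated_terminal_glycine: int
    n_dibasic_motif: int
    species_multiplicity: dict[str, int]


def batch_annotate(
    records: Sequence[SequenceRecord],
    manifest: Sequence[SpeciesMeta],
) -> tuple[list[PrecursorAnnotation], BatchSummary]:
    """Annotate a collection and tally the headline statistics.

    ``n_amidated_terminal_glycine`` counts complete precursors whose mature
    peptide ends in an amidated glycine; ``n_dibasic_motif`` counts those
    with any donor+dibasic processing signal. Every record's species must
    appear in the manifest.
    """
    known = {m.species for m in manifest}
    unknown = sorted({r.species for r in records if r.species} - known)
    if unknown:
        raise ValueError(f"species missing from manifest: {unknown}")
    annotations = [annotate_precursor(rec) for rec in records]
    complete = [a for a in annotations if a.completeness == "complete"]
    n_partial = sum(1 for a in annotations
                    if a.completeness == "partial_neurophysin_only")
    n_glycine = sum(
        1 for a in complete
        if a.mature is not None and a.mature.amidated
        and a.mature.terminal_residue == "G"
    )
    n_dibasic = sum(
        1 for a in complete
        if a.mature is not None and a.mature.amidation_signal
    )
    multiplicity = Counter(a.species for a in complete)
    summary = BatchSummary(
        n_records=len(annotations),
        n_complete=len(complete),
        n_partial=n_partial,
        n_rejected=len(annotations) - len(complete) - n_partial,
        n_amidated_terminal_glycine=n_glycine,
        n_dibasic_motif=n_dibasic,
        species_multiplicity=dict(multiplicity),
    )
    return annotations, summary
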