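"""Motif-anchor classification of candidate GPCRs.

Inotocin (oxytocin/vasopressin-like) receptors are separated from their
closest paralogues, the crustacean cardioactive peptide (CCAP) receptors,
by two diagnostic motifs:

* TM2/ECL1 (end of transmembrane helix 2 / start of extracellular loop 1):
  ``X-P-Q-X2-W-X5-6-F`` with anchors P, Q, W, F; at least 3 of the 4
  anchors must be identical. The CCAP variant is ``X2-D-X8-W``.
* TM7 (transmembrane helix 7): ``C-X-N-P-W`` with anchors C and W, at
  least 1 identical; the CCAP variant is ``A-X-N-P-[V/L/F]``.

Without structural TM assignments the motifs are localised positionally:
TM2/ECL1 is scanned over the N-terminal 60% of the sequence and TM7 over
the C-terminal 25%. Partial sequences missing the N-terminal domain are
classified on TM7 evidence alone. Anchor identity is exact residue
equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Sequence

from Bio import Align
from skbio import DistanceMatrix
from skbio.tree import nj

from .homology_search import ScoringScheme
from .seq_io import SequenceRecord

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "ReceptorCall",
    "TM2_ECL1",
    "TM7",
    "scan_motif",
    "classify_receptor",
    "pairwise_identity_tree",
]


@dataclass(frozen=True)
class MotifDefinition:
    """A positional motif with fixed anchors and variable spacers.

    ``anchors`` maps window offsets to the required residue(s) of the
    oxytocin/vasopressin-family pattern; ``ccap_anchors`` likewise for the
    CCAP variant. ``core`` residues must match for a window to be
    considered at all (shared by both families).
    """

    motif_id: str
    window_lengths: tuple[int, ...]
    anchors: dict[int, str]          # offset -> allowed residues (family)
    min_anchor_matches: int
    ccap_window_length: int
    ccap_anchors: dict[int, str]
    core: dict[int, str]
    scan_region: tuple[float, float]  # fraction of sequence length

    def anchor_offsets(self, window_length: int) -> dict[int, str]:
        """Anchor offsets with the terminal anchor pinned to the window end."""
        out = {}
        for off, allowed in self.anchors.items():
            out[off if off >= 0 else window_length + off] = allowed
        return out


TM2_ECL1 = MotifDefinition(
    motif_id="TM2_ECL1",
    window_lengths=(12, 13),          # X-P-Q-X2-W-X5-F / X6-F
    anchors={1: "P", 2: "Q", 5: "W", -1: "F"},
    min_anchor_matches=3,
    ccap_window_length=12,            # X2-D-X8-W
    ccap_anchors={2: "D", 11: "W"},
    core={},
    scan_region=(0.0, 0.6),
)

TM7 = MotifDefinition(
    motif_id="TM7",
    window_lengths=(5,),              # C-X-N-P-W
    anchors={0: "C", 4: "W"},
    min_anchor_matches=1,
    ccap_window_length=5,             # A-X-N-P-[VLF]
    ccap_anchors={0: "A", 4: "VLF"},
    core={2: "N", 3: "P"},
    scan_region=(0.75, 1.0),
)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    interval: tuple[int, int]
    matched_window: str
    anchor_matches: int
    family_vote: str  # inotocin | ccap | none


def _count_matches(window: str, offsets: dict[int, str]) -> int:
    return sum(
        1 for off, allowed in offsets.items()
        if off < len(window) and window[off] in allowed
    )


def scan_motif(seq: str | SequenceRecord, motif: MotifDefinition) -> list[MotifHit]:
    """Scan a sequence for one motif, both families, within its region.

    A window is reported when either family's criterion is satisfied
    (family anchors at ``min_anchor_matches``; all CCAP-variant anchors).
    If both are satisfied the vote is ``none``. Overlapping hits are
    pruned to the best-scoring (most anchors, then leftmost) per locus.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else str(seq).upper()
    if not s:
        raise ValueError("scan_motif requires a non-empty sequence")
    n = len(s)
    lo = int(motif.scan_region[0] * n)
    hi = int(round(motif.scan_region[1] * n))
    hits: list[MotifHit] = []
    lengths = sorted(set(motif.window_lengths) | {motif.ccap_window_length})
    for start in range(lo, hi):
        for wlen in lengths:
            end = start + wlen
            if end > hi:
                continue
            window = s[start:end]
            if any(window[off] not in allowed
                   for off, allowed in motif.core.items()):
                continue
            fam = 0
            if wlen in motif.window_lengths:
                fam = _count_matches(window, motif.anchor_offsets(wlen))
            ccap = 0
            if wlen == motif.ccap_window_length:
                ccap = _count_matches(window, motif.ccap_anchors)
            fam_ok = fam >= motif.min_anchor_matches
            ccap_ok = ccap == len(motif.ccap_anchors)
            if not fam_ok and not ccap_ok:
                continue
            if fam_ok and ccap_ok:
                vote = "none"
            elif fam_ok:
                vote = "inotocin"
            else:
                vote = "ccap"
            hits.append(
                MotifHit(
                    motif_id=motif.motif_id,
                    interval=(start, end),
                    matched_window=window,
                    anchor_matches=fam if fam_ok else ccap,
                    family_vote=vote,
                )
            )
    return _prune_overlaps(hits)


def _prune_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    hits = sorted(hits, key=lambda h: (-h.anchor_matches, h.interval))
    kept: list[MotifHit] = []
    for hit in hits:
        if all(hit.interval[1] <= k.interval[0] or hit.interval[0] >= k.interval[1]
               for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.interval)
    return kept


@dataclass(frozen=True)
class ReceptorCall:
    record_id: str
    species: str
    label: str  # inotocin_like | ccap_like | unclassified
    hits: tuple[MotifHit, ...]
    partial: bool
    flags: frozenset[str] = frozenset()


def classify_receptor(record: SequenceRecord, partial: bool = False) -> ReceptorCall:
    """Label one candidate receptor from its motif evidence.

    Full-length sequences combine both criteria with OR; conflicting
    votes (one motif inotocin, the other CCAP) yield ``unclassified``
    with the ``conflicting_evidence`` flag. Partial sequences (missing
    N-terminus) use only TM7.
    """
    hits: list[MotifHit] = []
    if not partial:
        hits.extend(scan_motif(record, TM2_ECL1))
    hits.extend(scan_motif(record, TM7))
    votes = {h.family_vote for h in hits} - {"none"}
    flags: set[str] = set()
    if votes == {"inotocin"}:
        label = "inotocin_like"
    elif votes == {"ccap"}:
        label = "ccap_like"
    elif votes == {"inotocin", "ccap"}:
        label = "unclassified"
        flags.add("conflicting_evidence")
    else:
        label = "unclassified"
    return ReceptorCall(
        record_id=record.identifier,
        species=record.species,
        label=label,
        hits=tuple(hits),
        partial=partial,
        flags=frozenset(flags),
    )


def _global_identity_distance(a: str, b: str, scheme: ScoringScheme) -> float:
    """1 - identities/columns from a global alignment with free end gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.load(
        scheme.matrix_name
    )
    aligner.open_gap_score = -(scheme.gap_open_penalty + scheme.gap_extend_penalty)
    aligner.extend_gap_score = -scheme.gap_extend_penalty
    try:
        aligner.open_end_gap_score = 0
        aligner.extend_end_gap_score = 0
    except AttributeError:  # older Biopython naming
        aligner.end_open_gap_score = 0
        aligner.end_extend_gap_score = 0
    alignment = aligner.align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return 1.0 - matches / len(sa) if sa else 1.0


def pairwise_identity_tree(records: Sequence[SequenceRecord],
                           scheme: ScoringScheme | None = None):
    """Neighbour-joining tree over pairwise global-alignment distances.

    Distances are 1 - fractional identity from global alignments with free
    end gaps under the search scoring scheme. Returns an unrooted
    ``skbio.TreeNode``; serialise with ``str(tree)`` or ``tree.write``.
    """
    if len(records) < 3:
        raise ValueError("pairwise_identity_tree requires at least 3 records")
    ids = [r.identifier for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record identifiers must be unique")
    scheme = scheme or ScoringScheme()
    n = len(records)
    dm = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = _global_identity_distance(
                records[i].residues, records[j].residues, scheme
            )
            dm[i][j] = dm[j][i] = d
    return nj(DistanceMatrix(dm, ids))


def write_calls_tsv(calls: Sequence[ReceptorCall], path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "record_id\tspecies\tlabel\tpartial\tmotifs\twindows\tflags\n"
        )
        for call in calls:
            motifs = ";".join(
                f"{h.motif_id}:{h.family_vote}:{h.anchor_matches}"
                for h in call.hits
            )
            windows = ";".join(h.matched_window for h in call.hits)
            handle.write(
                f"{call.record_id}\t{call.species}\t{call.label}\t"
                f"{str(call.partial).lower()}\t{motifs}\t{windows}\t"
                f"{','.join(sorted(call.flags))}\n"
            )
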