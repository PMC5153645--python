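"""End-to-end orchestration: search, annotate, classify, map.

Mirrors the mining workflow on real assemblies: homology search against
the dataset with reference precursor/receptor queries, precursor
annotation and receptor classification of the surviving hits, census and
presence aggregation, and Dollo loss inference on a taxonomy tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .census_and_phylomap import (
    DolloResult,
    PeptideCensus,
    PresenceTable,
    TaxonSummary,
    build_census,
    build_presence_table,
    dollo_losses,
)
from .homology_search import LocalAlignment, ScoringScheme, search_dataset
from .precursor_annotation import PrecursorAnnotation, annotate_precursor
from .receptor_classification import ReceptorCall, classify_receptor
from .seq_io import SequenceRecord, SpeciesMeta

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    precursor_hits: tuple[LocalAlignment, ...]
    receptor_hits: tuple[LocalAlignment, ...]
    annotations: tuple[PrecursorAnnotation, ...]
    calls: tuple[ReceptorCall, ...]
    census: PeptideCensus
    presence: PresenceTable
    summaries: tuple[TaxonSummary, ...]
    dollo: DolloResult | None


def run_pipeline(
    precursor_queries: Sequence[SequenceRecord],
    receptor_queries: Sequence[SequenceRecord],
    dataset: Sequence[SequenceRecord],
    manifest: Sequence[SpeciesMeta],
    tree_newick: str | None = None,
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-4,
) -> PipelineResult:
    """Run the full mining workflow over one dataset.

    Precursor and receptor candidates are the dataset sequences hit by
    the respective query sets at ``e_cutoff``; candidates are then
    annotated/classified, aggregated into census and presence tables, and
    (when a tree is given) losses are inferred for leaves named by
    species.
    """
    scheme = scheme or ScoringScheme()
    by_id = {rec.identifier: rec for rec in dataset}
    prec_hits = search_dataset(precursor_queries, dataset, scheme, e_cutoff)
    rec_hits = search_dataset(receptor_queries, dataset, scheme, e_cutoff)

    annotations = tuple(
        annotate_precursor(by_id[sid])
        for sid in dict.fromkeys(h.subject_id for h in prec_hits)
    )
    calls = tuple(
        classify_receptor(by_id[sid])
        for sid in dict.fromkeys(h.subject_id for h in rec_hits)
    )
    census = build_census(annotations)
    presence, summaries = build_presence_table(annotations, calls, manifest)
    dollo = None
    if tree_newick is not None:
        present = presence.present_species()
        leaves = {m.species: (m.species in present) for m in manifest}
        dollo = dollo_losses(tree_newick, leaves)
    return PipelineResult(
        precursor_hits=tuple(prec_hits),
        receptor_hits=tuple(rec_hits),
        annotations=annotations,
        calls=calls,
        census=census,
        presence=presence,
        summaries=summaries,
        dollo=dollo,
    )
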