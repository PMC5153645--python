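"""Labelled synthetic sequence datasets for pipeline testing.

Real inputs to the mining pipeline are public genome/transcriptome
assemblies, which are large, unversioned and unavailable offline. This
module generates datasets with the same structure and ground-truth labels:

* precursor proteins with the canonical architecture — hydrophobic signal
  region, mature peptide (drawn from the packaged peptide table by
  frequency weight), glycine+dibasic amidation signal, and a 14-cysteine
  neurophysin framework built from a packaged segment-length template;
* receptor proteins: 7-helix scaffolds carrying the TM2/ECL1 and TM7
  motifs in their inotocin-like or CCAP-like variants;
* decoys: residue-shuffled copies of real-composition sequences;

with configurable point-mutation and truncation noise. Every emitted
sequence carries a truth record (class label and domain intervals). The
same seed and configuration reproduce output byte-identically.

The generator composes sequences from disjoint residue alphabets (no
cysteines outside ring/framework positions, no dibasic pairs outside the
amidation signal, no Pro/Gln in receptor scaffolds outside the embedded
motifs) so that mutation-free output is unambiguous for the annotators;
mutation noise re-introduces ambiguity deliberately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seq_io import (
    PeptideFixtureRow,
    SequenceRecord,
    SpeciesMeta,
    load_table1_fixture,
    write_fasta,
    write_species_manifest,
)

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "SyntheticDataset",
    "NEUROPHYSIN_SEGMENT_TEMPLATE",
    "neurophysin_template",
    "generate_precursor",
    "generate_partial_precursor",
    "generate_receptor",
    "generate_decoy",
    "generate_dataset",
    "expand_table1_precursors",
    "amidation_survey_precursors",
]

# Residue alphabets, chosen so structural signals cannot arise by accident
# in mutation-free sequences (no C outside frameworks/rings, no K/R where
# a dibasic pair could form, no N-P core or P/Q/W anchors in receptor
# scaffolds outside embedded motifs).
_SIGNAL_ALPHABET = "AFILMVWPST"          # hydrophobic-biased, no C/G/K/R
_LINKER_ALPHABET = "ADEFGHILMNQSTVY"     # no C, no K/R
_TM_ALPHABET = "AFILMV"                  # hydrophobic, no N/P/Q/W/C
_LOOP_ALPHABET = "DEGHKNRSTY"            # hydrophilic, no P/Q/W/F/C
_MUTATION_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Inter-cysteine segment lengths of the packaged 14-cysteine neurophysin
# template. Chosen so that no two framework cysteines lie exactly 5 apart
# (which would mimic a mature-peptide ring); configuration, not a claim
# about real neurophysins.
NEUROPHYSIN_SEGMENT_TEMPLATE: tuple[int, ...] = (7, 6, 5, 2, 3, 5, 3, 10, 7, 5, 6, 2, 7)
_MAX_SEGMENT_JITTER = 8

# Fixed base strings shared by all members of a sequence class. Members of
# a real protein family are homologous over their whole length, not just at
# the diagnostic sites, so generated family members share this conserved
# background; per-record variation comes from segment-length draws and
# mutation noise.
_BASE_SEED = 20161213


def _base_material() -> dict[str, object]:
    global _BASE_CACHE
    try:
        return _BASE_CACHE
    except NameError:
        pass
    rng = np.random.default_rng(_BASE_SEED)
    _BASE_CACHE = {
        "signal": "M" + _draw(rng, _SIGNAL_ALPHABET, 30),
        "linker": _draw(rng, _LINKER_ALPHABET, 20),
        "lead": _draw(rng, _LINKER_ALPHABET, 15),
        "neuro_segments": tuple(
            _draw(rng, _LINKER_ALPHABET, g + _MAX_SEGMENT_JITTER)
            for g in NEUROPHYSIN_SEGMENT_TEMPLATE
        ),
        "nterm": "M" + _draw(rng, _LOOP_ALPHABET, 35),
        "tms": tuple(_draw(rng, _TM_ALPHABET, 26) for _ in range(7)),
        "loops": tuple(_draw(rng, _LOOP_ALPHABET, 20) for _ in range(6)),
        "cterm": _draw(rng, _LOOP_ALPHABET, 22),
    }
    return _BASE_CACHE

# Motif instances embedded into receptor scaffolds.
_TM2_INOTOCIN = "LPQLKWSLGATF"   # X-P-Q-X2-W-X5-F
_TM2_CCAP = "ILDAGTSLQRMW"       # X2-D-X8-W
_TM7_INOTOCIN = "CFNPW"          # C-X-N-P-W
_TM7_CCAP = "AFNPV"              # A-X-NP-[VLF]

_AMIDATION_SIGNALS = ("GKR", "GRK", "GKK")


def _default_peptide_pool() -> tuple[tuple[str, int], ...]:
    return tuple(
        (row.sequence, row.frequency)
        for row in load_table1_fixture()
        if row.is_arthropod
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable parameters of the synthetic-data generator.

    ``peptide_pool`` defaults to the packaged arthropod peptide table with
    observed frequencies as sampling weights. ``amidation_signal_weights``
    follow the observed skew (GKR most common, GRK/GKK rare).
    """

    seed: int = 0
    n_species: int = 20
    peptide_pool: tuple[tuple[str, int], ...] = field(
        default_factory=_default_peptide_pool
    )
    mutation_rate: float = 0.0
    truncation_prob: float = 0.0
    decoy_count: int = 50
    receptor_family_mix: tuple[tuple[str, float], ...] = (
        ("inotocin", 0.8),
        ("ccap", 0.2),
    )
    amidation_signal_weights: tuple[tuple[str, float], ...] = (
        ("GKR", 0.8),
        ("GRK", 0.1),
        ("GKK", 0.1),
    )
    segment_jitter: int = 2
    absent_orders: tuple[str, ...] = ("Lepidoptera", "Diptera")

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate < 0.5):
            raise ValueError("mutation_rate must be in [0, 0.5)")
        if not self.peptide_pool:
            raise ValueError("peptide_pool must be non-empty")
        for name, weights in (
            ("receptor_family_mix", self.receptor_family_mix),
            ("amidation_signal_weights", self.amidation_signal_weights),
        ):
            total = sum(w for _, w in weights)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1, got {total}")
        for sig, _ in self.amidation_signal_weights:
            if sig not in _AMIDATION_SIGNALS:
                raise ValueError(f"unknown amidation signal {sig!r}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated sequence."""

    record_id: str
    class_label: str  # precursor | partial_precursor | receptor_inotocin | receptor_ccap | decoy
    species: str = ""
    order: str = ""
    subphylum: str = ""
    peptide: str = ""
    amidated: bool = False
    signal_interval: tuple[int, int] | None = None
    mature_interval: tuple[int, int] | None = None
    amidation_interval: tuple[int, int] | None = None
    neurophysin_interval: tuple[int, int] | None = None
    tm2_interval: tuple[int, int] | None = None
    tm7_interval: tuple[int, int] | None = None


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=int(n)))


def _weighted_choice(rng: np.random.Generator,
                     items: Sequence[tuple[str, float]]) -> str:
    keys = [k for k, _ in items]
    weights = np.array([w for _, w in items], dtype=float)
    return keys[int(rng.choice(len(keys), p=weights / weights.sum()))]


def _jittered_segments(rng: np.random.Generator, jitter: int) -> tuple[int, ...]:
    """Template segment lengths with bounded jitter.

    Rejection-samples until no two framework cysteines are exactly 5
    residues apart, which would create a spurious mature-peptide ring.
    """
    base = np.array(NEUROPHYSIN_SEGMENT_TEMPLATE)
    while True:
        if jitter > 0:
            offsets = rng.integers(-jitter, jitter + 1, size=len(base))
            segs = np.maximum(base + offsets, 0)
        else:
            segs = base.copy()
        positions = [0]
        for g in segs:
            positions.append(positions[-1] + int(g) + 1)
        diffs = {b - a for i, a in enumerate(positions)
                 for b in positions[i + 1 :]}
        if 5 not in diffs:
            return tuple(int(g) for g in segs)
        if jitter == 0:  # template itself is safe by construction
            return tuple(int(g) for g in segs)


def neurophysin_template(rng: np.random.Generator | None = None,
                         jitter: int = 0) -> str:
    """A 14-cysteine neurophysin domain from the packaged template.

    Inter-cysteine fillers come from the fixed base material (conserved
    across generated precursors); ``jitter`` varies segment lengths.
    """
    rng = rng or np.random.default_rng(0)
    segments = _jittered_segments(rng, min(jitter, _MAX_SEGMENT_JITTER))
    fillers = _base_material()["neuro_segments"]
    parts = ["C"]
    for filler, g in zip(fillers, segments):
        parts.append(filler[:g])
        parts.append("C")
    return "".join(parts)


def _mutate(seq: str, protected: set[int], mu: float,
            rng: np.random.Generator) -> str:
    if mu <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < mu:
            choices = [c for c in _MUTATION_ALPHABET if c != out[i]]
            out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def generate_precursor(
    config: GeneratorConfig,
    rng: np.random.Generator,
    record_id: str = "syn_precursor",
    meta: SpeciesMeta | None = None,
    peptide: str | None = None,
    amidated: bool | None = None,
) -> tuple[SequenceRecord, TruthRecord]:
    """One complete precursor: signal + mature + amidation + neurophysin.

    ``peptide``/``amidated`` override the weighted draw from the pool
    (an unamidated peptide gets a short non-dibasic linker instead of the
    processing signal). Point mutations at ``config.mutation_rate`` spare
    the ring cysteines, the framework cysteines and the amidation signal
    so the truth labels stay valid.
    """
    if peptide is None:
        sequences = [p for p, _ in config.peptide_pool]
        weights = np.array([max(w, 1e-9) for _, w in config.peptide_pool])
        idx = int(rng.choice(len(sequences), p=weights / weights.sum()))
        peptide = sequences[idx]
        if amidated is None:
            amidated = peptide != "CFILDCPLM"  # the one known unprocessed form
    if amidated is None:
        amidated = True

    base = _base_material()
    signal = base["signal"][: int(rng.integers(19, 26))]
    sig_end = len(signal)
    mature_start = sig_end
    mature_end = mature_start + len(peptide)
    if amidated:
        amid = _weighted_choice(rng, config.amidation_signal_weights)
    else:
        amid = "I" + base["linker"][:2]  # unprocessed: no donor glycine
    amid_end = mature_end + len(amid)
    linker = base["linker"][: int(rng.integers(5, 16))]
    neuro = neurophysin_template(rng, jitter=config.segment_jitter)
    neuro_start = amid_end + len(linker)
    seq = signal + peptide + amid + linker + neuro

    protected = {mature_start, mature_start + 5}
    protected |= {i for i in range(neuro_start, len(seq)) if seq[i] == "C"}
    if amidated:
        protected |= set(range(mature_end, amid_end))
    seq = _mutate(seq, protected, config.mutation_rate, rng)

    record = SequenceRecord(
        identifier=record_id,
        residues=seq,
        molecule_type="protein",
        species=meta.species if meta else "",
        source_dataset="synthetic",
    )
    truth = TruthRecord(
        record_id=record_id,
        class_label="precursor",
        species=meta.species if meta else "",
        order=meta.order if meta else "",
        subphylum=meta.subphylum if meta else "",
        peptide=peptide,
        amidated=amidated,
        signal_interval=(0, sig_end),
        mature_interval=(mature_start, mature_end),
        amidation_interval=(mature_end, amid_end) if amidated else None,
        neurophysin_interval=(neuro_start, len(seq)),
    )
    return record, truth


def generate_partial_precursor(
    config: GeneratorConfig,
    rng: np.random.Generator,
    record_id: str = "syn_partial",
    meta: SpeciesMeta | None = None,
) -> tuple[SequenceRecord, TruthRecord]:
    """A neurophysin-only fragment (truncated transcript artefact)."""
    lead = _base_material()["lead"][: int(rng.integers(4, 12))]
    neuro = neurophysin_template(rng, jitter=config.segment_jitter)
    seq = lead + neuro
    protected = {i for i in range(len(seq)) if seq[i] == "C"}
    seq = _mutate(seq, protected, config.mutation_rate, rng)
    record = SequenceRecord(
        identifier=record_id,
        residues=seq,
        molecule_type="protein",
        species=meta.species if meta else "",
        source_dataset="synthetic",
    )
    truth = TruthRecord(
        record_id=record_id,
        class_label="partial_precursor",
        species=meta.species if meta else "",
        order=meta.order if meta else "",
        subphylum=meta.subphylum if meta else "",
        neurophysin_interval=(len(lead), len(seq)),
    )
    return record, truth


def generate_receptor(
    config: GeneratorConfig,
    family: str,
    rng: np.random.Generator,
    record_id: str = "syn_receptor",
    meta: SpeciesMeta | None = None,
    anchor_sparing: bool = True,
) -> tuple[SequenceRecord, TruthRecord]:
    """A 7-TM receptor scaffold with the family's diagnostic motifs.

    The TM2/ECL1 motif variant lands in the N-terminal 60% of the
    sequence and the TM7 variant in the C-terminal 25%. With
    ``anchor_sparing`` (default) mutations never touch motif positions,
    so truth labels stay valid at any mutation rate; switching it off is
    for robustness tests only. ``family='decoy'`` emits the scaffold with
    no diagnostic motifs at all (a paralogous GPCR outside both
    families).
    """
    if family not in ("inotocin", "ccap", "decoy"):
        raise ValueError(f"unknown receptor family {family!r}")
    tm2 = {"inotocin": _TM2_INOTOCIN, "ccap": _TM2_CCAP}.get(family)
    tm7 = {"inotocin": _TM7_INOTOCIN, "ccap": _TM7_CCAP}.get(family)

    base = _base_material()
    parts: list[str] = []
    tm2_interval = tm7_interval = (0, 0)
    parts.append(base["nterm"][: int(rng.integers(21, 33))])
    for helix in range(1, 8):
        tm_len = int(rng.integers(19, 24))
        tm = base["tms"][helix - 1][:tm_len]
        if helix == 7 and tm7 is not None:
            # Motif sits inside TM7, close to its cytoplasmic end.
            insert_at = tm_len - len(tm7) - 2
            start = sum(len(p) for p in parts) + insert_at
            tm = tm[:insert_at] + tm7 + tm[insert_at + len(tm7):]
            tm7_interval = (start, start + len(tm7))
        parts.append(tm)
        if helix < 7:
            loop = base["loops"][helix - 1][: int(rng.integers(8, 18))]
            if helix == 2 and tm2 is not None:
                # Motif spans the TM2/ECL1 boundary: put it at loop start.
                start = sum(len(p) for p in parts)
                loop = tm2 + loop
                tm2_interval = (start, start + len(tm2))
            parts.append(loop)
    parts.append(base["cterm"][: int(rng.integers(10, 20))])
    seq = "".join(parts)

    protected: set[int] = set()
    if anchor_sparing:
        protected |= set(range(*tm2_interval)) | set(range(*tm7_interval))
    seq = _mutate(seq, protected, config.mutation_rate, rng)

    record = SequenceRecord(
        identifier=record_id,
        residues=seq,
        molecule_type="protein",
        species=meta.species if meta else "",
        source_dataset="synthetic",
    )
    truth = TruthRecord(
        record_id=record_id,
        class_label=f"receptor_{family}",
        species=meta.species if meta else "",
        order=meta.order if meta else "",
        subphylum=meta.subphylum if meta else "",
        tm2_interval=tm2_interval,
        tm7_interval=tm7_interval,
    )
    return record, truth


def generate_decoy(
    rng: np.random.Generator,
    template: SequenceRecord,
    record_id: str = "syn_decoy",
    meta: SpeciesMeta | None = None,
) -> tuple[SequenceRecord, TruthRecord]:
    """A residue-shuffled copy of a real-composition sequence."""
    residues = list(template.residues)
    rng.shuffle(residues)
    record = SequenceRecord(
        identifier=record_id,
        residues="".join(residues),
        molecule_type="protein",
        species=meta.species if meta else "",
        source_dataset="synthetic",
    )
    truth = TruthRecord(
        record_id=record_id,
        class_label="decoy",
        species=meta.species if meta else "",
        order=meta.order if meta else "",
        subphylum=meta.subphylum if meta else "",
    )
    return record, truth


# Toy taxonomy used by generate_dataset: (order, subphylum) in a fixed
# ladder; the two default absent orders are sister taxa so a single Dollo
# loss explains them.
_TOY_TAXA: tuple[tuple[str, str], ...] = (
    ("Araneae", "Chelicerata"),
    ("Scolopendromorpha", "Myriapoda"),
    ("Calanoida", "Crustacea"),
    ("Orthoptera", "Hexapoda"),
    ("Hemiptera", "Hexapoda"),
    ("Hymenoptera", "Hexapoda"),
    ("Coleoptera", "Hexapoda"),
    ("Lepidoptera", "Hexapoda"),
    ("Diptera", "Hexapoda"),
)


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete runnable input set with ground truth."""

    records: tuple[SequenceRecord, ...]
    truths: tuple[TruthRecord, ...]
    manifest: tuple[SpeciesMeta, ...]
    tree_newick: str
    config: GeneratorConfig

    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.record_id: t for t in self.truths}


def _toy_tree(manifest: Sequence[SpeciesMeta]) -> str:
    """Ladder tree over orders, species combs within each order."""
    by_order: dict[str, list[str]] = {}
    for m in manifest:
        by_order.setdefault(m.order, []).append(m.species)

    def comb(tips: list[str]) -> str:
        if len(tips) == 1:
            return tips[0]
        return f"({tips[0]},{comb(tips[1:])})"

    orders = [comb(by_order[o]) for o, _ in _TOY_TAXA if o in by_order]
    # Keep Lepidoptera+Diptera as sisters at the ladder tip.
    tree = orders[-1]
    for clade in reversed(orders[:-1]):
        tree = f"({clade},{tree})"
    return tree + ";"


def generate_dataset(config: GeneratorConfig,
                     out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate a full labelled dataset (optionally written to disk).

    Species are assigned round-robin to the toy taxonomy. Species in
    ``config.absent_orders`` receive no signalling-system sequences —
    ground-truth absences for loss inference. Each remaining species gets
    one precursor and one receptor (family drawn from the mix), plus
    ``decoy_count`` shuffled decoys spread across all species. Writing to
    ``out_dir`` emits sequences.faa, manifest.tsv, truth.tsv, tree.nwk
    and config.json.
    """
    rng = np.random.default_rng(config.seed)
    manifest = tuple(
        SpeciesMeta(
            species=f"Species_{i + 1:03d}",
            order=_TOY_TAXA[i % len(_TOY_TAXA)][0],
            subphylum=_TOY_TAXA[i % len(_TOY_TAXA)][1],
            source_dataset="synthetic",
        )
        for i in range(config.n_species)
    )
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    for meta in manifest:
        if meta.order in config.absent_orders:
            continue
        rec, truth = generate_precursor(
            config, rng, record_id=f"{meta.species}|precursor", meta=meta
        )
        if config.truncation_prob > 0 and rng.random() < config.truncation_prob:
            cut = int(len(rec.residues) * 0.6)
            rec = SequenceRecord(
                identifier=rec.identifier,
                residues=rec.residues[:cut],
                molecule_type="protein",
                species=rec.species,
                source_dataset=rec.source_dataset,
            )
        records.append(rec)
        truths.append(truth)
        family = _weighted_choice(rng, config.receptor_family_mix)
        rec, truth = generate_receptor(
            config, family, rng, record_id=f"{meta.species}|receptor", meta=meta
        )
        records.append(rec)
        truths.append(truth)
    templates = [r for r in records] or [
        generate_precursor(config, rng, record_id="template")[0]
    ]
    for k in range(config.decoy_count):
        meta = manifest[k % len(manifest)] if manifest else None
        template = templates[int(rng.integers(0, len(templates)))]
        rec, truth = generate_decoy(
            rng, template, record_id=f"decoy_{k + 1:03d}", meta=meta
        )
        records.append(rec)
        truths.append(truth)

    dataset = SyntheticDataset(
        records=tuple(records),
        truths=tuple(truths),
        manifest=manifest,
        tree_newick=_toy_tree(manifest),
        config=config,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(dataset.records, out / "sequences.faa")
        write_species_manifest(dataset.manifest, out / "manifest.tsv")
        (out / "tree.nwk").write_text(dataset.tree_newick + "\n")
        with open(out / "truth.tsv", "w") as handle:
            handle.write("record_id\tclass_label\tspecies\tpeptide\tamidated\n")
            for t in dataset.truths:
                handle.write(
                    f"{t.record_id}\t{t.class_label}\t{t.species}\t"
                    f"{t.peptide}\t{str(t.amidated).lower()}\n"
                )
        cfg = asdict(config)
        cfg["peptide_pool"] = [list(x) for x in config.peptide_pool]
        (out / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    return dataset


def expand_table1_precursors(seed: int = 0) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Synthetic precursors expanding the packaged peptide table by frequency.

    Each arthropod row contributes ``frequency`` complete precursors
    embedding its peptide (amidated per the table flag); running the
    annotator and census over them reproduces the table's counts.
    """
    rng = np.random.default_rng(seed)
    config = GeneratorConfig(seed=seed)
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    k = 0
    for row in load_table1_fixture():
        if not row.is_arthropod:
            continue
        for _ in range(row.frequency):
            k += 1
            rec, truth = generate_precursor(
                config,
                rng,
                record_id=f"table1_{k:03d}",
                peptide=row.sequence,
                amidated=row.amidated,
            )
            records.append(rec)
            truths.append(truth)
    return records, truths


def amidation_survey_precursors(
    seed: int = 0, meta: SpeciesMeta | None = None
) -> list[SequenceRecord]:
    """A 110-precursor set mirroring the reported amidation proportions.

    103 precursors whose mature peptide ends in an amidated glycine, 6
    amidated peptides with a terminal alanine/serine, and one precursor
    with no processing signal at all.
    """
    rng = np.random.default_rng(seed)
    config = GeneratorConfig(seed=seed)
    g_pool = [(p, w) for p, w in config.peptide_pool
              if p.endswith("G") and w > 0]
    records: list[SequenceRecord] = []
    k = 0

    def emit(peptide: str, amidated: bool) -> None:
        nonlocal k
        k += 1
        rec, _ = generate_precursor(
            config, rng, record_id=f"survey_{k:03d}", peptide=peptide,
            amidated=amidated, meta=meta,
        )
        records.append(rec)

    weights = np.array([w for _, w in g_pool], dtype=float)
    for _ in range(103):
        idx = int(rng.choice(len(g_pool), p=weights / weights.sum()))
        emit(g_pool[idx][0], True)
    for peptide in ("CFITNCPRA", "CFITNCPPA", "CFISNCPVS", "CFISNCPVS",
                    "CFITNCPVGS", "CFITNCPVGS"):
        emit(peptide, True)
    emit("CFILDCPLM", False)
    return records
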