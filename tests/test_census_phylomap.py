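import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inotoscan.census_and_phylomap import (
    build_census,
    build_pfm,
    build_presence_table,
    derive_consensus,
    dollo_losses,
    flag_contamination,
    neurophysin_stats,
)
from inotoscan.precursor_annotation import annotate_precursor, find_neurophysin
from inotoscan.receptor_classification import classify_receptor
from inotoscan.seq_io import (
    ARTEFACT_FIXTURE_SPECIES,
    INSECT_FIXTURE_GROUPS,
    SequenceRecord,
    SpeciesMeta,
    load_order_tree_newick,
    load_table1_fixture,
)
from inotoscan.synthetic_data import (
    GeneratorConfig,
    expand_table1_precursors,
    generate_precursor,
    generate_receptor,
    neurophysin_template,
)


def _annotation(peptide, species="Sp", amidated=True, seed=0):
    config = GeneratorConfig(seed=seed)
    rng = np.random.default_rng(seed)
    meta = SpeciesMeta(species, "Coleoptera", "Hexapoda")
    rec, _ = generate_precursor(config, rng, record_id=f"{species}|{peptide}",
                                meta=meta, peptide=peptide, amidated=amidated)
    return annotate_precursor(rec)


class TestBuildCensus:
    def test_direct_counting(self):
        anns = [_annotation("CLITNCPRG", f"S{i}") for i in range(2)]
        anns.append(_annotation("CLITNCPKG", "S3"))
        census = build_census(anns)
        assert census.counts == {"CLITNCPRG": 2, "CLITNCPKG": 1}
        assert census.total == 3
        assert census.unique_count == 2

    def test_empty_input(self):
        census = build_census([])
        assert census.total == 0
        assert census.unique_count == 0

    def test_expanded_fixture_reproduces_reference_counts(self):
        records, _ = expand_table1_precursors(seed=0)
        census = build_census(annotate_precursor(r) for r in records)
        expected = {
            r.sequence: r.frequency
            for r in load_table1_fixture() if r.is_arthropod
        }
        assert census.counts == expected
        assert census.total == 121
        assert census.unique_count == 21

    def test_total_equals_contributing_annotations(self):
        anns = [_annotation("CLITNCPRG", f"S{i}") for i in range(5)]
        census = build_census(anns)
        assert census.total == sum(
            1 for a in anns if a.completeness == "complete"
        )

    def test_serialisation_order(self):
        anns = ([_annotation("CLITNCPKG", f"a{i}") for i in range(2)]
                + [_annotation("CLITNCPRG", f"b{i}") for i in range(2)]
                + [_annotation("CFITNCPPG", "c")])
        census = build_census(anns)
        items = census.sorted_items()
        assert items == [("CLITNCPKG", 2), ("CLITNCPRG", 2),
                         ("CFITNCPPG", 1)]


class TestBuildPfm:
    def test_single_peptide_one_hot(self):
        pfm = build_pfm(["CLITNCPRG"])
        assert pfm.length == 9
        assert pfm.frequencies[0] == {"C": 1.0}
        assert pfm.frequencies[7] == {"R": 1.0}

    def test_split_column(self):
        pfm = build_pfm(["CLITNCPRG", "CLITNCPKG"])
        assert pfm.frequencies[7] == {"K": 0.5, "R": 0.5}

    def test_length_mismatch_lists_offenders(self):
        with pytest.raises(ValueError, match="CYIINCIDND"):
            build_pfm(["CLITNCPRG", "CYIINCIDND"])

    def test_ring_cysteines_invariant_over_fixture_nonapeptides(self):
        peptides = [
            r.sequence
            for r in load_table1_fixture()
            if r.is_arthropod and len(r.sequence) == 9
            for _ in range(r.frequency)
        ]
        pfm = build_pfm(peptides)
        assert pfm.frequencies[0]["C"] == pytest.approx(1.0)
        assert pfm.frequencies[5]["C"] == pytest.approx(1.0)

    @given(st.lists(st.text("ACDEFG", min_size=6, max_size=6),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_columns_sum_to_one(self, peptides):
        pfm = build_pfm(peptides)
        for col in pfm.frequencies:
            assert sum(col.values()) == pytest.approx(1.0, abs=1e-9)


class TestDeriveConsensus:
    def test_single_sequence_all_invariant(self):
        result = derive_consensus(build_pfm(["CLITNCPRG"]))
        assert result.pattern == "CLITNCPRG"
        assert result.invariant_positions == frozenset(range(1, 10))

    def test_no_majority_gives_x(self):
        peptides = ["AC", "CD", "DE", "EA"]
        result = derive_consensus(build_pfm(peptides))
        assert result.pattern == "XX"

    def test_insect_ring_consensus(self):
        rows = [
            r for r in load_table1_fixture()
            if r.group_or_species in INSECT_FIXTURE_GROUPS
            and r.group_or_species not in ARTEFACT_FIXTURE_SPECIES
            and len(r.sequence) == 9
        ]
        rings = [r.sequence[:6] for r in rows for _ in range(r.frequency)]
        result = derive_consensus(build_pfm(rings))
        assert result.strict_pattern == "CXIXNC"
        assert result.invariant_positions == frozenset({1, 3, 5, 6})


class TestNeurophysinStats:
    def test_identical_frameworks_zero_sd(self):
        fw = find_neurophysin(neurophysin_template())
        stats, n_partial = neurophysin_stats([fw, fw, fw])
        assert len(stats) == 13
        assert n_partial == 0
        assert all(s.sd == 0 and s.n == 3 for s in stats)
        assert [s.mean for s in stats] == list(fw.segment_lengths)

    def test_single_framework_flagged(self):
        fw = find_neurophysin(neurophysin_template())
        stats, _ = neurophysin_stats([fw])
        assert all("single_observation" in s.flags for s in stats)

    def test_jittered_means_recovered(self):
        # Segment lengths jittered uniformly +-2 around the template; the
        # sample mean of each segment must fall within 3 standard errors.
        rng = np.random.default_rng(1)
        frameworks = []
        while len(frameworks) < 80:
            fw = find_neurophysin(neurophysin_template(rng, jitter=2))
            if fw.complete:
                frameworks.append(fw)
        stats, _ = neurophysin_stats(frameworks)
        from inotoscan.synthetic_data import NEUROPHYSIN_SEGMENT_TEMPLATE
        for s, template in zip(stats, NEUROPHYSIN_SEGMENT_TEMPLATE):
            se = s.sd / np.sqrt(s.n) if s.sd else 0.5
            assert abs(s.mean - template) <= 3 * se + 0.5

    def test_partial_frameworks_counted_not_averaged(self):
        complete = find_neurophysin(neurophysin_template())
        partial = find_neurophysin(neurophysin_template()[:40])
        stats, n_partial = neurophysin_stats([complete, partial])
        assert n_partial == 1
        assert all(s.n == 1 for s in stats)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            neurophysin_stats([])


def _toy_manifest():
    return [
        SpeciesMeta("Sp1", "Coleoptera", "Hexapoda"),
        SpeciesMeta("Sp2", "Coleoptera", "Hexapoda"),
        SpeciesMeta("Sp3", "Coleoptera", "Hexapoda"),
        SpeciesMeta("Sp4", "Coleoptera", "Hexapoda"),
    ]


class TestPresenceTable:
    def test_int_over_t(self):
        manifest = _toy_manifest()
        anns = [_annotation("CLITNCPRG", "Sp1")]
        config = GeneratorConfig(seed=0)
        rng = np.random.default_rng(0)
        rec, _ = generate_receptor(config, "inotocin", rng, record_id="r",
                                   meta=manifest[1])
        calls = [classify_receptor(rec)]
        table, summaries = build_presence_table(anns, calls, manifest)
        assert table.statuses["Sp1"].precursor_status == "present"
        assert table.statuses["Sp2"].receptor_status == "present"
        assert table.statuses["Sp3"].precursor_status == "absent"
        [summary] = summaries
        assert (summary.n_present, summary.n_sampled) == (2, 4)

    def test_partial_precursor_counts_toward_int(self):
        from inotoscan.synthetic_data import generate_partial_precursor

        manifest = _toy_manifest()
        config = GeneratorConfig(seed=0)
        rng = np.random.default_rng(0)
        rec, _ = generate_partial_precursor(config, rng, record_id="f",
                                            meta=manifest[0])
        table, summaries = build_presence_table(
            [annotate_precursor(rec)], [], manifest
        )
        assert table.statuses["Sp1"].precursor_status == "partial"
        assert summaries[0].n_present == 1

    def test_empty_hits_give_zero_int(self):
        table, summaries = build_presence_table([], [], _toy_manifest())
        assert summaries[0].n_present == 0
        assert all(not s.any_evidence for s in table.statuses.values())

    def test_ccap_calls_do_not_establish_presence(self):
        manifest = _toy_manifest()
        config = GeneratorConfig(seed=0)
        rng = np.random.default_rng(0)
        rec, _ = generate_receptor(config, "ccap", rng, record_id="r",
                                   meta=manifest[0])
        table, summaries = build_presence_table(
            [], [classify_receptor(rec)], manifest
        )
        assert summaries[0].n_present == 0

    def test_unknown_species_rejected(self):
        ann = _annotation("CLITNCPRG", "Elsewhere sp.")
        with pytest.raises(ValueError):
            build_presence_table([ann], [], _toy_manifest())

    def test_int_monotone_in_hits(self):
        manifest = _toy_manifest()
        anns = []
        previous = 0
        for i, sp in enumerate(["Sp1", "Sp2", "Sp3"]):
            anns.append(_annotation("CLITNCPRG", sp))
            _, summaries = build_presence_table(anns, [], manifest)
            assert summaries[0].n_present >= previous
            previous = summaries[0].n_present


def brute_force_min_losses(tree: dendropy.Tree, presence: dict) -> int:
    """Exhaustive minimisation over loss-edge subsets under a single gain."""
    tree = dendropy.Tree(tree)
    tree.is_rooted = True
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    present = [l for l in leaves if presence[l]]
    if not present:
        return 0
    gain = tree.mrca(taxa=[leaves[p].taxon for p in present])
    nodes = [n for n in gain.preorder_iter() if n is not gain]
    for k in range(len(nodes) + 1):
        for combo in itertools.combinations(nodes, k):
            lost = set()
            for node in combo:
                lost |= {l.taxon.label for l in node.leaf_iter()}
            inside = {l.taxon.label for l in gain.leaf_iter()}
            ok = all(
                (presence[l] and l not in lost)
                or (not presence[l] and (l in lost or l not in inside))
                for l in leaves
            )
            if ok:
                return k
    raise AssertionError("unreachable")


class TestDolloLosses:
    def test_all_present_no_losses(self):
        result = dollo_losses("((A,B),(C,D));",
                              {x: True for x in "ABCD"})
        assert result.n_losses == 0
        assert result.gain_clade == frozenset("ABCD")

    def test_no_present_leaves(self):
        result = dollo_losses("((A,B),(C,D));",
                              {x: False for x in "ABCD"})
        assert result.n_losses == 0
        assert result.gain_clade == frozenset()

    def test_single_loss_on_stem_of_absent_clade(self):
        absent = {"Trichoptera", "Lepidoptera", "Siphonaptera",
                  "Mecoptera", "Diptera"}
        newick = load_order_tree_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        presence = {l.taxon.label: l.taxon.label not in absent
                    for l in tree.leaf_node_iter()}
        result = dollo_losses(newick, presence)
        assert result.n_losses == 1
        assert result.loss_clades[0] == frozenset(absent)

    def test_missing_leaf_value_rejected(self):
        with pytest.raises(ValueError, match="C"):
            dollo_losses("((A,B),C);", {"A": True, "B": False})

    @pytest.mark.parametrize(
        "newick",
        [
            "(((((((A,B),C),D),E),F),G),H);",      # caterpillar
            "(((A,B),(C,D)),((E,F),(G,H)));",      # balanced
            "((A,(B,(C,D))),(E,(F,(G,H))));",      # mixed
        ],
    )
    def test_minimality_vs_brute_force(self, newick):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels = "ABCDEFGH"
        for bits in range(256):
            presence = {l: bool(bits >> i & 1) for i, l in enumerate(labels)}
            got = dollo_losses(newick, presence).n_losses
            expected = brute_force_min_losses(tree, presence)
            assert got == expected, (newick, presence)


class TestFlagContamination:
    def _setup(self, shared_peptide=True):
        manifest = (
            [SpeciesMeta(f"Fly{i}", "Diptera", "Hexapoda") for i in range(4)]
            + [SpeciesMeta("Copepod1", "Calanoida", "Crustacea")]
        )
        anns = [_annotation("CYITNCPWG", "Fly0")]
        other = "CYITNCPWG" if shared_peptide else "CFISNCPVS"
        anns.append(_annotation(other, "Copepod1"))
        census = build_census(anns)
        table, _ = build_presence_table(anns, [], manifest)
        return table, census, manifest

    def test_lone_species_with_shared_distant_peptide_flagged(self):
        table, census, manifest = self._setup(shared_peptide=True)
        assert flag_contamination(table, census, manifest) == ["Fly0"]

    def test_unique_peptide_not_flagged(self):
        table, census, manifest = self._setup(shared_peptide=False)
        assert flag_contamination(table, census, manifest) == []

    def test_all_present_order_not_flagged(self):
        manifest = [SpeciesMeta(f"B{i}", "Coleoptera", "Hexapoda")
                    for i in range(4)]
        anns = [_annotation("CLITNCPRG", f"B{i}") for i in range(4)]
        census = build_census(anns)
        table, _ = build_presence_table(anns, [], manifest)
        assert flag_contamination(table, census, manifest) == []
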