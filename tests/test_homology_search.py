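import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inotoscan.homology_search import (
    LocalAlignment,
    ScoringScheme,
    _score_only,
    evalue,
    search_dataset,
    smith_waterman,
)
from inotoscan.seq_io import SequenceRecord
from inotoscan.synthetic_data import (
    GeneratorConfig,
    generate_decoy,
    generate_precursor,
)

from conftest import reverse_complement

AA = "ACDEFGHIKLMNPQRSTVWY"


def cubic_local_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Gap-length-enumeration local alignment: O(n^3) oracle.

    Independent formulation (explicit gap lengths instead of affine state
    matrices) against which the production recursion is checked.
    """
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            v = max(0, H[i - 1][j - 1] + scheme.pair_score(a[i - 1], b[j - 1]))
            for g in range(1, i + 1):
                v = max(v, H[i - g][j]
                        - scheme.gap_open_penalty - scheme.gap_extend_penalty * g)
            for g in range(1, j + 1):
                v = max(v, H[i][j - g]
                        - scheme.gap_open_penalty - scheme.gap_extend_penalty * g)
            H[i][j] = v
            best = max(best, v)
    return best


def rescore_alignment(aln: LocalAlignment, scheme: ScoringScheme) -> int:
    """Recompute the raw score from the gapped strings."""
    score, in_gap = 0, False
    for x, y in zip(aln.aligned_query, aln.aligned_subject):
        if x == "-" or y == "-":
            score -= scheme.gap_extend_penalty
            if not in_gap:
                score -= scheme.gap_open_penalty
            in_gap = True
        else:
            score += scheme.pair_score(x, y)
            in_gap = False
    return score


class TestSmithWaterman:
    def test_inotocin_self_alignment_score(self, scheme):
        # BLOSUM62 diagonal: C9+L4+I4+T5+N6+C9+P7+R5+G6 = 55
        aln = smith_waterman("CLITNCPRG", "CLITNCPRG", scheme)
        assert aln.raw_score == 55
        assert aln.aligned_query == "CLITNCPRG"
        assert aln.query_interval == (0, 9)

    def test_no_positive_pair_gives_empty_alignment(self, scheme):
        aln = smith_waterman("AAAA", "CCCC", scheme)
        assert aln.raw_score == 0
        assert aln.is_empty

    def test_empty_sequence_rejected(self, scheme):
        with pytest.raises(ValueError):
            smith_waterman("", "ACDE", scheme)

    @pytest.mark.parametrize("seed", range(200))
    def test_score_matches_cubic_oracle(self, seed, scheme):
        r = random.Random(seed)
        a = "".join(r.choice(AA) for _ in range(r.randint(1, 15)))
        b = "".join(r.choice(AA) for _ in range(r.randint(1, 15)))
        expected = cubic_local_score(a, b, scheme)
        assert smith_waterman(a, b, scheme).raw_score == expected
        assert _score_only(scheme.encode(a), scheme.encode(b), scheme) == expected

    @given(st.text(AA, min_size=1, max_size=20),
           st.text(AA, min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_score_is_symmetric(self, a, b):
        scheme = ScoringScheme()
        assert (smith_waterman(a, b, scheme).raw_score
                == smith_waterman(b, a, scheme).raw_score)

    @given(st.text(AA, min_size=3, max_size=25),
           st.text(AA, min_size=3, max_size=25))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reported_alignment_rescores_to_raw_score(self, a, b):
        scheme = ScoringScheme()
        aln = smith_waterman(a, b, scheme)
        if aln.raw_score:
            assert rescore_alignment(aln, scheme) == aln.raw_score
            qs, qe = aln.query_interval
            ss, se = aln.subject_interval
            assert aln.aligned_query.replace("-", "") == a[qs:qe]
            assert aln.aligned_subject.replace("-", "") == b[ss:se]

    def test_agrees_with_biopython_local_aligner(self, scheme):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(scheme.gap_open_penalty + scheme.gap_extend_penalty)
        aligner.extend_gap_score = -scheme.gap_extend_penalty
        r = random.Random(7)
        for _ in range(25):
            a = "".join(r.choice(AA) for _ in range(r.randint(10, 40)))
            b = "".join(r.choice(AA) for _ in range(r.randint(10, 40)))
            expected = int(aligner.score(a, b))
            got = smith_waterman(a, b, scheme).raw_score
            if got == 0:
                assert expected <= 0 or expected == got
            else:
                assert got == expected


class TestEvalue:
    def test_closed_form_identity(self, scheme):
        # lambda*S = ln(K*m*n)  =>  E = 1
        m = n = 100
        s = math.log(scheme.K * m * n) / scheme.lam
        assert evalue(s, m, n, scheme) == pytest.approx(1.0)

    def test_known_value(self, scheme):
        # K*m*n*exp(-lambda*S) with S=55, m=n=9
        assert evalue(55, 9, 9, scheme) == pytest.approx(1.39e-6, rel=0.01)

    def test_strictly_decreasing_in_score(self, scheme):
        values = [evalue(s, 9, 1000, scheme) for s in range(0, 120)]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_nonpositive_lengths_rejected(self, scheme):
        with pytest.raises(ValueError):
            evalue(10, 0, 5, scheme)


class TestScoringScheme:
    def test_gap_penalties_validated(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open_penalty=0)

    def test_stop_never_scores_positive(self, scheme):
        for c in AA + "*":
            assert scheme.pair_score("*", c) < 0

    def test_unknown_residue_scored_as_x(self, scheme):
        assert scheme.pair_score("U", "L") == scheme.pair_score("X", "L")


class TestSearchDataset:
    def test_mutated_copy_found_among_shuffled_decoys(self, config):
        rng = np.random.default_rng(12)
        query, _ = generate_precursor(config, rng, record_id="query",
                                      peptide="CLITNCPRG")
        noisy_cfg = GeneratorConfig(seed=0, mutation_rate=0.05)
        target, _ = generate_precursor(noisy_cfg, rng, record_id="target",
                                       peptide="CLITNCPRG")
        decoys = [
            generate_decoy(rng, target, record_id=f"decoy_{i}")[0]
            for i in range(50)
        ]
        hits = search_dataset([query], [target] + decoys)
        assert [h.subject_id for h in hits] == ["target"]

    def test_zero_cutoff_gives_no_hits(self, config, rng):
        query, _ = generate_precursor(config, rng, record_id="q")
        hits = search_dataset([query], [query], e_cutoff=0.0)
        assert hits == []

    def test_empty_queries_rejected(self):
        with pytest.raises(ValueError):
            search_dataset([], [])

    def test_empty_dataset_gives_empty_result(self, config, rng):
        query, _ = generate_precursor(config, rng, record_id="q")
        assert search_dataset([query], []) == []

    def test_nucleotide_subject_hit_in_reverse_frame(self, config, rng):
        from conftest import CODON_TABLE

        query, _ = generate_precursor(config, rng, record_id="q",
                                      peptide="CLITNCPRG")
        codons = {aa: c for c, aa in CODON_TABLE.items()}
        dna = "".join(codons[aa] for aa in query.residues)
        subject = SequenceRecord(
            "nt", reverse_complement("A" + dna), molecule_type="nucleotide"
        )
        hits = search_dataset([query], [subject])
        assert len(hits) == 1
        assert hits[0].frame == -2
        # Protein-space coordinates: the full query aligns.
        assert hits[0].query_interval == (0, len(query.residues))
        assert hits[0].aligned_query == query.residues

    def test_hits_sorted_by_evalue(self, config, rng):
        query, _ = generate_precursor(config, rng, record_id="q")
        near, _ = generate_precursor(GeneratorConfig(seed=0, mutation_rate=0.1),
                                     rng, record_id="near")
        far, _ = generate_precursor(GeneratorConfig(seed=0, mutation_rate=0.3),
                                    rng, record_id="far")
        hits = search_dataset([query], [far, near])
        evalues = [h.e_value for h in hits]
        assert evalues == sorted(evalues)
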