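import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from ankevo import (
    Sequence,
    filter_homologs,
    find_pest,
    global_align,
    group_range_matrix,
)
from ankevo.seq_similarity import pest_score, _KD, _RESIDUE_MASS

from conftest import brute_force_global_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")

aa_text = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12)


class TestGlobalAlign:
    def test_self_alignment_is_identical(self):
        s = Sequence("s", "MKVLWAALLVTFLAGCQA")
        res = global_align(s, s)
        assert res.identity_pct == 100.0
        assert "-" not in res.aligned_a + res.aligned_b

    def test_equal_short_pair_scores_matrix_diagonal(self):
        expected = sum(float(BLOSUM62[c, c]) for c in "ACD")
        res = global_align(Sequence("a", "ACD"), Sequence("b", "ACD"))
        assert res.score == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(aas), size=rng.integers(3, 7)))
        b = "".join(rng.choice(list(aas), size=rng.integers(3, 7)))
        res = global_align(Sequence("a", a), Sequence("b", b))
        oracle = brute_force_global_score(a, b, BLOSUM62)
        assert res.score == pytest.approx(oracle)

    def test_score_symmetric(self):
        a = Sequence("a", "MKVLWAAL")
        b = Sequence("b", "MKWWAL")
        assert global_align(a, b).score == pytest.approx(global_align(b, a).score)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align(Sequence("a", "M"), Sequence("b", ""))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=aa_text, b=aa_text)
    def test_identity_100_iff_equal(self, a, b):
        res = global_align(Sequence("a", a), Sequence("b", b))
        assert 0 <= res.identity_pct <= res.similarity_pct <= 100
        assert (res.identity_pct == 100.0) == (a == b)


class TestGroupRanges:
    def test_identical_copies_give_100_everywhere(self):
        s = Sequence("x", "MKVLW")
        m = group_range_matrix(
            {"g1": [s, s], "g2": [s, s]}, metric="identity"
        )
        assert np.allclose(m.min_pct, 100.0)
        assert np.allclose(m.max_pct, 100.0)

    def test_single_cross_pair(self):
        m = group_range_matrix(
            {"g1": [Sequence("a", "AAAA")], "g2": [Sequence("b", "AAAT")]},
            metric="identity",
        )
        assert m.min_pct[0, 1] == pytest.approx(75.0)
        assert m.max_pct[0, 1] == pytest.approx(75.0)
        # singleton intra ranges are NA
        assert np.isnan(m.min_pct[0, 0]) and np.isnan(m.min_pct[1, 1])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        groups = {
            f"g{k}": [
                Sequence(f"g{k}s{i}", "".join(rng.choice(list(aas), size=15)))
                for i in range(3)
            ]
            for k in range(3)
        }
        m = group_range_matrix(groups, metric="similarity")
        names = list(groups)
        for i, gi in enumerate(names):
            for j, gj in enumerate(names):
                if i == j:
                    vals = [
                        global_align(groups[gi][u], groups[gi][v]).similarity_pct
                        for u in range(3)
                        for v in range(u + 1, 3)
                    ]
                else:
                    vals = [
                        global_align(x, y).similarity_pct
                        for x in groups[gi]
                        for y in groups[gj]
                    ]
                assert m.min_pct[i, j] == pytest.approx(min(vals))
                assert m.max_pct[i, j] == pytest.approx(max(vals))


class TestHomologFilter:
    def test_identical_hit_kept(self):
        q = Sequence("q", "MKVLWAALLVTFLAGCQAKVEQAVE" * 12)  # 300 residues
        kept, log = filter_homologs(
            [q], q, identity_min=35.0, length_window=(250, 350)
        )
        assert kept == [q] and log == []

    def test_length_window_bounds_are_strict(self):
        q = Sequence("q", "A" * 300)
        inside = Sequence("h1", "A" * 349)
        on_bound = Sequence("h2", "A" * 350)
        kept, log = filter_homologs(
            [inside, on_bound], q, identity_min=35.0, length_window=(250, 350)
        )
        assert [s.id for s in kept] == ["h1"]
        assert log[0][0] == "h2" and "length" in log[0][1]

    def test_twenty_hits_against_manual_rule_application(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        query = Sequence("q", "".join(rng.choice(aas, size=80)))
        hits = []
        for i in range(20):
            n = int(rng.integers(60, 110))
            if rng.random() < 0.5:  # related hit: mutated copy of the query
                base = list(query.residues)
                for pos in rng.choice(80, size=int(rng.integers(0, 50)), replace=False):
                    base[pos] = str(rng.choice(aas))
                resid = "".join(base)[:n].ljust(n, "A")
            else:
                resid = "".join(rng.choice(aas, size=n))
            hits.append(Sequence(f"h{i}", resid))
        window = (70, 100)
        kept, log = filter_homologs(
            hits, query, identity_min=35.0, length_window=window
        )
        manual = []
        for h in hits:
            if not (window[0] < len(h.residues) < window[1]):
                continue
            if global_align(h, query).identity_pct > 35.0:
                manual.append(h.id)
        assert [s.id for s in kept] == manual
        assert len(kept) + len(log) == 20


class TestPest:
    def test_poly_alanine_has_no_candidates(self):
        assert find_pest(Sequence("s", "A" * 40)) == []

    def test_minimal_candidate_between_lysines(self):
        regions = find_pest(Sequence("s", "K" + "EPSTEPSTEPST" + "K"))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (2, 13)
        assert len(r.segment) == 12
        assert set("EPST") <= set(r.segment)

    def test_candidates_never_contain_positive_residues(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            seq = Sequence("s", "".join(rng.choice(aas, size=120)))
            for r in find_pest(seq):
                assert r.end - r.start + 1 >= 12
                assert not set("KRH") & set(r.segment)
                assert set(r.segment) & set("DE")
                assert "P" in r.segment
                assert set(r.segment) & set("ST")

    def test_score_matches_independent_recomputation(self):
        # independent evaluation of the published score formula
        seg = "EPSTEDLSPTSE"
        mass = sum(_RESIDUE_MASS[c] for c in seg)
        depst = sum(_RESIDUE_MASS[c] for c in seg if c in "DEPST")
        depst -= _RESIDUE_MASS["E"] + _RESIDUE_MASS["P"] + _RESIDUE_MASS["T"]
        hydro = sum(10 * _KD[c] + 45 for c in seg) / len(seg)
        expected = 0.55 * (100 * depst / mass) - 0.5 * hydro
        assert pest_score(seg) == pytest.approx(expected, abs=1e-9)

    def test_enriched_segment_scores_above_depleted_one(self):
        rich = find_pest(Sequence("s", "K" + "EPSTDESPTSEDTP" + "K"))[0]
        poor = find_pest(Sequence("s", "K" + "EPSTAAAAVVLLIW" + "K"))[0]
        assert rich.score > poor.score
        assert rich.valid
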