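import numpy as np
import pytest

from tmcoffee.errors import ConfigError, DataError
from tmcoffee.extension import (BuiltinSWBackend, ExtendedProfile,
                                FilterParams, SearchHit, build_profile,
                                extend_all, filter_database_by_keyword,
                                filter_hits, search)
from tmcoffee.formats import AA_INDEX, Sequence
from tmcoffee.simulate import build_mini_database, make_family


def _hit(identity=70.0, coverage=80.0, evalue=1e-6, qid="q", sid="s"):
    n = 10
    seg = "A" * n
    return SearchHit(query_id=qid, subject_id=sid, identity=identity,
                     qstart=0, qend=n, sstart=0, send=n,
                     aligned_query=seg, aligned_subject=seg,
                     evalue=evalue, coverage=coverage)


class TestFilterHits:
    def test_high_identity_rejected(self):
        assert filter_hits([_hit(identity=95.0)]) == []

    def test_coverage_bound_is_strict(self):
        assert filter_hits([_hit(coverage=70.0)]) == []
        assert filter_hits([_hit(coverage=70.0001)]) != []

    def test_identity_bounds_inclusive(self):
        assert filter_hits([_hit(identity=50.0)]) != []
        assert filter_hits([_hit(identity=90.0)]) != []
        assert filter_hits([_hit(identity=49.9)]) == []

    def test_evalue_none_disables_filter(self):
        assert filter_hits([_hit(evalue=1e6)], evalue_max=None) != []
        assert filter_hits([_hit(evalue=1e6)], evalue_max=1.0) == []

    def test_bad_bounds(self):
        with pytest.raises(ConfigError):
            filter_hits([], id_min=80, id_max=50)

    def test_order_preserved_and_monotone_in_evalue(self):
        hits = [_hit(evalue=e, sid=f"s{k}")
                for k, e in enumerate([1e-3, 1e-9, 1e-6])]
        kept_tight = filter_hits(hits, evalue_max=1e-5)
        kept_loose = filter_hits(hits, evalue_max=1e-2)
        assert [h.subject_id for h in kept_tight] == ["s1", "s2"]
        assert set(h.subject_id for h in kept_tight) <= set(
            h.subject_id for h in kept_loose)


class TestBuildProfile:
    def test_zero_hits_point_mass(self):
        q = Sequence("q", "ACDEF")
        prof = build_profile(q, [])
        assert prof.freqs.shape == (5, 21)
        for p, ch in enumerate("ACDEF"):
            assert prof.freqs[p, AA_INDEX[ch]] == pytest.approx(1.0)
        assert np.allclose(prof.freqs.sum(axis=1), 1.0)

    def test_hand_worked_example(self):
        # query ACDEF, one hit on span 2-4 (1-based) aligned (CDE / CNE)
        q = Sequence("q", "ACDEF")
        hit = SearchHit(query_id="q", subject_id="s", identity=66.7,
                        qstart=1, qend=4, sstart=0, send=3,
                        aligned_query="CDE", aligned_subject="CNE",
                        evalue=1e-5, coverage=60.0)
        prof = build_profile(q, [hit])
        f = prof.freqs
        # columns 1 and 5: query residue at 0.5, gap 0.5 (gap counted)
        assert f[0, AA_INDEX["A"]] == pytest.approx(0.5)
        assert f[0, 20] == pytest.approx(0.5)
        assert f[4, AA_INDEX["F"]] == pytest.approx(0.5)
        assert f[4, 20] == pytest.approx(0.5)
        assert f[1, AA_INDEX["C"]] == pytest.approx(1.0)
        assert f[2, AA_INDEX["D"]] == pytest.approx(0.5)
        assert f[2, AA_INDEX["N"]] == pytest.approx(0.5)
        assert f[3, AA_INDEX["E"]] == pytest.approx(1.0)

    def test_query_gap_columns_dropped(self):
        # aligned pair (A-C / AGC): the subject G opposite the query gap
        # is discarded; the span still covers 2 query positions
        q = Sequence("q", "ACDEF")
        hit = SearchHit(query_id="q", subject_id="s", identity=100.0,
                        qstart=0, qend=2, sstart=0, send=3,
                        aligned_query="A-C", aligned_subject="AGC",
                        evalue=1e-5, coverage=40.0)
        prof = build_profile(q, [hit])
        assert prof.freqs.shape[0] == 5
        assert prof.freqs[0, AA_INDEX["A"]] == pytest.approx(1.0)
        assert prof.freqs[1, AA_INDEX["C"]] == pytest.approx(1.0)

    def test_corrupt_hit_rejected(self):
        q = Sequence("q", "ACDEF")
        hit = SearchHit(query_id="q", subject_id="s", identity=100.0,
                        qstart=0, qend=3, sstart=0, send=3,
                        aligned_query="AAA", aligned_subject="AAA",
                        evalue=1e-5, coverage=60.0)
        with pytest.raises(DataError):
            build_profile(q, [hit])

    def test_columns_sum_to_one_random(self, rng):
        fam = make_family(5, n_members=4, target_identity=0.7)
        db = build_mini_database([fam], n_decoys=5, seed=5)
        profs = extend_all(list(fam.descendants), db)
        for prof in profs.values():
            assert prof.freqs.shape[0] == len(prof.query)
            assert np.max(np.abs(prof.freqs.sum(axis=1) - 1.0)) < 1e-9


class TestBuiltinBackend:
    def test_self_hit(self):
        q = Sequence("q", "MKWVFLLLAVMKWVFLLLAV")
        hits = search(q, [q])
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(100.0)
        assert hits[0].coverage == pytest.approx(100.0)

    def test_no_common_signal_strict_evalue(self):
        q = Sequence("q", "MKWVF")
        other = Sequence("s", "GGSGGSGGSG")
        assert search(q, [other], evalue_max=1e-30) == []

    def test_identity_matches_hand_count(self):
        # identical 10-mers except one position: 9/10 = 90%
        q = Sequence("q", "MKWVFLLLAV")
        s = Sequence("s", "MKWVFLLLAI")
        (hit,) = search(q, [s])
        assert hit.identity == pytest.approx(90.0)

    def test_empty_database(self):
        assert search(Sequence("q", "MKWVF"), []) == []

    def test_hit_invariants(self):
        q = Sequence("q", "MKWVFLLLAVGGSTR")
        s = Sequence("s", "MKWVFILLAVGGSTR")
        (hit,) = search(q, [s])
        hit.validate_against(q)
        assert len(hit.aligned_query) == len(hit.aligned_subject)


class TestExtendAll:
    def test_empty_database_gives_self_profiles(self):
        seqs = [Sequence("a", "MKWVF"), Sequence("b", "ACDEF"),
                Sequence("c", "MKWIF")]
        profs = extend_all(seqs, [])
        assert set(profs) == {"a", "b", "c"}
        for s in seqs:
            assert profs[s.id].n_hits == 0
            assert np.allclose(
                profs[s.id].freqs,
                ExtendedProfile.from_sequence(s).freqs)

    def test_planted_homologs_add_support(self):
        fam = make_family(11, n_members=4, target_identity=0.75)
        db = build_mini_database([fam], n_decoys=5, seed=11)
        profs = extend_all(list(fam.descendants), db)
        for prof in profs.values():
            assert prof.n_hits >= 1
            assert prof.support.max() > 1

    def test_deterministic(self):
        fam = make_family(12, n_members=3, target_identity=0.75)
        db = build_mini_database([fam], n_decoys=3, seed=12)
        p1 = extend_all(list(fam.descendants), db)
        p2 = extend_all(list(fam.descendants), db)
        for sid in p1:
            assert np.array_equal(p1[sid].freqs, p2[sid].freqs)

    def test_duplicate_ids_rejected(self):
        s = Sequence("a", "MKWVF")
        with pytest.raises(DataError):
            extend_all([s, s], [])


class TestKeywordFilter:
    def _records(self):
        recs = [Sequence(f"r{i}", "MKWVF", "random protein")
                for i in range(7)]
        recs += [Sequence(f"t{i}", "MKWVF", "Transmembrane receptor")
                 for i in range(3)]
        return recs

    def test_token_count(self):
        kept = filter_database_by_keyword(self._records(), "transmembrane")
        assert len(kept) == 3

    def test_absent_keyword(self):
        assert filter_database_by_keyword(self._records(), "kinase") == []

    def test_token_not_substring(self):
        recs = [Sequence("x", "MKWVF", "transmembrane-like domain")]
        assert filter_database_by_keyword(recs, "transmembrane") == []

    def test_annotation_punctuation_splits(self):
        recs = [Sequence("x", "MKWVF", "keyword:transmembrane;signal")]
        assert len(filter_database_by_keyword(recs, "transmembrane")) == 1

    def test_order_preserved(self):
        kept = filter_database_by_keyword(self._records(), "transmembrane")
        assert [r.id for r in kept] == ["t0", "t1", "t2"]
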