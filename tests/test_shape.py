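import numpy as np
import pytest

from betaturn.core_io import ProteinChain, ShapeDatabaseEntry
from betaturn.shape import (
    BuiltinAlignmentBackend,
    HomologyHit,
    PsiBlastBackend,
    ShapeAssignment,
    assign_shape_string,
    filter_and_rank_hits,
    filter_by_identity,
    predict_shape_string,
    shape_accuracy,
)
from betaturn.synthetic import FixtureSpec, make_shape_world


def _hit(db_id, e, pairs, target_id="t"):
    return HomologyHit(target_id=target_id, db_id=db_id, e_value=e, aligned_pairs=list(pairs))


class TestFilterAndRank:
    def test_threshold_and_ascending_order(self):
        hits = [_hit("a", 1e-10, [(0, 0)]), _hit("b", 1e-3, [(0, 0)]), _hit("c", 1e-7, [(0, 0)])]
        ranked = filter_and_rank_hits(hits, e_threshold=1e-5)
        assert [h.db_id for h in ranked] == ["a", "c"]

    def test_empty_input(self):
        assert filter_and_rank_hits([]) == []

    def test_equal_e_value_tie_broken_by_db_id(self):
        hits = [_hit("b", 1e-8, [(0, 0)]), _hit("a", 1e-8, [(0, 0)])]
        assert [h.db_id for h in filter_and_rank_hits(hits)] == ["a", "b"]


class TestAssignShapeString:
    def test_worked_ten_residue_example(self):
        db = {
            "d1": ShapeDatabaseEntry(id="d1", sequence="AAAAAA", shape="SSRRAA"),
            "d2": ShapeDatabaseEntry(id="d2", sequence="AAAAAAA", shape="KKTTGGG"),
        }
        hit1 = _hit("d1", 1e-10, [(i, i) for i in range(6)])
        hit2 = _hit("d2", 1e-7, [(3 + j, j) for j in range(7)])
        result = assign_shape_string(10, filter_and_rank_hits([hit1, hit2]), db)
        assert result.shape == "SSRRAATGGG"
        assert result.coverage_fraction == 1.0
        assert result.source[0] == "d1" and result.source[9] == "d2"

    def test_no_hits_all_x(self):
        result = assign_shape_string(10, [], {})
        assert result.shape == "X" * 10
        assert result.coverage_fraction == 0.0

    def test_full_single_hit_full_coverage(self):
        db = {"d": ShapeDatabaseEntry(id="d", sequence="AAAAA", shape="SRUVK")}
        result = assign_shape_string(5, [_hit("d", 1e-9, [(i, i) for i in range(5)])], db)
        assert result.shape == "SRUVK" and result.coverage_fraction == 1.0

    def test_db_pos_out_of_range_names_hit(self):
        db = {"d": ShapeDatabaseEntry(id="d", sequence="AA", shape="SR")}
        with pytest.raises(ValueError, match="'d'"):
            assign_shape_string(5, [_hit("d", 1e-9, [(0, 0), (1, 5)])], db)

    def test_greedy_equals_per_position_best_hit_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            L = int(rng.integers(10, 31))
            n_db = int(rng.integers(1, 6))
            db, hits = {}, []
            for j in range(n_db):
                dlen = int(rng.integers(5, L + 5))
                shape = "".join(rng.choice(list("SRUVKATG"), size=dlen))
                db_id = f"d{j}"
                db[db_id] = ShapeDatabaseEntry(id=db_id, sequence="A" * dlen, shape=shape)
                t0 = int(rng.integers(0, max(1, L - 4)))
                d0 = int(rng.integers(0, max(1, dlen - 4)))
                span = int(rng.integers(1, min(L - t0, dlen - d0) + 1))
                hits.append(_hit(db_id, float(10.0 ** -rng.integers(6, 15)),
                                 [(t0 + i, d0 + i) for i in range(span)]))
            ranked = filter_and_rank_hits(hits)
            greedy = assign_shape_string(L, ranked, db)
            # oracle: each position takes the best-ranked hit covering it
            expected = ["X"] * L
            for pos in range(L):
                for h in ranked:
                    cover = {t: d for t, d in h.aligned_pairs}
                    if pos in cover:
                        expected[pos] = db[h.db_id].shape[cover[pos]]
                        break
            assert greedy.shape == "".join(expected)

    def test_adding_hits_never_decreases_coverage(self):
        rng = np.random.default_rng(1)
        db = {
            f"d{j}": ShapeDatabaseEntry(id=f"d{j}", sequence="A" * 20, shape="S" * 20)
            for j in range(5)
        }
        hits = []
        previous = 0.0
        for j in range(5):
            t0 = int(rng.integers(0, 10))
            hits.append(_hit(f"d{j}", 10.0 ** -(7 + j), [(t0 + i, i) for i in range(8)]))
            cov = assign_shape_string(20, filter_and_rank_hits(hits), db).coverage_fraction
            assert cov >= previous
            previous = cov

    def test_tightening_threshold_never_increases_coverage(self):
        db = {"a": ShapeDatabaseEntry(id="a", sequence="AAAA", shape="SRUV")}
        hits = [_hit("a", 1e-6, [(i, i) for i in range(4)])]
        loose = assign_shape_string(4, filter_and_rank_hits(hits, 1e-5), db).coverage_fraction
        tight = assign_shape_string(4, filter_and_rank_hits(hits, 1e-8), db).coverage_fraction
        assert tight <= loose


class TestShapeAccuracy:
    def test_perfect_match(self):
        assert shape_accuracy("SSRA", "SSRA") == 1.0

    def test_all_x_scores_zero(self):
        assert shape_accuracy("XXXX", "SSRA") == 0.0

    def test_three_of_four(self):
        assert shape_accuracy("SSRX", "SSRA") == 0.75

    def test_covered_only_denominator(self):
        assert shape_accuracy("SSRX", "SSRA", covered_only=True) == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            shape_accuracy("SS", "SSR")


class TestPredictShapeString:
    def test_self_hit_exclusion_gives_all_x(self):
        chain = ProteinChain(id="p", sequence="ACDEFGHIKLMNPQRSTVWY")
        db = [ShapeDatabaseEntry(id="p", sequence=chain.sequence, shape="S" * 20)]
        result = predict_shape_string(chain, db, BuiltinAlignmentBackend())
        assert result.shape == "X" * 20

    def test_identical_sequence_under_other_id_transfers_fully(self):
        chain = ProteinChain(id="p", sequence="ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
        shape = "SRUVKATGSRUVKATGSRUVKATGSRUVKA"
        db = [ShapeDatabaseEntry(id="q", sequence=chain.sequence, shape=shape)]
        result = predict_shape_string(chain, db, BuiltinAlignmentBackend())
        assert result.shape == shape
        assert result.coverage_fraction == 1.0

    def test_exclude_identical_sequences_flag(self):
        chain = ProteinChain(id="p", sequence="ACDEFGHIKLMNPQRSTVWY")
        db = [ShapeDatabaseEntry(id="q", sequence=chain.sequence, shape="S" * 20)]
        result = predict_shape_string(
            chain, db, BuiltinAlignmentBackend(), exclude_identical_sequences=True
        )
        assert result.shape == "X" * 20

    def test_unrelated_sequences_give_no_assignment(self):
        rng = np.random.default_rng(0)
        chain = ProteinChain(id="p", sequence="".join(rng.choice(list("ACDE"), size=30)))
        db = [
            ShapeDatabaseEntry(id=f"r{j}", sequence="".join(rng.choice(list("KRWY"), size=30)),
                               shape="S" * 30)
            for j in range(3)
        ]
        result = predict_shape_string(chain, db, BuiltinAlignmentBackend())
        assert result.shape == "X" * 30

    def test_backend_failure_propagates_with_name(self):
        def broken(chain, db):
            raise OSError("boom")

        broken.name = "broken"
        chain = ProteinChain(id="p", sequence="ACDE")
        with pytest.raises(RuntimeError, match="broken"):
            predict_shape_string(chain, [], broken)


class TestShapeWorld:
    def test_zero_mutation_full_entry_transfers_perfectly(self):
        spec = FixtureSpec(n_chains=3, chain_length_range=(30, 40), db_mutation_rate=0.0, seed=2)
        targets, db, reference, backend = make_shape_world(spec)
        for chain in targets:
            result = predict_shape_string(chain, db, backend)
            assert result.coverage_fraction == 1.0
            assert shape_accuracy(result, reference[chain.id]) == 1.0

    def test_half_coverage_entries_leave_x_tail(self):
        spec = FixtureSpec(n_chains=3, chain_length_range=(40, 40), db_mutation_rate=0.0, seed=2)
        targets, db, reference, backend = make_shape_world(spec, db_coverage=0.5)
        result = predict_shape_string(targets[0], db, backend)
        assert result.coverage_fraction == pytest.approx(0.5, abs=0.05)
        assert result.shape.endswith("X" * 10)

    def test_accuracy_degrades_with_mutation_rate(self):
        means = []
        for rate in (0.0, 0.1, 0.3):
            spec = FixtureSpec(n_chains=6, chain_length_range=(30, 50),
                               db_mutation_rate=rate, seed=4)
            targets, db, reference, backend = make_shape_world(spec)
            accs = [
                shape_accuracy(predict_shape_string(c, db, backend), reference[c.id])
                for c in targets
            ]
            means.append(np.mean(accs))
        assert means[0] > means[1] > means[2]


class TestPsiBlastBackend:
    def test_adapter_finds_identical_sequence(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
        chain = ProteinChain(id="query", sequence=seq)
        db = [
            ShapeDatabaseEntry(id="match", sequence=seq, shape="S" * len(seq)),
            ShapeDatabaseEntry(id="other", sequence="G" * 40, shape="R" * 40),
        ]
        result = predict_shape_string(chain, db, PsiBlastBackend())
        assert result.coverage_fraction > 0.9
        assert set(result.shape) <= {"S", "X"}


class TestIdentityFilter:
    def test_duplicate_dropped_unrelated_kept(self):
        a = ShapeDatabaseEntry(id="a", sequence="ACDEFGHIKLMNPQRSTVWY", shape="S" * 20)
        b = ShapeDatabaseEntry(id="b", sequence="ACDEFGHIKLMNPQRSTVWY", shape="R" * 20)
        c = ShapeDatabaseEntry(id="c", sequence="WYWYWYWYWYWYWYWYWYWY", shape="U" * 20)
        kept = filter_by_identity([a, b, c], max_identity=0.30)
        assert [e.id for e in kept] == ["a", "c"]
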