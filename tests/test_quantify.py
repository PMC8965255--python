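import numpy as np
import pandas as pd
import pytest

from isoqtl.quantify import (
    DabgParams,
    EquivalenceClasses,
    _membership_matrix,
    _zero_rule_failures,
    build_dabg,
    em_log_likelihood,
    em_quantify,
    requantify_after_removal,
    tpm,
)
from isoqtl.transcriptome import TranscriptomeAnnotation

from conftest import make_transcript


def ec(members, counts, libs=None):
    libs = libs or [f"L{i}" for i in range(np.atleast_2d(counts).shape[1])]
    return EquivalenceClasses(
        [tuple(m) for m in members],
        pd.DataFrame(np.atleast_2d(counts).reshape(len(members), -1), columns=libs),
    )


class TestEmQuantify:
    def test_unique_classes_return_class_counts(self):
        classes = ec([("a",), ("b",)], [[10], [25]])
        lengths = pd.Series({"a": 100.0, "b": 200.0})
        out = em_quantify(classes, lengths)
        assert out["L0"].to_dict() == pytest.approx({"a": 10.0, "b": 25.0})

    def test_symmetric_twins_split_evenly(self):
        classes = ec([("a", "b")], [[30]])
        lengths = pd.Series({"a": 500.0, "b": 500.0})
        out = em_quantify(classes, lengths)
        assert out.loc["a", "L0"] == pytest.approx(15.0)
        assert out.loc["b", "L0"] == pytest.approx(15.0)

    def test_zero_unique_support_drains_shared_reads(self):
        # unique counts (10, 0) plus a shared 10: the fixed point is (20, 0)
        classes = ec([("a",), ("b",), ("a", "b")], [[10], [0], [10]])
        lengths = pd.Series({"a": 100.0, "b": 100.0})
        out = em_quantify(classes, lengths)
        assert out.loc["a", "L0"] == pytest.approx(20.0, abs=1e-4)
        assert out.loc["b", "L0"] == pytest.approx(0.0, abs=1e-4)

    def test_read_conservation(self, rng):
        tids = ["a", "b", "c"]
        members = [("a",), ("b",), ("c",), ("a", "b"), ("b", "c"), ("a", "b", "c")]
        counts = rng.integers(0, 50, size=(len(members), 3))
        classes = ec(members, counts)
        lengths = pd.Series({t: float(rng.integers(100, 1000)) for t in tids})
        out = em_quantify(classes, lengths)
        np.testing.assert_allclose(out.sum(axis=0), counts.sum(axis=0), atol=1e-6)

    def test_orphan_class_reads_dropped(self):
        classes = ec([("a",), ("zz",)], [[10], [7]])
        lengths = pd.Series({"a": 100.0})
        out = em_quantify(classes, lengths, transcript_ids=["a"])
        assert out.loc["a", "L0"] == pytest.approx(10.0)
        assert float(out.sum().sum()) == pytest.approx(10.0)

    def test_likelihood_nondecreasing_vs_grid_oracle(self, rng):
        """EM iterates ascend the mixture likelihood; the fixed point beats a
        grid search over the 2-transcript abundance simplex."""
        for _ in range(20):
            lens = rng.uniform(100, 1000, 2)
            n1, n2, ns = rng.integers(0, 60, 3)
            if n1 + n2 + ns == 0:
                continue
            members = [("a",), ("b",), ("a", "b")]
            classes = ec(members, [[n1], [n2], [ns]])
            lengths = pd.Series({"a": lens[0], "b": lens[1]})
            C = _membership_matrix(members, ["a", "b"])
            nvec = np.array([n1, n2, ns], dtype=float)
            total = nvec.sum()

            alpha = np.array([total / 2, total / 2])
            prev = em_log_likelihood(alpha, lens, C, nvec)
            for _ in range(200):
                psi = alpha / lens
                denom = C @ psi
                ratio = np.where(denom > 0, nvec / np.where(denom > 0, denom, 1), 0)
                alpha = (C.T @ ratio) * psi
                cur = em_log_likelihood(alpha, lens, C, nvec)
                assert cur >= prev - 1e-9
                prev = cur
            # grid oracle over the simplex
            grid = np.linspace(1e-6, 1 - 1e-6, 2001)
            best = max(
                em_log_likelihood(np.array([p, 1 - p]) * total, lens, C, nvec)
                for p in grid
            )
            assert prev >= best - 1e-6


class TestRequantify:
    def test_removing_twin_reassigns_shared_reads(self):
        classes = ec([("a", "b"), ("b",)], [[30], [4]])
        lengths = pd.Series({"a": 100.0, "b": 100.0})
        out = requantify_after_removal(classes, ["a"], lengths)
        assert out.loc["a", "L0"] == pytest.approx(30.0)
        assert "b" not in out.index

    def test_removing_unique_only_transcript_leaves_others_unchanged(self):
        classes = ec([("a",), ("b",)], [[10], [9]])
        lengths = pd.Series({"a": 100.0, "b": 100.0})
        out = requantify_after_removal(classes, ["a"], lengths)
        assert out.loc["a", "L0"] == pytest.approx(10.0)

    def test_dominance_flip_matches_hand_em(self):
        # with c present the shared reads flow mostly to c and a is the
        # dominant isoform; removing c flips dominance to b.  Fixed point by
        # hand: alpha_b = 2 + 20*alpha_b/52 -> 3.25 (equal lengths).
        members = [("a",), ("c",), ("b", "c"), ("b",)]
        classes = ec(members, [[12], [30], [20], [2]])
        lengths = pd.Series({"a": 100.0, "b": 100.0, "c": 100.0})
        full = em_quantify(classes, lengths)
        assert full.loc["b", "L0"] == pytest.approx(2 * 52 / 32, abs=1e-4)
        assert full.loc["a", "L0"] > full.loc["b", "L0"]
        re = requantify_after_removal(classes, ["a", "b"], lengths)
        assert re.loc["b", "L0"] == pytest.approx(22.0)
        assert re.loc["b", "L0"] > re.loc["a", "L0"]

    def test_empty_retained_set_rejected(self):
        classes = ec([("a",)], [[1]])
        with pytest.raises(ValueError):
            requantify_after_removal(classes, [], pd.Series({"a": 1.0}))


class TestTpm:
    def test_single_transcript_gets_the_million(self):
        counts = pd.DataFrame({"L0": [42.0]}, index=["a"])
        out = tpm(counts, pd.Series({"a": 100.0}))
        assert out.loc["a", "L0"] == pytest.approx(1e6)

    def test_length_ratio(self):
        counts = pd.DataFrame({"L0": [10.0, 10.0]}, index=["a", "b"])
        out = tpm(counts, pd.Series({"a": 1.0, "b": 2.0}))
        assert out.loc["a", "L0"] / out.loc["b", "L0"] == pytest.approx(2.0)

    def test_direct_values(self):
        counts = pd.DataFrame({"L0": [3.0, 1.0]}, index=["a", "b"])
        out = tpm(counts, pd.Series({"a": 1.0, "b": 1.0}))
        assert out["L0"].to_dict() == pytest.approx({"a": 750_000.0, "b": 250_000.0})

    def test_per_library_sums(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, (20, 4)).astype(float))
        lengths = pd.Series(rng.uniform(200, 2000, 20), index=counts.index)
        out = tpm(counts, lengths)
        np.testing.assert_allclose(out.sum(axis=0), 1e6)

    def test_all_zero_library_warns(self):
        counts = pd.DataFrame({"L0": [0.0, 0.0]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            out = tpm(counts, pd.Series({"a": 1.0, "b": 1.0}))
        assert (out["L0"] == 0).all()


class TestZeroRule:
    def test_one_third_boundary_at_ninety_libraries(self, rng):
        libs = [f"L{i}" for i in range(90)]
        row_removed = [0.0] * 30 + [5.0] * 60  # zeros in exactly 30 of 90
        row_kept = [0.0] * 29 + [5.0] * 61
        counts = pd.DataFrame([row_removed, row_kept], index=["gone", "stay"],
                              columns=libs)
        failures = _zero_rule_failures(counts, libs, 1.0 / 3.0)
        assert failures == {"gone"}


def dabg_fixture():
    """Twelve transcripts with engineered failures per cascade rule.

    chromosome rule: t04-t06 on an unplaced contig; length rule: t07 (200 nt,
    boundary, removed), t09 (100 nt), with t08 (201 nt, boundary, kept);
    zero-count rule over the 5 deep libraries (ceil(5/3) = 2): t10 zero in
    exactly 2 (boundary, removed), t11 zero in 3, t12 zero in 1 (kept).
    Library L6 is below the 10M read-pair floor.  Expected survivors:
    t01 t02 t03 t08 t12.
    """
    ann = TranscriptomeAnnotation()

    def add(tid, chrom, length):
        ann.add(make_transcript(tid, f"gene_{tid}", chrom=chrom,
                                exons=((1000, 1000 + length - 1),),
                                source="ensembl"))

    for tid in ("t01", "t02", "t03"):
        add(tid, "1", 300)
    for tid in ("t04", "t05", "t06"):
        add(tid, "contig_1", 300)
    add("t07", "1", 200)
    add("t08", "1", 201)
    add("t09", "1", 100)
    for tid in ("t10", "t11", "t12"):
        add(tid, "1", 300)

    libs = [f"L{i}" for i in range(1, 7)]
    rows = {
        "t01": [9, 9, 9, 9, 9, 9],
        "t02": [5, 5, 5, 5, 5, 5],
        "t03": [7, 7, 7, 7, 7, 7],
        "t04": [9, 9, 9, 9, 9, 9],
        "t05": [9, 9, 9, 9, 9, 9],
        "t06": [9, 9, 9, 9, 9, 9],
        "t07": [9, 9, 9, 9, 9, 9],
        "t08": [9, 9, 9, 9, 9, 9],
        "t09": [9, 9, 9, 9, 9, 9],
        "t10": [0, 0, 9, 9, 9, 0],
        "t11": [0, 0, 0, 9, 9, 0],
        "t12": [0, 9, 9, 9, 9, 0],
    }
    classes = EquivalenceClasses(
        [(t,) for t in rows], pd.DataFrame(list(rows.values()), columns=libs)
    )
    meta = pd.DataFrame({
        "library": libs,
        "strain": [f"S{i}" for i in range(1, 7)],
        "batch": ["B1"] * 6,
        "read_pairs": [20_000_000] * 5 + [9_999_999],
    })
    return ann, classes, meta


class TestDabgCascade:
    def test_hand_enumerated_survivor_chain(self):
        ann, classes, meta = dabg_fixture()
        res = build_dabg(ann, classes, meta,
                         DabgParams(chromosomes=("1",)))
        assert sorted(res.annotation.transcript_ids) == [
            "t01", "t02", "t03", "t08", "t12"]
        chain = [s["n_transcripts"] for s in res.ledger.steps]
        assert chain == [12, 12, 9, 5, 5]
        assert res.retained_libraries == ["L1", "L2", "L3", "L4", "L5"]

    def test_length_boundary(self):
        ann, classes, meta = dabg_fixture()
        res = build_dabg(ann, classes, meta, DabgParams(chromosomes=("1",)))
        assert "t07" not in res.annotation  # exactly 200 nt removed
        assert "t08" in res.annotation      # 201 nt retained

    def test_zero_count_boundary(self):
        ann, classes, meta = dabg_fixture()
        res = build_dabg(ann, classes, meta, DabgParams(chromosomes=("1",)))
        assert "t10" not in res.annotation  # zeros in exactly ceil(5/3)=2 of 5
        assert "t12" in res.annotation      # zeros in 1 of 5

    def test_idempotent_on_own_output(self):
        ann, classes, meta = dabg_fixture()
        first = build_dabg(ann, classes, meta, DabgParams(chromosomes=("1",)))
        kept_classes = classes.restrict(first.annotation.transcript_ids)
        kept_classes = EquivalenceClasses(
            kept_classes.members, kept_classes.counts[first.retained_libraries]
        )
        meta2 = meta[meta["library"].isin(first.retained_libraries)]
        second = build_dabg(first.annotation, kept_classes, meta2,
                            DabgParams(chromosomes=("1",)))
        assert sorted(second.annotation.transcript_ids) == sorted(
            first.annotation.transcript_ids)

    def test_requantitation_never_decreases_survivors(self):
        # removal only frees reads on nested class structures
        ann = TranscriptomeAnnotation()
        for tid in ("a", "b"):
            ann.add(make_transcript(tid, f"g_{tid}", exons=((1000, 1500),)))
        classes = ec([("a",), ("a", "b")], [[10], [20]])
        lengths = pd.Series({"a": 501.0, "b": 501.0})
        before = em_quantify(classes, lengths)
        after = requantify_after_removal(classes, ["a"], lengths)
        assert after.loc["a", "L0"] >= before.loc["a", "L0"] - 1e-9

    def test_all_libraries_removed_is_an_error(self):
        ann, classes, meta = dabg_fixture()
        meta = meta.assign(read_pairs=1000)
        with pytest.raises(ValueError, match="librar"):
            build_dabg(ann, classes, meta, DabgParams(chromosomes=("1",)))


class TestEquivalenceClassIo:
    def test_tsv_round_trip(self, tmp_path, rng):
        members = [("a",), ("a", "b"), ("b", "c", "d")]
        counts = pd.DataFrame(rng.integers(0, 50, (3, 4)),
                              columns=[f"L{i}" for i in range(4)])
        classes = EquivalenceClasses(members, counts)
        path = tmp_path / "ec.tsv"
        classes.write_tsv(path)
        back = EquivalenceClasses.read_tsv(path)
        assert back.members == members
        pd.testing.assert_frame_equal(back.counts, counts)
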