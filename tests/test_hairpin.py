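"""Folding, metric extraction and the eleven-criterion hairpin validator."""

import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirfuse._seq import can_pair, random_seq, revcomp
from mirfuse.hairpin import (
    DEFAULT_THRESHOLDS,
    FoldError,
    HairpinMetrics,
    HairpinStructure,
    StructureError,
    call_novel,
    compute_metrics,
    fold,
    fold_bundled,
    parse_dotbracket,
    validate_hairpin,
)


def nussinov_maxpairs(s: str) -> int:
    """Independent maximum-pairing count by memoized recursion (min loop 3)."""

    @functools.lru_cache(maxsize=None)
    def f(i, j):
        if j - i <= 3:
            return 0
        best = f(i + 1, j)
        for k in range(i + 4, j + 1):
            if can_pair(s[i], s[k]):
                best = max(best, 1 + f(i + 1, k - 1) + (f(k + 1, j) if k < j else 0))
        return best

    return f(0, len(s) - 1)


class TestFold:
    def test_forced_stem(self):
        db, energy = fold_bundled("GGGGGAAAACCCCC")
        assert db == "(((((....)))))"
        assert energy < 0

    def test_supplied_structure_passthrough(self):
        st_ = fold("GGCAAT", structure="((..))", energy=-1.0)
        assert st_.dotbracket == "((..))"
        assert st_.mfe == -1.0

    def test_unbalanced_supplied_structure(self):
        with pytest.raises(FoldError):
            fold("GGCAAT", structure="((..team"[:6])

    def test_length_bounds(self):
        with pytest.raises(FoldError):
            fold("ACGT" * 5)  # 20 nt, below the foldable window
        with pytest.raises(FoldError):
            fold("ACGT" * 200)

    def test_matches_bruteforce_nussinov_up_to_30nt(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s = random_seq(rng, int(rng.integers(10, 31)))
            db, _ = fold_bundled(s)
            assert db.count("(") == nussinov_maxpairs(s)

    def test_pair_count_bounds_random(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            length = int(rng.integers(10, 61))
            s = random_seq(rng, length)
            db, _ = fold_bundled(s)
            pairs = parse_dotbracket(db)
            assert 0 <= len(pairs) <= length // 2

    def test_external_backend(self):
        seq = "G" * 20 + "AAAA" + "C" * 20
        st_ = fold(seq, backend="external_mfe")
        assert len(st_.dotbracket) == len(seq)
        assert st_.mfe < -15


class TestMetrics:
    def test_perfect_stem(self):
        seq = "G" * 20 + "AAAA" + "C" * 20
        db = "(" * 20 + "...." + ")" * 20
        m = compute_metrics(HairpinStructure(seq, db, -30.0, mature_span=(0, 20)))
        assert m.max_bulge_stem == 0
        assert m.mismatch_errors_mature == 0
        assert m.mature_paired_fraction == 1.0
        assert m.stem_basepairs == 20
        assert m.loop_length == 4
        assert m.hairpin_length == 44

    def test_single_side_bulge_in_mature(self):
        # 4 pairs, a 3-nt bulge on the 5' arm, 4 more pairs, 4-nt loop
        db = "((((...((((....))))))))"
        seq = "G" * 4 + "A" * 3 + "G" * 4 + "AAAA" + "C" * 4 + "C" * 4
        m = compute_metrics(HairpinStructure(seq, db, -10.0, mature_span=(0, 11)))
        assert m.max_bulge_mature == 3
        assert m.biased_bulges_mature == 1
        assert m.biased_errors_in_one_bulge_mature == 3

    def test_two_symmetric_internal_loops_in_mature(self):
        db = "((((.((((.((((....)))).)))).))))"
        seq = "G" * 4 + "A" + "G" * 4 + "A" + "G" * 4 + "AAAA" + "C" * 4 + "A" + "C" * 4 + "A" + "C" * 4
        m = compute_metrics(HairpinStructure(seq, db, -10.0, mature_span=(0, 14)))
        assert m.mismatch_errors_mature == 2
        assert m.biased_bulges_mature == 0

    def test_multiloop_rejected(self):
        db = "((((....))))((((....))))"
        with pytest.raises(StructureError):
            compute_metrics(HairpinStructure("G" * 24, db, -5.0, mature_span=(0, 5)))


PASSING = HairpinMetrics(
    max_bulge_stem=0, stem_basepairs=25, mfe=-40.0, hairpin_length=54,
    loop_length=4, max_bulge_mature=0, biased_errors_in_one_bulge_mature=0,
    biased_bulges_mature=0, mismatch_errors_mature=0, mature_basepairs=21,
    mature_paired_fraction=1.0,
)


class TestValidator:
    def test_all_pass(self):
        assert validate_hairpin(PASSING).passed

    @pytest.mark.parametrize(
        "field,value,criterion",
        [
            ("max_bulge_stem", 13, 1),
            ("stem_basepairs", 15, 2),   # strict >15
            ("mfe", -15.0, 3),           # strict < -15
            ("hairpin_length", 49, 4),
            ("loop_length", 351, 5),
            ("max_bulge_mature", 5, 6),
            ("biased_errors_in_one_bulge_mature", 3, 7),
            ("biased_bulges_mature", 3, 8),
            ("mismatch_errors_mature", 5, 9),
            ("mature_basepairs", 11, 10),
            ("mature_paired_fraction", 0.80, 11),
        ],
    )
    def test_strict_boundaries(self, field, value, criterion):
        m = HairpinMetrics(**{**PASSING.__dict__, field: value})
        v = validate_hairpin(m)
        assert not v.criteria[criterion]
        assert not v.passed

    @given(
        bulge=st.integers(0, 20),
        extra=st.integers(1, 10),
        which=st.sampled_from(
            ["max_bulge_stem", "max_bulge_mature", "mismatch_errors_mature",
             "biased_bulges_mature", "biased_errors_in_one_bulge_mature"]
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_enlarging_a_defect_never_rescues(self, bulge, extra, which):
        base = HairpinMetrics(**{**PASSING.__dict__, which: bulge})
        worse = HairpinMetrics(**{**PASSING.__dict__, which: bulge + extra})
        if not validate_hairpin(base).passed:
            assert not validate_hairpin(worse).passed

    def test_validator_is_backend_independent(self):
        # verdicts depend only on the metrics object, never on a structure
        assert validate_hairpin(PASSING).criteria == validate_hairpin(
            HairpinMetrics(**PASSING.__dict__)
        ).criteria


class TestCallNovel:
    def test_planted_novel_recovered(self, refs, truth):
        unmapped = [truth.true_mirnas[m] for m in sorted(truth.novel_mirnas)]
        cands = call_novel(unmapped, refs.genome)
        for mid in sorted(truth.novel_mirnas):
            rec = refs.precursors[truth.mirna_precursor[mid]]
            found = [
                c for c in cands
                if c.sequence == truth.true_mirnas[mid]
                and c.strand == "+"
                and c.start == rec.start + rec.mature_span[0]
            ]
            assert found, f"planted novel {mid} not recovered"
            assert found[0].verdict.passed

    def test_read_absent_from_genome(self):
        assert call_novel(["ACGT" * 5 + "A"], {"c": "G" * 300}) == []

    def test_unstructured_region_rejected(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            read = random_seq(rng, 21)
            g = random_seq(rng, 500)
            genome = {"c": g[:250] + read + g[250:]}
            if call_novel([read], genome):
                hits += 1
        assert hits == 0

    def test_star_arm_found_on_minus_strand(self, refs, truth):
        # the perfectly complementary star arm maps to the minus strand
        mid = sorted(truth.novel_mirnas)[0]
        rec = refs.precursors[truth.mirna_precursor[mid]]
        cands = call_novel([rec.mature], refs.genome)
        strands = {c.strand for c in cands}
        assert "+" in strands and "-" in strands
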