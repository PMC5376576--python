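"""isomiR naming grammar, database mapping and composition statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirfuse._seq import revcomp
from mirfuse.annotate import (
    DatabaseError,
    NotNameable,
    apply_suffix,
    build_db,
    composition_stats,
    map_precursor_to_genome,
    map_to_precursors,
    name_isomir,
)
from mirfuse.preprocess import ReadLibrary

PREC = "GCA" + "TCGGACCAGGCTTCATTCCCC" + "ATCGATCGAT" + revcomp("TCGGACCAGGCTTCATTCCCC") + "TGC"
MATURE = "TCGGACCAGGCTTCATTCCCC"  # at offset 3


@pytest.fixture()
def db():
    return build_db({"MIR001": PREC}, {"miR001-5p": (MATURE, "MIR001")})


class TestNameIsomir:
    def test_exact_match_empty_suffix(self):
        assert name_isomir(MATURE, MATURE, 0) == ""

    def test_5p_extension(self):
        observed = PREC[2 : 3 + len(MATURE)]
        assert name_isomir(MATURE, observed, -1) == "_L+1"

    def test_trimmed_both_ends(self):
        observed = MATURE[1:-1]
        assert name_isomir(MATURE, observed, 1) == "_L-1R-1"

    def test_single_substitution(self):
        observed = MATURE[:11] + "C" + MATURE[12:]
        assert MATURE[11] == "T"
        assert name_isomir(MATURE, observed, 0) == "_1ss12TC"

    def test_compound_extension_plus_substitution(self):
        base = PREC[3 : 4 + len(MATURE)]  # mature + 1 nt 3' context
        ref = base[20]
        obs_base = {"A": "T", "T": "A", "G": "A", "C": "A"}[ref]
        observed = base[:20] + obs_base + base[21:]
        assert name_isomir(MATURE, observed, 0) == f"_R+1_1ss21{ref}{obs_base}"

    def test_two_substitutions_not_nameable(self):
        observed = MATURE[:11] + "C" + MATURE[12:15] + "C" + MATURE[16:]
        assert MATURE[11] != "C" and MATURE[15] != "C"
        with pytest.raises(NotNameable):
            name_isomir(MATURE, observed, 0)

    @given(
        s5=st.integers(-2, 2),
        s3=st.integers(-2, 2),
        sub_pos=st.one_of(st.none(), st.integers(2, 17)),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_suffix_reconstructs_observed(self, s5, s3, sub_pos, data):
        start, end = 3 - s5, 3 + len(MATURE) + s3
        observed = list(PREC[start:end])
        if sub_pos is not None and sub_pos < len(observed) - 1:
            ref = observed[sub_pos]
            alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
            observed[sub_pos] = alt
        observed = "".join(observed)
        suffix = name_isomir(MATURE, observed, start - 3)
        assert apply_suffix(MATURE, suffix, PREC, 3) == observed


class TestMapToPrecursors:
    def test_exact_mature(self, db):
        calls = map_to_precursors([MATURE], db)
        assert calls[0].status == "known_mature"
        assert calls[0].suffix == ""
        assert calls[0].name == "miR001-5p"

    def test_shifted_isoform(self, db):
        calls = map_to_precursors([PREC[2 : 3 + len(MATURE)]], db)
        assert calls[0].status == "isoform_same_arm"
        assert calls[0].suffix == "_L+1"

    def test_substituted_isoform_records_mismatch(self, db):
        observed = MATURE[:11] + "C" + MATURE[12:]
        calls = map_to_precursors([observed], db)
        assert calls[0].status == "isoform_same_arm"
        assert calls[0].suffix == "_1ss12TC"
        assert calls[0].mismatch == (12, "T", "C")

    def test_star_arm_isoform(self, db):
        star = revcomp(MATURE)
        calls = map_to_precursors([star], db)
        assert calls[0].status == "isoform_other_arm"

    def test_unmapped(self, db):
        calls = map_to_precursors(["A" + "CGTT" * 5], db)
        assert calls[0].status == "unmapped"

    def test_conservation_each_sequence_one_status(self, db):
        seqs = [MATURE, PREC[2 : 3 + len(MATURE)], revcomp(MATURE), "A" + "CGTT" * 5]
        calls = map_to_precursors(seqs, db)
        assert len(calls) == len(set(seqs))
        assert all(
            c.status in ("known_mature", "isoform_same_arm", "isoform_other_arm", "unmapped")
            for c in calls
        )

    def test_db_order_invariance(self):
        prec2 = "TTT" + PREC + "AAA"
        db1 = build_db(
            {"MIR001": PREC, "MIR000": prec2},
            {"miR001-5p": (MATURE, "MIR001"), "miR000-5p": (MATURE, "MIR000")},
        )
        db2 = build_db(
            {"MIR000": prec2, "MIR001": PREC},
            {"miR000-5p": (MATURE, "MIR000"), "miR001-5p": (MATURE, "MIR001")},
        )
        c1 = map_to_precursors([MATURE], db1)
        c2 = map_to_precursors([MATURE], db2)
        assert c1[0].precursor_id == c2[0].precursor_id == "MIR000"  # lexicographic tie-break

    def test_duplicate_precursor_ids_rejected(self):
        with pytest.raises(DatabaseError):
            build_db({"MIR001": PREC}, {"m": (MATURE, "MIRX")})


class TestGenomeMapping:
    def test_exact_locus(self):
        genome = {"chr1": "A" * 100 + PREC + "T" * 100}
        loci = map_precursor_to_genome(PREC, genome)
        assert any(
            l.start == 100 and l.end == 100 + len(PREC) and l.strand == "+" and l.identity == 1.0
            for l in loci
        )

    def test_92_percent_identity_still_reported(self):
        rng = np.random.default_rng(3)
        prec = "".join(rng.choice(list("ACGT"), 100))
        mutated = list(prec)
        for pos in rng.choice(100, size=8, replace=False):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        genome = {"chr1": "A" * 50 + "".join(mutated) + "T" * 50}
        loci = map_precursor_to_genome(prec, genome, min_identity=0.90)
        assert loci and all(l.identity >= 0.90 for l in loci)

    def test_reverse_complement_opposite_strand(self):
        genome = {"chr1": "A" * 100 + PREC + "T" * 100}
        loci = map_precursor_to_genome(revcomp(PREC), genome)
        assert any(l.strand == "-" and l.start == 100 for l in loci)

    def test_empty_genome(self):
        assert map_precursor_to_genome(PREC, {}) == []


class TestCompositionStats:
    def _lib(self, counts):
        return ReadLibrary(counts=counts, condition="IFC", replicate="r1",
                           total_raw=sum(counts.values()))

    def test_all_same_length(self, db):
        calls = map_to_precursors([MATURE], db)
        stats = composition_stats(calls, [self._lib({MATURE: 10})])
        assert stats.length_hist == {21: 1.0}

    def test_first_nt_unweighted(self, db):
        from mirfuse.annotate import MiRNACall

        calls = [
            MiRNACall(sequence="T" + "ACG" * 7, status="known_mature", base_name="a"),
            MiRNACall(sequence="TTACG" + "ACG" * 5 + "C", status="known_mature", base_name="b"),
            MiRNACall(sequence="TAAACG" + "ACG" * 5, status="known_mature", base_name="c"),
            MiRNACall(sequence="G" + "CGA" * 7, status="known_mature", base_name="d"),
        ]
        stats = composition_stats(calls, [self._lib({"ACGT" * 5: 1})])
        assert stats.first_nt["U"] == 0.75
        assert stats.first_nt["G"] == 0.25

    def test_planted_u_start_fraction(self, refs, libraries, truth):
        calls = map_to_precursors(
            sorted({s for lib in libraries for s in lib.counts
                    if s in truth.true_mirnas.values()}),
            refs.db,
        )
        stats = composition_stats(calls, libraries)
        known = [c for c in calls if c.status != "unmapped"]
        planted_u = sum(1 for c in known if c.sequence.startswith("T")) / len(known)
        assert stats.first_nt["U"] == pytest.approx(planted_u)
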