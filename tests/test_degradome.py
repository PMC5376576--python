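"""Target-site scoring, t-plots, peak categories, p-values and classes."""

import functools

import numpy as np
import pytest
from scipy import stats

from mirfuse._seq import revcomp
from mirfuse.degradome import (
    GAP,
    InputError,
    MISMATCH,
    TPlot,
    WOBBLE,
    assign_class,
    build_tplot,
    categorize_peak,
    cleavage_coordinate,
    find_target_sites,
    score_target_alignment,
    site_pvalue,
    tpb,
)

MIRNA = "TCGGACCAGGCTTCATTCCCC"  # 21 nt


def oracle_penalty(mirna: str, site: str) -> float:
    """Independent unbanded minimum-penalty alignment by memoized recursion."""
    srev = site[::-1]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def w(i):
        return 2.0 if 2 <= i <= 13 else 1.0

    def pen(m, t):
        if t == comp[m]:
            return 0.0
        if (m, t) in (("G", "T"), ("T", "G")):
            return WOBBLE
        return MISMATCH

    @functools.lru_cache(maxsize=None)
    def f(i, j):
        if i == 0 and j == 0:
            return 0.0
        best = float("inf")
        if i > 0 and j > 0:
            best = f(i - 1, j - 1) + w(i) * pen(mirna[i - 1], srev[j - 1])
        if i > 0:
            best = min(best, f(i - 1, j) + w(i) * GAP)
        if j > 0:
            best = min(best, f(i, j - 1) + w(min(i + 1, len(mirna))) * GAP)
        return best

    return f(len(mirna), len(srev))


class TestScoring:
    def test_perfect_complement_zero_penalty(self):
        penalty, aln = score_target_alignment(MIRNA, revcomp(MIRNA))
        assert penalty == 0.0
        assert aln.pairs == len(MIRNA)

    def test_wobble_in_core_doubled(self):
        # make the target base opposite miRNA position 5 a G:U wobble
        assert MIRNA[4] == "A"
        mirna = MIRNA[:4] + "G" + MIRNA[5:]
        site = list(revcomp(mirna))
        site[len(mirna) - 5] = "T"  # G opposite U
        penalty, aln = score_target_alignment(mirna, "".join(site))
        assert penalty == pytest.approx(2 * WOBBLE)
        assert aln.wobbles == 1

    def test_mismatch_outside_core_not_doubled(self):
        site = list(revcomp(MIRNA))
        assert MIRNA[19] == "C"
        site[len(MIRNA) - 20] = "T"  # C:T mismatch opposite position 20
        penalty, aln = score_target_alignment(MIRNA, "".join(site))
        assert penalty == pytest.approx(MISMATCH)
        assert aln.mismatches == 1

    def test_non_nucleotide_rejected(self):
        with pytest.raises(InputError):
            score_target_alignment("ACGUN" * 4 + "A", revcomp(MIRNA))

    def test_matches_unbanded_oracle_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            mirna = "".join(rng.choice(list("ACGT"), 21))
            site = "".join(rng.choice(list("ACGT"), int(rng.integers(18, 25))))
            penalty, _ = score_target_alignment(mirna, site)
            assert penalty == pytest.approx(oracle_penalty(mirna, site))


class TestFindSites:
    def test_planted_perfect_site(self):
        rng = np.random.default_rng(1)
        bg = "".join(rng.choice(list("ACGT"), 200))
        tx = bg[:90] + revcomp(MIRNA) + bg[90:]
        hits = find_target_sites("m", MIRNA, {"TX1": tx}, max_penalty=4.0)
        assert len(hits) == 1
        h = hits[0]
        assert h.penalty == 0.0
        assert h.site_start == 91
        assert h.cleavage_coords[10] == cleavage_coordinate(91, 21, 10) == 91 + 21 - 10

    def test_site_embedded_twice_two_hits(self):
        rng = np.random.default_rng(2)
        bg = "".join(rng.choice(list("ACGT"), 150))
        tx = bg[:40] + revcomp(MIRNA) + bg[40:100] + revcomp(MIRNA) + bg[100:]
        hits = find_target_sites("m", MIRNA, {"TX1": tx}, max_penalty=4.0)
        assert len(hits) == 2
        assert all(h.penalty == 0.0 for h in hits)

    def test_scan_equals_bruteforce_on_small_transcriptome(self):
        rng = np.random.default_rng(3)
        tx = {"TXa": "".join(rng.choice(list("ACGT"), 120)),
              "TXb": "".join(rng.choice(list("ACGT"), 120))}
        tx["TXa"] = tx["TXa"][:50] + revcomp(MIRNA) + tx["TXa"][50:]
        max_penalty = 7.0
        hits = find_target_sites("m", MIRNA, tx, max_penalty=max_penalty)
        # brute force: oracle-score every window, then the same local-minimum rule
        expected = []
        for tid in sorted(tx):
            seq = tx[tid]
            pens = [oracle_penalty(MIRNA, seq[s : s + 21]) for s in range(len(seq) - 20)]
            for s, p in enumerate(pens):
                if p > max_penalty:
                    continue
                lo, hi = max(0, s - 3), min(len(pens), s + 4)
                if p > min(pens[lo:hi]):
                    continue
                if any(pens[k] == p for k in range(lo, s)):
                    continue
                expected.append((tid, s + 1, p))
        assert [(h.transcript_id, h.site_start, h.penalty) for h in hits] == expected


class TestTPlot:
    def test_identical_tags_counted_at_position(self):
        tx = "A" * 41 + "CGTTGCACGTTGCACGTTGCT" + "A" * 40
        tag = tx[41:61]
        tp = build_tplot({tag: 5}, "TX1", tx)
        assert tp.counts == {42: 5}

    def test_unmatched_tag_contributes_nothing(self):
        tp = build_tplot({"G" * 20: 3}, "TX1", "ACGT" * 30)
        assert tp.counts == {}


class TestCategorize:
    def test_unique_maximum(self):
        tp = TPlot("t", 100, {3: 5, 7: 2, 9: 2})
        assert categorize_peak(tp, 3) == 0

    def test_tied_maximum(self):
        tp = TPlot("t", 100, {3: 5, 7: 5, 9: 2})
        assert categorize_peak(tp, 3) == 1

    def test_median_rules_and_single_read(self):
        tp = TPlot("t", 100, {1: 10, 2: 4, 3: 2, 4: 2})
        assert categorize_peak(tp, 2) == 2  # above median 3
        assert categorize_peak(tp, 3) == 3  # at/below median
        tp1 = TPlot("t", 100, {1: 10, 2: 1})
        assert categorize_peak(tp1, 2) == 4  # single read

    def test_no_tags_is_an_error(self):
        with pytest.raises(InputError):
            categorize_peak(TPlot("t", 100, {1: 2}), 50)

    def test_partition_and_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            n_pos = int(rng.integers(2, 15))
            positions = rng.choice(np.arange(1, 200), size=n_pos, replace=False)
            counts = {int(p): int(c) for p, c in
                      zip(positions, rng.integers(1, 30, size=n_pos))}
            tp = TPlot("t", 200, counts)
            cats = {p: categorize_peak(tp, p) for p in counts}
            assert all(c in (0, 1, 2, 3, 4) for c in cats.values())
            # permute the position labels: categories travel with the counts
            perm = rng.permutation(list(counts))
            remap = {int(old): int(new) for old, new in zip(counts, perm)}
            tp2 = TPlot("t", 200, {remap[p]: c for p, c in counts.items()})
            for p in counts:
                assert categorize_peak(tp2, remap[p]) == cats[p]


class TestPValue:
    def test_extreme_concentration(self):
        tp = TPlot("t", 200, {10: 100})
        assert site_pvalue(tp, 10) < 1e-100

    def test_forced_single_position(self):
        tp = TPlot("t", 1, {1: 1})
        assert site_pvalue(tp, 1) == 1.0

    def test_binomial_matches_multinomial_monte_carlo(self):
        rng = np.random.default_rng(5)
        L, total, k = 50, 40, 3
        draws = rng.multinomial(total, [1 / L] * L, size=100_000)
        emp = float(np.mean(draws[:, 0] >= k))
        p = float(stats.binom.sf(k - 1, total, 1 / L))
        mc_sigma = np.sqrt(p * (1 - p) / 100_000)
        assert abs(emp - p) < 3 * mc_sigma
        tp = TPlot("t", L, {1: k, 2: total - k})
        assert site_pvalue(tp, 1) == pytest.approx(p)


class TestClassAssignment:
    @pytest.mark.parametrize(
        "category,p,expected",
        [
            (0, 0.01, "I"), (0, 0.05, "I"), (1, 0.04, "I"),
            (1, 0.20, "II"), (0, 0.051, "II"), (2, 0.001, "II"), (2, 0.9, "II"),
            (3, 0.001, "III"), (3, 0.9, "III"), (4, 0.001, "III"), (4, 0.9, "III"),
        ],
    )
    def test_rules(self, category, p, expected):
        assert assign_class(category, p) == expected

    def test_total_on_random_grid(self):
        rng = np.random.default_rng(6)
        for _ in range(10_000):
            cat = int(rng.integers(0, 5))
            p = float(rng.random())
            cls = assign_class(cat, p)
            if cat in (0, 1):
                assert cls == ("I" if p <= 0.05 else "II")
            elif cat == 2:
                assert cls == "II"
            else:
                assert cls == "III"

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            assign_class(5, 0.5)
        with pytest.raises(InputError):
            assign_class(0, 1.5)


class TestTpb:
    def test_value(self):
        assert tpb(100, 2_000_000) == pytest.approx(50_000)

    def test_zero(self):
        assert tpb(0, 100) == 0.0

    def test_homogeneity(self):
        assert tpb(100, 2_000_000) == pytest.approx(tpb(300, 6_000_000))

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            tpb(1, 0)


class TestEndToEnd:
    def test_planted_target_recovered_class_one(self, refs, truth, degradome_tags):
        from mirfuse.degradome import annotate_hits

        mid, tid, coord = truth.true_targets[0]
        hits = find_target_sites(mid, truth.true_mirnas[mid], refs.transcriptome)
        hits = annotate_hits(hits, degradome_tags, refs.transcriptome)
        match = [h for h in hits if h.transcript_id == tid and h.cleavage_coord == coord]
        assert match
        assert match[0].category == 0
        assert match[0].cls == "I"
        assert match[0].penalty == 0.0
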