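"""Degradome (PARE) target identification and t-plot peak classification.

A miRNA binds its target site with near-complete antiparallel
complementarity; slicing occurs opposite the bond between miRNA nucleotides
10 and 11 (registers 9 and 11 are also examined to allow for imprecise
cleavage or 5'-end variation).  Candidate sites are scored with a plant
target-prediction penalty scheme: mismatch 1.0, G:U wobble 0.5, gap 2.0,
with penalties doubled at miRNA positions 2-13.  Degradome tags aligned to
the transcript give a t-plot (tag 5'-end count per position); the peak at a
predicted cleavage site is assigned a category:

    4  the peak has exactly one read
    0  unique maximum of the transcript
    1  tied maximum
    2  above the median of covered positions
    3  at or below that median

and a binomial p-value under a uniform positional null.  Category and
p-value combine into confidence classes: Class I = category 0/1 with
p <= 0.05; Class II = category 0/1 with p > 0.05 or any category 2;
Class III = category 3/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import as_dna, is_nucleotide, revcomp

MISMATCH = 1.0
WOBBLE = 0.5
GAP = 2.0
CORE = (2, 13)  # miRNA positions (1-based) with doubled penalties


class InputError(ValueError):
    pass


@dataclass
class TPlot:
    """Per-transcript degradome profile: tag 5'-end counts by 1-based position."""

    transcript_id: str
    length: int
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class SiteAlignment:
    pairs: int
    mismatches: int
    wobbles: int
    gaps: int
    mirna_aligned: str
    site_aligned: str


@dataclass
class DegradomeHit:
    mirna_id: str
    transcript_id: str
    site_start: int  # 1-based first position of the site on the transcript
    site_end: int    # inclusive
    penalty: float
    alignment: SiteAlignment
    cleavage_register: int = 10
    cleavage_coords: dict[int, int] = field(default_factory=dict)  # register -> coordinate
    category: int | None = None
    p: float | None = None
    cls: str | None = None
    categories: dict[str, int | None] = field(default_factory=dict)  # per condition
    pvalues: dict[str, float | None] = field(default_factory=dict)
    tpb: dict[str, float] = field(default_factory=dict)

    @property
    def cleavage_coord(self) -> int:
        return self.cleavage_coords[self.cleavage_register]


def _pos_weight(mirna_pos: int) -> float:
    return 2.0 if CORE[0] <= mirna_pos <= CORE[1] else 1.0


def _pair_penalty(m: str, t: str) -> float:
    """Penalty of miRNA base m opposite target base t (both 5'->3' of their own strand)."""
    if t == {"A": "T", "C": "G", "G": "C", "T": "A"}[m]:
        return 0.0
    if (m, t) in (("G", "T"), ("T", "G")):
        return WOBBLE
    return MISMATCH


def score_target_alignment(
    mirna: str, site: str, band: int = 4
) -> tuple[float, SiteAlignment]:
    """Score the antiparallel duplex of a miRNA and a candidate target site.

    The miRNA (5'->3') is aligned against the site read 3'->5' by banded
    dynamic programming minimizing total penalty; position-dependent weights
    double penalties in the miRNA core (positions 2-13).  Gap penalties use
    the weight of the nearest miRNA position consumed.
    """
    mirna = as_dna(mirna)
    site = as_dna(site)
    if not is_nucleotide(mirna) or not is_nucleotide(site):
        raise InputError("non-nucleotide symbols in input")
    if abs(len(site) - len(mirna)) > band:
        raise InputError("site length outside the allowed envelope")
    srev = site[::-1]  # 3'->5'; position i of mirna faces srev positions
    n, m = len(mirna), len(srev)
    INF = float("inf")
    D = np.full((n + 1, m + 1), INF)
    D[0, 0] = 0.0
    for i in range(0, n + 1):
        for j in range(max(0, i - band), min(m, i + band) + 1):
            if i == 0 and j == 0:
                continue
            best = INF
            w = _pos_weight(i)  # weight of miRNA position i (1-based)
            if i > 0 and j > 0:
                best = D[i - 1, j - 1] + w * _pair_penalty(mirna[i - 1], srev[j - 1])
            if i > 0:
                best = min(best, D[i - 1, j] + w * GAP)
            if j > 0:
                best = min(best, D[i, j - 1] + _pos_weight(min(i + 1, n)) * GAP)
            D[i, j] = best
    penalty = float(D[n, m])

    # traceback for the alignment summary
    i, j = n, m
    pairs = mism = wob = gaps = 0
    ma, sa = [], []
    while i > 0 or j > 0:
        w = _pos_weight(i)
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + w * _pair_penalty(
            mirna[i - 1], srev[j - 1]
        ):
            pen = _pair_penalty(mirna[i - 1], srev[j - 1])
            if pen == 0.0:
                pairs += 1
            elif pen == WOBBLE:
                wob += 1
            else:
                mism += 1
            ma.append(mirna[i - 1])
            sa.append(srev[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + w * GAP:
            gaps += 1
            ma.append(mirna[i - 1])
            sa.append("-")
            i -= 1
        else:
            gaps += 1
            ma.append("-")
            sa.append(srev[j - 1])
            j -= 1
    aln = SiteAlignment(
        pairs=pairs,
        mismatches=mism,
        wobbles=wob,
        gaps=gaps,
        mirna_aligned="".join(reversed(ma)),
        site_aligned="".join(reversed(sa)),
    )
    return penalty, aln


def cleavage_coordinate(site_start: int, site_len: int, register: int) -> int:
    """Transcript coordinate (1-based) of the first nucleotide of the 3'
    cleavage fragment, for a site at ``site_start`` and a given register
    (the miRNA position opposite that nucleotide)."""
    return site_start + site_len - register


def find_target_sites(
    mirna_id: str,
    mirna: str,
    transcriptome: dict[str, str],
    max_penalty: float = 7.0,
    registers: tuple[int, ...] = (9, 10, 11),
) -> list[DegradomeHit]:
    """Exhaustively scan a transcriptome for target sites of one miRNA.

    Every window of miRNA length is scored; windows with penalty <=
    ``max_penalty`` that are strict local minima within +-3 nt are reported
    in deterministic order (transcript id, position), each with cleavage
    coordinates for the requested registers (canonical register 10).
    """
    mirna = as_dna(mirna)
    L = len(mirna)
    if not transcriptome:
        raise InputError("empty transcriptome")
    hits: list[DegradomeHit] = []
    for tid in sorted(transcriptome):
        seq = as_dna(transcriptome[tid])
        if len(seq) < L:
            continue
        penalties = np.full(len(seq) - L + 1, np.inf)
        alns: dict[int, SiteAlignment] = {}
        for s in range(len(seq) - L + 1):
            pen, aln = score_target_alignment(mirna, seq[s : s + L])
            penalties[s] = pen
            alns[s] = aln
        for s in range(len(penalties)):
            if penalties[s] > max_penalty:
                continue
            lo = max(0, s - 3)
            hi = min(len(penalties), s + 4)
            neigh = penalties[lo:hi]
            if penalties[s] > neigh.min():
                continue
            # tie within the neighbourhood: keep the leftmost position
            if any(penalties[k] == penalties[s] for k in range(lo, s)):
                continue
            coords = {r: cleavage_coordinate(s + 1, L, r) for r in registers}
            hits.append(
                DegradomeHit(
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    site_start=s + 1,
                    site_end=s + L,
                    penalty=float(penalties[s]),
                    alignment=alns[s],
                    cleavage_coords=coords,
                )
            )
    return hits


def build_tplot(tags: dict[str, int], transcript_id: str, transcript: str) -> TPlot:
    """Count degradome tag 5' ends per transcript position (exact sense matches).

    A tag matching at several positions contributes once per matching
    position.
    """
    transcript = as_dna(transcript)
    counts: dict[int, int] = {}
    for tag, c in tags.items():
        tag = as_dna(tag)
        start = transcript.find(tag)
        while start != -1:
            pos = start + 1
            counts[pos] = counts.get(pos, 0) + c
            start = transcript.find(tag, start + 1)
    return TPlot(transcript_id=transcript_id, length=len(transcript), counts=counts)


def categorize_peak(tplot: TPlot, position: int) -> int:
    """Category of a t-plot peak at ``position`` (1-based).

    4: the peak has exactly one read; 0: unique maximum; 1: tied maximum;
    2: above the median of covered positions; 3: at or below it.
    """
    count = tplot.counts.get(position, 0)
    if count == 0:
        raise InputError(f"no tags at position {position}")
    if count == 1:
        return 4
    values = np.array(list(tplot.counts.values()))
    vmax = values.max()
    if count == vmax:
        return 0 if (values == vmax).sum() == 1 else 1
    med = float(np.median(values))
    return 2 if count > med else 3


def site_pvalue(tplot: TPlot, position: int, null_model: str = "binomial") -> float:
    """P-value of the peak height at a site under a uniform positional null.

    Tags are thrown uniformly over the transcript's positions; p is the exact
    binomial upper-tail probability of seeing at least the observed count at
    the site.
    """
    if tplot.length <= 0:
        raise InputError("transcript length must be positive")
    n = tplot.total
    if n < 1:
        raise InputError("need at least one tag")
    k = tplot.counts.get(position, 0)
    if null_model != "binomial":
        raise InputError(f"unknown null model {null_model!r}")
    return float(stats.binom.sf(k - 1, n, 1.0 / tplot.length))


def assign_class(category: int, p: float) -> str:
    """Confidence class from peak category and p-value."""
    if category not in (0, 1, 2, 3, 4):
        raise InputError(f"invalid category {category}")
    if not 0.0 <= p <= 1.0:
        raise InputError(f"invalid p-value {p}")
    if category in (0, 1):
        return "I" if p <= 0.05 else "II"
    if category == 2:
        return "II"
    return "III"


def tpb(site_count: int, library_total: int) -> float:
    """Normalized tag abundance: tags per billion library tags."""
    if library_total <= 0:
        raise InputError("library total must be > 0")
    return site_count / library_total * 1_000_000_000


def annotate_hits(
    hits: list[DegradomeHit],
    tags_by_condition: dict[str, dict[str, int]],
    transcriptome: dict[str, str],
    register: int = 10,
) -> list[DegradomeHit]:
    """Attach t-plot category, p-value, class and TPB to candidate hits.

    Category, p-value and TPB are computed per condition; a hit must have
    coverage at the cleavage site in at least one condition.  The reported
    class is the best (I < II < III) over the covered conditions, and the
    representative category/p are those of the condition achieving it.
    """
    order = {"I": 0, "II": 1, "III": 2}
    totals = {cond: sum(t.values()) for cond, t in tags_by_condition.items()}
    tplots: dict[tuple[str, str], TPlot] = {}
    out = []
    for hit in hits:
        hit.cleavage_register = register
        coord = hit.cleavage_coords[register]
        best = None
        for cond, tags in tags_by_condition.items():
            key = (cond, hit.transcript_id)
            if key not in tplots:
                tplots[key] = build_tplot(tags, hit.transcript_id, transcriptome[hit.transcript_id])
            tp = tplots[key]
            count = tp.counts.get(coord, 0)
            hit.tpb[cond] = tpb(count, totals[cond]) if totals[cond] else 0.0
            if count > 0:
                cat = categorize_peak(tp, coord)
                p = site_pvalue(tp, coord)
                cls = assign_class(cat, p)
                hit.categories[cond] = cat
                hit.pvalues[cond] = p
                if best is None or order[cls] < order[best[0]]:
                    best = (cls, cat, p)
            else:
                hit.categories[cond] = None
                hit.pvalues[cond] = None
        if best is None:
            continue
        hit.cls, hit.category, hit.p = best
        out.append(hit)
    return out
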