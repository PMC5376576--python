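"""Hairpin folding and structural validation of miRNA precursor candidates.

A candidate precursor is folded into a single stem-loop (hairpin) secondary
structure and judged against eleven structural criteria widely used for plant
miRNA annotation: bounds on bulge sizes, stem base-pair counts, folding free
energy, hairpin and loop lengths, and the pairing quality of the mature-miRNA
region.

Two folding backends are provided:

``bundled``
    A deterministic maximum-pairing folder (Nussinov-style dynamic program,
    minimum loop 3 nt) that breaks ties in favour of stacked helices and
    reports a calibrated pseudo-energy.  It has no thermodynamic ambition;
    it exists so that the whole pipeline is reproducible with no external
    binary.

``external_mfe``
    Calls the ``RNAfold`` executable (ViennaRNA) when present, returning its
    minimum-free-energy structure and energy.

Structures may also be supplied directly as dot-bracket + energy, bypassing
folding entirely, so that validation is backend-independent.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import as_dna, can_pair, revcomp

MIN_LOOP = 3
_PAIR_W = 4096  # lexicographic weight: maximize pairs first, stacks second
_NEG = np.iinfo(np.int64).min // 4

# Pseudo-energy per pair / per stacked pair (kcal/mol-like units) for the
# bundled backend; calibrated so that genuine miRNA-like stems score well
# below the -15 kcal/mol criterion while sparse pairing does not.
_E_PAIR = 0.3
_E_STACK = 1.5


class FoldError(ValueError):
    """Raised for unfoldable input or malformed supplied structures."""


class StructureError(ValueError):
    """Raised when a structure is not a single hairpin."""


@dataclass
class HairpinStructure:
    """A folded candidate precursor.

    ``mature_span`` is the 0-based half-open interval of the candidate
    mature miRNA on the precursor, or ``None`` when not annotated.
    """

    sequence: str
    dotbracket: str
    mfe: float
    mature_span: tuple[int, int] | None = None

    def pairs(self) -> list[tuple[int, int]]:
        return parse_dotbracket(self.dotbracket)


@dataclass
class HairpinMetrics:
    max_bulge_stem: int
    stem_basepairs: int
    mfe: float
    hairpin_length: int
    loop_length: int
    max_bulge_mature: int
    biased_errors_in_one_bulge_mature: int
    biased_bulges_mature: int
    mismatch_errors_mature: int
    mature_basepairs: int
    mature_paired_fraction: float


@dataclass(frozen=True)
class HairpinThresholds:
    """The eleven structural cut-offs (all strict inequalities)."""

    max_bulge_stem: int = 13          # (1)  bulge in stem < 13 nt
    min_stem_basepairs: int = 15      # (2)  stem base pairs > 15
    max_mfe: float = -15.0            # (3)  free energy < -15 kcal/mol
    min_hairpin_length: int = 49      # (4)  hairpin length > 49 nt
    max_loop_length: int = 351        # (5)  terminal loop < 351 nt
    max_bulge_mature: int = 5         # (6)  bulge in mature region < 5 nt
    max_biased_errors: int = 3        # (7)  biased errors in one bulge < 3
    max_biased_bulges: int = 3        # (8)  biased bulges in mature < 3
    max_mismatch_errors: int = 5      # (9)  mismatch errors in mature < 5
    min_mature_basepairs: int = 11    # (10) mature base pairs > 11
    min_mature_paired_fraction: float = 0.80  # (11) mature bases in stem > 80%


DEFAULT_THRESHOLDS = HairpinThresholds()


@dataclass
class CriteriaVerdict:
    """Per-criterion booleans, numbered 1-11; overall pass is their conjunction."""

    criteria: dict[int, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.criteria.values())


def parse_dotbracket(db: str) -> list[tuple[int, int]]:
    """Parse a dot-bracket string into a sorted base-pair list."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, c in enumerate(db):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise FoldError(f"unbalanced dot-bracket at position {idx}")
            pairs.append((stack.pop(), idx))
        elif c != ".":
            raise FoldError(f"invalid dot-bracket symbol {c!r}")
    if stack:
        raise FoldError("unbalanced dot-bracket: unclosed '('")
    return sorted(pairs)


def pairs_to_dotbracket(pairs: list[tuple[int, int]], n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def _pseudo_energy(pairs: list[tuple[int, int]]) -> float:
    pset = set(pairs)
    stacks = sum(1 for i, j in pairs if (i + 1, j - 1) in pset)
    return round(-(_E_PAIR * len(pairs) + _E_STACK * stacks), 2)


def fold_bundled(seq: str) -> tuple[str, float]:
    """Maximum-pairing fold with stacking tie-break; returns (dot-bracket, energy).

    Dynamic program over two matrices: V[i,j] is the best score with (i,j)
    paired, W[i,j] the best score for the interval.  Scores are
    ``_PAIR_W * pairs + stacks`` so the pair count is maximized first and
    stacking only breaks ties.  Traceback is deterministic (smallest split
    first).
    """
    s = as_dna(seq)
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype="S1")
    pairmat = np.zeros((n, n), dtype=bool)
    for a, b in [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]:
        pairmat |= (arr[:, None] == a.encode()) & (arr[None, :] == b.encode())

    V = np.full((n, n), _NEG, dtype=np.int64)
    W = np.zeros((n, n), dtype=np.int64)

    for d in range(MIN_LOOP + 1, n):
        i = np.arange(0, n - d)
        j = i + d
        inner = np.maximum(W[i + 1, j - 1], V[i + 1, j - 1] + 1)
        vdiag = np.where(pairmat[i, j], _PAIR_W + inner, _NEG)
        V[i, j] = vdiag
        wbest = W[i + 1, j].copy()
        for t in range(MIN_LOOP + 1, d + 1):
            k = i + t
            tail = W[k + 1, j] if t < d else 0
            np.maximum(wbest, V[i, k] + tail, out=wbest)
        W[i, j] = wbest

    pairs: list[tuple[int, int]] = []
    stack: list[tuple[int, int, bool]] = [(0, n - 1, False)]
    while stack:
        i, j, on_v = stack.pop()
        if i >= j:
            continue
        if on_v:
            pairs.append((i, j))
            if (
                j - 1 - (i + 1) > MIN_LOOP
                and V[i + 1, j - 1] > _NEG
                and V[i, j] == _PAIR_W + V[i + 1, j - 1] + 1
            ):
                stack.append((i + 1, j - 1, True))
            else:
                stack.append((i + 1, j - 1, False))
            continue
        if W[i, j] == 0:
            continue
        if W[i, j] == W[i + 1, j]:
            stack.append((i + 1, j, False))
            continue
        for t in range(MIN_LOOP + 1, j - i + 1):
            k = i + t
            tail = W[k + 1, j] if k < j else 0
            if V[i, k] > _NEG and W[i, j] == V[i, k] + tail:
                stack.append((i, k, True))
                if k < j:
                    stack.append((k + 1, j, False))
                break
        else:  # pragma: no cover - DP bookkeeping guarantees a split exists
            raise RuntimeError("traceback failed")

    pairs.sort()
    return pairs_to_dotbracket(pairs, n), _pseudo_energy(pairs)


def fold_external(seq: str) -> tuple[str, float]:
    """Fold with the RNAfold executable (ViennaRNA)."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise FoldError("RNAfold executable not found on PATH")
    rna = as_dna(seq).replace("T", "U")
    out = subprocess.run(
        [exe, "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
    ).stdout.splitlines()
    line = out[1]
    db = line.split()[0]
    energy = float(line[line.index("(", len(db) - 1) + 1 : line.rindex(")")])
    return db, energy


def fold(
    seq: str,
    backend: str = "bundled",
    mature_span: tuple[int, int] | None = None,
    structure: str | None = None,
    energy: float | None = None,
) -> HairpinStructure:
    """Fold a candidate precursor, or wrap a supplied structure.

    When ``structure`` is given it is validated (balanced brackets, length)
    and returned unchanged with the supplied ``energy``.
    """
    seq = as_dna(seq)
    if structure is not None:
        if len(structure) != len(seq):
            raise FoldError("structure/sequence length mismatch")
        parse_dotbracket(structure)
        return HairpinStructure(seq, structure, 0.0 if energy is None else energy, mature_span)
    if not 40 <= len(seq) <= 600:
        raise FoldError(f"sequence length {len(seq)} outside foldable range 40-600")
    if backend == "bundled":
        db, e = fold_bundled(seq)
    elif backend == "external_mfe":
        db, e = fold_external(seq)
    else:
        raise FoldError(f"unknown backend {backend!r}")
    return HairpinStructure(seq, db, e, mature_span)


def _terminal_loops(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Closing pairs of hairpin loops: pairs with no pair nested inside."""
    loops = []
    for i, j in pairs:
        if not any(i < a and b < j for a, b in pairs):
            loops.append((i, j))
    return loops


def _internal_loops(chain: list[tuple[int, int]]) -> list[tuple[int, int, int, int]]:
    """(left_size, right_size, left_start, right_start) between consecutive chain pairs."""
    out = []
    for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
        left = i2 - i1 - 1
        right = j1 - j2 - 1
        if left or right:
            out.append((left, right, i1 + 1, j2 + 1))
    return out


def compute_metrics(structure: HairpinStructure) -> HairpinMetrics:
    """Derive the eleven-criterion metrics from a single-hairpin structure.

    The stem is the chain of pairs from the outermost pair down to the pair
    closing the terminal loop.  An internal loop between consecutive stem
    pairs with equal unpaired runs on both strands is a run of "mismatch
    errors" (counted per position); an unequal one is a "biased bulge" whose
    size is the larger side and whose "biased errors" are the unbalanced
    positions.  Mature-region metrics consider only loops touching the
    annotated mature interval.
    """
    pairs = structure.pairs()
    if not pairs:
        raise StructureError("no base pairs: not a hairpin")
    loops = _terminal_loops(pairs)
    if len(loops) != 1:
        raise StructureError(f"{len(loops)} terminal loops: not a single hairpin")
    chain = pairs  # single terminal loop => pairs form a nested chain
    outer = chain[0]
    closing = loops[0]
    span = structure.mature_span
    ms, me = span if span is not None else (0, 0)

    def in_mature(pos_start: int, size: int) -> int:
        """Number of positions of an unpaired run lying inside the mature interval."""
        if span is None or size == 0:
            return 0
        return max(0, min(pos_start + size, me) - max(pos_start, ms))

    max_bulge_stem = 0
    max_bulge_mature = 0
    biased_errors_mature = 0
    biased_bulges_mature = 0
    mismatch_errors_mature = 0
    for left, right, lstart, rstart in _internal_loops(chain):
        size = max(left, right)
        max_bulge_stem = max(max_bulge_stem, size)
        touches = in_mature(lstart, left) + in_mature(rstart, right)
        if touches == 0:
            continue
        max_bulge_mature = max(max_bulge_mature, size)
        if left == right:
            mismatch_errors_mature += max(in_mature(lstart, left), in_mature(rstart, right))
        else:
            biased_bulges_mature += 1
            biased_errors_mature = max(biased_errors_mature, abs(left - right))

    paired_pos = {p for ij in pairs for p in ij}
    if span is not None:
        mature_bp = sum(1 for p in range(ms, me) if p in paired_pos)
        mature_len = me - ms
        frac = mature_bp / mature_len if mature_len else 0.0
    else:
        mature_bp = 0
        frac = 0.0

    return HairpinMetrics(
        max_bulge_stem=max_bulge_stem,
        stem_basepairs=len(pairs),
        mfe=structure.mfe,
        hairpin_length=outer[1] - outer[0] + 1,
        loop_length=closing[1] - closing[0] - 1,
        max_bulge_mature=max_bulge_mature,
        biased_errors_in_one_bulge_mature=biased_errors_mature,
        biased_bulges_mature=biased_bulges_mature,
        mismatch_errors_mature=mismatch_errors_mature,
        mature_basepairs=mature_bp,
        mature_paired_fraction=frac,
    )


def validate_hairpin(
    metrics: HairpinMetrics, thresholds: HairpinThresholds = DEFAULT_THRESHOLDS
) -> CriteriaVerdict:
    """Apply the eleven structural criteria (strict inequalities) to metrics."""
    t = thresholds
    c = {
        1: metrics.max_bulge_stem < t.max_bulge_stem,
        2: metrics.stem_basepairs > t.min_stem_basepairs,
        3: metrics.mfe < t.max_mfe,
        4: metrics.hairpin_length > t.min_hairpin_length,
        5: metrics.loop_length < t.max_loop_length,
        6: metrics.max_bulge_mature < t.max_bulge_mature,
        7: metrics.biased_errors_in_one_bulge_mature < t.max_biased_errors,
        8: metrics.biased_bulges_mature < t.max_biased_bulges,
        9: metrics.mismatch_errors_mature < t.max_mismatch_errors,
        10: metrics.mature_basepairs > t.min_mature_basepairs,
        11: metrics.mature_paired_fraction > t.min_mature_paired_fraction,
    }
    return CriteriaVerdict(criteria=c)


def extract_hairpin(
    structure: HairpinStructure,
    mature_span: tuple[int, int],
    max_gap: int = 12,
    max_overhang: int = 4,
) -> HairpinStructure | None:
    """Extract the stem-loop containing the mature region from a folded window.

    From the terminal loop overlapping (or nearest to) the mature interval,
    the enclosing chain of pairs is followed outward while the enclosing pair
    (a) is the only branch at its level and (b) is separated from its inner
    neighbour by at most ``max_gap`` unpaired nucleotides per strand.  The
    precursor is trimmed to the outermost retained pair, extended (as
    unpaired context) to cover a mature region that dangles out of the stem
    by up to ``max_overhang`` nucleotides in total — dangling bases count as
    unpaired in the metrics.  Returns ``None`` when the window has no pairs
    or the mature region lies substantially outside the extracted hairpin.
    """
    pairs = structure.pairs()
    if not pairs:
        return None
    # nesting tree: parent = nearest enclosing pair
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    nchildren: dict[tuple[int, int], int] = {p: 0 for p in pairs}
    for p in pairs:
        i, j = p
        enclosing = [q for q in pairs if q[0] < i and j < q[1]]
        par = max(enclosing, key=lambda q: q[0]) if enclosing else None
        parent[p] = par
        if par is not None:
            nchildren[par] += 1

    ms, me = mature_span

    def overlap(p: tuple[int, int]) -> int:
        return max(0, min(p[1] + 1, me) - max(p[0], ms))

    best_chain: list[tuple[int, int]] | None = None
    best_key: tuple[int, int] | None = None
    for closing in _terminal_loops(pairs):
        chain = [closing]
        cur = closing
        while True:
            par = parent[cur]
            if par is None or nchildren[par] != 1:
                break
            if cur[0] - par[0] - 1 > max_gap or par[1] - cur[1] - 1 > max_gap:
                break
            chain.append(par)
            cur = par
        outer = chain[-1]
        key = (overlap(outer), -outer[0])
        if best_key is None or key > best_key:
            best_key = key
            best_chain = chain
    assert best_chain is not None
    a, b = best_chain[-1]
    # allow the mature to dangle slightly outside the stem; larger excursions
    # mean the read is not on this hairpin's arm
    a2 = min(a, ms)
    b2 = max(b, me - 1)
    if (a - a2) + (b2 - b) > max_overhang:
        return None
    sub_pairs = sorted((i - a2, j - a2) for i, j in best_chain)
    sub = structure.sequence[a2 : b2 + 1]
    db = pairs_to_dotbracket(sub_pairs, len(sub))
    return HairpinStructure(
        sequence=sub,
        dotbracket=db,
        mfe=_pseudo_energy(sub_pairs),
        mature_span=(ms - a2, me - a2),
    )


@dataclass
class NovelCandidate:
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    arm: str
    precursor: HairpinStructure
    metrics: HairpinMetrics
    verdict: CriteriaVerdict


def call_novel(
    unmapped_seqs,
    genome: dict[str, str],
    flank: int = 120,
    backend: str = "bundled",
    thresholds: HairpinThresholds = DEFAULT_THRESHOLDS,
) -> list[NovelCandidate]:
    """Screen unmapped reads for novel miRNA candidates.

    Each read with a perfect genome match is extended by ``flank`` nt and
    folded in two candidate windows (read as 5' arm and as 3' arm); the
    stem-loop containing the read is extracted and validated against the
    eleven criteria.  Candidates passing all criteria are reported with
    their locus; one candidate per (chrom, locus, strand).
    """
    out: list[NovelCandidate] = []
    seen: set[tuple[str, int, str]] = set()
    for seq in sorted(set(unmapped_seqs)):
        seq = as_dna(seq)
        for chrom in sorted(genome):
            g = genome[chrom]
            for strand in "+-":
                text = g if strand == "+" else revcomp(g)
                start = text.find(seq)
                while start != -1:
                    end = start + len(seq)
                    gstart = start if strand == "+" else len(g) - end
                    key = (chrom, gstart, strand)
                    if key in seen:
                        start = text.find(seq, start + 1)
                        continue
                    windows = [
                        ("5p", max(0, start - 20), min(len(text), end + flank)),
                        ("3p", max(0, start - flank), min(len(text), end + 20)),
                    ]
                    for arm, ws, we in windows:
                        if we - ws < 40:
                            continue
                        span = (start - ws, end - ws)
                        folded = fold(text[ws:we], backend=backend, mature_span=span)
                        hp = extract_hairpin(folded, span)
                        if hp is None:
                            continue
                        try:
                            metrics = compute_metrics(hp)
                        except StructureError:
                            continue
                        verdict = validate_hairpin(metrics, thresholds)
                        if verdict.passed:
                            seen.add(key)
                            out.append(
                                NovelCandidate(
                                    sequence=seq,
                                    chrom=chrom,
                                    start=gstart,
                                    end=gstart + len(seq),
                                    strand=strand,
                                    arm=arm,
                                    precursor=hp,
                                    metrics=metrics,
                                    verdict=verdict,
                                )
                            )
                            break
                    start = text.find(seq, start + 1)
    return out
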