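"""Known-miRNA and isomiR identification against a precursor/mature database.

Unique retained sequences are mapped to annotated mature miRNAs on their
precursors, allowing length variation at the 5'/3' ends and at most one
internal mismatch.  Variants are named in a compact suffix dialect:

    _L+n / _L-n    5' end extended / trimmed by n nt
    _R+n / _R-n    3' end extended / trimmed by n nt
    _1ss<pos><ref><obs>   single substitution at 1-based position pos
                          (reference base -> observed base, DNA alphabet)

so e.g. ``miR159c-3p_L-1R-1`` is the annotated mature trimmed by one
nucleotide at each end, and ``miR156b-3p_1ss6TC`` carries a T->C change at
position 6.  Applying the named transformation to the database mature always
reproduces the observed sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from ._seq import as_dna, revcomp
from .preprocess import ReadLibrary


class DatabaseError(ValueError):
    pass


class NotNameable(ValueError):
    """Observed sequence is outside the shift/substitution envelope."""


@dataclass
class MatureRecord:
    name: str
    sequence: str
    precursor_id: str
    start: int  # position of the mature on its precursor
    end: int


@dataclass
class PrecursorDB:
    precursors: dict[str, str]
    matures: list[MatureRecord]


@dataclass
class MiRNACall:
    sequence: str
    status: str  # known_mature | isoform_same_arm | isoform_other_arm | unmapped
    base_name: str = ""
    suffix: str = ""
    precursor_id: str = ""
    mismatch: tuple[int, str, str] | None = None  # (1-based pos, ref, obs)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.base_name + self.suffix if self.base_name else ""


@dataclass
class CompositionStats:
    length_hist: dict[int, float]
    first_nt: dict[str, float]


def build_db(precursors: dict[str, str], matures: dict[str, tuple[str, str]]) -> PrecursorDB:
    """Assemble a database from precursor sequences and mature annotations.

    ``matures`` maps mature name -> (sequence, precursor id); the mature must
    occur in its precursor (its arm coordinates are located by exact search).
    """
    if len(set(precursors)) != len(precursors):
        raise DatabaseError("duplicate precursor ids")
    precs = {k: as_dna(v) for k, v in precursors.items()}
    recs = []
    for name, (seq, pid) in matures.items():
        seq = as_dna(seq)
        if pid not in precs:
            raise DatabaseError(f"mature {name}: unknown precursor {pid}")
        pos = precs[pid].find(seq)
        if pos < 0:
            raise DatabaseError(f"mature {name} not found in precursor {pid}")
        recs.append(MatureRecord(name, seq, pid, pos, pos + len(seq)))
    return PrecursorDB(precursors=precs, matures=recs)


def name_isomir(mature: str, observed: str, offset: int) -> str:
    """Name an isomiR relative to its database mature.

    ``offset`` is the position of the observed 5' end relative to the mature
    5' end on the precursor (negative = observed extends upstream).  Raises
    :class:`NotNameable` for more than one internal substitution.
    """
    mature = as_dna(mature)
    observed = as_dna(observed)
    d5 = -offset  # +n: observed 5' end extended upstream by n
    d3 = (offset + len(observed)) - len(mature)
    ends = ""
    if d5:
        ends += f"L{d5:+d}"
    if d3:
        ends += f"R{d3:+d}"
    parts = [f"_{ends}"] if ends else []
    # compare over the overlap of observed with the (shifted) mature
    subs = []
    for i, obs_base in enumerate(observed):
        mpos = offset + i
        if 0 <= mpos < len(mature):
            if mature[mpos] != obs_base:
                subs.append((i + 1, mature[mpos], obs_base))
    if len(subs) > 1:
        raise NotNameable(f"{len(subs)} substitutions")
    for pos, ref, obs in subs:
        parts.append(f"_1ss{pos}{ref}{obs}")
    return "".join(parts)


def apply_suffix(mature: str, suffix: str, precursor: str, mature_start: int) -> str:
    """Reconstruct the observed sequence named by ``mature + suffix``.

    End extensions draw their bases from the precursor context; used for the
    round-trip property that a suffix always parses back to the
    transformation it names.
    """
    import re

    s5 = s3 = 0
    sub = None
    m = re.search(r"L([+-]\d+)", suffix)
    if m:
        s5 = int(m.group(1))
    m = re.search(r"R([+-]\d+)", suffix)
    if m:
        s3 = int(m.group(1))
    m = re.search(r"_1ss(\d+)([ACGT])([ACGT])", suffix)
    if m:
        sub = (int(m.group(1)), m.group(2), m.group(3))
    start = mature_start - s5
    end = mature_start + len(mature) + s3
    if start < 0 or end > len(precursor):
        raise NotNameable("extension outside precursor")
    seq = list(precursor[start:end])
    if sub is not None:
        pos, ref, obs = sub
        if seq[pos - 1] != ref:
            raise NotNameable("substitution reference base mismatch")
        seq[pos - 1] = obs
    return "".join(seq)


def _align_to_precursor(seq: str, prec: str, max_mm: int) -> list[tuple[int, int]]:
    """All (offset, n_mismatches) ungapped placements of seq on prec with <= max_mm."""
    out = []
    for off in range(0, len(prec) - len(seq) + 1):
        mm = sum(1 for a, b in zip(seq, prec[off : off + len(seq)]) if a != b)
        if mm <= max_mm:
            out.append((off, mm))
    return out


def map_to_precursors(
    unique_seqs,
    db: PrecursorDB,
    max_end_shift: int = 2,
    max_internal_mismatch: int = 1,
) -> list[MiRNACall]:
    """Assign each unique sequence to its best-matching mature annotation.

    A placement is in the envelope of a mature when both ends lie within
    ``max_end_shift`` of the annotated ends and it carries at most
    ``max_internal_mismatch`` substitutions (at internal positions 2..L-1 of
    the observed read).  Best match = fewest mismatches, then smallest total
    end shift, then lexicographically smallest precursor id.  Placements on
    the precursor outside any mature envelope give arm isoforms.
    """
    by_prec: dict[str, list[MatureRecord]] = {}
    for rec in db.matures:
        by_prec.setdefault(rec.precursor_id, []).append(rec)

    calls = []
    for seq in sorted(set(as_dna(s) for s in unique_seqs)):
        candidates = []  # (mm, end_shift, prec_id, kind, rec, offset)
        for pid in sorted(db.precursors):
            prec = db.precursors[pid]
            for off, mm in _align_to_precursor(seq, prec, max_internal_mismatch):
                # mismatches must be internal (not at the first/last base)
                mpos = [
                    i
                    for i in range(len(seq))
                    if seq[i] != prec[off + i]
                ]
                if any(i == 0 or i == len(seq) - 1 for i in mpos):
                    continue
                for rec in by_prec.get(pid, []):
                    shift5 = off - rec.start
                    shift3 = (off + len(seq)) - rec.end
                    if abs(shift5) <= max_end_shift and abs(shift3) <= max_end_shift:
                        kind = "mature" if (mm == 0 and shift5 == 0 and shift3 == 0) else "same_arm"
                        candidates.append(
                            (mm, abs(shift5) + abs(shift3), pid, kind, rec, off)
                        )
                    else:
                        candidates.append((mm, abs(shift5) + abs(shift3), pid, "other_arm", rec, off))
        if not candidates:
            calls.append(MiRNACall(sequence=seq, status="unmapped"))
            continue
        candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3] != "mature", c[3] != "same_arm"))
        mm, _, pid, kind, rec, off = candidates[0]
        if kind == "mature":
            calls.append(
                MiRNACall(
                    sequence=seq,
                    status="known_mature",
                    base_name=rec.name,
                    suffix="",
                    precursor_id=pid,
                )
            )
        elif kind == "same_arm":
            suffix = name_isomir(rec.sequence, seq, off - rec.start)
            mismatch = None
            for i in range(len(seq)):
                if seq[i] != db.precursors[pid][off + i]:
                    mismatch = (i + 1, db.precursors[pid][off + i], seq[i])
            calls.append(
                MiRNACall(
                    sequence=seq,
                    status="isoform_same_arm",
                    base_name=rec.name,
                    suffix=suffix,
                    precursor_id=pid,
                    mismatch=mismatch,
                )
            )
        else:
            calls.append(
                MiRNACall(
                    sequence=seq,
                    status="isoform_other_arm",
                    base_name=rec.name,
                    suffix=f"_arm{off}",
                    precursor_id=pid,
                )
            )
    return calls


@dataclass
class GenomeLocus:
    chrom: str
    start: int
    end: int
    strand: str
    identity: float


def map_precursor_to_genome(
    precursor: str,
    genome: dict[str, str],
    min_identity: float = 0.90,
    min_coverage: float = 0.95,
) -> list[GenomeLocus]:
    """Locate a precursor on the genome by local alignment on both strands.

    Loci with identity >= ``min_identity`` over at least ``min_coverage`` of
    the precursor length are reported (0-based half-open, with strand).
    Alignment is edit-distance based (edlib, infix mode).
    """
    precursor = as_dna(precursor)
    n = len(precursor)
    max_dist = int(n * (1.0 - min_identity))
    loci = []
    for chrom in sorted(genome):
        text = as_dna(genome[chrom])
        for strand in "+-":
            query = precursor if strand == "+" else revcomp(precursor)
            res = edlib.align(query, text, mode="HW", task="locations", k=max_dist)
            if res["editDistance"] < 0:
                continue
            seen: set[tuple[int, int]] = set()
            for s, e in res["locations"]:
                e = e + 1
                if (e - s) < min_coverage * n:
                    continue
                if any(abs(s - ps) < n // 2 for ps, _ in seen):
                    continue
                seen.add((s, e))
                identity = 1.0 - res["editDistance"] / n
                loci.append(GenomeLocus(chrom, s, e, strand, round(identity, 4)))
    return loci


def composition_stats(calls: list[MiRNACall], retained: list[ReadLibrary]) -> CompositionStats:
    """Length histogram (count-weighted, over retained reads) and first-nucleotide
    fractions (over unique known-miRNA sequences, unweighted)."""
    if not retained:
        raise ValueError("no retained libraries")
    length_counts: Counter = Counter()
    for lib in retained:
        for seq, c in lib.counts.items():
            length_counts[len(seq)] += c
    total = sum(length_counts.values())
    hist = {length: c / total for length, c in sorted(length_counts.items())} if total else {}

    known = sorted(
        {c.sequence for c in calls if c.status in ("known_mature", "isoform_same_arm", "isoform_other_arm")}
    )
    first = Counter(seq[0] for seq in known)
    nuniq = len(known)
    first_nt = {b: (first.get(b, 0) / nuniq if nuniq else 0.0) for b in "ACGT"}
    # report U rather than T for the RNA reading
    first_nt["U"] = first_nt.pop("T")
    return CompositionStats(length_hist=hist, first_nt=first_nt)
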