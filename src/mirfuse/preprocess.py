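"""Adapter trimming, length filtering and hierarchical read classification.

Raw small-RNA reads are trimmed of their 3' sequencing adapter, filtered to a
retained length window, and assigned to exactly one accounting category by a
fixed first-match hierarchy mirroring the usual composition table of a
small-RNA library:

    3ADT&length -> junk -> rRNA -> tRNA -> snoRNA -> snRNA -> other Rfam
    -> mRNA -> repeats -> retained

A read matches a contaminant category when it is an exact substring of any
reference sequence of that category, on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import as_dna, revcomp

#: classification order; first match wins
CATEGORY_ORDER = (
    "3ADT&length",
    "junk",
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "other_Rfam",
    "mRNA",
    "repeats",
)

REFERENCE_CATEGORIES = ("rRNA", "tRNA", "snoRNA", "snRNA", "other_Rfam", "mRNA", "repeats")


class ConfigError(ValueError):
    pass


@dataclass
class ReadLibrary:
    """Unique sequences with counts for one sample."""

    counts: dict[str, int]
    condition: str = ""
    replicate: str = ""
    total_raw: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def unique(self) -> int:
        return len(self.counts)

    @property
    def sample(self) -> str:
        return f"{self.condition}_{self.replicate}" if self.replicate else self.condition


@dataclass
class FilterReport:
    """Per-category total/unique read accounting for one sample."""

    sample: str
    raw_total: int
    raw_unique: int
    categories: dict[str, tuple[int, int]] = field(default_factory=dict)  # name -> (total, unique)
    valid_total: int = 0
    valid_unique: int = 0

    def percentages(self) -> dict[str, float]:
        """Category totals as percent of raw reads."""
        if self.raw_total == 0:
            return {k: 0.0 for k in self.categories}
        out = {k: 100.0 * t / self.raw_total for k, (t, _) in self.categories.items()}
        out["valid"] = 100.0 * self.valid_total / self.raw_total
        return out

    def to_rows(self) -> list[dict]:
        rows = [
            {
                "category": "Raw reads",
                "total": self.raw_total,
                "unique": self.raw_unique,
                "pct_total": 100.0,
            },
            {
                "category": "Valid reads",
                "total": self.valid_total,
                "unique": self.valid_unique,
                "pct_total": round(100.0 * self.valid_total / max(1, self.raw_total), 2),
            },
        ]
        for cat in CATEGORY_ORDER:
            t, u = self.categories.get(cat, (0, 0))
            rows.append(
                {
                    "category": cat,
                    "total": t,
                    "unique": u,
                    "pct_total": round(100.0 * t / max(1, self.raw_total), 2),
                }
            )
        return rows

    @classmethod
    def from_rows(cls, sample: str, rows: list[dict]) -> "FilterReport":
        by = {r["category"]: (int(r["total"]), int(r["unique"])) for r in rows}
        rep = cls(
            sample=sample,
            raw_total=by["Raw reads"][0],
            raw_unique=by["Raw reads"][1],
            valid_total=by["Valid reads"][0],
            valid_unique=by["Valid reads"][1],
        )
        rep.categories = {cat: by[cat] for cat in CATEGORY_ORDER if cat in by}
        return rep


def is_junk(seq: str) -> bool:
    """Low-complexity ("junk") read rule.

    True when any single base makes up >=80% of the read, a mono- or
    di-nucleotide repeat covers >=90% of it, or it contains a non-ACGT
    symbol.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if any(c not in "ACGT" for c in seq):
        return True
    n = len(seq)
    if max(seq.count(c) for c in "ACGT") >= 0.8 * n:
        return True
    for a in "ACGT":
        for b in "ACGT":
            unit = a + b
            rep = (unit * (n // 2 + 1))[:n]
            same = sum(1 for x, y in zip(seq, rep) if x == y)
            same_shift = sum(1 for x, y in zip(seq, (unit * (n // 2 + 1))[1 : n + 1]) if x == y)
            if max(same, same_shift) >= 0.9 * n:
                return True
    return False


def trim_adapter(
    reads: dict[str, int],
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_frac: float = 0.10,
) -> tuple[dict[str, int], dict[str, int]]:
    """Trim a 3' adapter from raw reads.

    The adapter is located by the best suffix-prefix match (adapter prefix
    against a read suffix-to-end region) with at most ``max_mismatch_frac``
    mismatches and at least ``min_overlap`` matched bases.  Returns
    ``(trimmed, no_adapter)`` count dictionaries; reads without an adapter
    hit go to ``no_adapter`` (the 3ADT&length category).
    """
    if not adapter:
        raise ConfigError("adapter must be nonempty")
    adapter = as_dna(adapter)
    trimmed: dict[str, int] = {}
    no_adapter: dict[str, int] = {}
    for read, count in reads.items():
        read = as_dna(read)
        hit = None
        for start in range(0, len(read) - min_overlap + 1):
            ov = min(len(adapter), len(read) - start)
            mism = sum(1 for a, b in zip(read[start : start + ov], adapter[:ov]) if a != b)
            if mism <= max_mismatch_frac * ov:
                hit = start
                break
        if hit is None:
            no_adapter[read] = no_adapter.get(read, 0) + count
        else:
            insert = read[:hit]
            if insert:
                trimmed[insert] = trimmed.get(insert, 0) + count
            else:
                no_adapter[read] = no_adapter.get(read, 0) + count
    return trimmed, no_adapter


def _match_any(read: str, texts: list[str]) -> bool:
    return any(read in t for t in texts)


def classify_reads(
    library: ReadLibrary,
    refs: dict[str, list[str]],
    length_window: tuple[int, int] = (18, 25),
    prefiltered: dict[str, int] | None = None,
) -> tuple[ReadLibrary, FilterReport]:
    """Assign every read to exactly one category; return retained reads + report.

    ``refs`` maps category name (rRNA, tRNA, snoRNA, snRNA, other_Rfam, mRNA,
    repeats) to reference sequences; matching is exact-substring on either
    strand.  ``prefiltered`` holds reads already removed by adapter trimming
    (counted under 3ADT&length).
    """
    lo, hi = length_window
    if lo > hi:
        raise ConfigError(f"invalid length window {length_window}")
    texts: dict[str, list[str]] = {}
    for cat in REFERENCE_CATEGORIES:
        seqs = [as_dna(s) for s in refs.get(cat, [])]
        texts[cat] = seqs + [revcomp(s) for s in seqs]

    cat_counts: dict[str, list[int]] = {c: [0, 0] for c in CATEGORY_ORDER}
    retained: dict[str, int] = {}
    pre = dict(prefiltered or {})
    for read, count in pre.items():
        cat_counts["3ADT&length"][0] += count
        cat_counts["3ADT&length"][1] += 1

    for read, count in library.counts.items():
        read = as_dna(read)
        if not lo <= len(read) <= hi:
            cat = "3ADT&length"
        elif is_junk(read):
            cat = "junk"
        else:
            for cat in REFERENCE_CATEGORIES:
                if _match_any(read, texts[cat]):
                    break
            else:
                cat = None
        if cat is None:
            retained[read] = retained.get(read, 0) + count
        else:
            cat_counts[cat][0] += count
            cat_counts[cat][1] += 1

    raw_total = library.total + sum(pre.values())
    raw_unique = library.unique + len(pre)
    out = ReadLibrary(
        counts=retained,
        condition=library.condition,
        replicate=library.replicate,
        total_raw=raw_total,
    )
    report = FilterReport(
        sample=library.sample,
        raw_total=raw_total,
        raw_unique=raw_unique,
        categories={c: (t, u) for c, (t, u) in cat_counts.items()},
        valid_total=sum(retained.values()),
        valid_unique=len(retained),
    )
    return out, report
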