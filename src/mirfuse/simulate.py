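"""Synthetic data generator with planted ground truth.

Emulates the study design the pipeline analyses: two ovary phenotypes (IFC,
CFC) x two replicate small-RNA libraries, a genome carrying miRNA precursor
hairpins (a subset withheld from the annotation database to act as novel
miRNAs), a transcriptome with complementary target sites, degradome tag
libraries concentrated at the position pairing miRNA nucleotide 10, a
contaminant background (rRNA/tRNA/snoRNA/snRNA/other Rfam/mRNA/repeats/junk)
at configurable fractions, and hormone time courses (2 phenotypes x 4
stages, n = 8 paired observations) with planted correlation signs.

Counts follow a Poisson model per (sequence, sample); planted
differentially expressed miRNAs differ between conditions by a configured
fold change in expectation.  Every output is a deterministic function of
the configuration, including its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import random_seq, revcomp
from .annotate import PrecursorDB, build_db
from .degradome import cleavage_coordinate
from .hairpin import compute_metrics, fold, validate_hairpin
from .hormones import HORMONES, PHENOTYPES, STAGES
from .preprocess import ReadLibrary


class SizingError(ValueError):
    pass


class SimInputError(ValueError):
    pass


def _default_contaminants() -> dict[str, float]:
    # fractions loosely shaped like a real maize ovary library composition
    return {
        "rRNA": 0.055,
        "tRNA": 0.02,
        "snoRNA": 0.003,
        "snRNA": 0.002,
        "other_Rfam": 0.004,
        "mRNA": 0.045,
        "repeats": 0.002,
        "junk": 0.005,
        "length_filter": 0.01,
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_precursors: int = 12
    n_novel: int = 2
    genome_length: int = 30_000
    mature_length_range: tuple[int, int] = (20, 22)
    u_start_fraction: float = 0.6  # planted 5'-uridine bias of mature miRNAs
    conditions: tuple[str, ...] = ("IFC", "CFC")
    replicates_per_condition: int = 2
    n_de: int = 4
    planted_fc: float = 4.0
    library_depth: int = 60_000
    isomir_fraction: float = 0.15
    contaminant_fractions: dict[str, float] = field(default_factory=_default_contaminants)
    n_transcripts: int = 10
    transcript_length: int = 300
    n_targets: int = 6
    degradome_tags_per_target: int = 500
    degradome_background_per_transcript: int = 40
    degradome_signal_fraction: float = 0.8
    tag_length: int = 20
    hormone_r: float = 0.9
    hormone_noise: float = 0.1
    n_hormone_assoc: int = 6

    def validate(self) -> None:
        if self.planted_fc <= 0:
            raise SimInputError("planted_fc must be > 0")
        if sum(self.contaminant_fractions.values()) > 1:
            raise SimInputError("contaminant fractions must sum to <= 1")
        if not 0 <= self.degradome_signal_fraction <= 1:
            raise SimInputError("degradome_signal_fraction must be in [0,1]")
        lo, hi = self.mature_length_range
        if lo > hi or lo < 16:
            raise SimInputError("invalid mature length range")


@dataclass
class PrecursorRecord:
    id: str
    sequence: str
    mature: str
    mature_span: tuple[int, int]
    chrom: str
    start: int
    end: int
    novel: bool


@dataclass
class References:
    genome: dict[str, str]
    precursors: dict[str, PrecursorRecord]
    db: PrecursorDB  # known (non-novel) precursors + matures
    transcriptome: dict[str, str]
    contaminants: dict[str, list[str]]


@dataclass
class TruthSet:
    true_mirnas: dict[str, str]             # miRNA id -> mature sequence
    mirna_precursor: dict[str, str]         # miRNA id -> precursor id
    novel_mirnas: set[str]
    isomirs: dict[str, tuple[str, str]]     # variant seq -> (parent id, suffix)
    true_de: dict[str, str]                 # miRNA id -> planted direction
    true_targets: list[tuple[str, str, int]]  # (miRNA id, transcript id, cleavage coord)
    true_hormone_assoc: list[tuple[str, str, int]]  # (series id, hormone, sign)


def _make_precursor(
    rng: np.random.Generator, length_range: tuple[int, int], u_start: float = 0.0
) -> tuple[str, str, tuple[int, int]]:
    """One hairpin precursor: mature + loop + perfect star arm, validated."""
    for _ in range(200):
        mlen = int(rng.integers(length_range[0], length_range[1] + 1))
        mature = random_seq(rng, mlen)
        if rng.random() < u_start:
            mature = "T" + mature[1:]
        loop = random_seq(rng, int(rng.integers(10, 16)))
        # short unpaired-by-design flanks give isomiR end variants context
        prec = random_seq(rng, 3) + mature + loop + revcomp(mature) + random_seq(rng, 3)
        structure = fold(prec, mature_span=(3, 3 + mlen))
        try:
            metrics = compute_metrics(structure)
        except ValueError:
            continue
        if validate_hairpin(metrics).passed:
            return prec, mature, (3, 3 + mlen)
    raise RuntimeError("could not generate a valid precursor in 200 attempts")


def gen_reference(config: SimConfig) -> References:
    """Genome, precursors, transcriptome and contaminant reference sets."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    precs: dict[str, PrecursorRecord] = {}
    matures: dict[str, tuple[str, str]] = {}
    seen_matures: set[str] = set()
    for i in range(config.n_precursors):
        while True:
            seq, mature, span = _make_precursor(
                rng, config.mature_length_range, config.u_start_fraction
            )
            if mature not in seen_matures:
                seen_matures.add(mature)
                break
        novel = i >= config.n_precursors - config.n_novel
        pid = f"syn-MIR{i + 1:03d}"
        precs[pid] = PrecursorRecord(
            id=pid, sequence=seq, mature=mature, mature_span=span,
            chrom="chr1", start=-1, end=-1, novel=novel,
        )
        if not novel:
            matures[f"syn-miR{i + 1:03d}-5p"] = (mature, pid)

    # place precursors on a random genome, well separated so the 120-nt
    # flanking windows of one never reach into another
    slot = 400
    needed = config.n_precursors * slot + 200
    if config.genome_length < needed:
        raise SizingError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_precursors} precursors (need >= {needed})"
        )
    genome = list(random_seq(rng, config.genome_length))
    starts = rng.permutation(config.n_precursors)
    for idx, pid in enumerate(sorted(precs)):
        start = 100 + int(starts[idx]) * slot
        rec = precs[pid]
        genome[start : start + len(rec.sequence)] = rec.sequence
        rec.start = start
        rec.end = start + len(rec.sequence)
    genome_s = "".join(genome)

    # transcriptome with planted complementary target sites
    known = [pid for pid in sorted(precs) if not precs[pid].novel]
    transcriptome: dict[str, str] = {}
    for t in range(config.n_transcripts):
        tid = f"TX{t + 1:03d}"
        seq = list(random_seq(rng, config.transcript_length))
        if t < config.n_targets:
            rec = precs[known[t % len(known)]]
            site = revcomp(rec.mature)
            smax = config.transcript_length - len(site) - config.tag_length - 10
            s = int(rng.integers(50, smax))
            seq[s : s + len(site)] = site
        transcriptome[tid] = "".join(seq)

    # the mRNA reference is distinct from the target-carrying transcriptome:
    # planted target sites are antisense-complementary to planted matures and
    # would otherwise swallow the miRNAs in the filtering cascade
    contaminants = {
        cat: [random_seq(rng, int(rng.integers(150, 400))) for _ in range(2)]
        for cat in ("rRNA", "tRNA", "snoRNA", "snRNA", "other_Rfam", "repeats", "mRNA")
    }

    db = build_db({pid: precs[pid].sequence for pid in known}, matures)
    return References(
        genome={"chr1": genome_s},
        precursors=precs,
        db=db,
        transcriptome=transcriptome,
        contaminants=contaminants,
    )


def _mirna_ids(refs: References) -> tuple[list[str], dict[str, PrecursorRecord]]:
    ids = []
    by_id = {}
    for pid in sorted(refs.precursors):
        rec = refs.precursors[pid]
        mid = f"syn-miR{pid[7:]}-5p"
        ids.append(mid)
        by_id[mid] = rec
    return ids, by_id


def _variant_of(rng: np.random.Generator, rec: PrecursorRecord, kind: int) -> tuple[str, str]:
    """A single isomiR variant of a planted mature: end shift or substitution."""
    prec, (ms, me) = rec.sequence, rec.mature_span
    if kind == 0 and ms >= 1:  # 5' extension
        return prec[ms - 1 : me], "_L+1"
    if kind == 1 and me < len(prec):  # 3' extension
        return prec[ms : me + 1], "_R+1"
    if kind == 2:  # 3' trim
        return prec[ms : me - 1], "_R-1"
    # internal substitution at a fixed interior position
    seq = list(prec[ms:me])
    pos = int(rng.integers(2, len(seq) - 1))
    ref = seq[pos]
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    seq[pos] = alt
    return "".join(seq), f"_1ss{pos + 1}{ref}{alt}"


def gen_sread_libraries(
    config: SimConfig, refs: References
) -> tuple[list[ReadLibrary], TruthSet]:
    """Per-sample small-RNA read libraries plus the planted truth."""
    if not refs.precursors:
        raise SimInputError("empty references")
    rng = np.random.default_rng([config.seed, 2])
    ids, by_id = _mirna_ids(refs)

    # planted DE set: first n_de known miRNAs, alternating direction
    known_ids = [m for m in ids if not by_id[m].novel]
    true_de = {
        mid: ("up" if k % 2 == 0 else "down")
        for k, mid in enumerate(known_ids[: config.n_de])
    }

    weights = rng.uniform(0.5, 1.5, size=len(ids))
    mirna_fraction = 1.0 - sum(config.contaminant_fractions.values())
    base_total = config.library_depth * mirna_fraction
    base = base_total * weights / weights.sum()

    isomirs: dict[str, tuple[str, str]] = {}
    variant_for: dict[str, tuple[str, str]] = {}
    for k, mid in enumerate(ids):
        var_seq, suffix = _variant_of(rng, by_id[mid], k % 4)
        variant_for[mid] = (var_seq, suffix)
        isomirs[var_seq] = (mid, suffix)

    # contaminant fragment pools (fixed across samples)
    pools: dict[str, list[str]] = {}
    for cat, frac in config.contaminant_fractions.items():
        if frac == 0:
            pools[cat] = []
            continue
        frags = []
        if cat == "junk":
            for _ in range(20):
                unit = "AT" if rng.random() < 0.5 else random_seq(rng, 1) * 2
                n = int(rng.integers(18, 26))
                frags.append((unit * 15)[:n])
        elif cat == "length_filter":
            for _ in range(20):
                n = int(rng.integers(15, 18))
                frags.append(random_seq(rng, n))
        else:
            sources = refs.contaminants.get(cat, [])
            for _ in range(30):
                src = sources[int(rng.integers(len(sources)))]
                n = int(rng.integers(18, 26))
                s = int(rng.integers(0, len(src) - n))
                frags.append(src[s : s + n])
        pools[cat] = frags

    libraries: list[ReadLibrary] = []
    for cond in config.conditions:
        for rep in range(1, config.replicates_per_condition + 1):
            counts: dict[str, int] = {}

            def add(seq: str, n: int) -> None:
                if n > 0:
                    counts[seq] = counts.get(seq, 0) + int(n)

            for k, mid in enumerate(ids):
                mean = base[k]
                direction = true_de.get(mid)
                if direction == "up" and cond == config.conditions[0]:
                    mean *= config.planted_fc
                elif direction == "down" and cond != config.conditions[0]:
                    mean *= config.planted_fc
                var_seq, _ = variant_for[mid]
                add(by_id[mid].mature, rng.poisson(mean * (1 - config.isomir_fraction)))
                add(var_seq, rng.poisson(mean * config.isomir_fraction))

            for cat, frac in config.contaminant_fractions.items():
                frags = pools[cat]
                if not frags:
                    continue
                per = config.library_depth * frac / len(frags)
                for fseq in frags:
                    add(fseq, rng.poisson(per))

            libraries.append(
                ReadLibrary(
                    counts=counts,
                    condition=cond,
                    replicate=f"r{rep}",
                    total_raw=sum(counts.values()),
                )
            )

    # planted degradome targets: transcripts TX001..TX{n_targets}
    known_precs = [pid for pid in sorted(refs.precursors) if not refs.precursors[pid].novel]
    true_targets = []
    for t in range(config.n_targets):
        tid = f"TX{t + 1:03d}"
        rec = refs.precursors[known_precs[t % len(known_precs)]]
        site = revcomp(rec.mature)
        s = refs.transcriptome[tid].find(site)
        assert s >= 0
        coord = cleavage_coordinate(s + 1, len(site), 10)
        mid = f"syn-miR{rec.id[7:]}-5p"
        true_targets.append((mid, tid, coord))

    truth = TruthSet(
        true_mirnas={mid: by_id[mid].mature for mid in ids},
        mirna_precursor={mid: by_id[mid].id for mid in ids},
        novel_mirnas={mid for mid in ids if by_id[mid].novel},
        isomirs=isomirs,
        true_de=true_de,
        true_targets=true_targets,
        true_hormone_assoc=[],
    )
    return libraries, truth


def gen_degradome(
    config: SimConfig, refs: References, truth: TruthSet
) -> dict[str, dict[str, int]]:
    """Degradome tag libraries (tag sequence -> count) per condition."""
    if not truth.true_targets:
        raise SimInputError("no planted targets")
    rng = np.random.default_rng([config.seed, 3])
    out: dict[str, dict[str, int]] = {}
    tl = config.tag_length
    for cond in config.conditions:
        tags: dict[str, int] = {}

        def add_tag(transcript: str, pos: int, n: int = 1) -> None:
            tag = transcript[pos - 1 : pos - 1 + tl]
            if len(tag) == tl and n > 0:
                tags[tag] = tags.get(tag, 0) + n

        target_tids = {tid for _, tid, _ in truth.true_targets}
        for mid, tid, coord in truth.true_targets:
            tx = refs.transcriptome[tid]
            if coord + tl - 1 > len(tx):
                warnings.warn(f"target at {tid}:{coord} too close to the 3' end; skipped")
                continue
            n_total = config.degradome_tags_per_target
            n_signal = int(round(config.degradome_signal_fraction * n_total))
            add_tag(tx, coord, n_signal)
            n_bg = n_total - n_signal
            positions = rng.integers(1, len(tx) - tl + 2, size=n_bg)
            for pos in positions:
                add_tag(tx, int(pos))
        for tid in sorted(refs.transcriptome):
            if tid in target_tids:
                continue
            tx = refs.transcriptome[tid]
            positions = rng.integers(
                1, len(tx) - tl + 2, size=config.degradome_background_per_transcript
            )
            for pos in positions:
                add_tag(tx, int(pos))
        out[cond] = tags
    return out


def gen_hormone_panel(
    config: SimConfig, truth: TruthSet
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Hormone table (hormone x phenotype x stage) plus paired expression series.

    For each planted association the n = 8 concatenated expression series
    (IFC stages 0-3 then CFC stages 0-3) correlates with the hormone series
    with the planted sign; |r| is controlled by adding Gaussian noise of
    variance (1/r^2 - 1) to the standardized hormone series.
    """
    rng = np.random.default_rng([config.seed, 4])
    rows = []
    hormone_series: dict[str, np.ndarray] = {}
    for h in HORMONES:
        base = rng.uniform(5, 50)
        slope = rng.uniform(-2, 2)
        vals = []
        for pheno in PHENOTYPES:
            offset = rng.uniform(-2, 2)
            for stage in STAGES:
                v = base + offset + slope * stage + config.hormone_noise * rng.normal()
                vals.append(max(v, 0.01))
        series = np.array(vals)
        if np.ptp(series) == 0:
            series[0] += 0.01
        hormone_series[h] = series
        for i, pheno in enumerate(PHENOTYPES):
            for j, stage in enumerate(STAGES):
                rows.append({"hormone": h, "phenotype": pheno, "stage": stage,
                             "value": series[i * 4 + j]})
    panel = pd.DataFrame(rows)

    expr: dict[str, np.ndarray] = {}
    assoc = []
    r = config.hormone_r
    sigma = float(np.sqrt(max(1.0 / (r * r) - 1.0, 0.0))) if r > 0 else 0.0
    for k in range(config.n_hormone_assoc):
        h = HORMONES[k % len(HORMONES)]
        sign = 1 if k % 2 == 0 else -1
        sid = f"series{k + 1}"
        z = hormone_series[h]
        z = (z - z.mean()) / z.std()
        e = sign * z + sigma * rng.normal(size=8)
        e = e - e.min() + 0.1  # expression values stay positive
        expr[sid] = e
        assoc.append((sid, h, sign))
    truth.true_hormone_assoc = assoc
    return panel, expr
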