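"""End-to-end pipeline orchestration over a run directory.

Stages run in a fixed order (simulate -> preprocess -> annotate -> novel ->
de -> degradome -> hormones); each stage writes its TSV outputs into the run
directory and never mutates another stage's inputs.  Re-running with the
same configuration and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate, degradome, expression, fileio, hairpin, hormones, preprocess
from .simulate import (
    References,
    SimConfig,
    TruthSet,
    gen_degradome,
    gen_hormone_panel,
    gen_reference,
    gen_sread_libraries,
)


@dataclass
class PipelineConfig:
    outdir: str = "run"
    sim: SimConfig = field(default_factory=SimConfig)
    length_window: tuple[int, int] = (18, 25)
    max_end_shift: int = 2
    max_internal_mismatch: int = 1
    flank: int = 120
    fold_backend: str = "bundled"
    fc_min: float = 1.5
    alpha: float = 0.05
    ne_min: float = 5.0
    detect_min: float = 1.0
    max_penalty: float = 7.0
    register: int = 10

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if isinstance(sim, dict):
            sim.setdefault("conditions", ("IFC", "CFC"))
            sim["conditions"] = tuple(sim["conditions"])
            if "mature_length_range" in sim:
                sim["mature_length_range"] = tuple(sim["mature_length_range"])
            cfg.sim = SimConfig(**sim)
        else:
            cfg.sim = sim
        for key in ("length_window",):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


@dataclass
class PipelineResult:
    refs: References
    truth: TruthSet
    libraries: list[preprocess.ReadLibrary]
    retained: list[preprocess.ReadLibrary]
    reports: list[preprocess.FilterReport]
    calls: list[annotate.MiRNACall]
    novel: list[hairpin.NovelCandidate]
    matrix: expression.ExpressionMatrix
    de: list[expression.DEResult]
    hits: list[degradome.DegradomeHit]
    correlations: list[hormones.CorrelationResult]
    groups: dict


def stage_simulate(cfg: PipelineConfig, outdir: Path):
    refs = gen_reference(cfg.sim)
    libraries, truth = gen_sread_libraries(cfg.sim, refs)
    tags = gen_degradome(cfg.sim, refs, truth)
    panel, expr_series = gen_hormone_panel(cfg.sim, truth)

    fileio.write_fasta(refs.genome, outdir / "genome.fa")
    fileio.write_fasta(refs.transcriptome, outdir / "transcriptome.fa")
    fileio.write_fasta(
        {pid: rec.sequence for pid, rec in refs.precursors.items()},
        outdir / "precursors.fa",
    )
    for cat, seqs in refs.contaminants.items():
        fileio.write_fasta(
            {f"{cat}{i}": s for i, s in enumerate(seqs)}, outdir / f"ref_{cat}.fa"
        )
    for lib in libraries:
        fileio.write_collapsed_fasta(lib, outdir / f"reads_{lib.sample}.fa")
    for cond, t in tags.items():
        fileio.write_collapsed_fasta(
            preprocess.ReadLibrary(counts=t, condition=cond, replicate="deg"),
            outdir / f"degradome_{cond}.fa",
        )
    fileio.write_tsv(panel, outdir / "hormones.tsv")
    fileio.write_tsv(
        pd.DataFrame(
            [{"mirna": m, "direction": d} for m, d in sorted(truth.true_de.items())]
        ),
        outdir / "truth_de.tsv",
    )
    fileio.write_tsv(
        pd.DataFrame(
            [{"mirna": m, "transcript": t, "coord": c} for m, t, c in truth.true_targets]
        ),
        outdir / "truth_targets.tsv",
    )
    return refs, libraries, truth, tags, panel, expr_series


def stage_preprocess(cfg: PipelineConfig, libraries, refs: References, outdir: Path):
    retained, reports = [], []
    for lib in libraries:
        ret, rep = preprocess.classify_reads(
            lib, refs.contaminants, length_window=cfg.length_window
        )
        retained.append(ret)
        reports.append(rep)
        fileio.write_report(rep, outdir / f"report_{lib.sample}.tsv")
    return retained, reports


def stage_annotate(cfg: PipelineConfig, retained, refs: References, outdir: Path):
    unique = sorted({s for lib in retained for s in lib.counts})
    calls = annotate.map_to_precursors(
        unique, refs.db, max_end_shift=cfg.max_end_shift,
        max_internal_mismatch=cfg.max_internal_mismatch,
    )
    for call in calls:
        call.counts = {lib.sample: lib.counts.get(call.sequence, 0) for lib in retained}
    rows = [
        {
            "sequence": c.sequence,
            "name": c.name,
            "status": c.status,
            "precursor": c.precursor_id,
            **c.counts,
        }
        for c in calls
    ]
    fileio.write_tsv(pd.DataFrame(rows), outdir / "mirna_calls.tsv")
    stats = annotate.composition_stats(calls, retained)
    fileio.write_tsv(
        pd.DataFrame(
            [{"metric": f"len_{k}", "value": v} for k, v in stats.length_hist.items()]
            + [{"metric": f"first_{b}", "value": f} for b, f in stats.first_nt.items()]
        ),
        outdir / "composition.tsv",
    )
    return calls, stats


def stage_novel(cfg: PipelineConfig, calls, refs: References, outdir: Path):
    unmapped = [c.sequence for c in calls if c.status == "unmapped"]
    candidates = hairpin.call_novel(
        unmapped, refs.genome, flank=cfg.flank, backend=cfg.fold_backend
    )
    rows = [
        {
            "sequence": c.sequence,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "arm": c.arm,
            "precursor": c.precursor.sequence,
            "structure": c.precursor.dotbracket,
            "mfe": c.precursor.mfe,
            "passes": c.verdict.passed,
        }
        for c in candidates
    ]
    fileio.write_tsv(pd.DataFrame(rows), outdir / "novel_candidates.tsv")
    fileio.write_bed(
        [(c.chrom, c.start, c.end, c.sequence, 0, c.strand) for c in candidates],
        outdir / "novel_candidates.bed",
    )
    return candidates


def build_matrix(calls, retained, reports) -> expression.ExpressionMatrix:
    """Count matrix per miRNA name per sample, normalized by clean totals."""
    samples = [lib.sample for lib in retained]
    clean = pd.Series({rep.sample: rep.valid_total for rep in reports})
    counts: dict[str, dict[str, int]] = {}
    for c in calls:
        if c.status == "unmapped" or not c.name:
            continue
        row = counts.setdefault(c.name, {s: 0 for s in samples})
        for s in samples:
            row[s] += c.counts.get(s, 0)
    df = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=samples).fillna(0)
    conditions = {lib.sample: lib.condition for lib in retained}
    return expression.ExpressionMatrix.from_counts(df, clean[samples], conditions)


def stage_de(cfg: PipelineConfig, matrix, outdir: Path):
    results = expression.call_de(
        matrix, fc_min=cfg.fc_min, alpha=cfg.alpha, ne_min=cfg.ne_min,
        detect_min=cfg.detect_min,
    )
    rows = [
        {
            "id": r.id,
            **{f"mean_NE_{c}": round(v, 3) for c, v in r.mean_ne.items()},
            "fold_change": round(r.fold_change, 3),
            "direction": r.direction,
            "p": r.p,
            "passes": r.passes,
        }
        for r in results
    ]
    fileio.write_tsv(pd.DataFrame(rows), outdir / "differential_expression.tsv")
    return results


def stage_degradome(cfg: PipelineConfig, de_results, truth: TruthSet, refs: References,
                    tags, outdir: Path):
    de_ids = [r.id for r in de_results if r.passes]
    query = {
        mid: truth.true_mirnas[mid]
        for mid in sorted(truth.true_mirnas)
        if any(d.startswith(mid) for d in de_ids) or mid in de_ids
    }
    if not query:  # fall back to every planted miRNA
        query = dict(sorted(truth.true_mirnas.items()))
    hits = []
    for mid, seq in query.items():
        hits.extend(
            degradome.find_target_sites(mid, seq, refs.transcriptome,
                                        max_penalty=cfg.max_penalty)
        )
    hits = degradome.annotate_hits(hits, tags, refs.transcriptome, register=cfg.register)
    rows = [
        {
            "mirna": h.mirna_id,
            "transcript": h.transcript_id,
            "cleavage_coord": h.cleavage_coord,
            "register": h.cleavage_register,
            "penalty": h.penalty,
            **{f"category_{c}": (v if v is not None else "") for c, v in h.categories.items()},
            "p": h.p,
            "class": h.cls,
            **{f"TPB_{c}": round(v, 1) for c, v in h.tpb.items()},
        }
        for h in hits
    ]
    fileio.write_tsv(pd.DataFrame(rows), outdir / "degradome_hits.tsv")
    return hits


def stage_hormones(cfg: PipelineConfig, panel: pd.DataFrame, expr_series, outdir: Path):
    corrs = []
    for sid, series in expr_series.items():
        for h in hormones.HORMONES:
            sub = panel[panel.hormone == h]
            y = [
                float(sub[(sub.phenotype == p) & (sub.stage == s)].value.iloc[0])
                for p in hormones.PHENOTYPES
                for s in hormones.STAGES
            ]
            corrs.append(hormones.correlate(series, y, series_id=sid, hormone=h))
    rows = [
        {"series": c.series_id, "hormone": c.hormone, "r": round(c.r, 3),
         "p": round(c.p, 5), "flag": c.flag}
        for c in corrs
    ]
    fileio.write_tsv(pd.DataFrame(rows), outdir / "hormone_correlations.tsv")
    return corrs


def run_all(cfg: PipelineConfig) -> PipelineResult:
    outdir = fileio.ensure_dir(cfg.outdir)
    refs, libraries, truth, tags, panel, expr_series = stage_simulate(cfg, outdir)
    retained, reports = stage_preprocess(cfg, libraries, refs, outdir)
    calls, _ = stage_annotate(cfg, retained, refs, outdir)
    novel = stage_novel(cfg, calls, refs, outdir)
    matrix = build_matrix(calls, retained, reports)
    de_results = stage_de(cfg, matrix, outdir)
    hits = stage_degradome(cfg, de_results, truth, refs, tags, outdir)
    corrs = stage_hormones(cfg, panel, expr_series, outdir)
    groups = {}
    summary = {
        "samples": [lib.sample for lib in libraries],
        "n_unique_retained": int(sum(lib.unique for lib in retained)),
        "n_known_calls": int(sum(c.status == "known_mature" for c in calls)),
        "n_isomir_calls": int(sum(c.status.startswith("isoform") for c in calls)),
        "n_novel_candidates": len(novel),
        "n_de_passing": int(sum(r.passes for r in de_results)),
        "n_degradome_hits": len(hits),
        "n_class_I": int(sum(h.cls == "I" for h in hits)),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return PipelineResult(
        refs=refs, truth=truth, libraries=libraries, retained=retained,
        reports=reports, calls=calls, novel=novel, matrix=matrix, de=de_results,
        hits=hits, correlations=corrs, groups=groups,
    )
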