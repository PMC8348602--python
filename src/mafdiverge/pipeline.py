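"""End-to-end orchestration of the seven-step selection pipeline.

Stages: (1) association filters → (2) LD clumping against the reference
panel → (3) pooled MAF-divergence selection → (4) matched-SNP background
construction → (5) matched-null divergence selection → (6) gene mapping and
motif-disruption scoring of the surviving SNPs → (7) pathway
over-representation of the mapped genes and of the transcription factors
whose motifs are disrupted.

Stages communicate exclusively through TSV artifacts in the output
directory, so any stage can be re-run and inspected on its own. A stage
with zero survivors halts the run cleanly (partial report, no exception).
The analysis is fully deterministic: two runs from one config produce
byte-identical stage artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import PipelineError
from .io import (FilterThresholds, read_sumstats, filter_sumstats,
                 write_sumstats, read_vcf_panel, read_fasta, read_bed_genes,
                 read_gmt, read_meme)
from .ld import ClumpParams, clump, write_clumps, panel_maf_all
from .divergence import (SelectionParams, divergence_table,
                         select_divergent_pooled, select_divergent_matched,
                         write_divergence)
from .matching import (MatchParams, build_profiles, MatchProfile, match_snp,
                       match_report, write_matches)
from .motifs import MotifBreakParams, break_snp, write_hits
from .enrich import map_snps_to_genes, hypergeom_enrich, write_enrichment

logger = logging.getLogger(__name__)

STAGES = ("filter", "clump", "divergence_pooled", "match",
          "divergence_matched", "annotate", "enrich")


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    sumstats: Path
    vcf_ref: Path
    genome: Path
    genes: Path
    gmt: Path
    motifs: Path
    out_dir: Path
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    clump: ClumpParams = field(default_factory=ClumpParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    matching: MatchParams = field(default_factory=MatchParams)
    motif_break: MotifBreakParams = field(default_factory=MotifBreakParams)
    flank: int = 0
    seed: int = 0  # echoed in the report; the analysis itself is deterministic

    def __post_init__(self) -> None:
        for name in ("sumstats", "vcf_ref", "genome", "genes", "gmt",
                     "motifs"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise PipelineError(f"{name} file not found: {p}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text())
        sub = {"filters": FilterThresholds, "clump": ClumpParams,
               "selection": SelectionParams, "matching": MatchParams,
               "motif_break": MotifBreakParams}
        kwargs = {}
        for key, value in obj.items():
            if key in sub:
                kwargs[key] = sub[key](**(value or {}))
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def echo(self) -> dict:
        d = {}
        for key, value in self.__dict__.items():
            if hasattr(value, "__dataclass_fields__"):
                d[key] = asdict(value)
            elif isinstance(value, Path):
                d[key] = str(value)
            else:
                d[key] = value
        return d


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    survivors: list[str]


@dataclass
class RunReport:
    """Per-stage counts, survivor ids, drop reasons and run metadata."""

    config: dict
    version: str = __version__
    stages: list[StageRecord] = field(default_factory=list)
    fates: dict[str, tuple[str, str]] = field(default_factory=dict)
    input_ids: list[str] = field(default_factory=list)
    match_quality: dict = field(default_factory=dict)
    n_motif_hits: int = 0
    n_disrupting_snps: int = 0
    mapped_genes: list[str] = field(default_factory=list)
    tf_genes: list[str] = field(default_factory=list)
    halted_at: str | None = None
    wall_time: float = 0.0

    def add_stage(self, name: str, n_in: int, survivors: list[str]) -> None:
        self.stages.append(StageRecord(name=name, n_in=n_in,
                                       n_out=len(survivors),
                                       survivors=list(survivors)))

    def drop(self, snp_id: str, stage: str, reason: str) -> None:
        self.fates.setdefault(snp_id, (stage, reason))

    def counts(self) -> dict[str, tuple[int, int]]:
        return {s.name: (s.n_in, s.n_out) for s in self.stages}

    def to_json(self) -> str:
        obj = {"config": self.config, "version": self.version,
               "stages": [asdict(s) for s in self.stages],
               "fates": {k: list(v) for k, v in self.fates.items()},
               "input_ids": self.input_ids,
               "match_quality": self.match_quality,
               "n_motif_hits": self.n_motif_hits,
               "n_disrupting_snps": self.n_disrupting_snps,
               "mapped_genes": self.mapped_genes,
               "tf_genes": self.tf_genes,
               "halted_at": self.halted_at,
               "wall_time": self.wall_time}
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        obj = json.loads(text)
        rep = cls(config=obj["config"], version=obj["version"])
        rep.stages = [StageRecord(**s) for s in obj["stages"]]
        rep.fates = {k: tuple(v) for k, v in obj["fates"].items()}
        rep.input_ids = obj["input_ids"]
        rep.match_quality = obj["match_quality"]
        rep.n_motif_hits = obj["n_motif_hits"]
        rep.n_disrupting_snps = obj["n_disrupting_snps"]
        rep.mapped_genes = obj["mapped_genes"]
        rep.tf_genes = obj["tf_genes"]
        rep.halted_at = obj["halted_at"]
        rep.wall_time = obj["wall_time"]
        return rep

    def summary(self) -> str:
        lines = [f"mafdiverge {self.version} run report"]
        for s in self.stages:
            lines.append(f"  {s.name:<20s} {s.n_in:>7d} -> {s.n_out:d}")
        if self.match_quality:
            iq = self.match_quality
            size = (f"{iq['match_size_pct']:.2f}%"
                    if iq.get("match_size_pct") is not None else "n/a")
            lines.append(f"  insufficient-matches {iq['insufficient_pct']:.2f}%"
                         f", match-size {size}")
        lines.append(f"  motif hits: {self.n_motif_hits} "
                     f"({self.n_disrupting_snps} disrupting SNPs)")
        lines.append(f"  genes mapped: {len(self.mapped_genes)}; "
                     f"TF genes disrupted: {len(self.tf_genes)}")
        if self.halted_at:
            lines.append(f"  HALTED: zero survivors at stage {self.halted_at}")
        lines.append(f"  wall time: {self.wall_time:.2f} s")
        return "\n".join(lines)


def _finish(report: RunReport, out: Path, t0: float) -> RunReport:
    report.wall_time = time.perf_counter() - t0
    (out / "report.json").write_text(report.to_json() + "\n")
    (out / "report.txt").write_text(report.summary() + "\n")
    logger.info("run complete:\n%s", report.summary())
    return report


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; returns the report (see module docstring)."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.echo())

    # stage 1: association filters -------------------------------------
    records = read_sumstats(config.sumstats)
    report.input_ids = [r.snp_id for r in records]
    kept = filter_sumstats(records, config.filters)
    kept_ids = {r.snp_id for r in kept}
    for r in records:
        if r.snp_id not in kept_ids:
            reason = (f"pval {r.pval:.3g} >= {config.filters.pval_max:g}"
                      if r.pval >= config.filters.pval_max
                      else f"maf {r.maf:.3g} <= {config.filters.maf_min:g}")
            report.drop(r.snp_id, "filter", reason)
    write_sumstats(kept, out / "stage1_filtered.tsv")
    report.add_stage("filter", len(records), [r.snp_id for r in kept])
    if not kept:
        report.halted_at = "filter"
        return _finish(report, out, t0)

    # stage 2: LD clumping ----------------------------------------------
    panel = read_vcf_panel(config.vcf_ref)
    result = clump(kept, panel, config.clump)
    write_clumps(result, out / "stage2_clumps.tsv")
    index_ids = [c.index_snp for c in result.clumps]
    for c in result.clumps:
        for m in c.members:
            report.drop(m, "clump", f"member of clump {c.index_snp}")
    for sid in result.unassigned:
        report.drop(sid, "clump", "not an index (p > p1) and in no clump")
    for sid in result.absent:
        report.drop(sid, "clump", "absent from reference panel")
    report.add_stage("clump", len(kept), index_ids)
    if not index_ids:
        report.halted_at = "clump"
        return _finish(report, out, t0)

    # stage 3: pooled divergence ----------------------------------------
    maf_a = pd.Series({r.snp_id: r.maf for r in records})
    maf_b = panel_maf_all(panel).dropna()
    table = divergence_table(maf_a, maf_b)
    queries3 = [sid for sid in index_ids if sid in table.index]
    for sid in index_ids:
        if sid not in table.index:
            report.drop(sid, "divergence_pooled",
                        "no panel MAF (divergence undefined)")
    pooled = select_divergent_pooled(
        table.loc[queries3, "delta"], config.selection,
        background_deltas=table["delta"])
    pooled_full = table.loc[queries3].join(pooled[["p_raw", "p_adj",
                                                   "selected"]])
    write_divergence(pooled_full, out / "stage3_divergence.tsv")
    selected3 = [sid for sid in queries3 if bool(pooled.loc[sid, "selected"])]
    for sid in queries3:
        if sid not in selected3:
            report.drop(sid, "divergence_pooled",
                        f"adjusted p {pooled.loc[sid, 'p_adj']:.3g} >= "
                        f"{config.selection.alpha_adj:g}")
    report.add_stage("divergence_pooled", len(index_ids), selected3)
    if not selected3:
        report.halted_at = "divergence_pooled"
        return _finish(report, out, t0)

    # stage 4: matched-SNP background ------------------------------------
    genes = read_bed_genes(config.genes)
    profiles = build_profiles(panel, genes, config.matching)
    # candidates must carry both MAFs (divergence computable downstream)
    profiles = profiles.loc[[i for i in profiles.index if i in table.index]]
    query_profiles = [MatchProfile(snp_id=sid, **{
        "maf": float(profiles.loc[sid, "maf"]),
        "ld_buddies": int(profiles.loc[sid, "ld_buddies"]),
        "dist_nearest_gene": int(profiles.loc[sid, "dist_nearest_gene"]),
        "gene_density": int(profiles.loc[sid, "gene_density"])})
        for sid in selected3]
    candidates = profiles.drop(index=selected3, errors="ignore")
    matched_sets = [match_snp(q, candidates, config.matching)
                    for q in query_profiles]
    write_matches(matched_sets, out / "stage4_matches.tsv")
    quality = match_report(matched_sets)
    report.match_quality = {"insufficient_pct": quality.insufficient_pct,
                            "match_size_pct": quality.match_size_pct}
    enough = [m for m in matched_sets if len(m.matched_ids) >= 3]
    for m in matched_sets:
        if len(m.matched_ids) < 3:
            report.drop(m.query_id, "match",
                        f"insufficient matches ({len(m.matched_ids)} < 3)")
    report.add_stage("match", len(selected3), [m.query_id for m in enough])
    if not enough:
        report.halted_at = "match"
        return _finish(report, out, t0)

    # stage 5: matched-null divergence -----------------------------------
    matched_deltas = {m.query_id: table.loc[list(m.matched_ids), "delta"]
                      .to_numpy() for m in enough}
    qdeltas = table.loc[[m.query_id for m in enough], "delta"]
    matched_df, excluded = select_divergent_matched(
        qdeltas, matched_deltas, config.selection)
    out5 = table.loc[matched_df.index].join(
        matched_df[["n_matched", "median_matched", "p_raw", "p_adj",
                    "selected"]])
    write_divergence(out5, out / "stage5_selected.tsv")
    selected5 = [sid for sid in matched_df.index
                 if bool(matched_df.loc[sid, "selected"])]
    for sid in matched_df.index:
        if sid not in selected5:
            report.drop(sid, "divergence_matched",
                        "not significant against matched background "
                        f"(adjusted p {matched_df.loc[sid, 'p_adj']:.3g})"
                        if matched_df.loc[sid, "p_adj"]
                        >= config.selection.alpha_adj
                        else "delta not above the median cut-off")
    report.add_stage("divergence_matched", len(enough), selected5)
    if not selected5:
        report.halted_at = "divergence_matched"
        return _finish(report, out, t0)

    # stage 6a: gene mapping ----------------------------------------------
    final_records = [r for r in records if r.snp_id in set(selected5)]
    snp_map = map_snps_to_genes(final_records, genes, flank=config.flank)
    snp_map.assignments.to_csv(out / "stage6_genes.tsv", sep="\t",
                               index=False)
    report.mapped_genes = snp_map.genes

    # stage 6b: motif disruption ------------------------------------------
    genome = read_fasta(config.genome)
    pwms = read_meme(config.motifs)
    hits = []
    for rec in final_records:
        hits.extend(break_snp(genome, rec, pwms, config.motif_break))
    write_hits(hits, out / "stage6_motif_hits.tsv")
    disrupting = sorted({h.snp_id for h in hits if h.effect != "neutral"})
    tf_genes = sorted({h.motif_id.split("_")[0] for h in hits
                       if h.effect != "neutral"})
    report.n_motif_hits = len(hits)
    report.n_disrupting_snps = len(disrupting)
    report.tf_genes = tf_genes
    report.add_stage("annotate", len(selected5), selected5)

    # stage 7: pathway over-representation --------------------------------
    gene_sets = read_gmt(config.gmt)
    universe = [g.gene_symbol for g in genes]
    if snp_map.genes:
        enr = hypergeom_enrich(snp_map.genes, gene_sets, universe)
        write_enrichment(enr, out / "stage7_enrichment_genes.tsv")
    tf_in_universe = [g for g in tf_genes if g in set(universe)]
    if tf_in_universe:
        enr_tf = hypergeom_enrich(tf_in_universe, gene_sets, universe)
        write_enrichment(enr_tf, out / "stage7_enrichment_tfs.tsv")
    report.add_stage("enrich", len(selected5), selected5)
    return _finish(report, out, t0)


def trace_snp(report: RunReport, snp_id: str) -> list[tuple[str, str, str]]:
    """Per-stage fate of one SNP: (stage, retained|dropped, reason)."""
    if snp_id not in set(report.input_ids):
        raise KeyError(f"SNP {snp_id!r} not among the run's input records")
    drop_stage, reason = report.fates.get(snp_id, (None, ""))
    trace = []
    for stage in report.stages:
        if stage.name == drop_stage:
            trace.append((stage.name, "dropped", reason))
            break
        trace.append((stage.name, "retained", ""))
    return trace
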