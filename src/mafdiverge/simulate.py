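"""Synthetic inputs with the statistical structure the pipeline assumes.

Two populations share one variant scaffold; their allele frequencies drift
apart under the Balding–Nichols model (Beta-distributed around an ancestral
frequency, parameterised by Fst). Linkage disequilibrium arises from
founder-haplotype copying: each LD block has a small pool of founder
haplotypes drawn Bernoulli(freq) per SNP, and every sample copies two
founders per block (strong within-block, near-zero between-block LD).

A planted subset of SNPs is both associated (small GWAS p-value) and
divergent (population MAF gap of at least `planted_delta_min`); the
annotation layer embeds transcription-factor motif consensus sequences over
planted SNPs so that a disruption hit is guaranteed to exist. The returned
TruthTable records the ground truth for recovery tests.

Everything is a deterministic function of the config (including the seed):
the same SimConfig yields byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .ld import GenotypePanel
from .enrich import GeneModel
from . import io as gio

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults are the desk-scale conditions the package is validated under:
    two populations of 200 samples, 2,000 SNPs in 20-SNP LD blocks,
    Fst = 0.02 drift, and 20 planted SNPs that are both strongly associated
    (p <= 1e-5) and divergent (true MAF gap >= 0.15).
    """

    n_samples_a: int = 200
    n_samples_b: int = 200
    n_snps: int = 2000
    block_len: int = 20
    n_founder_haplotypes: int = 100
    fst: float = 0.02
    n_planted: int = 20
    planted_delta_min: float = 0.15
    planted_pval_max: float = 1e-5
    genome_len: int = 1_000_000
    n_genes: int = 40
    n_pathways: int = 15
    n_motifs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples_a", "n_samples_b", "n_snps", "block_len",
                     "n_founder_haplotypes", "genome_len", "n_genes",
                     "n_pathways"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_planted < 0 or self.n_motifs < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_planted > self.n_snps:
            raise ValidationError("n_planted > n_snps")
        if not (0.0 <= self.fst < 1.0):
            raise ValidationError("fst outside [0, 1)")
        if not (0.0 <= self.planted_delta_min <= 0.5):
            raise ValidationError("planted_delta_min outside [0, 0.5]")
        if not (0.0 < self.planted_pval_max <= 1.0):
            raise ValidationError("planted_pval_max outside (0, 1]")
        if self.genome_len < self.n_snps:
            raise ValidationError("genome_len must be >= n_snps")


@dataclass
class TruthTable:
    """Ground truth of the planted signal."""

    planted: pd.DataFrame          # snp_id, freq_a, freq_b, pval
    motif_snp_ids: tuple[str, ...]  # planted SNPs embedded in a motif consensus

    @property
    def planted_snp_ids(self) -> set[str]:
        return set(self.planted["snp_id"])


@dataclass
class Annotations:
    genome: dict[str, str]
    genes: list[GeneModel]
    pathways: dict[str, tuple[str, frozenset[str]]]
    pwm_matrices: list[tuple[str, np.ndarray]]  # (motif_id, 4 x L probabilities)


@dataclass
class SimBundle:
    config: SimConfig
    variants: pd.DataFrame
    truth: TruthTable
    annotations: Annotations
    panel_a: GenotypePanel
    panel_b: GenotypePanel
    sumstats: list
    paths: dict[str, Path] = field(default_factory=dict)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg.seed])


def balding_nichols(p0, fst: float, rng: np.random.Generator, size=None):
    """Population frequencies drifted around ancestral p0.

    Beta(p0(1-F)/F, (1-p0)(1-F)/F): mean p0, variance F*p0*(1-p0).
    fst = 0 degenerates to p0 itself.
    """
    p0 = np.asarray(p0, dtype=float)
    if size is not None:
        p0 = np.broadcast_to(p0, size)
    if fst == 0.0:
        return np.array(p0, copy=True)
    scale = (1.0 - fst) / fst
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def generate_frequencies(cfg: SimConfig) -> pd.DataFrame:
    """Variant scaffold with true per-population alt-allele frequencies.

    Columns: snp_id chrom pos ref alt block planted freq_a freq_b.
    Frequencies are clipped into (0, 1); planted SNPs are overridden so the
    folded-MAF gap is at least planted_delta_min (both frequencies < 0.5,
    so folding is the identity for them).
    """
    rng = _rng(cfg, 1)
    n = cfg.n_snps
    pos = np.sort(rng.choice(cfg.genome_len, size=n, replace=False)) + 1
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    block = np.arange(n) // cfg.block_len

    p0 = rng.uniform(0.05, 0.5, size=n)
    freq_a = balding_nichols(p0, cfg.fst, rng)
    freq_b = balding_nichols(p0, cfg.fst, rng)
    eps = 1e-3
    freq_a = np.clip(freq_a, eps, 1 - eps)
    freq_b = np.clip(freq_b, eps, 1 - eps)

    planted = np.zeros(n, dtype=bool)
    n_blocks = int(block.max()) + 1
    if cfg.n_planted > 0:
        if cfg.n_planted <= n_blocks:
            # one planted SNP per block keeps the signals clump-independent
            chosen_blocks = rng.choice(n_blocks, cfg.n_planted, replace=False)
            idx = []
            for b in np.sort(chosen_blocks):
                members = np.flatnonzero(block == b)
                idx.append(int(rng.choice(members)))
            idx = np.array(idx)
        else:
            idx = np.sort(rng.choice(n, cfg.n_planted, replace=False))
        planted[idx] = True
        # true gaps sit comfortably above the floor, as a planted effect would
        delta = np.minimum(cfg.planted_delta_min
                           + rng.uniform(0.05, 0.25, size=idx.size), 0.48)
        maf_a = rng.uniform(delta + 0.01, 0.49)
        freq_a[idx] = maf_a
        freq_b[idx] = maf_a - delta

    return pd.DataFrame({
        "snp_id": [f"rs{i + 1:06d}" for i in range(n)],
        "chrom": "1",
        "pos": pos.astype(int),
        "ref": _BASES[ref_i],
        "alt": _BASES[alt_i],
        "block": block,
        "planted": planted,
        "freq_a": freq_a,
        "freq_b": freq_b,
    })


def generate_annotations(cfg: SimConfig, variants: pd.DataFrame,
                         ) -> tuple[Annotations, pd.DataFrame, tuple[str, ...]]:
    """Genome, genes, pathways and motifs consistent with the variant scaffold.

    The genome carries every SNP's reference allele at its position. Motif
    consensus sequences are written over planted SNP positions (where they
    fit without covering another SNP); those SNPs' ref allele becomes the
    consensus base and their alt allele the motif's worst base, so the
    alternate allele is guaranteed to disrupt the site. Returns the
    annotations, the (possibly allele-updated) variant table, and the ids of
    motif-embedded planted SNPs.
    """
    rng = _rng(cfg, 2)
    variants = variants.copy()

    genome_arr = rng.integers(0, 4, size=cfg.genome_len)

    # genes: one per equal-width slot -> pairwise disjoint by construction
    slot = cfg.genome_len // cfg.n_genes
    hi = min(15_000, slot - 1)
    lo = min(2_000, hi)
    if hi < 100:
        raise ValidationError(
            f"{cfg.n_genes} genes do not fit a {cfg.genome_len} bp genome")
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        length = int(rng.integers(lo, hi + 1))
        start = slot * i + int(rng.integers(0, slot - length))
        genes.append(GeneModel(gene_symbol=f"GENE{i + 1:04d}", chrom="1",
                               start=start, end=start + length))
    gene_names = [g.gene_symbol for g in genes]

    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    max_size = min(15, cfg.n_genes)
    for i in range(cfg.n_pathways):
        size = int(rng.integers(min(3, max_size), max_size + 1))
        members = rng.choice(gene_names, size=size, replace=False)
        pathways[f"PW{i + 1:04d}"] = (f"synthetic pathway {i + 1}",
                                      frozenset(members.tolist()))

    pwm_matrices: list[tuple[str, np.ndarray]] = []
    consensi: list[np.ndarray] = []
    for i in range(cfg.n_motifs):
        L = int(rng.integers(6, 11))
        cons = rng.integers(0, 4, size=L)
        mat = np.full((4, L), 0.05)
        mat[cons, np.arange(L)] = 0.85
        tf_gene = gene_names[int(rng.integers(0, len(gene_names)))]
        pwm_matrices.append((f"{tf_gene}_SYNT.{i}", mat))
        consensi.append(cons)

    pos0 = variants["pos"].to_numpy() - 1
    snp_positions = set(pos0.tolist())
    motif_ids: list[str] = []
    planted_rows = np.flatnonzero(variants["planted"].to_numpy())
    for k, row in enumerate(planted_rows):
        if not pwm_matrices:
            break
        m = k % len(pwm_matrices)
        cons = consensi[m]
        L = cons.size
        offset = int(rng.integers(0, L))
        start = int(pos0[row]) - offset
        if start < 0 or start + L > cfg.genome_len:
            continue
        window_positions = set(range(start, start + L)) - {int(pos0[row])}
        if window_positions & snp_positions:
            continue  # would overwrite another SNP's reference base
        genome_arr[start:start + L] = cons
        ref_idx = int(cons[offset])
        mat = pwm_matrices[m][1]
        worst = [b for b in np.argsort(mat[:, offset], kind="stable")
                 if b != ref_idx][0]
        variants.iat[row, variants.columns.get_loc("ref")] = "ACGT"[ref_idx]
        variants.iat[row, variants.columns.get_loc("alt")] = "ACGT"[int(worst)]
        motif_ids.append(variants.iat[row, variants.columns.get_loc("snp_id")])
    if cfg.n_planted > 0 and cfg.n_motifs > 0 and not motif_ids:
        raise ValidationError(
            "could not place any planted SNP inside a motif consensus")

    # reference alleles must match the genome everywhere
    ref_codes = np.array(["ACGT".index(b) for b in variants["ref"]])
    genome_arr[pos0] = ref_codes
    genome = {"1": "".join(_BASES[genome_arr])}
    return (Annotations(genome=genome, genes=genes, pathways=pathways,
                        pwm_matrices=pwm_matrices),
            variants, tuple(motif_ids))


def generate_panel(cfg: SimConfig, variants: pd.DataFrame,
                   population: str = "a",
                   ensure_polymorphic: bool = True) -> GenotypePanel:
    """Founder-copy genotype panel for one population.

    Haplotype blocks are independent: each sample draws two founders per
    block. With ensure_polymorphic (the default), every SNP is forced
    polymorphic in the panel (one haplotype slot flipped when a column comes
    out monomorphic) so empirical MAFs are strictly positive — SNPs are
    polymorphic by definition in a reference panel.
    """
    if population not in ("a", "b"):
        raise ValidationError("population must be 'a' or 'b'")
    rng = _rng(cfg, 3 if population == "a" else 4)
    freqs = variants[f"freq_{population}"].to_numpy()
    n_samples = cfg.n_samples_a if population == "a" else cfg.n_samples_b
    K = cfg.n_founder_haplotypes
    block = variants["block"].to_numpy()
    n = len(variants)
    geno = np.empty((n_samples, n), dtype=float)
    for b in np.unique(block):
        cols = np.flatnonzero(block == b)
        founders = (rng.random((K, cols.size)) < freqs[cols]).astype(float)
        pick = rng.integers(0, K, size=(2, n_samples))
        geno[:, cols] = founders[pick[0]] + founders[pick[1]]
    if ensure_polymorphic:
        total = geno.sum(axis=0)
        for j in np.flatnonzero((total == 0) | (total == 2 * n_samples)):
            i = int(rng.integers(0, n_samples))
            geno[i, j] += 1.0 if total[j] == 0 else -1.0
    prefix = population.upper()
    samples = [f"{prefix}{i + 1:05d}" for i in range(n_samples)]
    return GenotypePanel(
        genotypes=geno,
        variants=variants[["snp_id", "chrom", "pos", "ref", "alt"]]
        .reset_index(drop=True),
        samples=samples)


def generate_sumstats(cfg: SimConfig, variants: pd.DataFrame,
                      panel_a: GenotypePanel | None = None,
                      ) -> tuple[list, TruthTable]:
    """Association statistics for population A plus the ground-truth table.

    The MAF column is the folded population-A frequency. It is deliberately
    the *true* frequency, not a panel estimate: the emulated input is a
    biobank-scale cohort whose sampling error is negligible, whereas a
    desk-scale panel would add frequency noise the real input does not have.
    Association p-values are Uniform(0, 1] for background SNPs and
    Uniform(0, planted_pval_max] for planted SNPs.
    """
    from .io import SummaryStatRecord

    rng = _rng(cfg, 5)
    f = variants["freq_a"].to_numpy()
    mafs = pd.Series(np.minimum(f, 1.0 - f), index=variants["snp_id"])
    u = rng.random(len(variants))
    planted = variants["planted"].to_numpy()
    pvals = np.where(planted, cfg.planted_pval_max * (1.0 - u), 1.0 - u)
    records = []
    for i, row in enumerate(variants.itertuples(index=False)):
        rec = SummaryStatRecord(
            snp_id=row.snp_id, chrom=str(row.chrom), pos=int(row.pos),
            ref=row.ref, alt=row.alt, pval=float(pvals[i]),
            maf=float(mafs.iloc[i]))
        rec.validate()
        records.append(rec)
    truth_df = variants.loc[planted, ["snp_id", "freq_a", "freq_b"]].copy()
    truth_df["pval"] = pvals[planted]
    gap = (np.minimum(truth_df["freq_a"], 1 - truth_df["freq_a"])
           - np.minimum(truth_df["freq_b"], 1 - truth_df["freq_b"])).abs()
    assert (gap >= cfg.planted_delta_min - 1e-12).all()
    return records, TruthTable(planted=truth_df.reset_index(drop=True),
                               motif_snp_ids=())


def simulate_bundle(cfg: SimConfig, out_dir: str | Path | None = None,
                    ) -> SimBundle:
    """Generate the full input bundle and (optionally) write it to disk.

    Files written: sumstats.tsv, panel_a.vcf, panel_b.vcf, genome.fa,
    genes.bed, pathways.gmt, motifs.meme, truth.json.
    """
    variants = generate_frequencies(cfg)
    annotations, variants, motif_ids = generate_annotations(cfg, variants)
    panel_a = generate_panel(cfg, variants, "a")
    panel_b = generate_panel(cfg, variants, "b")
    records, truth = generate_sumstats(cfg, variants)
    truth = TruthTable(planted=truth.planted, motif_snp_ids=motif_ids)

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {k: out / v for k, v in {
            "sumstats": "sumstats.tsv", "panel_a": "panel_a.vcf",
            "panel_b": "panel_b.vcf", "genome": "genome.fa",
            "genes": "genes.bed", "gmt": "pathways.gmt",
            "motifs": "motifs.meme", "truth": "truth.json"}.items()}
        gio.write_sumstats(records, paths["sumstats"])
        contigs = {"1": cfg.genome_len}
        gio.write_vcf_panel(panel_a, paths["panel_a"], contig_lengths=contigs)
        gio.write_vcf_panel(panel_b, paths["panel_b"], contig_lengths=contigs)
        gio.write_fasta(annotations.genome, paths["genome"])
        gio.write_bed_genes(annotations.genes, paths["genes"])
        gio.write_gmt(annotations.pathways, paths["gmt"])
        gio.write_meme(annotations.pwm_matrices, paths["motifs"])
        truth_obj = {
            "planted": truth.planted.round(6).to_dict(orient="records"),
            "motif_snp_ids": list(truth.motif_snp_ids),
            "config": asdict(cfg),
        }
        paths["truth"].write_text(json.dumps(truth_obj, indent=1,
                                             sort_keys=True) + "\n")
        logger.info("simulate_bundle: wrote %d files to %s", len(paths), out)
    return SimBundle(config=cfg, variants=variants, truth=truth,
                     annotations=annotations, panel_a=panel_a,
                     panel_b=panel_b, sumstats=records, paths=paths)


def load_truth(path: str | Path) -> TruthTable:
    obj = json.loads(Path(path).read_text())
    return TruthTable(planted=pd.DataFrame(obj["planted"]),
                      motif_snp_ids=tuple(obj["motif_snp_ids"]))
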