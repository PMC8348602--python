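"""Generate a synthetic input bundle and inspect its ground truth.

The generator emulates the pipeline's real-world inputs: a biobank-style
summary-statistic table for population A, a reference genotype panel (VCF)
for population B whose allele frequencies drifted apart under the
Balding–Nichols model, a genome, gene/pathway annotations, and a motif
library. A planted subset of SNPs is both associated and divergent.
"""

from mafdiverge import SimConfig, simulate_bundle

cfg = SimConfig(n_snps=500, n_samples_a=100, n_samples_b=100, n_planted=8,
                fst=0.02, planted_delta_min=0.15, genome_len=250_000,
                n_genes=15, n_pathways=8, n_motifs=5, seed=7)
bundle = simulate_bundle(cfg, "scratch/example_bundle")

print(f"wrote {len(bundle.paths)} files to scratch/example_bundle/")
print(f"{cfg.n_snps} SNPs, {len(bundle.truth.planted_snp_ids)} planted "
      f"(true MAF gap >= {cfg.planted_delta_min})")
print(f"{len(bundle.truth.motif_snp_ids)} planted SNPs sit inside a motif "
      "consensus, so their alternate allele must disrupt the site")
print("\nplanted truth (first 5):")
print(bundle.truth.planted.head().to_string(index=False))
# freq_a/freq_b are the true population frequencies; the pipeline only ever
# sees the summary statistics and the genotype panel.
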