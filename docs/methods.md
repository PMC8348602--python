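# Methods

This note documents the statistical models behind `mafdiverge`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer should know
about. The package's own tests and `scripts/acceptance.py` compute every
empirical number referred to here; nothing below is asserted beyond what
they measure.

## The selection procedure

The pipeline identifies trait-associated SNPs whose minor allele frequency
(MAF) differs between a discovery population (A, summary statistics) and a
reference population (B, genotype panel). Its statistical core is a
repeated outlier test on the distribution of per-SNP MAF differences
Δ = |fold(f_A) − fold(f_B)|, fold(f) = min(f, 1−f).

**Divergence test.** For a focal SNP with difference Δ_s and a background
collection of differences {Δ_i}, we test H₀: "Δ_s is a typical location for
the background" with a one-sample Wilcoxon signed-rank test of {Δ_i} against
the hypothesized location Δ_s, one-sided (`alternative="less"`) so that a
small p-value means the background lies below Δ_s, i.e. Δ_s is in the upper
tail. Raw p-values are Benjamini–Hochberg adjusted across the SNPs tested
in a round and selected at adjusted p < α (default 10⁻³). Two properties of
this construction matter in practice:

- it is a *location* test: in a continuous background even a modest upper
  order statistic becomes significant as the background grows, so the
  pooled round behaves like a calibrated upper-tail selector, not an
  effect-size threshold;
- it is monotone in Δ_s: raising a query's difference can only lower its
  p-value, never deselect it (tested as an invariant).

The pooled round (step 3) uses, by default, the leave-one-out background of
the candidate set itself. The orchestrated pipeline instead passes the
genome-wide background (differences of all SNPs shared between the summary
statistics and the panel). Rationale: after the association filter and
clumping, the candidate set is small and — whenever the trait signal is real
— enriched for divergent SNPs, so a within-set comparison loses power
exactly when the method works; the genome-wide distribution is the natural
null for "is this SNP unusually divergent". Both behaviours are exposed
(`background_deltas=` argument).

The matched round (step 5) compares each query only against its own
matched background (below) and additionally requires Δ_s to exceed the
median of that background's Δ distribution (`median_mode="matched"`, the
default). A variant that takes the median over the pooled query Δs
(`median_mode="queries"`) is provided; note that variant can never pass
more than half the queries, which is why it is not the default.

**Wilcoxon implementation.** Differences equal to the hypothesized location
are dropped. For n ≤ 25 tie-free observations the exact permutation null is
used; otherwise the normal approximation with tie-variance and continuity
corrections (both via `scipy.stats.wilcoxon`). A fully degenerate sample
(all values at the location) returns p = 1 with a warning. Tests compare
the exact branch against an independent sign-pattern enumeration (equality
to 10⁻¹²) and the approximation against the same oracle (|Δp| < 0.01 at
n = 20).

**LD and clumping.** LD is the squared Pearson correlation of unphased
genotype dosages over jointly non-missing samples; a pair with a constant
vector in the overlap has *undefined* r² and is reported as such (never
silently 0 or 1) — undefined r² never satisfies an LD threshold and never
counts as an LD buddy. Clumping is the greedy PLINK procedure with
inclusive thresholds (p ≤ p₁ index, p ≤ p₂ member, |Δpos| ≤ window,
r² ≥ r²_min); ties on p break by (chromosome, position), making the output
deterministic. Tested against a naive recompute-from-scratch reference on
random instances.

**Matched backgrounds.** Matching is windowed, not nearest-neighbour: a
candidate is eligible iff its MAF is within ±0.05 (absolute) and its LD
buddy count, distance to nearest gene, and gene density are each within
±50% (relative) of the query's values; a query value of zero uses the
window [0, 1]. These tolerances follow the published defaults of the
SNPsnap web tool, which the procedure re-implements at desk scale; the
requested background size defaults to 100 (the web tool's default is far
larger — scale, not logic, differs). Eligible candidates are ranked by
|ΔMAF| then lexicographic id, so matching is deterministic. Positions in
profiles are 0-based; the distance to a half-open gene interval [start,
end) is the distance to the nearest covered base (0 inside).

**Motif disruption.** A position probability matrix (pseudocount 10⁻³,
columns renormalized) scores a window as Σ_j IC_j · p_j(s_j), min/max
normalized so the consensus scores 1 and the per-column-worst sequence 0,
with IC_j the column's relative entropy against the uniform background in
bits. This is an information-content-weighted match score in the spirit of
the "ic" scoring used by motif-disruption tools; exact numeric parity with
any particular tool is a non-goal — behavioural parity (consensus-breaking
alleles are flagged) is what the tests assert. Score p-values are exact
tail probabilities under i.i.d. uniform bases: full 4^L enumeration for
L ≤ 8; for longer motifs a round-down integer-grid convolution whose
reported tail is a guaranteed upper bound on the exact tail (floor() can
lose at most one grid unit per position, so the threshold is relaxed by L
units). The grid uses 65,536 bins: with the coarser 4,096-bin grid the
L-unit threshold slack admits up to ~10⁻² of probability mass in the
distribution bulk, while at 65,536 bins the measured gap at upper-tail
scores is ≤ 2×10⁻⁴. For each SNP, every full window overlapping it is
scored on both strands (reverse strand = reverse complement), the window
maximizing max(score_ref, score_alt) is kept per motif and strand, and a
hit requires min(p_ref, p_alt) < 10⁻³ — "either allele is a significant
match", the reading adopted for the tool-provided p-value filter. Effects:
|score_ref − score_alt| ≥ 0.4 strong, ≤ 0.05 neutral, else weak (all
configurable). Windows truncated by a contig edge are skipped; a
reference-allele/genome mismatch is an error naming the SNP.

**Gene mapping and enrichment.** SNPs map to genes by strict containment in
0-based half-open intervals (a SNP at a gene's `end` is outside); an
optional `flank` widens intervals but defaults to 0. Over-representation
uses the upper-tail hypergeometric P(X ≥ k) on a universe defaulting to all
genes in the annotation (the Reactome-style web tools keep their universe
internal; here it is explicit and overridable), BH across pathways,
deterministic (p, id) ordering. Disrupted-motif TF genes are derived from
the motif identifier's leading token (the `TFNAME_…` convention of
HOCOMOCO-style libraries).

## The synthetic-data generator

The generator produces every input the pipeline consumes, with known ground
truth. Its defaults are the package's reference study conditions: 2,000
SNPs on one 1 Mb chromosome, populations of 200 + 200 samples, 20-SNP LD
blocks, Fst = 0.02, 20 planted SNPs with true MAF gap ≥ 0.15 and
association p ≤ 10⁻⁵, 40 genes, 15 pathways, 8 motifs.

- **Drift**: ancestral frequencies p₀ ~ U(0.05, 0.5); each population's
  frequency is Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) — the Balding–Nichols model,
  mean p₀ and variance F·p₀(1−p₀), degenerating to p₀ at F = 0. Verified
  against the closed-form variance by simulation.
- **Planted signal**: planted SNPs are placed one per LD block (keeping the
  signals independent under clumping) and their frequencies overridden to a
  true folded gap of delta_min + U(0.05, 0.25), capped at 0.48 — planted
  effects sit comfortably above the contractual floor, as a real effect
  would, rather than hugging the boundary. Their association p-values are
  U(0, p_max]; background p-values are U(0, 1].
- **LD**: per block and population, `n_founder_haplotypes` (default 100)
  founder haplotypes are drawn Bernoulli(freq) per SNP and every sample
  copies two founders, independently across blocks. Finite founder count is
  the sole source of LD, so within-block r² ≈ 1/K exceeds between-block
  r² ≈ 1/(2n); K = 100 keeps founder-resampling noise on panel frequencies
  (≈ 0.05 SD) subordinate to the drift signal. A single founder reproduces
  the degenerate all-samples-identical panel.
- **Summary-statistic MAF** is the folded *true* population-A frequency:
  the emulated input is a biobank-scale cohort whose sampling error is
  negligible, and a 200-sample empirical estimate would inject noise the
  real input does not carry. Population B's MAF, by contrast, is always
  estimated from the panel genotypes downstream — exactly as the method
  does on real data.
- **Panels** force each SNP polymorphic per population (one haplotype slot
  flipped if needed): variant sites are polymorphic by definition, and this
  keeps empirical MAFs strictly positive.
- **Annotation**: genes occupy one random interval per equal-width genome
  slot (disjoint by construction); pathways sample genes without
  replacement; motifs have 0.85/0.05 consensus columns and lengths 6–10.
  Each planted SNP (where it fits without covering another SNP) gets a
  motif consensus written over its position, its reference allele set to
  the consensus base and its alternate to the motif's worst base — so a
  disruption hit provably exists. The genome carries every SNP's reference
  allele at its position.
- **Determinism**: every stage draws from `default_rng([stream, seed])`;
  identical configs produce byte-identical files.

What the generator does *not* emulate: realistic demography or
recombination maps (LD is block-diagonal with sharp edges), association
effect sizes (null p-values are uniform; planted ones merely sub-threshold),
sex chromosomes, multi-allelic sites, genotyping error or imputation
uncertainty, overlapping genes, and correlated pathway membership. Passing
tests therefore demonstrate that the *selection machinery* is correct and
calibrated under the assumed structure — not that the pipeline is robust to
real-data pathologies such as stratification or array artifacts.

Under the reference conditions (10 seeds), the full pipeline recovers
94–96% of planted SNPs through the matched-null round with ≤ 1% background
selections, and every consensus-planted SNP yields a non-neutral motif hit;
`scripts/acceptance.py` recomputes these figures.

## Numerical choices and degenerate inputs

- Strict inequalities at the step-1 thresholds ("higher than 5%" read
  literally; the p-value side made strict for symmetry); both configurable.
- Variant identity is (chromosome, position, ref, alt) with an optional
  `chr` prefix stripped; SNP ids are labels, not keys.
- Filter and selection rounds preserve input order; BH returns adjusted
  values in input order; enrichment output sorts by (p, pathway id).
- Score p-values use a 10⁻⁹ relative slack below the raw threshold so the
  consensus retains its own probability mass under floating-point rounding.
- Zero survivors at any stage halts the run cleanly with a partial report
  (`halted_at` set) rather than raising.
- Degenerate conventions: all-missing genotype column → explicit error;
  monomorphic pair → undefined LD status; all values at the tested location
  → Wilcoxon p = 1 with a warning; zero pathway overlap → p = 1.

## Problem sizes used in validation

The test suite and acceptance script run at desk scale: 200 random clumping
instances (≤ 50 SNPs, ≤ 30 samples), sign-pattern enumeration to n = 12 and
100 approximation comparisons at n = 20, 100 random PWMs at L ≤ 6 plus 10
at L = 8, the full hypergeometric parameter grid to N = 60, ten full
pipeline runs at the reference conditions, and two byte-compared runs at
400 SNPs. These sizes were chosen so the entire validation completes in
about a minute while still exercising every code path at meaningful n.

## Known limitations

- Folding MAFs per population understates divergence when the minor allele
  differs between populations (a gap of f vs 1−f folds to the same value);
  documented consequence of defining Δ on folded frequencies.
- Dosage r² approximates haplotype r²; panels are treated as unphased.
- The pooled round's upper-tail behaviour means "significantly divergent"
  is relative to the supplied background distribution; users comparing
  candidate sets should keep the genome-wide background (the pipeline
  default).
- The motif score is a faithful information-content scorer but not a
  numeric clone of any external tool; disruption classes depend on the
  configurable |Δscore| thresholds.
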