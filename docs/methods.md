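# Methods

`phqtl` maps protein and phosphopeptide quantitative trait loci (pQTL,
phQTL) in a multiparent homozygous panel — modeled on the Collaborative
Cross (CC), a panel of recombinant inbred mouse strains whose genomes are
mosaics of eight founder haplotypes — and attributes phosphorylation QTL to
one of two mechanisms: transmission through parent-protein abundance
(mechanism 1) versus an independent driver of site stoichiometry such as a
kinase or phosphatase (mechanism 2).  This note documents the models, the
synthetic data that stands in for a real study, the numerical choices, and
the limits of what the tests demonstrate.

## Quantification model

Peptide intensities from isobaric-label (TMT) experiments are processed in
a fixed order:

1. **Polymorphic-peptide filter.**  A peptide whose sequence differs in any
   of the eight founder proteomes is removed: a strain carrying the variant
   allele loses the reference peptide's signal, which would otherwise forge
   a spurious local QTL.  Phosphopeptides must additionally be conserved in
   the three flanking residues on each side, since a variant next to the
   site changes the measured species.
2. **Loading normalization.**  Within each TMT batch, sample `i` is scaled
   by `phi_i = max_batch(total intensity) / total_i` computed over observed
   cells, equalizing cumulative intensity within batch (`phi_i >= 1`, with
   equality for the batch's largest sample).
3. **Bridge-relative abundance.**  Protein abundance is
   `log2((sum of peptide intensities + 1) / (same sum in the batch's bridge
   channel + 1))`; phosphopeptides use the same ratio without summation.
   The +1 pseudo-count keeps zero intensities finite.  Sums skip missing
   cells rather than zero-imputing them, which would distort bridge ratios.
4. **Missingness filter.**  Features unobserved in half or more of samples
   are dropped.
5. **Batch adjustment.**  Per feature, a linear mixed model
   `y = mu + sex + strain + batch + e` (sex fixed; strain and batch random,
   fit by REML through statsmodels MixedLM) supplies BLUP batch effects
   that are subtracted from the data.  Random-effect treatment shrinks
   batch estimates toward zero when evidence is thin.
6. **Parent adjustment.**  Each phosphopeptide is regressed (OLS) on its
   parent protein — quantified after excluding any peptide whose sequence
   matches a detected phosphopeptide — and the residual is the "adjusted"
   phosphopeptide.  By least-squares orthogonality the residual has exactly
   zero correlation with the parent on the fitting samples.
7. **Strain summaries.**  Strain average = mean of the observed sexes (a
   single observed sex stands for the strain, keeping feature coverage);
   strain difference = male − female, missing unless both sexes observed.
   Differences carry sex-by-genotype interaction signal.

## Mapping model

At marker `p` the strain-level trait is modeled as

    y_i = mu + d_ip' b + g_i + e_i,
    g ~ N(0, G_c tau^2),  e ~ N(0, sigma^2 I),

where `d_ip` is the 8-vector of founder haplotype dosages and `b` the
founder allele effects (fixed).  `G_c` is the realized genomic relationship
matrix computed from mean-centered founder dosages over all markers *except*
chromosome `c` (leave-one-chromosome-out), so the kinship term cannot absorb
the tested QTL; it is rescaled to unit average diagonal so the variance
fraction `h^2 = tau^2/(tau^2 + sigma^2)` reads as heritability.  The LOD at
a marker is `(n/2) log10(RSS_0 / RSS_1)` from generalized least squares
after whitening by the null model's covariance.

**Two-step variance profile.**  Variance components are estimated once per
feature and chromosome under the no-QTL null (REML) and frozen across that
chromosome's markers.  A brute-force oracle that re-estimates the variance
fraction at every marker under the alternative model is implemented in
`phqtl.evaluation.oracle_scan`; at desk scale (20 strains, 8 founder
effects, ~12 residual df) the per-marker REML optimum genuinely swings to
boundary values at strong-signal markers and the two approaches can differ
by several LOD there.  The two-step profile is the standard, stable choice;
the oracle quantifies — rather than hides — the approximation.

**Identifiability.**  The eight dosage columns sum to one and collide with
the intercept, so scans drop one founder column; the fit and LOD are
invariant to which.  Reported allele effects instead come from a random
effect `b ~ N(0, I tau_qtl^2)` whose BLUPs are shrunk toward zero, finite
even for founders absent at the marker, and centered.

**Heritability and sex effects** are fit at the individual level (two mice
per strain), where within-strain replication identifies the genetic
variance component; the kinship matrix is expanded across individuals.  Sex
effects are tested by a likelihood-ratio test with both models fit by
maximum likelihood (not REML), as appropriate for a fixed-effect contrast,
against chi-square with 1 df.

## Significance

Per feature, strain labels on the haplotype rows are permuted genome-wide
(1,000 times in tests, 10,000 in full-fidelity runs), the genome rescanned,
and the maximum LOD recorded; a generalized extreme value distribution fit
to the maxima converts the observed maximum into a genome-wide p-value
`p = 1 − F(max LOD)`, clamped to `[1/(n_perm+1), 1 − 1/(n_perm+1)]`.
Benjamini–Hochberg across features (per matrix kind and summary level)
gives q-values; linear interpolation of the sorted (p, q) pairs yields the
p-value where q crosses the target (0.1), mapped through each feature's
inverse GEV CDF into a per-feature LOD threshold.  A lenient threshold
(q = 0.5) defines the input set for parent-mediation analysis.

The permutation leaves the phenotype–kinship pairing intact by design, so
its exchangeable null is a trait independent of the genomes.  A trait with
real polygenic background is *not* exchangeable under genome shuffling:
LOCO scans see part of that signal as quasi-QTL evidence while permutation
replicates do not, so thresholds are mildly anticonservative for strongly
polygenic traits.  This is a property of the published scheme itself, which
the calibration study makes explicit by using genome-independent nulls.

## Mediation

*Parent mediation.*  For each detected phQTL the model is refit at the peak
marker with the parent protein as a fixed covariate (LOCO kinship
retained); the mediation LOD comes from the same QTL-vs-null contrast.
`Delta LOD % = 100 (LOD_med − LOD_orig)/LOD_orig`; below −50% the call is
mechanism 1.  Above −20% the call is mechanism 2 and the band between is
"mixed" — the −50% boundary is the scientifically meaningful one; the
−20%/mixed band is a package convention to keep calls testable.

*Mediator scans.*  For a distant QTL, each candidate mediator (transcripts
and proteins genome-wide, excluding the target and its parent) enters as a
fixed covariate in an ordinary regression without kinship (dropping kinship
here is deliberate, matching the conditional-LOD formulation; it keeps the
scan O(candidates)).  Because almost all candidates are not the true
mediator, the conditional LODs form an empirical null centered near the
original LOD; z-scores standardize them (mean/sd over all candidates;
median/MAD available) and `z < −8` flags strong candidates, with a
co-mapping flag when the candidate's own local QTL lies within 10 Mbp of
the target's distant QTL.  Strength of the QTL→mediator and mediator→target
links is summarized as `PVE = 1 − RSS_1/RSS_0` with an ANOVA F-test.

*Classification.*  A QTL is "local" when within 10 Mbp (inclusive) of the
gene midpoint on the same chromosome, "distant" otherwise; one peak (the
genome-wide maximum, ties to the lowest coordinate) is reported per feature.

## Synthetic panel

The generator plays the role of the study's raw data and every test bed.

* **Genomes.**  Homozygous founder mosaics from a first-order Markov chain
  along each chromosome: uniform start among 8 founders, switch probability
  0.1 per marker step to a uniformly chosen other founder.  Defaults: 58
  strains, 2 chromosomes × 50 markers at 2 Mbp spacing — small enough for
  10k-permutation studies on one CPU while preserving the LD-block
  structure that the local/distant call and LOCO need.  Probabilities are
  hard 0/1 (CC strains are essentially fully inbred); `blur_probabilities`
  adds symmetric noise for robustness tests.
* **Traits.**  Strain-level latents on a unit-variance log2 scale with
  explicit shares: planted QTL PVE (0.4 for local pQTL; 0.7 for mechanism-2
  mediators, matching a strong kinase-like driver), polygenic share 0.15
  drawn from the realized GRM, the remainder iid noise (placed at sample
  level, scaled so strain averages carry the stated share).  Sex effects
  shift males by +1 latent SD by default, planted either on the parent
  protein (the phospho site inherits it and loses it upon parent
  adjustment) or on the phosphosite itself (it survives adjustment).
* **Phosphosites.**  Mechanism 1: `site = parent + N(0, 0.2)`.  Mechanism
  2: `site = mediator + 0.2 * parent + N(0, 0.2)`, the mediator being a
  protein with its own local pQTL on another chromosome.  The lognormal
  peptide-noise model below is a stand-in — no generative model for
  phosphopeptide noise is established — and is parameterized so sensitivity
  can be probed.
* **Observation layer.**  Latents are exponentiated, split across 3–6
  peptides per protein with lognormal ionization efficiencies (sigma 0.5),
  multiplied by lognormal per-sample loading (sigma 0.2) and peptide-level
  noise (sigma 0.25), given a per-batch × per-protein log2 artifact
  (sigma 0.3) on non-bridge samples representing batch effects that survive
  bridge normalization, and masked missing completely at random (rate 0.1;
  the real missingness mechanism is intensity-dependent and is deliberately
  not modeled).  The bridge channel is the per-batch mean of non-bridge
  intensities, mimicking a pooled digest.  11-plex batches: 10 samples plus
  one bridge.  4.4% of peptides receive an injected founder variant
  (sometimes flank-only for phosphopeptides, to exercise the flank rule).
* **What this does not show.**  Passing tests demonstrate correctness of
  the statistical machinery under this generative model — not robustness to
  ratio compression, isotope interference, intensity-dependent missingness,
  shared-peptide ambiguity, or real CC pedigree structure (strains here are
  unrelated beyond chance; kinship information comes from realized marker
  sharing).

## Numerical choices

* LMMs with one genomic variance component are fit spectrally: rotate by
  the GRM's eigenvectors, 1-D profile (RE)ML over the variance fraction
  `h` on a 21-point grid refined by bounded Brent (tolerance 1e-7), bounds
  `[0, 1 − 1e-6]`.  Non-finite profile values (degenerate weights) are
  treated as −inf.
* Scans solve per-marker GLS by exact least squares (`lstsq`, which also
  resolves markers where a founder is absent).  The permutation engine uses
  a compiled kernel exploiting hard founder calls: for indicator dosages,
  the normal equations are founder-group aggregations of a fixed n × n
  inverse-covariance matrix, with a relative ridge of 1e-10 guarding
  rank-deficient markers; the dense numpy fallback handles blurred
  probabilities.  The two paths agree to ~1e-11 LOD and the kernel matches
  direct GLS to ~1e-9.
* GEV fitting is scipy maximum likelihood; a warning fires below 100
  permutations; degenerate (constant) samples are an error.
* BLUP allele-effect variance is optimized on a log-ratio scale in
  `[e^-12, e^8]` with a boundary check that collapses to ~zero variance
  when the likelihood prefers no QTL effect; Woodbury identities keep all
  solves 8 × 8.
* BH interpolation: q-values are made monotone by a cumulative maximum
  before `np.interp`; when no feature attains the target FDR the threshold
  for the smallest achievable q is reported and the table flagged.
* Mediation z-scores use the population (ddof 0) standard deviation so the
  candidate set standardizes exactly to mean 0, sd 1.

## Known limitations

* One QTL per feature (the genome-wide maximum); no multi-QTL or epistatic
  models, no confidence intervals for location.
* The X chromosome receives no special dosage treatment.
* Permutation thresholds are mildly anticonservative for strongly polygenic
  traits (see Significance above).
* The per-marker variance-refit oracle and the production two-step scan
  diverge at strong-signal markers in small panels; with dozens of strains
  the two-step profile is the defensible choice, but users extrapolating to
  very small panels should expect LOD values to depend on that choice.
* Mediation is conditional-regression screening, not formal causal model
  selection; a mediator flagged at `z < −8` is a candidate, not a proof.
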