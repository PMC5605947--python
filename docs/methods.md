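# Methods

This note records the models, algorithms and design choices behind
haploscan, in the spirit of a statistical supplement: what is computed,
under which assumptions, and what the synthetic-data experiments do and
do not demonstrate.

## Haplotype windows

Windows are defined in genetic distance, not physical distance: SNP bp
positions are mapped to cM by linear interpolation between genetic-map
anchors (positions beyond the terminal anchors extrapolate at the
terminal interval's rate, which is never negative because cM is
non-decreasing in bp). For each window size w ∈ {1, 0.5, 0.25} cM the
window slides in steps of w/4 starting from 0 cM; the last gridded
window is the final full-size window fitting on the chromosome, and if
SNPs beyond its end would be uncovered one terminal window ending at
the chromosome end is appended. Membership is half-open [start, end)
except for the last window on a chromosome, which is closed — this
prevents double counting at shared boundaries while covering the
terminal SNP. Windows with no SNP are discarded. A window's reported
bp span is that of its outermost member SNPs.

A haplotype allele is the exact SNP-allele string over a window's
members on one chromosome copy; no mismatch tolerance is applied.
Frequencies are counts over the 2n chromosomes and per-individual
dosage is the count of the string among an individual's two haplotypes,
so per window Σ frequencies = 1 and per individual Σ dosages = 2 —
these conservation identities are asserted by property tests.

Haplotype QC: a window with fewer than 5 member SNPs contributes no
assessed alleles (all allele strings of a window have the window's
length, so the "fewer than 5 SNPs" rule is a window-level rule); an
allele with frequency < 0.005 or Hardy–Weinberg P < 10⁻⁶ is excluded
from assessment but retained in the alternative class, so it still
counts in other alleles' frequency denominators and in the dosage
complement. The HWE test collapses the window to a biallelic system
(this allele vs all others) and applies a 1-df chi-square on the
observed 0/1/2 diplotype counts, matching the dosage coding used for
association; the chi-square is only trusted at n ≥ 50 (below that the
allele is not excluded on HWE grounds).

## Mixed-model association

Variance components are estimated by average-information (AI) REML with
a 3-iteration EM warm-up, convergence when the relative change in the
restricted log-likelihood falls below 1e-8 (at most 100 iterations),
and step-halving whenever a proposed update would decrease the
restricted likelihood. Components are constrained to at least
1e-6 × var(y); a component pinned at that floor re-enters whenever its
gradient turns positive, because every update moves all non-fixed
components. The AI system is solved with a pseudoinverse so that an
unidentifiable component (e.g. a zero or duplicated relationship
matrix) cannot derail the other components. For a single GRM the model
is rotated into the GRM's eigenbasis, making each iteration O(n·p²)
after one eigendecomposition; the two-matrix model uses the direct
O(n³) iteration. Standard errors come from the inverse AI matrix;
heritability standard errors use the delta method on σ²ᵤ/(σ²ᵤ+σ²ₑ).

The genome scan estimates null variance components once per chromosome
(with the LOCO G, plus thresholded G_t for the discovery model) and
holds them fixed for every haplotype on that chromosome; each haplotype
is then tested by GLS, β = d'Py/d'Pd with se = (d'Pd)^(-1/2), where
P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹. This is the standard mixed-model
association approximation: refitting the variance components for every
haplotype would multiply the cost by the number of haplotypes while
changing small-effect estimates negligibly. An exact per-haplotype
refit is available behind `refit_per_haplotype=True` and is compared
against the approximation in the test suite. Haplotypes with constant
dosage, or collinear with the covariates (d'Pd ≈ 0), are flagged
untestable rather than dropped silently. Age and sex enter as linear
fixed effects; binary phenotypes can be passed as 0/1 y under the same
linear model (no liability-scale machinery).

GREML heritability is the one-GRM model on a relatedness-pruned
subsample: individuals are removed greedily (highest count of pairs
with relationship > 0.025 first, ties to the lowest index) until no
pair exceeds the cutoff. Greedy pruning does not maximize the retained
n, but it is deterministic and order-invariant.

The GRM uses the same (x−2p)²/(2p(1−p)) form on the diagonal as off the
diagonal, with allele frequencies estimated from the analysis sample;
monomorphic SNPs are excluded with a warning. G_t zeroes off-diagonals
below 0.05 by signed comparison (negative relationships are zeroed),
reading the threshold rule literally.

## Clumping, threshold, meta-analysis, power

Clumping visits haplotypes by ascending P (ties: chromosome, bp, allele
string, making the result invariant to input order); each unassigned
haplotype becomes an index and captures all unassigned same-chromosome
haplotypes with dosage r² ≥ 0.4. No bp-distance window is imposed: r²
is computed within-chromosome only, which reproduces the "independently
segregating" semantics without an arbitrary distance cutoff (the
threshold and a distance cutoff are configurable). The significance
threshold is α divided by the independent count, reported at one
significant figure (0.05/1,070,216 = 4.67e-8, reported 5e-8).

Meta-analysis is fixed-effects IVW: wᵢ = seᵢ⁻², pooled β = Σwᵢβᵢ/Σwᵢ,
pooled se = (Σwᵢ)^(-1/2), two-sided normal P. A haplotype missing from
a cohort (not observed there, or untestable) contributes "?" to the
direction string and is dropped from the pooled estimate. No
heterogeneity statistics are computed. Replication power uses the
non-central χ²₁ with ncp = n·r²/(1−r²) at the α = 0.05 critical value;
the analytic curve is checked against 50,000 simulated score tests in
the test suite.

## g score

g is the first unrotated principal component of the standardized test
battery (PCA on the correlation matrix). The sign is fixed after the
eigendecomposition so the loadings sum positive — higher g means better
average performance — and reversed-scored timed tests should be
log-transformed (log of the mean time across repeated trials) but not
negated; their loading comes out negative. The proportion of battery
variance explained is λ₁/K. Missing test scores are handled by
listwise deletion with a reported count; no imputation or rotation.
Standardization is unstratified; age and sex are model covariates
downstream rather than pre-adjustments.

## Checksum overlap detection

500 shared SNPs (panel serialized so both cohorts use the identical
selection and order) are split into 10 equal batches, each sorted by
position; per individual and batch the 0/1/2 genotype codes (missing
encoded as "M" so missingness patterns cannot silently collide) are
concatenated and hashed with CRC-32 — a fixed, documented checksum
choice. Overlap is declared at 10/10 matching batches by default; the
per-batch match count is always reported and the threshold is
configurable down to the single-batch sensitivity mode. Two planted
duplicates among 10⁶ independent cross-pairs are recovered with zero
false 10/10 matches in the validation experiment.

## The simulator

The simulator generates what the pipeline consumes: a genetic map
(exponential cM gaps normalized to the chromosome length, bp gaps
following the cM gaps at ~1 Mb/cM with log-normal rate jitter, or
uniform spacing on request), truth-phased founder haplotypes, a
nuclear-family pedigree, gene-dropped offspring and a cognitive
battery.

Founder LD is modelled with block template pools: within each 0.5 cM
segment, 6 ancestral haplotypes are constructed so each SNP's pool
frequency approximates a target drawn from the MAF range (at least one
carrier and one non-carrier template), and every founder chromosome
copies one template per block with a 1% per-SNP copying error. This is
the simplest structure that yields a handful of haplotype alleles per
window at non-trivial frequencies; it does not reproduce human LD decay,
allele-frequency spectra or recombination hotspots. Meiosis is
Poisson/Haldane — crossover counts per chromosome are Poisson with mean
equal to the map length in Morgans, positions uniform in cM, no
interference — which is adequate for generating realized relatedness
and window-scale haplotype sharing. Families are founder couples with
0–4 offspring (distribution configurable); couples share their
children's household identifier.

The trait is g = polygenic + causal-haplotype + family-environment +
noise. The polygenic term sums N(0,1) effects of standardized SNP
dosages (optionally restricted to a chromosome subset) rescaled to
exactly h² of the variance; each causal window contributes the
standardized dosage of one designated haplotype allele (frequency
closest to 0.2, designated once on the founder pool when several
cohorts are simulated together so the causal unit is identical across
cohorts); the family-environment component is shared within households;
components are rescaled to their exact sample variances. Defaults —
h² = 0.30 (inside the 0.17–0.41 range reported for g), household c² =
0.20, four subtests with loadings in (0.45, 0.65) so the first PC
explains just under half of the battery variance, sex Bernoulli(0.5)
and age uniform with small nominal fixed effects on the subtests — are
the simulated study conditions; per-haplotype causal variances around
0.004 match the reported scale of top-haplotype effects.

## Validation experiments and their problem sizes

`scripts/acceptance.py` (and the mirroring tests) use desk-scale
problem sizes, chosen so each experiment is statistically informative:

* **GREML recovery** — unrelated cohorts of n = 2,000 over 5
  chromosomes × 1,000 SNPs (m = 5,000), h² ∈ {0, 0.2, 0.5}; estimates
  recover the truth within two standard errors. With ~5% probability a
  single replicate legitimately falls just outside two s.e.
* **Null-scan calibration** — a gene-dropped family cohort of ~2,000
  individuals (1,060 founders, 4 chromosomes × 750 SNPs). Traits are
  drawn per chromosome from the discovery model's own null,
  y ~ MVN(0, 0.3·G_loco + 0.2·G_t + 0.5·I), so the two-GRM analysis is
  exactly correctly specified and the rejection rate at α = 0.05 is a
  true type-I error measurement; the single-GRM analysis cannot
  represent the extra close-relative covariance with one genome-wide
  coefficient and shows λ inflation (≈ +0.07–0.09 here). For this
  experiment windows are tiled without overlap and two independent
  trait draws are pooled per chromosome, so the ~14,000 tests behave
  close to independently and the binomial confidence interval is the
  appropriate yardstick; quarter-step overlapping windows would make
  the nominal test count roughly triple the effective count.
* **Checksum experiment** — 1,000 × 1,000 individuals (10⁶ pairs) at
  500 panel SNPs.

What passing these experiments shows: the estimators are unbiased at
simulation scale, the test is calibrated under its own model, and the
bookkeeping (conservation, clump bounds, thresholds) is exact. What
they do not show: behaviour under real human LD, genotyping and phasing
error (phased input is assumed complete and correct), population
stratification beyond family structure, or cohort sizes and SNP
densities of the real studies — the published window occupancies
(157/79/34 SNPs per 1/0.5/0.25 cM window) are emulated only as ratios,
not absolute counts.

## Numerical and interface conventions

Coordinates are 1-based bp (VCF convention); regions are closed
intervals intersected against the haplotype's outermost-SNP span.
Cross-cohort haplotype matching is by identical allele string over the
shared SNP panel within the same cM window; a haplotype absent from a
replication cohort is reported as missing, never imputed. Strand-
ambiguous (A/T, C/G) sites are kept but flagged during harmonization;
ref/alt-swapped sites are retained with a dosage flip. All randomness
flows through explicit seeds (one stream per simulation stage), so
identical configurations reproduce outputs bit-for-bit.

## Known limitations

Phasing itself is out of scope (inputs are already-phased or
truth-phased). The simulator's LD is block-structured, not
coalescent-accurate; there is no mutation, no X chromosome, no
missingness. The replication model treats g as quantitative throughout.
LD-score-style stratification diagnostics are not implemented; the λ_GC
diagnostic stands in. GCTA binary GRM files are not read or written —
GRMs are exchanged as plain triplet TSVs.
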