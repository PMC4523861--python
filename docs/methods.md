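# Methods

## Quantification model

A SILAC experiment measures each peptide species as a collection of PSM
events spread over charge states and SCX fractions, in two channels
(heavy/light). The package's quantification unit is the *unique modified
peptide*: the peptide key is the full sequence with phosphosite placement
encoded (lowercase residue), so two placements of the same phosphate are
distinct quantifiable species. Per peptide and biological replicate the
channel intensities are summed over all events and the abundance ratio is

    log2( sum treated / sum control )

The treated channel defaults to heavy and is configurable per replicate
(label swaps). The ratio of sums weights high-intensity (well-measured)
events more than a mean of per-event ratios would; the two disagree
whenever event intensities are unbalanced, and the regression tests pin
the ratio-of-sums value. Events with a zero in one channel still
contribute the other channel to its sum; a peptide-replicate whose
treated or control *sum* is zero is flagged with a reason code
(`zero-numerator` / `zero-denominator` / `zero-both`) and excluded from
downstream statistics rather than silently dropped.

Normalization subtracts, per replicate, the median log2 ratio of all
quantified peptides — including non-phosphopeptides from the flow-through
fractions, which are assumed mostly unregulated and anchor the zero
point. Only defined ratios enter the median (a median over flagged rows
would be undefined). The implementation applies one refinement pass
(`offset += median(x - offset)`); without it the post-normalization
median of an even-sized population can sit one ulp away from zero.

## Differential statistics

Peptides with at least `min_replicates = 3` defined normalized ratios
are tested against zero with a two-sided one-sample Student t test.
Degenerate inputs are handled explicitly: zero variance with zero mean
gives p = 1, zero variance with nonzero mean gives the smallest positive
double as a sentinel; both are flagged. Benjamini–Hochberg step-up
q-values (computed via statsmodels) are thresholded at FDR = 10% in a
single pass over all testable phosphopeptides; direction is the sign of
the mean log2 ratio.

An empirical-Bayes *moderated* t option (off by default) shrinks each
peptide's variance toward an F-distributed prior fitted across peptides
by the method of moments (prior df by trigamma inversion; when the
observed log-variances are under-dispersed the prior df is infinite, the
prior variance is the mean sample variance, and the total df is capped
at the pooled residual df). The implementation reproduces Bioconductor
limma::eBayes p-values to ~1e-13 relative error, which is frozen as a
test with limma as the independent oracle. With 3–4 replicates the
unmoderated t has little power: at a planted |log2| effect of 1.0 and
noise SD 0.3 its recall at the BH-effective threshold is ~45–55%,
because the df-3 variance estimate is itself noisy. The moderated
variant recovers essentially all planted effects at the same design
point while holding the empirical FDR near nominal; the recovery test
exercises it explicitly. Under a pure null both variants keep the
realized false-discovery proportion at the BH 10% level within
Monte-Carlo error.

## Site mapping

Peptides are located in their assigned protein by substring search
(first occurrence wins, with a warning when a peptide maps more than
once — rare for tryptic peptides). Protein coordinates are 1-based
throughout. The per-site localization confidence is the maximum score
over supporting PSM events (one confident observation suffices), and the
confidence filter keeps scores strictly above 80, following the
phosphoRS convention of "above 80". Windows are 13-mers (half-width 6,
the de facto standard for phospho-motif work, configurable) padded with
`_` at protein termini. Peptide-level calls roll up to unique sites;
a site supported by both an up and a down peptide is flagged `conflict`
and excluded from motif foregrounds, and regulated evidence outranks
`unchanged` support (a missed-cleavage variant that fails the replicate
filter should not veto a significant call).

## Motif discovery

Extraction is the iterative greedy scheme of Motif-X. Within the current
foreground/background, every candidate (offset, residue) pair with
foreground count ≥ `min_occurrences` (default 20) is scored by the exact
upper-tail binomial p-value of its foreground count given the current
background frequency; the smallest p below `p_threshold` (default 1e-6)
is fixed, both sets are reduced to matching windows, and the search
repeats. The motif score is the sum of stage-wise −log10 p; the fold
change compares match proportions at the *pre-reduction* sizes (Motif-X's
"fold increase" semantics). Matched foreground windows are then removed
and extraction restarts for further motifs. Ties on p are broken by
larger foreground count, then lexicographic (offset, residue), making
extraction fully deterministic. Background residue counts of zero
receive a pseudo-count of 0.5 occurrences so the background frequency
stays inside (0, 1); the same pseudo-count keeps fold changes finite
when no background window matches a full motif.

Binomial tails are summed term-by-term in log space
(logsumexp over binomial log-pmf terms), so stage p-values far below the
double-precision range (common for strong motifs) still contribute
exact −log10 p increments to the score. Central residues are grouped
into classes before extraction; S and T are pooled by default (the
conventional pS/pT treatment) with Y separate, and the center offset is
never a candidate position.

The logo matrix is the signed per-cell analogue: −log10 of the
upper-tail p where a residue is over-represented, +log10 of the
lower-tail p where under-represented, magnitudes capped (default 10) for
display. It is a display statistic for PhosphoLogo-style figures, not a
multiple-testing-corrected inference.

## Kinase classes and PSSMs

Window classification uses a declarative priority rule table:
proline-directed first (P at +1; a strict mode additionally requires P
at −2, covering the stricter reading of "proline at +1 and −2"), then
basophilic (R/K at −3 or −2, H at −3 only — histidine's basophilic
contribution is conventionally upstream-proximal), then acidophilic
(≥ 2 of D/E within +1…+3), else `other`. Every window receives exactly
one class (property-tested). PSSM scoring is additive log-odds over
non-padding offsets; it is a deliberately simple stand-in for
network-context kinase predictors, which need resources (kinase model
libraries, protein association networks) outside this package's scope.
The rule table and matrices are data, editable without code changes.

## Synthetic data generator

The generator emulates the study design the pipeline targets: a random
proteome (residue frequencies approximating a vertebrate proteome,
configurable), 4 biological replicates, peptides observed in charge
states 2–3 across 6 SCX fractions, log-normal base intensities
(log10 mean 6.5, SD 0.6), per-replicate global log2 biases, 10% missing
replicates per peptide, and localization scores from a
high-confidence/ambiguous mixture (75% near 93 ± 4, else 60 ± 12) so the
localization filter is genuinely exercised. By default 5% of
phosphopeptides are up- and 5% down-regulated with |log2| effect 1.0 and
measurement noise SD 0.3 — a few hundred regulated species among
thousands, matching the scale of acute-stimulation phosphoproteome
studies. Regulated sites have their motif residue written into the
protein sequence itself (R at −3 for up, P at +1 for down), so site
windows extracted downstream genuinely carry the motif; peptides occupy
disjoint 30-residue slots so edits never collide.

Noise enters once per peptide × replicate and is shared across that
pair's PSM events, whose intensities split by a Dirichlet-like
partition; this preserves log2(ΣH/ΣL) = effect + bias + noise exactly,
so planted effects are recoverable without estimator bias (the
zero-noise test demands exact identity). Event charge/fraction labels
are drawn independently per event, so repeated PSMs of one
charge × fraction can occur, as in real search-engine output.

What the generator does **not** emulate: intensity-dependent
(missing-not-at-random) dropout, per-event ratio distortion
(e.g. isotope impurity, ratio compression from co-eluting peptides),
retention-time structure, multi-phosphorylated peptides, shared peptides
between proteins, and correlated replicate noise. Tests passing on this
generator therefore demonstrate correctness of the computation and
calibration under idealized noise, not robustness to those real-data
pathologies.

## Problem sizes and numerical choices

Simulation-based checks run at deliberately modest sizes chosen to give
stable statistics: the null-calibration check uses 5000 peptides × 4
replicates over 200 seeds; planted-recovery checks use 300–2000
phosphopeptides over 5–20 seeds; motif-recovery uses 200-window
foregrounds against 2000-window backgrounds over 50 runs. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config + seed reproduces outputs
bit-for-bit. p-values are kept strictly positive (smallest-double
sentinel) so BH input validation of (0, 1] is meaningful.

## Known limitations

- Peptides are assumed to map to a single protein; shared/razor peptide
  handling is out of scope.
- The localization filter consumes per-site scores as given; it does not
  recompute localization from spectra.
- Motif extraction follows the Motif-X convention of a hard significance
  threshold per stage; no multiplicity correction is applied across the
  (offset, residue) grid.
- The site/peptide aggregation treats a site's supporting peptides
  symmetrically; isoform-aware mapping is not attempted.
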