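# Methods

`aedesid` evaluates a two-probe multiplex TaqMan qPCR assay that
discriminates *Aedes aegypti* from *Aedes sierrensis* through fixed SNP
differences in the mitochondrial COI barcode. The package covers the full
evaluation workflow: simulation of tissue and eDNA panels, species
calling, latent-class proxy truth for unverified eDNA samples, diagnostic
sensitivity/specificity with confidence intervals, pooled Ct summaries,
Welch comparisons, and two-graph ROC (TG-ROC) Ct-cutoff selection. This
note records the models, the defaults and why, and the choices made where
the design was genuinely open.

## Data model

One qPCR well yields a `ReplicateResult`: the instrument-called
amplification flag and, when amplification occurred, the cycle threshold
(Ct) in (0, 40] — the assay runs 40 cycles, so 40 is a hard ceiling.
Amplification is taken as instrument truth; re-thresholding fluorescence
curves is out of scope, and an amplified well without a Ct is an error
(the lower-Ct calling rule needs a number) rather than an imputation
target. Tissue specimens carry a morphologically verified species; eDNA
site samples do not, and always carry 3 replicates x 2 probes = 6 wells.

eDNA results are recoded for the latent-class model as six two-level
indicators (2 = amplification, 1 = none), ordered sierr-probe replicates
1–3 then aegypti-probe replicates 1–3. Any fixed order is statistically
equivalent; one must be canonical for reproducibility.

## Species calling

A channel is positive when at least one of its wells amplified with Ct at
or below the channel's cutoff (default 40, i.e. no thresholding). One
positive channel calls that species; two positive channels call the
lower-Ct channel, since a lower Ct reflects higher target-DNA abundance
and dual amplification is interpreted as non-specific cross-amplification
— the two species occupy different larval habitats (artificial containers
vs treeholes) and are not expected to co-occur in one sample. An exact Ct
tie is not defined by the field convention; the call goes to the
sierr-probe (canonical channel order) and is flagged, preserving
auditability rather than pretending ties cannot happen. Multi-replicate
tissue records are called per replicate and aggregated by majority vote,
lower total deciding Ct breaking ties — the least-assumption aggregate.

Confusion counts are per-channel: for a specimen verified as species S,
the S channel contributes TP (amplified) or FN (not), and the other
channel FP or TN, so each specimen adds one positive-truth and one
negative-truth unit. eDNA samples are scored identically per extraction
replicate against the latent-class proxy truth. The No Detection class
has no correct channel: both probes count toward specificity only, its
sensitivity being undefined for lack of true positives.

## Synthetic panels

The tissue generator draws, per specimen, a correct-channel amplification
with probability 1 − fn_rate (Ct ~ Normal(mean, sd) truncated to (0, 40]
by rejection; the truncated tail mass is negligible for every default
parameterization and generation fails loudly if a parameterization makes
it degenerate) and a wrong-channel false positive with probability
fp_rate. Defaults are the eight published evaluation groups: group sizes
(114, 119, 24, 132, 31, 40, 47, 72), per-group Ct mean ± SD, and
false-negative/false-positive proportions (e.g. field-collected adult
*Ae. sierrensis*: fp 25.0%, fn 0%; field larvae: fn 11.8%). The published
table lists two colony-labelled adult *Ae. sierrensis* Ct rows; the
second (14.567 ± 1.231) is assigned to the field-collected adult group,
and the generated dataset's metadata records that mapping. No
false-positive Ct distribution is published for tissue, so wrong-channel
Cts default to 35.3 ± 3.1, the late-cycle scale observed for non-specific
amplification in environmental samples.

The eDNA generator draws each site sample's latent class (uniform
prevalences by default over *Ae. sierrensis*, *Ae. aegypti*, No
Detection), then amplifies each of the 6 wells independently with the
class's per-probe probability — matching the conditional-independence
assumption of the latent-class model, so the generator sits inside the
fitted model family. Correct-probe Ct distributions are the published
true-positive summaries (30.090 ± 4.482 sierr; 32.535 ± 4.126 aegypti);
cross-probe and No-Detection amplifications use the published
false-positive summaries (37.008 ± 1.732, 35.290 ± 3.133, 34.100 ± 4.903,
37.544 ± 1.348). Amplification probabilities are defaults, not published
values: 0.95 for a class's correct probe and 0.05 otherwise, a
"high/low" regime consistent with the reported per-class diagnostic
performance. The default scale is 168 pattern rows — 56 sites filtered in
triplicate, each extraction replicate contributing one 6-indicator row —
the sample size implied by the published information criteria.
Amplification flags and Ct magnitudes are independent given the channel;
no joint detection/Ct model, eDNA degradation kinetics, inhibitors, or
larval-density effects are modeled. Passing tests therefore demonstrate
correctness of the analysis machinery under the assumed structure, not
robustness to real-data violations of it (replicate correlation,
inhibition, curve-shape artifacts).

## Latent-class model

For R classes with prevalences p_r and response probabilities
π_jr = P(indicator j amplifies | class r),

P(y) = Σ_r p_r Π_j π_jr^{y_j} (1 − π_jr)^{1 − y_j},

fitted by EM on the unique-pattern sufficient statistics. E-step:
posteriors ∝ p_r × conditional likelihood (computed in log space with a
log-sum-exp mixture). M-step: prevalences become mean posteriors,
responses the posterior-weighted indicator means. Responses are clamped
to [1e-6, 1 − 1e-6] so boundary solutions never produce log(0).
Convergence is an absolute log-likelihood improvement below 1e-8 or 5000
iterations. Mixture likelihoods are multimodal, so 20 random starts
(responses ~ Uniform(0.1, 0.9), prevalences ~ symmetric Dirichlet(1)) are
used by default and the best-likelihood start kept. The EM log-likelihood
is non-decreasing by construction and the test suite asserts it at every
iteration.

Goodness of fit is computed over all 2^6 = 64 response patterns:
G² = 2 Σ_{O_k>0} O_k ln(O_k/E_k) (observed cells only) and Pearson
χ² = Σ_{E_k>0} (O_k − E_k)²/E_k, with df = 64 − 1 − n_params and
n_params = (R − 1) + 6R. These are the standard sparse-multinomial cell
conventions. Model selection fits each candidate R and chooses minimum
BIC (N = number of pattern rows); the full AIC/BIC/G²/χ² table is always
returned and per-criterion winners recorded, so a disagreement between
criteria is reported rather than silently resolved.

The three-class fit is labeled by response profiles: with s_r (a_r) the
mean response over sierr (aegypti) indicators, argmax(s_r − a_r) is
*Ae. sierrensis*, argmax(a_r − s_r) is *Ae. aegypti*, the remainder No
Detection. Labeling fails loudly when the argmaxes coincide or the
winning margin is below 0.1 — an uninterpretable fit should surface, not
be guessed at. Each sample's proxy truth is its modal-posterior class.

## Diagnostic statistics

Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) are undefined (None)
on a zero denominator. Intervals use the simple asymptotic (Wald) method
without continuity correction, p ± z√(p(1−p)/n) with z = 1.96; upper
bounds above 100% are capped at 100%. The cap is the published
convention; the lower bound is symmetrically clamped at 0 to keep the
interval inside [0, 1], with raw bounds retained in the result. The CI's
n is the estimate's own denominator (tp+fn or tn+fp) — the only
self-consistent choice. Exact (Clopper–Pearson) and Wilson intervals are
deliberately not offered.

Pooled Ct summaries combine subgroup (n_i, mean_i, sd_i) exactly:
pooled mean = Σ n_i mean_i / N and pooled sum of squares
Σ[(n_i − 1) sd_i² + n_i(mean_i − pooled mean)²] over (N − 1). The rule is
associative and reproduces the statistics of the recombined raw sample to
machine precision (tested against a brute-force oracle at 1e-9).

Welch's unpaired two-tailed t-test is computed from summary statistics
(raw per-well Ct data are not available for the published comparison),
with Welch–Satterthwaite df and a scipy t distribution for p and the 95%
CI. The published prefilter comparison does not state its per-arm n; the
package takes n explicitly, and the acceptance script uses 24 per arm
(8 split samples x 3 filter replicates).

## TG-ROC

Sensitivity and specificity are swept over a maximum-Ct cutoff grid from
10.0 to 40.0 in 0.5-cycle steps (10 is below every plausible tissue Ct;
the published convention fixes the step, not the origin). Sensitivity is
non-decreasing and specificity non-increasing in the cutoff by
construction. Cutoff selection: a crossing — strict sign change of
se − sp between adjacent grid points, or equality at an isolated grid
point — selects that grid cutoff (a between-point sign change takes the
lower adjacent point: the cutoff must live on the grid, and lower is the
conservative, stricter choice); curves that coincide over a run of two or
more grid points and then diverge select the run's last point; curves
that never meet, or coincide through the end of the grid, default to 40,
the final qPCR cycle. Equality uses a 1e-12 tolerance — the curves are
exact small-integer fractions, so this only guards float accumulation.
Multiple isolated crossings return the lowest and flag the curve. The
selection is grid-resolution limited by design; refining the grid below
0.5 cycles can move the selected cutoff within one grid step.

## Oligo scan

The six published primers/probes (fluorophore, quencher and internal ZEN
tags stripped to the matchable sequence) are slid over both strands of a
reference; minus-strand binding is detected by matching the oligo's
reverse complement on the plus strand, with coordinates reported in the
supplied reference frame. Matching is Hamming-only — the assay's
discrimination rests on substitution SNPs, so gapped alignment is out of
scope — and IUPAC ambiguity codes in the reference match any compatible
base. The assay report flags any oligo that matches a non-target
reference at least as well as its target.

## Pipeline and reproducibility

The pipeline derives an independent per-step seed substream from the
single run seed via seed sequences, so identical config + seed gives
byte-identical outputs and any downstream step can be re-run from saved
intermediates with identical results. The manifest lists every written
file with a SHA-256 hash.

## Problem sizes

Default analysis scale is the study scale: 579 tissue specimens in eight
groups and 168 eDNA pattern rows. Statistical stress tests use 10,000
specimens per group for generator round trips (3-sigma binomial
tolerances), 1,000 sites for latent-class parameter recovery (errors
within 0.05 after label alignment), and 5,000 sites for class-frequency
checks.

## Known limitations

* The generator's conditional-independence and independence of Ct from
  detection are modeling conveniences, not validated properties of eDNA.
* Mixed infections (both species truly present) are not modeled or
  called; dual amplification is always resolved to one species.
* The simple asymptotic CI degenerates to zero width at p ∈ {0, 1};
  boundary estimates therefore look more certain than they are. This is
  the published convention, kept deliberately.
* Tissue false-positive Ct parameters are package defaults, not
  published measurements.
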