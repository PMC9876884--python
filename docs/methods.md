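# Methods

## Measurement model

Flow cytometry measures relative fluorescence of stained nuclei. With an
intercalating dye (propidium iodide, PI) fluorescence is proportional to
total DNA amount; with a base-specific dye (DAPI, AT-preferential) it also
depends on base composition. `ploidyflow` implements the standard
internal-calibration estimators:

* **2C value.** For a sample co-processed with an internal standard of
  known genome size (here *Solanum lycopersicum*, 2C = 2.00 pg),

  `2C_sample = mean_G0/G1_peak(sample) x 2C_standard / mean_G0/G1_peak(standard)`.

  The estimator is scale-invariant — instrument gain cancels in the ratio.

* **AT% / GC%.** With R_PI and R_DAPI the sample/standard intensity
  ratios for each fluorochrome,

  `AT%_sample = AT%_standard x (R_DAPI / R_PI)^(1/r)`, `GC% = 100 - AT%`,

  where r is the DAPI binding-length exponent (default 3: DAPI needs runs
  of ~3 AT base pairs per binding site) and AT%_standard = 64.50 for
  tomato. With the simulator's DAPI mean proportional to
  2C x (AT/100)^r, the ratio-of-ratios exactly cancels 2C and gain, so
  the estimator is unbiased under the model.

* **QC rule.** Only G0/G1 peaks with CV strictly below 5% are accepted
  for estimation. The threshold is configurable; the strictness at the
  boundary (4.99 passes, 5.00 fails) is fixed by the rule's wording
  "less than".

## Peak detection

Real instruments report histogram peaks via vendor software; here
detection must be reproducible and testable, so it is model-based:

1. Candidate peak positions come from a 512-bin histogram smoothed with a
   Gaussian kernel (sigma 2 bins), retaining local maxima with prominence
   at least max(3 counts, 1% of the maximum).
2. Candidates are augmented with caller-supplied *expected positions*
   (typically the internal standard's calibrated channel). Expected
   positions are always kept as seeds; a histogram bump within 0.5% of a
   seed is treated as coincident, anything further is a separate seed.
   This matters because a bump slightly offset from an expected position
   is usually a *merged pair* (e.g. a 1.90 pg sample peak against the
   2.00 pg standard — under 2 pooled SD apart at CV 2–3%) that plain
   mode-finding cannot split.
3. A one-dimensional Gaussian-mixture EM, with an optional exponential
   debris component (scale estimated by EM), is fitted for k = 1..max_peaks
   components seeded from the top-k candidates; k is chosen by BIC.
4. Events are then assigned deterministically: each event belongs to the
   nearest fitted peak mean if within 3 fitted SD of it (ties to the lower
   peak); unassigned events count as debris and are excluded from
   event-fraction denominators. Peak mean, SD and CV are recomputed from
   the assigned events, so `cv == 100*sd/mean` holds exactly.
5. Peaks below `min_fraction` (default 0.05) of assigned events are
   dropped and fractions recomputed; an empty result carries a
   `no_peak_above_min_fraction` flag instead of raising.

Hard assignment slightly biases the means of strongly overlapping peaks
(truncation at the midpoint); at the 1.90/2.00 pg overlap this contributes
below ~1% to the 2C estimate and is included in the recovery bounds below.

The standard peak cannot be distinguished from sample peaks by shape, so
its expected position (gain calibration or user annotation) is a required
input wherever a standard must be marked.

## Synthetic data

The simulator generates per-event intensities for both channels from one
RNG stream per sample (seeded; identical specs are bit-identical):

* Each population contributes a Gaussian G0/G1 peak at the model mean with
  SD = CV x mean; negative draws are redrawn (intensities are physical).
* An optional G2 fraction of each population sits at twice the G0/G1 mean.
* Debris follows an exponential decay truncated at the largest peak mean,
  scale 0.3 x the smallest peak mean — the standard empirical shape for
  chopping debris; its purpose is to exercise the detector, not to model
  any specific tissue.
* Defaults: CV 3% (mid-range of instrument-quality plant histograms, and
  below the 5% acceptance rule), 10 000 events per sample, standard at
  half the non-debris events.
* Populations closer than 3 pooled SD are simulated as requested but
  flagged `peaks_may_merge`, since the detector may legitimately merge
  them.

Per-event ground-truth labels are kept in sample metadata so tests can use
label-wise averages as an exact oracle. What the simulator does **not**
emulate: doublets and pulse-geometry artifacts, secondary-metabolite
staining inhibition (the stoichiometric error real guava tissue shows),
fluorescence spillover, or cell-cycle kinetics beyond the G2 fraction.
Passing recovery tests therefore demonstrate estimator correctness under
the stated measurement model, not robustness to those artifacts.

Measured closure under the defaults (100 seeds, 10 000 events, CV 3%, 5%
G2, 10% debris; computed in the test suite): mean |2C error| < 2% of
truth, mean |AT% error| < 1 percentage point, and mixoploid component
fractions (30/70 mixture at 0.95/1.90 pg next to the 2.00 pg standard)
recovered with mean error < 3 points.

## Ploidy, cytotypes, mixoploidy, hybrids

* **Ploidy** is round(2C / 1Cx_ref) with 1Cx_ref the reference monoploid
  value (default 0.475 pg, the diploid *P. guajava* value; configurable),
  2n = 11 x ploidy on the genus basic number x = 11. Calls with residual
  > 0.25 x 1Cx_ref are flagged ambiguous; 0.25 splits the distance
  between adjacent integer ploidies symmetrically at half the flagging
  band and is configurable. Odd levels are allowed (3x, 5x, 7x cytotypes
  occur).
* **Cytotype variation** within a species/family is flagged when the 2C
  range (max - min) reaches 0.9 x 1Cx_ref. The factor 0.9
  operationalizes "close to or higher than" the monoploid value;
  configurable.
* **Mixoploidy**: somatic peaks are converted to 2C, fractions
  renormalized over somatic peaks, and the call is positive when at least
  two components each reach the reporting threshold (default 0.10,
  comfortably below the 30% minor component of the motivating case while
  above debris-shoulder artifacts).
* **Hybrid scenarios** for a diploid x tetraploid cross enumerate the
  four reduced/unreduced gamete combinations; a gamete contributes half
  the parental 2C if reduced, the full 2C if not. Classification of an
  observed 2C picks the nearest scenario, returning "unresolved" beyond a
  caller-supplied tolerance or when the two best distances tie within 10%
  of it. Note the allohexaploid expectation from parental means
  0.96 + 1.90 is 2.86 pg.
* **FISH expectation**: signals = copies per monoploid genome x ploidy.

## Tocher clustering (optimized)

The method is named in the field's software (GENES) but not specified
algorithmically there; this package's operationalization, validated
against a brute-force oracle, is:

* theta = max over accessions of the nearest-neighbour distance, computed
  once from the full matrix.
* Construction: seed a group with the closest ungrouped pair (if even the
  closest remaining pair exceeds theta, all remaining accessions become
  singletons); repeatedly admit the candidate with the smallest mean
  distance to the group while that mean <= theta.
* Optimized refinement: iterate passes in which an accession moves to the
  group minimizing its mean within-group distance. A move is accepted only
  if it strictly lowers the mover's own mean, lands at a mean <= theta,
  and does not increase the total (over accessions) of mean within-group
  distances — the last condition makes the refinement monotone in that
  total, which a per-item criterion alone does not guarantee.
* All ties (seeding, admission, move targets) break by ascending id, making
  the output deterministic and invariant to input order.

Distances are univariate Euclidean (|v_i - v_j|), as the variables (2C,
GC%) are clustered separately. Group memberships are equivariant under
positive rescaling of the variable (theta rescales identically).

## Summaries, correlations, retention indices

Group summaries report n, mean, sample SD (ddof = 1, omitted as NaN for
singletons), min, max and range per variable. Correlations are plain
Pearson r with pairwise-complete deletion and no multiple-testing
correction (p-values are optional output); pairs with fewer than 3
complete observations or zero variance are reported as undefined, never
as 0. Both per-individual and group-mean correlation modes exist because
the appropriate unit of analysis for heterogeneous revisited datasets is
genuinely ambiguous. Retention indices use the van den Dool & Kratz
linear formulation (appropriate for temperature-programmed runs):
RI = 100 x [n + (t - t_n)/(t_{n+1} - t_n)] for bracketing alkanes n, n+1,
generalized proportionally across gaps in the alkane series; anchor times
reproduce carbon number x 100 exactly.

## Numerical choices and degenerate inputs

* EM: SD floor 1e-6 x mean; convergence at relative log-likelihood change
  1e-8, max 300 iterations; BIC = -2 logL + p ln n with p counting free
  weights, means, SDs and the debris weight/scale.
* A sample whose events are all identical returns a single zero-CV peak.
* Event tables round-trip exactly (17-significant-digit write,
  round-trip float parsing on read).
* Tie comparisons in Tocher use an epsilon of 1e-12 on distances.
* Integer event counts are apportioned to populations by largest
  remainder, so counts always sum exactly to n_events.

## Known limitations

* Peak CVs from hard assignment are mildly shrunk for overlapping peaks
  (3 SD truncation); QC decisions near the 5% boundary on heavily
  overlapped peaks inherit this bias.
* The debris model is a single exponential; real histograms can show
  multi-scale debris and nuclei fragments that would demand a richer
  background model.
* Binned-histogram ingestion (bin-midpoint expansion) floors the CV by up
  to half a bin width; it is provided for compatibility, not precision.
* The Tocher refinement is a local fixed point, not a global optimum;
  group counts on real data can differ from other software that names the
  same method.
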