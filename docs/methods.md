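# Methods

## Isotope patterns and the MIDA kernel

Every analyte is reduced to an elemental composition (C, H, N, O, S).
Natural isotopologue patterns are computed per element in closed form
(multinomial coefficients over the heavy-isotope shifts) and convolved
across elements at nominal-mass resolution; the abundance table is a
single versioned TSV (IUPAC-style representative values) shared by the
implementation and the test oracles. Isotope fine structure (¹³C vs ²H at
the same nominal mass) is deliberately not resolved — the instruments
report nominal-mass channels.

A molecule synthesized while body water carries a deuterium fraction *p*
is modeled as the natural pattern convolved with Binomial(*n*, *p*) over
its *n* active C–H sites. The tiny probability that a labeling site would
also have carried natural deuterium is ignored (double-counting of order
*n*·0.000115·*p*, far below instrument noise). Non-integral *n* — effective
site counts for lipids and summed residue tables — interpolates linearly
between the renormalized distributions at ⌊n⌋ and ⌈n⌉.

All distributions live on the reported channel window (M0–M3 for peptide
extracts, M0–M2 for GC-MS analytes) and are renormalized over that window.
Baseline, enriched and measured patterns are treated identically, which
keeps the precursor–product ratio f = EM/EMmax exactly linear in the
mixing fraction; the trade-off is that a channel window must be declared
consistently (the `channels` argument of `theoretical_max_em`).

Estimated fractions slightly outside [0, 1] are measurement noise at the
boundaries: ratios in (−0.02, 0) clamp to 0 and (1, 1.05) to 1 with a
quality flag; anything further out is recorded as a failed measurement and
excluded downstream.

## Per-residue deuterium sites

The per-residue effective site counts (Ala 4.0, Gly 2.06, …) are
literature-derived conventions for body-water labeling in rodent liver,
shipped as an editable TSV; laboratories with their own calibration can
substitute a file. Peptide *n* is the sum over residues. Fixed
modifications default to carbamidomethyl-Cys (the standard iodoacetamide
alkylation); the modification set is an argument.

## Proteome pipeline

Peptide f values aggregate to protein × animal as an unweighted mean, with
the SD across peptides kept as a dispersion estimate. The estimator is the
simplest defensible default given the ≥ 2-peptide support rule;
peptide-count weighting happens later, at the pathway level, where peptide
counts measure evidence per protein. Proteins with fewer than two peptide
isotope measurements per sample are excluded. k = −ln(1 − f)/t uses the
labeling duration in days (inputs carry hours, matching the 6–72 h
design); time points are analyzed independently — no longitudinal model.

Group comparison is a two-tailed Welch (unequal-variance) t-test on
per-animal protein f, reported with the treated/control ratio of group
means and its log2. Raw p-values are the primary readout (matching
volcano-plot practice); Benjamini–Hochberg q-values are reported alongside
rather than substituted, so the default analysis is not silently changed.
Proteins detected in only one group go to a separate one-sided-detection
table instead of being dropped.

Pathway summaries average log2 ratios of significant (p < 0.05) proteins,
weighted by peptide count, over a many-to-many protein → pathway mapping;
pathways with fewer than five significant proteins are suppressed.

## Lipid pipeline

GC-MS analytes are measured as M0–M2 with a concurrently run unenriched
standard. Both measurement and standard are renormalized over the three
channels and subtracted; this absorbs instrument abundance-sensitivity
bias that shifts both spectra alike (the generator includes such an offset
to verify the cancellation). f_DNL is EM(M0)/EMmax(M0) by default; M1 and
M2 estimates are cross-reported and a spread above 0.05 among usable
channels raises the MIDA internal-consistency flag. Effective site counts
are configuration constants (palmitate 22, cholesterol 26, glycerol 4.0 —
standard MIDA conventions, overridable per laboratory/derivative).
Absolute synthesis in grams is f × pool mass and is only computed when a
pool mass is supplied; it is never imputed.

## Labeling protocols and pool dynamics

Body water relaxes first-order toward each protocol segment's steady state
(plateau = 0.625 × drinking-water enrichment, reproducing a 5% plateau on
8% drinking water; 0 during washout) with a default half-life of 3.5 days;
a loading bolus sets p(0⁺). Tissue pools obey dE/dt = k(c·p(t) − E), where
c converts precursor enrichment to the asymptotic product excess (|EMmax|
per unit p from the kernel); the solver is checked against the constant-p
closed form to 10⁻⁶. Default turnover constants — liver TG 0.7/day,
adipose TG 0.02/day — encode the qualitative fast-liver/slow-adipose
asymmetry and are explicit configuration.

The washout design premise (residual liver ≪ adipose enrichment after a
7-week label and 2-week washout) is evaluated under the idealized step
precursor — plateau while labeling, zero during washout — i.e. the closed
form c·p·(1 − e^(−k·t_label))·e^(−k·t_washout) per pool, which depends
only on the two pool constants. With the full 3.5-day body-water
relaxation instead, the fast liver pool tracks the slowly decaying body
water and retains ~16% of the adipose enrichment at day 63; both
behaviours are available through the API, and the distinction matters when
planning washout durations.

## Redistribution classifier

Inputs are per-animal excess enrichments for liver palmitate, liver
glycerol and adipose palmitate (treated and control). Significance means a
Welch two-tailed p < 0.05 **and** an absolute effect above 0.002 excess
enrichment, so that noise-only significance at large n cannot flip calls.
Rules, in order:

1. intact glycerolipid transfer — liver palmitate and glycerol both up
   significantly, with the glycerol/palmitate delta ratio within ±50% of
   the adipose source-pool ratio (moiety ratios survive intact transfer
   but not hydrolysis/re-esterification);
2. free-fatty-acid uptake — liver palmitate up and adipose palmitate down
   significantly, liver glycerol not up;
3. dietary dilution — liver palmitate down significantly with the glycerol
   delta also negative. Significance is demanded only of the high-signal
   palmitate stream: after washout the liver glycerol pool sits near the
   detection floor, and a proportional dilution of it is real but too
   small to test reliably at n = 4;
4. otherwise indeterminate.

All thresholds are declared package decisions, exposed on
`ClassifierThresholds`.

## Synthetic-data generator

The generator emulates the labeling designs the analysis assumes: a
two-group proteome (default 100 proteins, 5 animals/group, harvests at
6–72 h, p = 0.05) with log-normal turnover spanning ~0.05–2/day,
shifted-geometric peptides-per-protein (min 1, mean 4, so the ≥ 2-peptide
filter is exercised), and per-pathway treated-effect multipliers (a
chaperone-like pathway gets > 1 to emulate induced stress proteins);
GC-MS lipid panels at configured true f per analyte/group/time with
matched standards and a shared instrument offset; and the pre-label study
(4 animals/group) built from the pool dynamics above with three transfer
mechanisms — free-fatty-acid flux moves palmitate label only,
intact-glycerolipid flux adds both moieties in exactly the source ratio,
dietary influx scales both liver moieties down.

Liver pools receive a basal pre-treatment enrichment from adipose-derived
fatty-acid recycling (30% of the adipose palmitate enrichment) and
residual intact uptake (10% for glycerol): a pure-washout liver pool would
be empty and no *decrease* could ever be detected, whereas real livers
re-esterify adipose-derived FA continuously. These fractions are
configuration constants of the generator.

Measurement noise defaults to per-channel Gaussian SD 0.003 on peptide
abundances and 0.002 on GC-MS channels (typical instrument
repeatability); a multinomial ion-count mode is available for count
realism. All randomness flows from one integer seed through numpy's
`default_rng`; fixed seed ⇒ identical tables.

What the generator does **not** emulate: chromatographic interference,
retention-time drift, peptide misidentification, missing-value structure,
between-animal biological variability in turnover, or diurnal/feeding
rhythms in p(t). Passing recovery tests therefore demonstrates
correctness of the inference chain under the stated statistical model,
not robustness to every pathology of real data.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the designs at desk scale
as the package's own verification sizes: 100-protein proteomes at one time
point for recovery, 1000 protein-replicates for null calibration, 200
replicates for lipid power and classifier accuracy, 50 random compositions
(≤ 30 residues) for oracle equivalence. Distribution agreement with the
exact-fraction oracles is required to 10⁻¹⁰ per channel; ODE solutions to
10⁻⁶ of closed forms; linearity identities to 10⁻⁹. Ties and degenerate
cases: identical constant groups get p = 1 (p = 0 if means differ but
variances are zero); EMmax = 0 (p = 0) raises a degeneracy error rather
than returning an undefined f; empty aggregation outputs are legal.

## Known limitations

* Peptide *n* comes from fixed residue tables; per-peptide curve-fitting
  of *n* is not implemented.
* Lipid compositions are the underivatized species; the monitored
  derivative fragments share their channel arithmetic but a laboratory
  using different fragments should edit the analyte registry.
* Single-pool first-order kinetics throughout; no precursor lag or
  multi-compartment protein turnover.
* The classifier is a decision rule over three enrichment streams, not a
  likelihood model; indeterminate is a first-class outcome.
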