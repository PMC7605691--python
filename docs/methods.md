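# Methods

## Experimental model

The package targets two-phase deficit-irrigation trials on forest-tree
seedlings. Phase 1 ("tube", 280 cm³ tubes) applies four water-replacement
levels V1..V4 through drip emitters of increasing flow rate; one
soil-water-tension actuator installed in the wettest treatment (V4) opens a
valve shared by all four lines, so every treatment receives the same
valve-open time and cumulative applied volumes are proportional to emitter
flows. Phase 2 ("pot", 18 dm³ pots) irrigates all plants uniformly at full
replacement. Growth is tracked as plant height (cm) and collar diameter
(mm); water as cumulative litres per plant.

## Growth plant factor (Gpf)

For a growth variable Va under applied volumes Vola with full-replacement
volume Volm, the deficit law is

    1 − Va/Vm = Gpf · (1 − Vola/Volm),

a regression through the origin in deficit coordinates. The asymptote Vm is
a nuisance parameter fixed by the estimating condition that the ordinary
least-squares intercept be zero. Writing x = 1 − Vola/Volm, the intercept
as a function of Vm is

    a(Vm) = 1 − Vm*/Vm,   Vm* = mean(Va) − x̄·S_xVa/S_xx,

strictly increasing in Vm with the unique positive root Vm* (when Vm* > 0),
so the estimator has a closed form: Vm = Vm* and
Gpf = −S_xVa / (Vm*·S_xx), the OLS slope at that Vm.

Two methods are exposed. `closed_form` (default) evaluates the expressions
above. `root_find` brackets a(Vm) on [0.5, 50]·max(Va) and solves with
Brent's method (xtol 1e-12, ≤200 iterations), mirroring the iterative
spreadsheet-solver procedure the estimator originates from; both must agree
to 1e-6 relative and the reported |intercept| must be below 1e-8, asserted
at run time. A degenerate design (fewer than 3 distinct volumes) or a
bracket without sign change raises an error rather than returning a value.

Two deliberate conventions:

- **Vm may resolve below max(Va).** When the wettest treatment
  over-performs the fitted line, Vm* falls slightly below the largest
  observed value (the *C. myrianthum* height fit is such a case), giving a
  small negative deficit y for that treatment. The zero-intercept condition
  defines the estimator; "maximising Vm" describes the search direction of
  the original iterative procedure, not a hard bound, and is not enforced.
- **Treatment means are the default fitting unit** (four points per
  species × variable), matching how the published estimates were produced.
  Replicate-level fitting is available (`use_replicates=True`) but flagged
  experimental: the published values cannot be verified at that level
  because the replicate-level raw data was never released.

Interpretation follows the Ky convention: Gpf < 1 → growth loss
proportionally smaller than the water deficit ("low sensitivity"); = 1
proportional; > 1 "high sensitivity". The boundary uses a 1e-9 tolerance.

## Water efficiency (HWE/DWE)

WE = Vg / Tva with Vg the **final** observed value of the variable in the
phase, not the final-minus-initial increment. The convention was identified
by back-computation: published WE × volume reproduces the published final
sizes (42.5, 37.4, 27.4 cm), which an increment definition would not.
Pot-phase Tva is the species-level uniform volume applied to every
treatment-legacy group. For replicate data, group letters come from Tukey's
HSD (statsmodels `pairwise_tukeyhsd`) after a Bartlett homogeneity check on
the groups; a Bartlett rejection warns but does not block the letters
(no fallback analysis is defined for that case). The one-way comparison is
Tukey-protected pairwise testing, the standard reading of the original
statistical description, which is ambiguous on this point.

The compact letter display uses insert-and-absorb: all groups start in one
letter class; each significantly different pair splits every class
containing both; subset classes are absorbed. This guarantees significant
pairs never share a letter, non-significant pairs always share one, and the
display is invariant to group input order. Classes are lettered a, b, ... in
descending order of their largest group mean. Degenerate input (zero
within-group variance with unequal means) raises an error; identical groups
collapse to a single class "a".

## Growth response fits and H/D

Final size against applied volume is fitted by OLS (statsmodels), linear by
default, quadratic on request; no model selection is performed and tiny
quadratic coefficients are reported as-is. Slope p-values use the classical
t statistic with n−k degrees of freedom and are NaN when the residual
degrees of freedom are zero (exact fits); with the 4-point treatment-mean
dataset they are reported, not asserted. For a constant response (zero
total variance) r² is defined as 1 for an exact fit and 0 otherwise, keeping
the r² ∈ [0, 1] invariant. The H/D quality ratio (cm/mm) flags values ≥ 8.0,
treating the boundary as non-compliant.

On the reconstructed treatment-mean dataset the fitted slopes agree with the
published replicate-level slopes to well under 5% for three of the four
published values (4.730 vs 4.7309 cm/L, 1.621 vs 1.6212 mm/L, 2.384 vs
2.3842 mm/L) and within 3.4% for the fourth (21.07 vs 20.3816 cm/L); the
residual discrepancy is attributed to replicate-level fitting in the
original analysis, whose raw data is unavailable.

## The reconstructed reference dataset

`build_inpaper_fixture` compiles the published experiment from its printed
summary: per-cell water-efficiency values × per-treatment volumes give the
final sizes (3 species × 2 phases × 4 treatments = 24 treatment-mean
records), with emitter flows and applied volumes attached. The published WE
table prints one cell with a decimal comma ("17,002"); it is read as 17.002,
the only physically possible reading and the one consistent with the
monotone column around it. Units are fixed (cm, mm, L); no auto-detection.
Because cells are means (n=1), letter displays and replicate-level analyses
are exercised on simulated data only.

## Simulator

`SimConfig` defaults encode the *S. parahyba* tube-phase conditions: emitter
flows (1.2, 1.8, 2.1, 2.9) L/h, 60 irrigation days, total V4 demand 2.40 L
delivered in 73 actuations (event quantum 2.40/73 L per firing),
15 replicates per treatment, growth noise cv 0.05, vm_true 42.0 cm and
gpf_true 0.43 (the values the estimator recovers from the reconstructed
dataset for that species). The controller is deterministic: daily V4 demand
accrues (optionally ramping linearly to echo a growing plant; constant by
default) and each time the unmet demand reaches one quantum the valve opens
for quantum/flow_V4 hours, crediting every line with flow × duration litres.
Water conservation (volumes = flow × total open time) and flow
proportionality hold to 1e-9 by construction and are asserted in tests.

Growth noise is multiplicative lognormal with unit mean
(σ² = ln(1+cv²), μ = −σ²/2), keeping sizes positive; the original study
reports no noise model, so this is the package's choice. Diameters follow
the same deficit law scaled by 0.2 mm/cm (matching the ~8.4 mm at ~42 cm
full-replacement sizes) with independent noise. All randomness lives in the
growth layer and derives from the single `seed` field via one
`numpy.random.default_rng(seed)` generator; the controller is noise-free, so
different seeds share an identical actuation log.

What the simulator does *not* emulate: soil-water-tension dynamics
(retention curves, substrate hydraulics), greenhouse microclimate,
time-resolved growth trajectories, or between-replicate competition.
Passing recovery tests therefore show the estimator inverts the deficit law
under realistic sampling noise — not that the law itself is the right model
for any particular species.

## Problem sizes and numerical choices

Acceptance-level computations run on the 24-record reconstructed dataset
(four points per Gpf fit) and finish in milliseconds. The parameter-recovery
study uses 200 simulated experiments per true Gpf value
(15 replicates × 4 treatments each), a size at which the median estimate is
stable to well under the ±0.05 recovery criterion. CSV output uses %.17g
floats so write-then-read is the exact identity; reading uses pandas'
round-trip float parser.

## Known limitations

- The reconstruction recovers treatment means only; any published quantity
  that depends on replicate-level spread (significance stars, letter
  displays in the published table) cannot be checked directly and is
  validated by simulation instead.
- Gpf is undefined for the pot phase by design (uniform volumes give zero
  deficit spread) and the estimator correctly refuses it.
- The abstract-style pairing of efficiency values across phases is not
  modelled; the per-cell table is the authoritative quantity.
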