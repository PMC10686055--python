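# Methods

This note documents the models, conventions and numerical choices
behind `pepferm`, in the order the pipeline applies them.

## Consumption scoring

**Normalization.** Raw per-analyte responses are scaled to percent of
the response at inoculation (t = 0 must exist and be positive; missing
intermediate samples are handled by the trapezoid itself, i.e. linear
interpolation between observed nodes). Values above the starting
response are capped at 100%, but the pre-capping maximum ratio is
retained on the series: the exclusion filter keys on the raw rise, and
capping first would hide it.

**Filters.** An analyte is *excluded* when its raw signal exceeds the
start by strictly more than 20% at any sampled time (such signals are
not behaving as depleting substrates — matrix effects, coelution or
release can all inflate them). A reduction of at least 20% (minimum
capped abundance ≤ 80%) counts as *consumed*; otherwise *unchanged*.
Status and level are reported independently: every non-excluded
analyte gets a level, and the status column records which rule fired.

**AUC and levels.** The capped curve is integrated by the trapezoid
rule over [0, 72 h] and divided by the virtual-control area 100 × 72.
The 72-h window is fixed by the control's definition even though
sampling continues to 288 h; samples beyond it are ignored, and if no
sample falls exactly on 72 h the curve is linearly interpolated there.
Whether the original analysis used trapezoids or another quadrature is
not documented; trapezoids on observed nodes are the declared choice
here, and a dense midpoint-rule oracle in the test suite pins the
implementation to piecewise-linear exactness (≤ 1e-9 relative).
Levels use half-open bands closed at the lower edge: [0.80, 1] → 0,
[0.60, 0.80) → 1, [0.40, 0.60) → 2, [0.20, 0.40) → 3, [0, 0.20) → 4,
so a fraction of exactly 0.60 is level 1 and exactly 0.80 is level 0
("equal or higher than 80%"). Free amino acids are scored by the
identical procedure and reported as length class 1.

## Kinetics

The OD₆₀₀ curve is fitted with the three-parameter logistic
n(t) = k / (1 + ((k − n₀)/n₀)e^(−rt)) by bounded least squares
(`scipy.optimize.curve_fit`). Initialization: k from the maximum OD,
n₀ from the first positive OD, r from the log-OD slope across the
first two points above n₀ (clipped to [1e-3, 5] /h). A curve whose
total rise is under 2% of its maximum is flagged degenerate (no
growth) instead of fitted; non-convergence returns a flagged result
with the optimizer's message, never a silent failure. On noise-free
logistic data the fit recovers the generating parameters to ≤ 1e-6
relative; a 100-replicate study at 2% multiplicative noise on the
standard sampling grid keeps the median relative error of k and r
under 5%.

CO₂ rates are raw finite differences between consecutive gravimetric
samples, assigned to interval midpoints; vmax is their maximum with
ties resolved to the earliest interval. No smoothing by default — the
grid is coarse (≥ 6 h) and raw differences are reproducible; an
optional centered 3-point moving average is available. Threshold
times (lag = 1 g CO₂; t80 = 80% of the theoretical maximum) are first
crossings with linear interpolation between samples. A threshold that
is never attained is returned as `None`, an explicit "not reached"
marker — never a placeholder number — because slow fermentations
routinely plateau below full attenuation.

## Media accounting

Media are declared by nitrogen source class in mg N/L (ammonium, free
amino acids, peptides). Proline nitrogen is a data-preparation
exclusion, not a runtime subtraction: configs are authored without it,
since yeast does not assimilate proline during fermentation. Total
YAN is the plain sum. The theoretical CO₂ capacity uses 2 mol CO₂ per
mol hexose with a single molar mass of 180.156 g/mol for the
equimolar glucose/fructose pool (isomers, so the split is irrelevant)
and 44.0095 g/mol for CO₂; both constants are pinned for bit-stable
tests. Sulfur limitation is a scalar annotation (`sulfate_scale`,
0.13 for an 87% reduction) consumed by the simulator and the
expression model; salt-level chemistry (K₂SO₄/MgSO₄ amounts) is not
modelled because no concentrations are available, and the K/Mg
chloride compensation is recorded as a flag only.

## Composition-level peptide identity

Residue monoisotopic masses and the water mass come from the standard
table shipped with pyteomics. I and L are exactly isobaric and merged
into one `[I/L]` class (19 classes total); K and Q differ by
0.03638 Da and remain distinct. The inverse search enumerates residue
multisets of a given length by depth-first search over the sorted
alphabet with branch-and-bound on the residual mass (suffix min/max
residue-mass pruning), which is exact and fast at desk scale where a
naive 19⁷ scan would be wasteful. The default tolerance is 5 ppm on
the neutral monoisotopic mass — consistent with a modern QTof at
32,000 FWHM; the upstream instrument method does not state its
tolerance, so this default is declared, not inferred. Output ordering
is by length then lexicographic count vector, independent of search
order. Charge states, adducts and m/z conversion are out of scope:
the pipeline consumes already-identified neutral masses.

## Expression

Technical qPCR replicates are averaged on the Ct scale (geometric mean
on the expression scale, the standard convention), then each gene is
referenced to the ACT1 housekeeping Ct of the same sample:
expression = E^(−ΔCt) with E = 2.0 by default (100% efficiency) and
per-gene overrides available. Replicate spreads above 0.5 cycles set a
QC flag without suppressing the value. Whether the original "AU"
normalization was 2^(−ΔCt) or an efficiency-corrected ratio is not
documented; 2^(−ΔCt) is the declared choice.

## Synthetic-data generator

The generator emulates the study design so that every pipeline stage
has realistic, fully-specified input: 100 mL fermentations of 220 g/L
equimolar glucose/fructose must, sampled every 6 h to 48 h, every 12 h
to 96 h, every 24 h to 168 h, with endpoint checks at 240 and 288 h;
the monitored panel is 18 FAAs, 19 dipeptides, 29 tripeptides and
smaller tetra- to heptapeptide groups (14/12/10/8).

**Peptide depletion** is first-order with an onset delay:
a(t) = 100·e^(−rate·max(0, t − onset)), times multiplicative lognormal
noise (default σ = 5%, emulating relative MS response error; the t = 0
sample is pinned at 100). First-order-with-onset is the simplest
family spanning both "fully consumed by 18–36 h" and late-onset
behaviour; depletion is deliberately not coupled to simulated biomass,
since the analysis consumes only curve shapes. Which lengths deplete
follows the genotype: Fot transporters cover lengths 2–4 (rate
0.25/h, onset 6 h), Opt2 covers 4–7 strongly (0.22/h, onset 9 h) and
2–3 weakly (0.015/h, onset 12 h), and Opt1/Dal5 move no peptides in
the emulated conditions. When ammonium is present **and** the genotype
carries peptide transporters besides Opt2, the Opt2 onset is pushed
back 21 h — longer-peptide uptake is secondary to preferred sources
when alternatives exist, which is why an Opt2-only strain consumes
tetra- to heptapeptides early in any medium while a strain that also
carries other transporters delays them under ammonium/FAA. One
dipeptide (`pep2_PP`) is non-transportable for every genotype and
serves as the negative control. When several transporters cover a
length, the (rate, onset) pair with the larger depletion potential
rate × max(0, 72 − onset) is kept (dominant-transporter
approximation, adequate because scoring only sees the resulting
shape). All rate/onset constants are illustrative by design — the
reference experiments report levels, not rate constants — and live in
a versioned fixtures file (`data/simulator_params.yaml`), not code.

**Growth and CO₂.** The carrying capacity rises linearly with the
nitrogen the genotype can access: accessible N = ammonium + FAA +
peptide N weighted by the mean per-length fraction depleted by 72 h
(peptide nitrogen assumed uniform over lengths 2–7, since its true
distribution over length classes is unknown); k = 0.5 + 0.05·N_acc OD.
Cumulative CO₂ follows a yield-limited model driven by biomass,
co2(t) = A·(1 − e^(−α·∫n dt / A)), with the attainable maximum
A = theoretical max × min(1, N_acc / 100 mg/L) and α = 0.0127 g CO₂
per OD per hour. The two growth constants and α were calibrated once
so that a full consumer reaches 80% attenuation in ≈250 h at
108 mg N/L and ≈150 h at ≈200 mg N/L, with a lag (1 g CO₂) near
25–35 h — the qualitative anchors of the emulated experiments — and
give the stated contract for free: genotypes without peptide access on
peptide-only media plateau far below 80% attenuation (t80 = not
reached). OD noise is multiplicative; CO₂ noise is applied to
increments so cumulative curves stay monotone.

**Ct tables.** ACT1 sits at Ct 20; transporter genes present in the
genotype are placed at Ct values implying 0.3 AU at 18 h and 1.5 AU at
48 h, with a 3× OPT1 boost under sulfate limitation and a 0.5×
OPT2 damping when ammonium is present. Technical duplicates carry
0.05-cycle noise when the scenario noise is on.

**Determinism.** Every output stream draws from its own
`numpy.random.Generator` derived from the scenario seed plus a stable
stream label, so identical seed + config gives bit-identical datasets
and adding one output never perturbs another.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis
assumes — sampling grid, noise model, monotone depletion, genotype ×
length block structure, nitrogen-dependent kinetics — so green tests
demonstrate that the pipeline recovers known structure from data of
the right shape. It does not emulate real-matrix effects (coeluting
signals, the autolysis-driven endpoint rise of stalled fermentations,
sequence-dependent uptake within a length class, FAA-specific
kinetics), so passing tests say nothing about instrument-level
robustness; the filter rules exist precisely for such artefacts.

## Problem sizes

Default test and reproduction runs use the panel above (~110 analytes
per scenario), 1,000 random piecewise-linear series for the quadrature
oracle, exhaustive enumeration up to length 3 (≤ 1,330 multisets) for
the composition oracle, and 100 replicates for the logistic recovery
study — desk-scale sizes chosen to make the full suite a matter of
seconds while keeping Monte-Carlo error well below the tolerances
tested.
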