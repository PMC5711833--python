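# Methods

## Scope and model

The package analyses a glucose-amendment incubation of agricultural soils in
which heat, CO₂ and its ¹³C signature, soil chemistry and SIP-fraction 16S
OTU tables are measured on the same experimental units. The design is a
split-plot field trial: management system (conventional `CON` vs organic
`ORG`) × cropping history (`ANN` vs `PER`) × 4 field replicates, with a
laboratory amendment factor (glucose at 500 µg C g⁻¹ dry soil vs water) and
headspace sampling at 4, 12, 24, 36 and 48 h, the jars flushed with CO₂-free
air after every sampling so each gas reading is an interval amount.

### Energetics

Cumulative heat is the trapezoidal integral of the power trace
(µW g⁻¹ → J g⁻¹); Simpson's rule is available behind a flag but the default
mirrors the simplest defensible choice for noisy, densely sampled traces. An
optional equilibration exclusion (default 0 h; 0.75 h is a sensible value for
ampoule-insertion artifacts) replaces the initial segment by constant
back-extrapolation of the first retained value rather than shortening the
window. The efficiency index `η_eff = 1 − (Q_glucose − Q_control)/ΔH_glucose`
is reported unclamped: values < 0 mean more heat was released than the
substrate contained (possible with strong priming) and are diagnostic, so
they warn instead of failing.

The thermal yield `η_CO₂ = ΔH_CO · n(CO₂-C)/ΔH_glucose` needs a per-mole
heat constant `ΔH_CO` that the source experiment never states numerically.
The default is 467,200 J mol⁻¹ C (glucose combustion enthalpy
2,803 kJ mol⁻¹ ÷ 6 C), which is physically standard. Published yield values
of ≈0.43–0.45 for this system are **not** reproducible from the printed CO₂
and heat means with this constant (they imply an effective constant near
462 kJ mol⁻¹ C applied to a control-only-corrected CO₂ amount); the
operation therefore exposes a `mode` label recording which CO₂ accounting
the caller supplied (`as_written`: primed and control both subtracted, i.e.
strictly glucose-derived CO₂; `calibrated`: control-only), and the test suite
checks the yield's algebraic properties (exact complement `η_CO₂ + η_soil = 1`,
zero at zero moles, linearity) rather than the printed numbers.

### Isotope partition

The two-source mixing model assigns each flush interval's CO₂-C to glucose
or SOM using the interval's measured atom fraction, the labelled-glucose
endmember (0.195 for the respiration jars) and the soil endmember taken as
the time-matched mean of the water-only control jars in the same treatment
(pooling over time is an option; with a time-constant soil endmember the
per-interval and whole-window partitions are algebraically identical).
Partitioning per interval and summing is the default because it stays exact
when abundances drift over the incubation. Negative priming
(`R_SOM < R_basal`) is biologically meaningful and is preserved; a negative
`R_glucose` (possible only through noise) is clamped to zero with a warning.
Missing intervals fail loudly — no imputation. δ¹³C↔atom-fraction conversion
uses the VPDB ratio 0.0111802; headspace concentration→mass conversion is
ideal-gas accounting with blank-jar correction (negative corrected
concentrations clamp to zero with a warning). Microbial biomass C is the
fumigation-extraction flux divided by k_ec = 0.45.

### Community stage

Counts are rarefied to equal depth (default 23,932 when column sums allow,
otherwise the minimum column sum) by exact subsampling without replacement
(multivariate hypergeometric draws), so columns sum to the depth exactly and
the expected rarefied count is `depth · count/total`. Bray–Curtis
dissimilarity is computed on per-sample relative abundances. PCoA is
classical scaling of the Gower-centred matrix; negative eigenvalues are
reported, no correction is applied, and axis signs are fixed by making the
largest-magnitude coordinate positive. PERMANOVA uses the distance-based
linear-model trace construction with sequential (Type I) decomposition over
one or two categorical terms, so the term and residual R² sum to one; when
all distinct sample permutations fit within the permutation budget the exact
distribution is enumerated (p = #{F* ≥ F}/N, identity included), otherwise
p = (#{F* ≥ F}+1)/(B+1) over sampled permutations. The nested split-plot
error structure is approximated by optional within-block permutation
(`blocks=` a replicate column), which preserves exchangeability without
reimplementing full strata semantics.

The differential-abundance screen is a deliberate, transparent stand-in for
negative-binomial Wald machinery (DESeq2-style) and is **not** numerically
comparable to it. Per OTU the effect is the log₂ fold-change of mean relative
abundance (pseudocount 1 added to counts); the test statistic is a
variance-moderated mean difference of log₂ relative abundances
(`diff / (se + s₀)`, `s₀` = median per-OTU standard error, the SAM-style
variance floor that tames spuriously stable low-count OTUs). p-values come
from a permutation null pooled across OTUs, which gives resolution
1/(relabelings × OTUs + 1) — with 4 + 4 samples a per-OTU permutation p can
never beat 1/70 and would make stringent FDR thresholds unattainable by
construction. All distinct relabelings are enumerated when they fit the
permutation budget, and the observed labeling (and its mirror for equal group
sizes) is excluded from the null so the tested signal cannot inflate its own
reference distribution. Benjamini–Hochberg converts p to q; the default
discovery threshold is q < 0.01.

Spearman correlation heatmaps relate each selected OTU's relative abundance
to soil attributes (chemistry, partition totals, indices) across matched
samples; rows are ordered by log₂ fold-change, columns by average-linkage
clustering of correlation profiles on 1 − |ρ|, and a constant variable yields
a missing value, never zero. Publication-grade plotting is out of scope; the
matrix itself is the deliverable.

### Reporting

Summaries report mean ± SE at two grouping levels (individual treatment
n = 4, management-system pooled n = 8; pooled means equal means of treatment
means only for balanced designs, which the generator always produces).
Because published summaries of such experiments mix aggregation conventions,
fold-ratios are emitted both as ratio-of-pooled-means and as
mean-of-per-replicate-ratios, side by side. Display rounding follows the
field's conventions (heats 2 dp, respiration 1 dp, indices 3 dp, quotients
2 dp) while TSVs keep 10 significant digits.

## Synthetic generator: the stated world

Ground-truth defaults are the published treatment means of the emulated
field trial: cumulative heats (1.76/7.47, 1.54/7.41, 1.18/7.01,
1.22/6.86 J g⁻¹ control/glucose for CON-ANN, CON-PER, ORG-ANN, ORG-PER),
48-h basal respiration (37.4, 31.2, 26.1, 26.9 µg CO₂-C g⁻¹), glucose-C
fractions respired (0.345, 0.347, 0.338, 0.336 = published glucose-derived
CO₂ ÷ 500) and priming coefficients (primed/basal: 1.02, 1.07, 1.33, 1.31).
Endmembers are 0.195 (labelled glucose) and 0.0108 (unlabelled CO₂, natural
abundance). Chemistry defaults are the published per-treatment means with
sd = SE·√n.

Stand-in choices where the source gives no information:

* **Heat pulse**: a gamma density (shape 3) on top of constant basal power,
  renormalised on the discrete 1-min grid so the trapezoidal integral equals
  the target heat exactly. The generator rejects pulse parameters leaving
  > 1 % of analytic pulse mass beyond the record; a mode at exactly 12 h
  (scale 6 h) violates that bound at shape 3, so the default scale is 5.5 h
  (mode 11 h, tail 0.77 %).
* **Glucose kinetics**: single-pool first-order with 10 h half-life,
  interval masses renormalised so the within-window glucose-derived total
  equals `fraction_respired × glucose_c_rate` exactly.
* **Priming**: proportional to basal flux and constant in time (only the
  48-h cumulative value is constrained by the emulated data).
* **Noise**: additive Gaussian — power sd 0.5 µW g⁻¹ (TAM-Air-class
  instrument noise), interval CO₂-C sd 1.0 µg C g⁻¹ (GC repeatability),
  atom-fraction sd 0.0005 (IRMS). Chosen once, before any acceptance
  measurement.
* **OTU tables**: Dirichlet-multinomial with concentration 10,000 —
  homogenized, pre-incubated soil aliquots, giving ~10 % replicate CV for a
  1 %-abundance taxon. This was fixed by a pre-build power simulation: the
  screen recovers a median 18.5/20 planted log₂FC = 4 taxa at FDR < 0.01
  (10 seeds, 0 false positives) under these defaults. Planted
  glucose-utilizers multiply their expected relative abundance by
  `2^log2fc` in ¹³C-heavy samples of their designated management system;
  columns sum exactly to the sequencing depth.

All randomness flows from one integer seed through named, CRC-keyed
substreams per output type, so any single output is byte-reproducible
regardless of which other outputs are generated.

### What a green test does and does not establish

The generator reproduces the *structure* of the emulated experiment — design
balance, flushed-interval accounting, exact two-source mixtures, planted
enrichment — but not several features of real data: temporally drifting soil
endmembers, correlated instrument drift, compositional effects of CsCl
gradient fractionation (GC-content density shifts), taxon-specific sequencing
biases, or the long-tailed OTU richness of real soils (hundreds of taxa here
vs tens of thousands). Parameter-recovery tests therefore certify the
*inverse machinery* (integration, mixing model, screens) against a known
truth, not the field accuracy of the laboratory pipeline.

## Numerical choices

Trapezoidal integration at 1-min sampling is accurate to ≪ 0.1 % for the
smooth pulse shapes used. Endmember collapse (`x_glucose = x_soil`) and
misaligned accumulation windows raise errors; zero residual degrees of
freedom in PERMANOVA raise; a perfectly separated PERMANOVA design (zero
residual) yields F = +∞ handled explicitly so the exact toy case gives
p = #{equivalent relabelings}/#{relabelings}. BH adjustment is delegated to
statsmodels. Rarefaction drops under-depth samples with a warning rather than
failing the run.

## Known limitations

* The screen's pooled null assumes OTU statistics are comparable after
  moderation; strongly heteroscedastic tables (a few hyper-dominant taxa)
  may make it conservative for rare OTUs.
* Sequential PERMANOVA supports at most two terms and no interactions; the
  original mixed-model inference (random replicate effects, Tukey letters)
  is out of scope.
* The thermal-yield constant `ΔH_CO` is configuration, not measurement; any
  comparison across studies must state it.
* With per-interval partitioning and a noisy, time-matched soil endmember,
  the glucose bound `0 ≤ R_glucose ≤ R_t` can be violated slightly by noise;
  only the negative side is clamped (with a warning).
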