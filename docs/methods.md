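# Methods

This note documents the models implemented in `crickspace`, the conventions
and numerical choices behind them, and what the synthetic-data generator
does and does not emulate.

## Central-dogma model and units

Each gene is summarized by four reaction rates: transcription β_m
[mRNA h⁻¹], translation β_p [protein mRNA⁻¹ h⁻¹], mRNA decay α_m [h⁻¹] and
protein decay α_p [h⁻¹]. The copy-number dynamics dm/dt = β_m − α_m m,
dp/dt = β_p m − α_p p have the unique steady state m = β_m/α_m,
p = β_m β_p/(α_m α_p). Protein decay combines degradation and dilution
(α_p = α_deg + μ); mRNA decay is dominated by degradation because mRNA
half-lives are short relative to the cell cycle.

All rates are stored per hour. Half-lives in minutes convert as
60·ln2/half-life; elongation speeds in aa s⁻¹ convert with 3600 s h⁻¹.
Ribosome footprints are kept as fractional codon counts (28 nt = 9.33
codons), so the maximal translation rate v/L is not distorted by rounding.

The organism presets store published constants at their printed precision.
Because those are rounded to 2–3 significant figures, the internal
consistency checks (α_p = α_deg + μ, Σβ_m = N_m·α_m) are enforced at 2%
relative tolerance rather than machine precision. The preset `beta_p_max`
is the top percentile of measured translation rates (the quantity the
boundary prediction uses); the mechanistic bound v/L is available
separately via `max_translation_rate` and agrees with it to within a factor
of ~2.

## Rate estimation

Per-gene mRNA-seq RPKMs r_i and ribosome-profiling RPKMs s_i are relative;
they become absolute by anchoring to whole-cell budgets: m_i = N_m·r_i/Σr,
β_m,i = m_i·α_m, and β_p,i = (N_p·α_p/m_i)·s_i/Σs, which allocates the
cellwide protein-synthesis flux N_p·α_p across genes in proportion to
footprint density. Median decay rates stand in for per-gene values by
default (the 2-D simplification); per-gene α columns override them when
supplied.

Low-coverage genes are filtered first. Modelling sequencing as a Poisson
process, keeping the log10-abundance error below ε requires
n > (1/(10^ε − 1))² reads; `min_reads_for_error` exposes this bound, while
the default operational thresholds are 10 mRNA-seq and 20 RP reads.
Normalization sums run over retained genes (post-filter), switchable to
pre-filter sums. RPKMs are treated as already length-normalized.

Synthetic construct libraries (relative mRNA level, relative protein/mRNA
ratio) are placed on the absolute scale by matching each axis's 99th
percentile to the corresponding percentile of the reference gene set, on
the assumption that the strongest constructs rival the strongest natural
genes.

## Boundary, depletion test, smoothing

The boundary intercept k is the lower empirical quantile of the ratio
β_p/β_m at the exclusion fraction (default 1%): the order statistic at
0-based index ⌊f·n⌋, i.e. the largest observed ratio with at most f·n genes
strictly below it. Ties resolve toward the smaller k. When f·n < 1 the
minimum ratio is used, with a warning. The standard error is a 200-resample
nonparametric bootstrap over genes (the choice of 200 balances Monte-Carlo
error in the SE against runtime; the published analysis states no method).

The depletion null preserves what expression is *for* — protein abundance —
while destroying the coupling between transcription and translation: each
shuffle resamples p and β_p independently from their empirical marginals
(with replacement by default; a permutation mode exists) and derives
β_m = p·α_m·α_p/β_p. The statistic is the count of genes below the fixed
boundary; the p-value uses the add-one estimator
(1 + #{null ≤ observed})/(1 + n_shuffles), so it is never zero and an
observed count below all 10⁴ null counts reports p < 10⁻⁴ by construction.

CV smoothing is a Gaussian-weighted average on a log10-rate grid (default
50×50). The smoothing width is one fifth of the data range per axis; the
Gaussian prefactor 1/√(2πσ_mσ_p) cancels in the weighted mean but sets the
scale of Σw against the density cutoff (default 200), which masks
sparsely supported grid nodes.

## Telegraph noise model

A promoter switches on at k_on, off at k_off, transcribes at δ while on;
the effective transcription rate is β_m = δ·P_on with
P_on = k_on/(k_on+k_off), and the mean burst size is b = δ/k_off. The
stationary squared CV of protein abundance has an exact three-term closed
form (Poisson birth–death, small-mRNA amplification, activation/bursting);
`cv2_exact` implements it and is the internal reference.

Two regime forms re-express the activation term through measurable
quantities: for α_m ≫ α_p and k_off ≫ α_p (fast mRNA turnover, bacteria),
cv² ≃ 1/p + α_p/β_m + α_p(1 − β_m/δ)/k_on; for k_on + k_off ≫ α_p
(eukaryotes), cv² ≃ 1/p + (α_p/β_m)·ϕ with
ϕ = (q/(1+q))(1 + b(1−P_on)²) and q = α_m/α_p. Regime checks warn rather
than fail at 10-fold margins, since the approximations are routinely applied
at finite ratios (q ≈ 3). When activation kinetics saturate at high
transcription, the burst form tends to a constant — the noise floor
cv0² = (q/(1+q))(1−P_on)²α_p/(k_off·P_on) — which motivates the
phenomenological form cv² = 1/p + α_p/β_m + cv0² used in the fitness
theory. cv² (not cv) is the canonical internal quantity; components always
sum to the total.

The validating simulator is an exact continuous-time jump process over the
six reactions, advanced for all cells in lockstep through vectorized draws.
Cells start off-state and empty; protein counts are read at t_end, which
defaults to ten multiples of the slowest relaxation timescale, and a
warning fires when the population mean still drifts more than 5% over the
last two quarters of the run. The Monte-Carlo error of the empirical cv² is
a 200-resample bootstrap over cells.

## Fitness theory

Fitness peaks are represented by their quadratic expansion
(f_max, p*, f″(p*) ≤ 0); arbitrary functional forms are out of scope. The
noise load is ½|f″(p*)|σ², the transcription cost c_m·l_m·β_m, with the
per-nucleotide cost estimable from whole-cell quantities as
c_m = μ/(l_m·Σβ_m) (each transcribed nucleotide of a useless mRNA displaces
an averagely useful one). Maximizing mean fitness at fixed p* — so that
translation co-varies with transcription and only the α_p/β_m variance term
depends on β_m — gives β_m = √(α_p α_m Q p*/C) and the optimal ratio
β_p/β_m = C/Q, with C = c_m l_m α_m (cost per mRNA) and Q = ½|f″(p*)|p*
(noise sensitivity). Inverting the optimum predicts per-gene curvature from
the observed ratio.

The noise floor caps selectable noise sensitivity: requiring positive mean
fitness with f_max ≤ ρμ and σ/p* ≥ cv0 bounds Q by
Q_max = √(α_p α_m ρμ C)/(β_p^max cv0), and the boundary follows as
k = C/Q_max = β_p^max·cv0/√(ρ·α_p·Σβ_m) — an identity the tests verify to
1e-12 independently of l_m and μ, which cancel. ρ is the fraction of the
growth rate a gene's deletion can cost (1 for essential genes); ρ < 1
raises the predicted boundary. Fitness is measured in h⁻¹ (growth-rate
differences) throughout.

## Cost inference

Clone-competition data follow log(x_{m,p}(t)/x_{0,0}(t)) = −t·c_p·p −
t·c_m·m relative to a low-expression reference class; the regression is fit
without intercept by default because the model is anchored to that
reference (an intercept flag exists as a robustness check). A nested F-test
(protein-only versus protein+mRNA, via statsmodels OLS) asks whether mRNA
carries a measurable cost. Only the composite coefficients t·c_m and t·c_p
are identifiable without knowing the competition time t; their ratio is
reported as-is.

Copy-number titrations give slopes s_N (full construct) and s_D
(destabilized DAmP construct, protein output reduced by the factor φ) of
relative growth versus copy number, either supplied directly or fit by
least squares through (0, 1). The transcription-attributable cost is
c_m = μ₀(s_D − s_N·φ)/(l_m·β_m·(1−φ)). Because φ is only known to lie
between 1/30 and 1/10, an interval over that range can be propagated.

## Synthetic data: what it emulates, what it does not

The generator produces every pipeline input with known ground truth,
bit-reproducibly per seed, and always returns the truth alongside the
observables.

Gene tables: protein abundances are lognormal (default three decades of
spread around 10⁴ copies, matching the observed 1000-fold range of
expression) and pinned exactly to the organism's protein budget. A
structural point discovered in building the generator: once both whole-cell
budgets (Σm = N_m, Σp = N_p) are pinned — as they must be for the absolute
rate estimator to be consistent — the scale of the
translation/transcription ratio distribution is no longer a free parameter.
Without a planted boundary the generator therefore samples relative
translation strengths log-uniformly (default 3 decades) and lets the mRNA
budget set their scale. With a hard planted boundary k_true, ratios are
log-uniform above k_true and the spread (in decades) is solved from the
mRNA-budget equation by root finding; a specification whose boundary cannot
be reconciled with the budgets raises an infeasibility error rather than
silently drifting. Sequencing is Poisson at configurable depth (default
5×10⁶ reads per assay, typical of the profiling datasets emulated), with
expected counts proportional to m (mRNA-seq) and to β_p·m (RP); gene
lengths are held constant so RPKMs are proportional to counts.

Not emulated: organism-specific abundance distribution shapes, gene-length
variation, ribosome-profiling positional bias, multi-mapping artifacts, and
gene-specific decay-rate variation. Consequently, passing recovery tests
show that the estimator and boundary machinery are correct under the
stated noise model — not that real libraries are free of the biases above.

CV labels apply the phenomenological noise law to the true rates plus
lognormal measurement scatter (default log-sd 0.2). Clone libraries and
titration series are exact forward models of the linear cost equations plus
Gaussian noise; their default planted coefficients (t·c_m = 4×10⁻² per
mRNA, t·c_p = 2.2×10⁻⁶ per protein) are the scale reported for the
competition data the design emulates.

## Problem sizes and determinism

Default analysis sizes were chosen to make each result statistically
decisive at interactive runtimes: 5000-gene tables for boundary recovery,
10³–10⁴ shuffles for depletion p-values, 10⁴ cells per simulator validation
point, 200-resample bootstraps for standard errors. Every stochastic entry
point takes a seed; pipeline reports are a pure function of (inputs,
configuration, seed) and are stamped with both the seed and a configuration
hash.

## Known limitations

- The 2-D treatment ignores gene-specific decay rates except as optional
  overrides, and has no time-dependent or cell-cycle structure.
- The boundary-prediction constants are published point estimates; the
  package propagates no uncertainty through predict_k beyond the reference
  standard errors carried as metadata.
- The telegraph analytics assume stationarity and a single promoter; the
  noise floor is phenomenological wherever activation kinetics are not the
  true cause (e.g. extrinsic noise).
- Measured boundary intercepts for the four organisms (1.1, 14, 44, 66)
  require the original genome-scale datasets and are therefore carried as
  reference metadata on the presets, not recomputed.
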