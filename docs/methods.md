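# Methods

This note documents the statistical procedure, the simulation model behind
the validation harness, the numerical conventions, and the design choices
made where the procedure was genuinely open.

## 1. Change-point analysis (CPA)

A series `x` of length `N` is scanned exhaustively over all splits into a
prefix `x1` and suffix `x2` (each at least `min_seg` points: 1 for the mean
cost, 2 for variance and trend).  Segment costs:

| kind          | cost                                   | min_seg |
|---------------|----------------------------------------|---------|
| mean          | `N · var(x)` (sample variance, N−1)    | 1       |
| variance      | `N · log(var(x) + 1e−12)`              | 2       |
| linear_trend  | sum of squared OLS residuals on (t, x) | 2       |

Length-1 (mean) and exactly-fitted segments cost 0.  The best split is the
earliest argmin of `C(x1)+C(x2)`; the reported position is the 1-based index
of the first point of the second segment.

**Detection gate.** For continuous-valued data *some* split always lowers
the raw cost, so the bare inequality `C(x1)+C(x2) < C(x)` would flag every
series.  A change point is therefore reported only when the likelihood-ratio
gain at the best split exceeds the Schwarz/SIC model-selection penalty for a
single change point, `n_eff · log(fit0/fit1) > p · log(n_eff)` with `p = 2`
extra parameters for a mean or variance change and `p = 3` for a trend
break.  `n_eff = n·(1−ρ̂₁)/(1+ρ̂₁)` (clipped to `[8, 3n]`) is the classical
Bartlett effective sample size computed from the lag-1 autocorrelation of
the two-segment residuals; it matters because the sliding-window
representations fed to CPA (Dynamic Complexity, recurrence and
time-frequency rows) are smooth by construction, and an i.i.d. penalty
would fire on essentially every such row.  `penalty="none"` restores the
bare rule for inspection.

## 2. Secondary representations

**Dynamic Complexity** (window `w = 7`, one week of daily ratings; rating
bounds `[s_min, s_max]` required).  Per window, the fluctuation measure `F`
splits the window into maximal strictly monotone runs, sums amplitude/
duration per run and normalises by the maximum attainable on the scale
(min–max alternation at every step), so `F ∈ [0, 1]`.  The distribution
measure `D` compares all pairwise gaps of the sorted window values against
a perfectly even spread over the scale and accumulates only the shortfall,
so `D = 1` for even coverage and `0` for a constant window.  `DC = F·D` is
assigned to the window's **last** time point, so complexity rises register
at, not after, a transition.  On noisy input the nominal bounds are widened
to the observed hull.

**Recurrence distances.**  Delay embedding with `m = 3`, `τ = 1`
(configurable) and the unthresholded Euclidean distance matrix.  Each of
the `L−2` rows is a time series along the recording's axis.

**Stockwell transform.**  Discrete S-transform via the standard FFT
formulation: row `n` (cycles per record) is the inverse FFT of the shifted
spectrum `H[m+n]` windowed by `exp(−2π²m²/n²)`.  The zero-frequency row is
excluded (level changes are already covered by mean-cost CPA on the raw
series); rows `1 … ⌊L/2⌋` are kept as amplitude moduli.

**Matrix condensation.**  Mean-cost CPA runs on every non-constant row;
row votes falling in the 10% edge zones are discarded (edge artifacts of
row-wise scans).  Votes are histogrammed with bin width `round(L/5)`, edges
anchored at t = 1; the earliest modal bin wins ties and the returned
position is the rounded median of the votes inside the modal bin.  The bin
chooses the consensus region; the in-bin median keeps the resolution the
rows agree on (a literal bin-midpoint would quantise every matrix vote to a
five-point lattice, which both degrades step recovery near bin boundaries
and manufactures spurious cross-series coincidences).

## 3. Aggregation

1. **Outlier deletion** — iterative generalized extreme Studentized deviate
   test (α = 0.05, at most ⌈0.1·L⌉ removals); deleted points are excised and
   an index map keeps all downstream positions on the original axis.
   Constant series are left untouched (the statistic is undefined).
2. **Collection** — up to six change points per series: raw mean/variance/
   trend, DC (mean cost), recurrence histogram, time-frequency histogram.
3. **Edge filter** — keep `⌈0.1L⌉ < p ≤ ⌊0.9L⌋`.
4. **Significance** — observed IQR of the surviving positions versus 100
   replicates of equally many integers uniform on `[1, L]`; significant iff
   the observed IQR is strictly below the replicates' 2.5th percentile
   (central-95% reading; a normal-approximation bound `mean − 1.96·SD` is
   available via `ci_method="normal"`).  Fewer than `min_cps = 3` surviving
   change points yield a negative verdict — an IQR of one or two points is
   degenerate.
5. **Transition point** — rounded (half-up) median of the surviving
   positions; the probability band `Σ_p exp(−(t−p)²/10)` visualises their
   convergence but does not define the TP.

Whole-system mode pools the change points of all variables before steps
3–5.  The only randomness in the pipeline is the significance resampling,
driven by `PtdaConfig.seed`; identical seeds give identical results.

## 4. The simulation model

The validation data generator is a **synthetic** model of psychotherapeutic
change, built for this package (see the `sim_model` docstring for the
equations).  Five order parameters — emotions E, problem severity P,
motivation M, insight I, therapeutic success S — evolve as a unidirectional
coupled-logistic ring on unit coordinates (couplings 0.1–0.2, insight as a
slow integrator), with growth rates `μ_V = 2.6 + 1.4·(trait mix)` set by
four trait parameters a, c, m, r ∈ [0, 1].  Observed values add a
trait-dependent level (weight 0.35) on top of the internal regime and are
mapped to `[−1, 1]` for E, P, S and `[0, 1]` for I, M.  The design
rationale: traits should move both the *dynamic pattern* (through the
period-doubling route of the growth rates) and, usually but not always, the
*level* — so most transitions are visible to mean CPA while a minority
express themselves only in variance, frequency or complexity; the ring
topology prevents the complete synchronisation that master–slave or
mutually-coupled variants exhibit, letting the five variables carry
distinct patterns.

**Validation protocol.**  Runs of T = 400 iterations from uniform random
initial values and traits; at iteration 250 all traits shift by a random
amount `|Δ| ≥ 0.05` (upward by default; a trait within 0.05 of the upper
bound moves down instead, and a signed variant is available), either
instantaneously or ramped linearly over 10–30 iterations.  The first 100
points are discarded (transient), runs are kept only if all five post-
transient pre-shift series are periodic with period ≥ 16 or chaotic
(tolerance 1e−6 on the last 64 points, periods up to 32 tested), and
100-point windows are cut so that the shift sits at a chosen in-window
position (position 50 ↔ the adjusted interval [100, 200]; no-transition
windows lie entirely before the shift).  Noise is Gaussian with variance
equal to a percentage of each series' sample variance.  One master seed
drives everything through spawned child seeds.

**What the generator does and does not emulate.**  It reproduces bounded
rating-like scales, regime diversity (fixed points, cycles, chaos),
transitions of heterogeneous character, and a realistic one-to-few-point
detection lag.  It does not emulate missing data, ordinal discretisation,
weekly cycles, or the exact attractor geometry of any fitted model of
therapy processes; logistic-family cores show intermittent complexity
bursts inside stationary regimes, which raises false-positive rates of the
convergence detector above what smoother chaotic systems would produce.
Passing the validation harness therefore demonstrates correct recovery of
induced transitions under these synthetic conditions, not clinical validity
on empirical recordings.

## 5. Performance metrics

Mean and SD are taken over detected TPs only.  Precision is the share of
detected TPs within ±5 points of the true position (detected-only
denominator, since misses are reported separately).  False negatives are
counted on transition-bearing series, false positives on shift-free
windows — disjoint denominators.  The full-scale experiment (60 runs, 300
series) is the default of `run_table_experiment` and of
`scripts/acceptance.py`; examples use 10 runs for speed.

## 6. RQA quantifiers

Thresholded recurrence plots (`ε = 0.1` on raw distances; a fixed
recurrence-rate alternative is out of scope) restricted to square windows
along the main diagonal, widths 25/45/65, step 1, value at the window's
last index.  `DET` is the fraction of recurrence points on diagonal lines
of length ≥ 2, main diagonal excluded; runs cut by the window border are
censored observations of longer lines and count as deterministic at their
truncated length — otherwise a strictly periodic signal could never reach
DET = 1 in a finite window.  `RTE` is the Shannon entropy (natural log) of
recurrence times, read as the index gaps between successive recurrence
points per column (white vertical lines); the black-line variant is
available via `vertical="black"`.

## 7. Numerical conventions and degenerate inputs

Round-half-up wherever an index is rounded; earliest split/bin wins ties;
variance-cost floor `ε_var = 1e−12`; a numerical tolerance proportional to
the series scale keeps least-squares round-off from counting as cost gain;
constant series yield no change points anywhere; series shorter than 4
points produce a warning and no result; GESD requires ≥ 15 points and
refuses to flag more than half a series.

## 8. Known limitations

- At most one transition point per recording; multi-transition processes
  are out of scope.
- The significance test assumes independent uniform positions under the
  null.  Pooled change points are neither independent (variables of one
  system share events) nor continuous (histogram votes), so whole-system
  false-positive rates on strongly coupled stationary systems run well
  above the nominal level; single-series verdicts are the safer default on
  such data.
- The SIC detection gate is a principled stand-in for the undocumented
  internal threshold of the original CPA tooling; it is somewhat more
  conservative on stationary windows, trading false positives for false
  negatives relative to the original tool's reported operating point.
- Dynamic Complexity needs the theoretical rating bounds; observed min/max
  is a logged fallback that biases D upward on short series.
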