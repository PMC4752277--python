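# Methods

## Model

The model describes a gut colonized by two isogenic *E. coli* lineages — one
carrying a temperate prophage (lysogens L), one susceptible (S) — together
with the free phage V they exchange, newly lysogenized susceptibles S^L, and
latent cells Q committed to lysis. Assumptions:

* Bacteria grow logistically with a shared maximal rate r and carrying
  capacity k; only replicating cells (N = S + L + S^L) occupy capacity,
  latent cells do not divide.
* Free phage adsorb to every bacterium at rate a (mass action, aNV removed
  from V), but only adsorption to susceptibles (aSV) has an effect —
  lysogens are immune and act as a phage sink.
* An infection lysogenizes with probability g (entering S^L) and otherwise
  enters the latent pool Q; prophages in L and S^L induce at rate x, also
  entering Q; latent cells lyse at rate l releasing y phage each.
* Gastrointestinal transit removes every compartment at dilution rate d.
  The gut is treated as well mixed; fecal densities are taken as
  proxies for luminal ones.

Time is in hours, bacterial densities in cfu/g of feces, phage in pfu/g.

Two reductions are used throughout: the receptor-less (LamB⁻) model is the
same system with a = 0 (free phage arise from induction only, and S, L, Q
decouple from V), and two-phase simulations switch parameters at a fixed
time with a continuous state — e.g. a → 0 at 48 h to represent loss of
phage susceptibility, or x → 2×10⁻⁷ for a non-inducible prophage.

### Equilibria

With a = x = 0 the total population settles at the effective capacity
k(1 − d/r); when r ≤ d everything washes out (the equilibrium finder
returns the zero state explicitly rather than erroring). At the calibrated
values the attracting equilibrium from mixed starts excludes susceptibles
(S* → 0: induction-fed phage pressure outweighs their growth edge) and
satisfies, in turn, 1 − N*/k = (x+d)/r, Q* = x N*/(l+d), and the free-virus
balance y l Q* = (a N* + d) V*. The finder integrates to a long horizon
(2000 h, doubling up to 32000 h) and polishes with a Newton root solve,
accepting when every |dY/dt| ≤ tol·(1+|Y|) with tol = 1e-9.

## Calibration pipeline

Parameters separate into four sequentially estimated groups; each stage
fixes the results of the previous ones.

1. **Growth (r, k).** The monocolonization data follow the 1-D logistic with
   dilution, whose closed form is a logistic with rate r − d and capacity
   k(1 − d/r). Squared residuals of log₁₀ density are minimized jointly
   over mice (shared r, k; each mouse's time-0 count as its initial
   condition). d = 0.25 h⁻¹ is fixed a priori (transit measurements).
2. **Induction and latency (x, l).** The a = 0 submodel is fitted to the
   L, S and Q series of receptor-less competitions, equal weights on the
   three log₁₀ residual sets, bounds x ∈ [0, 1], l ∈ [0, 5]. ln(L/S)
   declines at rate x and Q/L ≈ x/(l+d), so x is well identified while l is
   weak (its transient equilibrates within hours) — consistent with the
   wide calibrated interval for l.
3. **Adsorption (a).** Inversion of the free-virus equilibrium balance:
   a = (y l Q* − d V*)/(N* V*), with the burst size y = 12.1 fixed from the
   in vitro single-burst assay. In `estimate_all` the equilibrium
   observations are the mouse means at the latest competition sample time,
   and Q* (not countable in wild-type experiments) is reconstructed from
   the stage-2 estimates via the dQ/dt = 0 balance, Q* = x(L*+S^L*)/(l+d).
   A negative inversion is clipped to zero and flagged.
4. **Lysogenization (g).** Bounded scalar least squares on the log₁₀ of the
   L/(S+S^L) ratio at the 36-h observation (configurable; observations
   within one sampling interval of the target time are used), simulating
   each mouse from its observed initial densities, all other parameters
   fixed.

Numerical choices shared by the fits: residuals on log₁₀ densities (plating
noise is multiplicative and spans decades); counts recorded at the detection
limit are censored and excluded from residuals; bounded trust-region least
squares with a 5-point multi-start (the objectives are smooth and unimodal
in practice — the multi-start is a guard, and bootstrap refits may use a
single start); model predictions are floored at 10⁻³ cfu/g inside logs.

**Bootstrap intervals** case-resample mice with replacement and refit,
reporting percentile 2.5/97.5 bounds; replicates whose fit fails are dropped
and counted, with >20% failures aborting. Intervals are deterministic given
the seed. *Limitation:* with the 3–13 mice of realistic group sizes the
percentile interval undercovers (measured ≈86–88% instead of 95% in nested
simulation — the usual small-cluster behaviour); coverage reaches its
nominal band by ≈25 mice, which is the regime the coverage test uses.

## Assay estimators

* **Adsorption decay:** OLS of ln N_t on t under N_t = N₀e^(−Bat);
  a = −slope/B with the slope's standard error propagated. Zero counts are
  censored at 1 PFU with a warning. Units are per ml of culture — the in
  vivo model constant is per gram of feces and the two are never
  interconverted.
* **Burst size:** max/initial PFU of a single-burst series.
* **Per-generation induction:** ln(L/S) regressed on generations elapsed
  under the two-phase schedule (growth at r for the first 24 h of
  colonization, turnover at d thereafter, divided by ln 2). x = −slope —
  the small-x approximation; the exact per-generation survival factor gives
  −ln(1−x), within 1% of x at these magnitudes. Unweighted OLS on the
  pooled ratio series.
* **Infective centres:** n_centres/n_plated with an exact Clopper–Pearson
  95% interval.

## Sensitivity analysis

The endpoint is the lysogen gain L/(S+S^L) at 100 h (the ratio is within 1%
of its 500-h value by then), for initial L:S ratios 1:1, 1:10, 1:100 with
L₀ = 10⁶ cfu/g. Default sweep grids are 21 log-spaced points over ×0.1–×10
of the baseline value (clipped to the parameter's validity range). The gain
falls monotonically in both g and x. For g the inverse-proportionality
diagnostic reports both (ratio × g) and ((ratio − 1) × g); empirically
ratio × g is the flat one (≈3% spread over g ∈ [0.05, 0.5]) and is what the
stability test checks. The gain is insensitive to the phage-kinetics rates
l, y, a while lytic amplification operates; pushing y toward 1 or l toward
0.1 h⁻¹ leaves that regime and the gain collapses, so "modest impact"
claims are only tested within it.

## Synthetic data

The generators emulate the experimental designs, not the animals: gavage at
10⁶ cfu/g of lysogens (susceptibles scaled by the L:S ratio), per-mouse
inoculum densities lognormal with CV 0.3, sampling at
{0, 6, 24, 30, 48, 72, 96, 144, 216} h (daily cadence densified over the
fast first two days), multiplicative lognormal plating noise with CV 0.2
(mean-one), and flooring at a 10² counts/g detection limit with a censoring
flag. The receptor-less scenario runs a = 0 and additionally reports latent
cells Q (free phage can be spun away before plating there); wild-type
competitions report L, S+S^L, S^L and V; monocolonizations a single lineage.
Defaults for self-consistency testing are noiseless.

Not emulated: the invasion of receptor-loss (maltose-regulon) mutants that
truncates real wild-type infection dynamics after ~2 days — so synthetic
wild-type data are only model-faithful on the ≤48 h window while the model
itself is integrated as far as asked; phage mutants; gene-capture
recombinants; low-copy demographic stochasticity (densities are continuous).
Passing recovery tests therefore demonstrates pipeline self-consistency
(the estimators invert the generators), not fidelity of the model to real
mice. Two known model-vs-data discrepancies: simulated early phage
propagation is faster than observed, and the receptor-less model
accumulates free phage to ~2×10⁹/g at equilibrium (only dilution removes
them) whereas measured free-phage:lysogen ratios in receptor-less mice are
far below wild-type ones — the model was never fitted to those counts.

## Numerics

Integration is LSODA in linear space with rtol 10⁻⁸, atol 10⁻² cfu/g.
Negative dips at output are solver noise up to the per-step error allowance;
values above −(10·atol + 10⁻⁶·max density) are clamped to zero and anything
below that floor raises an error rather than being silently repaired.
Trajectory grids must start at 0 and increase strictly. The two-phase
integrator re-anchors the second phase on a local clock to keep step-size
control clean across the switch. ODE fits cache simulations keyed by
(parameters, initial state, grid), which collapses repeated objective
evaluations on noiseless replicated mice.

## Test and script problem sizes

The suite favours small, fast configurations chosen once: 3-mouse noiseless
bundles for self-consistency (recovery is exact, more mice add nothing),
100-seed repeats for noisy-recovery rates, 500-seed Monte Carlo for the
Poisson decay assay, a 200×149 nested simulation at 25 mice for bootstrap
coverage, and 8–13-point grids for profile/unimodality scans. The
acceptance script uses 3 mice per scenario group and the daily 0–216 h
schedule for the regression target.
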