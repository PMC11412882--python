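# Methods

## The update rule

All species counts are exact natural numbers.  Time advances in unit steps;
in each step every reaction performs one binomial draw and the counts change
by exact stoichiometric multiples of the number of successes, so
non-negativity and integer-ness hold by construction, without clamping.

For a general reaction `q1·X1 + q2·X2 + … -> r1·Y1 + r2·Y2 + …` with rate
constant `k` and normalization parameter `N`:

* **trials** `n = floor(min_i X_i/q_i)` — the limiting reactant (minimum of
  the exact ratios `X_i/q_i`, compared with integer cross-products; first
  declared wins ties) bounds how many reaction events are possible;
* **success probability** `p = Π_{i≠lim} (k·X_i/(q_i·N)) / (1 + k·X_i/(q_i·N))`
  over the non-limiting reactants (evaluated in log space when more than ten
  factors are present);
* **update** `ΔX_i = −q_i·B`, `ΔY_j = +r_j·B` with `B ~ Binomial(n, p)`.

Single-reactant (`mono`) reactions `a·X -> products` use `n = floor(X/a)`
and `p = k/(1+k)`; `decay_zero` is the same with no products.  The linear
families make at most one trial per step with `p = k/(1+k)`: `linear_inc`
adds `b` copies on success, `linear_dec` removes `a` copies and only fires
while `X ≥ a`.

`N` divides the reactant counts inside `p`, so a rate-constant set is
transferable across system sizes: scaling every count and `N` by the same
factor leaves all success probabilities unchanged.

### Sequencing within a step

The original description leaves intra-step ordering open; here reactions
apply **sequentially in declaration order**, each seeing the state already
updated by earlier reactions in the same step, and scheduled in/out events
apply at the start of their step before any reaction.  This preserves the
natural-number invariant exactly, but makes declared order meaningful: a
backward reaction declared after its forward partner observes the mid-step
count.  All stationarity oracles in this package account for that (see
below).  A single seeded generator is consumed in this deterministic order,
so seed + model reproduce a bit-identical trajectory.

### Sampling

Draws use the platform binomial sampler for `n ≤ 2⁶³−1`.  Beyond that
integer range (e.g. 2×10²⁴ water molecules) the draw is the moment-matched
normal `round(n·p + z·√(n·p·(1−p)))` clamped to `[0, n]`; at such trial
counts the skewness correction is ≤ 10⁻⁷ of a standard deviation, far below
the statistical noise of any observable here.  The threshold is a fixed
documented constant, not per-reaction configuration.

## Flux-balance oracles

A reversible pair is stationary when expected per-step fluxes balance.
Because of sequential updating, the *recorded* (end-of-step) state `x` of a
forward/backward pair satisfies `d = R(x + d)` where `d` is the forward
flux produced earlier in the step and `R` the backward flux — not the naive
`d = R(x)`; ignoring this leaves a relative bias of order one over the
relaxation time (≈1% for the default water constants, i.e. pseudo-pH 7.004
instead of 7.000).  The solvers in `nnsim.examples`
(`binding_equilibrium`, `water_equilibrium`, `water_rate_constants`) solve
the corrected balance in continuous counts.

**Water calibration.**  Requiring the recorded ion ratio `H+/H2O = 10⁻⁷`
(the pure-water ion product) with recombination constant `k_rec = 10⁵`
yields `k_diss ≈ 1.0101×10⁻⁹` by a fixed-point solve; the derivation uses
only count-to-`N` ratios, so the same pair is valid at `N = 2×10¹⁹` and
`2×10²⁴`.  `k_rec = 10⁵` sets the equilibrium relaxation time to ≈100 steps
so a 20,000-step run is fully equilibrated over its measured tail; the true
physical rate constants are unknown and the time axis is in calculation
steps.

## Information metrics

Each event `(n, p, B)` yields a self-information `−log2 pmf(B; n, p)`
(log-gamma evaluation, valid for arbitrarily large `n`), accumulated per
reaction as a non-decreasing series; events with `n = 0` contribute zero
bits (single-outcome distribution).  The reaction entropy is the Shannon
entropy of `Binomial(n, p)`: exact summation for `n ≤ 10⁴`, and above that
the Gaussian differential entropy *plus* the `O(1/n)` series correction
`(1/12)(1/n − 1/(np) − 1/(nq))` nats.  The correction matters: the plain
Gaussian misses the exact sum by ≈1.2×10⁻³ bits at `n = 10⁴, p = 0.01`,
while the corrected form stays within 4×10⁻⁵ bits over `p ∈ [0.01, 0.99]`.
Both per-reaction curves and a whole-system sum are exposed, since either
aggregation may be wanted.

The pseudo-pH is `−log10(count(H+)/count(H2O))`, a count-ratio stand-in
for the activity ratio; it is exactly 7 at the calibrated neutral point.

## Example-model defaults

Only the hemoglobin rate ladder (0.1, 0.5, 10, 50 vs the non-cooperative
0.1 × 4), the feed-forward stimulus times (10,000 and 20,000 of a 50,000-step
horizon) and the water normalizations (2×10¹⁹, 2×10²⁴) are prescribed by the
systems being modeled; all other numbers below are this package's own
reconstructions chosen to reproduce the qualitative behaviours at
desk-scale run times.

| model | counts | rate constants | N | horizon |
|---|---|---|---|---|
| binding | A=B=10,000 | k_on=1 (k_off opt-in) | 10⁴ | 10,000 |
| water | H2O=N, ions 0 | derived (see above) | 2×10¹⁹ | 20,000 |
| michaelis_menten | E=1000, S=10,000 | k1=1, k−1=0.1, k2=0.1 | 10⁴ | 10,000 |
| mwc_hemoglobin | Hb=1000, O2=10,000 | (0.1, 0.5, 10, 50) | 10⁴ | 10,000 |
| feedback | Stimulus=50, gene=1, NTP=AA=10⁴, Ribosome=10 | act 100, txn 1, tln 10, deact 1 | 10⁴ | 5,000 |
| feedforward | pX=500, genes 1, stimuli +500 | act 10, bind 10, expr 1 | 10³ | 50,000 |

The one-gene feedback model tracks the single gene through three states,
`DNA_i -> DNA -> DNA_d` (inactive, stimulus-activated, protein-silenced), so
`DNA_i + DNA + DNA_d = 1` exactly and a silenced gene can never transcribe
again.  Ribonucleotide and amino-acid pools are modeled as one species
each, consumed one copy per mRNA/protein.  The feed-forward motif uses an
AND-gate trimolecular binding (`pX* + pY* + DNA-Z -> complex`) and
catalytic gene complexes that regenerate themselves while emitting product
protein; it comprises 11 species and six reactions.

## What the examples do and do not show

These systems exercise exact conservation laws, equilibrium recovery
against analytic oracles, stimulus timing, and the large-count sampling
path.  They are idealized: real gene expression has many rate-limiting
substeps, real solutions have volume and diffusion, and real rate constants
carry units tied to experimental time.  Passing tests demonstrate the
correctness of the update algorithm and analytics under the stated model,
not quantitative agreement with any laboratory system.

## Numerical notes and limitations

* Counts are arbitrary-precision integers end to end; CSV output is exact
  digit strings.
* Floats enter only in probabilities, rate constants and `N`; the
  probability product is clamped by construction (each factor < 1).
* Trajectories record every `csv_interval` steps; conservation assertions
  in the tests use interval 1.
* The test-suite and acceptance run sizes (20,000-step water runs, 200-step
  mean-field ensembles of 100 seeds, 25,000-step feed-forward pairs) were
  chosen as the smallest sizes at which the measured quantities are
  statistically stable.
* Declared reaction order affects small-count trajectories (sequential
  updating); large-count mean behaviour is insensitive to it.
* No reversible-reaction sugar: declare the two directions separately.
* SBML import is a reserved stub; units, compartments and spatial effects
  are out of scope.
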