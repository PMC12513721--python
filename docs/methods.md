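# Methods

## Model

A tumour is a collection of individual cancer cells, each identified by
its set of somatic mutations, partitioned per cell into an antigenic set
and a neutral set. Cells divide at per-capita rate *b* and die at rate
*d*; at division the mother is replaced by two daughters, each of which
inherits the mother's full mutation sets and independently acquires
Poisson(*p_a*·λ) new antigenic and Poisson((1−*p_a*)·λ) new neutral
mutations. Mutation identifiers come from a monotone counter and are never
reused (infinite sites: every mutation is unique, so two point mutations
never co-occur at one site). With probability *p_e* per daughter per
division the daughter undergoes immune escape: its entire antigenic set —
inherited and newly acquired — is moved into its neutral set. Escape is
lineage-local (other carriers keep the mutation antigenic) and reversible
only by acquiring new antigenic mutations. The escape draw is made for
every daughter regardless of whether it currently carries antigenic
mutations (a no-op when it carries none); at the baseline *p_e* = 10⁻⁶
this choice is immaterial.

Each antigenic mutation *i* present in the population summons a dedicated
effector-cell type: passive recruitment is a zeroth-order Poisson process
with intensity *B*, gated on the mutation having at least one living
carrier; effectors die at per-capita rate *D*. Pairwise encounters between
a carrier and a matching effector follow mass action — propensity = rate ×
*C_i* × *E_i* — for three channels: active recruitment at per-pair rate
`α_i = α₀ I_i / (1 + α₀ h_α C_i I_i)`, killing at `β_i = β₀ A_i`, and
inhibition at `γ_i = γ₀`. `A_i` and `I_i` are drawn once per mutation from
Exp(mean 1). The kill victim is chosen uniformly among current carriers of
*i*: cells are exchangeable within a carrier class, and any bias would be
unsupported. The founder state is a single mutation-free cancer cell with
no effectors at *t* = 0.

Baseline parameters: *b* = 1, *d* = 0.1, λ ∈ {1, 10}, *p_a* = 0.075,
*p_e* = 10⁻⁶, *B* = 0.2, *D* = 0.1, γ₀ = 10⁻³, ending size *K* = 3×10⁴,
horizon *T_end* = 16 (all rates per unit time). α₀ and β₀ are the swept
interaction constants.

### The saturation constant h_α

`h_α` bounds how fast one effector type can be amplified: for a large
target subclone the per-effector recruitment rate saturates at
`I_i / h_α`. No baseline value is tabulated for it, so it was calibrated
once against the model's qualitative phenomenology and then frozen at
**h_α = 0.1**. The reasoning: the characteristic burst-like specialised
responses (a high-immunogenicity type amplifying against a growing
subclone, overshooting, eliminating it and decaying) require the saturated
amplification rate to exceed tumour growth *b* − *d* = 0.9 by a healthy
margin for upper-tail `I_i`; at `h_α = 1` amplification caps at `I_i`
(mean 1), the burst phenomenology disappears entirely (no spikes, ~0
cycles), while at `h_α ≤ 0.03` immunity is so strong that tumours under
weak interaction parameters no longer escape, flattening the outcome
phase diagram. `h_α = 0.1` (amplification cap 10·`I_i`) preserves both
the phase structure — at λ = 10, α₀ = 0.005, β₀ = 0.01 most tumours grow
to *K*, while β₀ = 0.3 suppresses essentially all — and the cyclic spike
dynamics. The constant is exposed in the configuration; conclusions that
depend on its order of magnitude are flagged in test docstrings.

## Exact simulation

The engine is a standard Gillespie algorithm: exponential waiting times at
the total propensity, channel choice proportional to propensity. A naive
implementation recomputes every propensity each event, which is
prohibitive when the number of antigen types grows with the tumour. The
engine instead maintains a dependency-tracked propensity cache: the five
channels attached to an antigen type (passive recruitment, effector death,
active recruitment, killing, inhibition) are recomputed only when one of
their inputs — carrier count or effector count — changes, so the cost per
event is proportional to the affected cell's antigenic burden, not to the
population or the number of types. Per-antigen total weights live in a
binary sum tree (O(log n) update and weighted selection); internal sums
are rebuilt from the leaves every 2¹⁶ updates to bound float drift, and
the per-channel values themselves are assigned (not incrementally
adjusted), so they equal a from-scratch recomputation bitwise — an
invariant the test-suite checks event by event against the naive oracle.
Cells and carrier sets use an indexed-set structure with O(1) uniform
random choice for death and kill victims. Antigen types whose carrier and
effector counts both reach zero are pruned from the active registry and
archived; identifiers are never reused, so pruned types cannot revive.

A realisation terminates when *C* ≥ *K* (no suppression), *C* = 0
(extinction) or *t* ≥ *T_end* (slow growth). Effector decay after cancer
extinction is not simulated: it cannot change the outcome, and
`final_E` reports the effector count at the moment of extinction.
Trajectories are sampled on a fixed grid (default Δt = 0.01, i.e. 1600
samples over the baseline horizon — fine enough to resolve effector
spikes without storing every event), carrying the last state forward
across event-free intervals; the terminal state is appended as the last
row. One seeded generator drives each realisation; ensembles derive
replicate seeds as base + replicate index, so tables are reproducible and
independent of execution order.

## Summary statistics

`S_j` counts mutations of a class carried by exactly *j* cells; `B_k`
counts cells carrying exactly *k* mutations of the class, including the
*k* = 0 bin so that `Σ_k B_k = C`. Both are computed by direct recount
over living cells with per-cell classification — a mutation escaped in one
lineage contributes to the neutral spectrum for that lineage and to the
antigenic spectrum for lineages still carrying it antigenically. The
identity `Σ_j j·S_j = Σ_k k·B_k = U` is exact on every snapshot and is
asserted, not assumed. `⟨A⟩` and `⟨I⟩` are effector-weighted means over
all currently existing effector cells, including types whose target is
already eradicated (they persist until decayed); with no effectors the
averages are undefined and reported as NaN.

### Neutral baselines

Under no immune response the expected mean burden grows as `2νbt` (ν the
per-daughter mutation mean of the class): each division adds one cell and
2ν expected mutations, so d(*U*/*C*)/d*t* = 2ν*b* independently of the
death rate. This law governs the cell-weighted ensemble mean (total
occurrences over total cells); the per-realisation mean of *U*/*C* sits
systematically below the line at late times (measured ≈13% low at
*t* = 8), a known finite-population/conditioning effect, which is why the
package's checks use the cell-weighted estimator. Expected neutral SFS and
MBD curves are generated by a bundled Monte-Carlo oracle: ensembles of
simulations with every immune channel disabled (*B* = α₀ = β₀ = γ₀ = 0;
mutations of both classes still accrue), grown to a matched population
size — matched size, not matched time, because distribution comparisons
are made between tumours of comparable size. Closed-form neutral
expectations exist in the literature; the oracle pathway is used here as
the authoritative reference and keeps the baseline assumptions identical
to the simulator's.

### Wasserstein selection signature

Burden distributions are compared by the 1-Wasserstein distance after
rescaling the burden axis by the largest support value across the two
inputs to [0, 1] and normalising each histogram to unit mass; the
distance is symmetric and lies in [0, 1]. The shared rescaling constant
is a choice (nothing pins it uniquely); it is what makes the statistic
comparable across ensembles of different burden ranges. Ensemble
signatures average per-replicate histograms bin-wise with equal replicate
weight over tumours that reached *K*, then compare against the matched
neutral reference.

## Cycle counting and spikes

Cancer and effector abundances cycle like antagonistic predator–prey
pairs, but on top of strong growth trends, and their fluctuations are
multiplicative (demographic noise scales with population size). Counting
is therefore done in log space: both series are `log1p`-transformed,
smoothed by a short moving average (0.1 time units), and detrended by a
centred moving average (window 3.0 time units — wider than a cycle,
narrower than the trend). The displacement of the system from its running
trend is standardised per axis (making counts invariant under axis
rescaling) and the signed angle between consecutive displacement vectors
is accumulated into a winding angle; each ±2π crossing is one completed
loop, counter-clockwise (cancer rises first, effectors follow) or
clockwise by sign. A revolution counts only if the log-excursion from
trend reached 0.25 (≈28% of the population) on both axes — smaller loops
are demographic noise. Rotation measured while the system sits within
0.05 standard units of its trend is discarded, since the angle of a
near-zero vector is noise. Linear-scale winding with an absolute
amplitude floor was evaluated first and is blind on growing populations
(global standardisation masks early cycles); the log formulation replaced
it.

The counter is validated on (i) analytic circles, where winding counts
are exact by construction, and (ii) a non-evolving stochastic
Lotka–Volterra control — prey birth 1.0, predation 0.005 with conversion
1.0, predator death 1.0, started at the deterministic centre (200, 200) —
whose quasi-cycle count is independently measured by counting prominent
peaks of the prey series (prominence ≥ 0.5 SD, separation ≥ half the
linearised period 2π/√(a·m) ≈ 6.3). Ensemble means agree to 0.1 cycles
over 20 replicates (4.55 vs 4.55 measured), against a linear-theory
expectation of ≈5 periods over the horizon.

Effector spikes are prominent local maxima of *E*(*t*); on growing
trajectories detection runs on the log scale with multiplicative
prominence (default ≥1.5-fold excursion), since a fixed fraction of the
late-time maximum misses every early spike. In realisations with large
spikes, the dominant single effector type carries the majority of the
total-population spike and peaks at the same time — the burst-like
specialised response described above.

## Experiment driver

Sweeps cross log-spaced (α₀, β₀) grids (matching the decade structure of
the outcome heat maps), run independent replicates per point, and
tabulate outcome proportions with Wilson 95% intervals on the suppression
proportion, mean end times, and Wasserstein distances of grown-tumour
burden distributions against the matched neutral reference (NaN where no
tumour reached *K*). Per-replicate failures are counted and excluded,
never silently dropped. Desk-scale defaults (*K* = 10⁴, tens of
replicates per point) keep ensemble experiments in the minutes range on
one CPU; the baseline *K* = 3×10⁴ is reserved for single illustrative
runs. The recorded *K* column guards against comparing suppression across
different *K* (a smaller *K* can reclassify slow-growing as grown).

## What the generator does and does not emulate

All inputs are generated internally; there is no external data. The
simulator reproduces the mechanistic ingredients of early tumour–immune
ecology — demographic stochasticity at small sizes, unique-neoantigen
specificity, saturating recruitment, escape — but not spatial structure,
cell-cycle phases, effector handling/conjugate states, mechanistic HLA
detail, or sequencing noise (read depth, allele-frequency detection
limits). Passing tests therefore demonstrate internal consistency with
branching-process, queueing and predator–prey theory and the qualitative
phase structure of the interaction model, not agreement with any
particular patient cohort.

## Numerical choices and limitations

- Channel order is canonical (global birth/death first, then per-antigen
  channels by sum-tree slot; within an antigen: passive, effector death,
  recruitment, kill, inhibition), making runs bit-reproducible given
  (parameters, seed).
- Winding-angle crossings use a 10⁻⁹ tolerance so an exactly closed
  analytic loop is not lost to float summation.
- `wasserstein_mbd` of two point masses at zero burden returns 0 (the
  distributions are identical; the rescaling constant would otherwise be
  degenerate).
- Sub-critical neutral references (*b* ≤ *d*) are rejected rather than
  approximated.
- The cycle count per realisation at desk scale is order one, so cycle
  comparisons are made on ensembles, never single runs.
- Mean cycle counts at the two exemplar parameter sets differ by a modest
  margin (≈0.9 vs ≈0.75 at 30–45 replicates); the counter's absolute
  counts depend on the amplitude floor, while the ordering and the
  counter-clockwise majority are stable across the examined settings.
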