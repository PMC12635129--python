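# Methods

This note documents the models, conventions and numerical choices behind
`mobilearn`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Measures (kinematics)

**Instantaneous speed.**  Marker positions (mm, 60 Hz) are differentiated
with the central difference, `V_t = |p_{t+1} − p_{t−1}| / 2T`; the two
endpoint samples are dropped.  On a circle of radius r at angular rate ω
the estimator returns `r·ω·sinc(ωT)`, a relative bias of `(ωT)²/6`
(≈ 5·10⁻⁴ at ω = π rad/s and 60 Hz) — negligible against behavioural
variability.

**Displacement rate.**  The sliding mean of speed over `[t−τ, t+τ]` with
τ = 30 s, i.e. the amount of movement in a 1-min window.  Near the
recording edges the window is truncated to the available support and
normalised by the number of samples actually present, so rate curves
cover the full 12-min session (edge behaviour is exact for constant
speed).  The implementation is a cumulative-sum sliding window and is
tested to 10⁻¹² relative agreement against a naive per-sample loop.

**Baseline ratio.**  The displacement rate divided by its baseline-phase
mean.  The divisor is computed only over window centres whose full ±τ
window lies inside the baseline phase (t ∈ [30, 90] s for a 2-min
baseline): a centre at t = 100 s would otherwise average play-phase
movement into the "baseline" level.  By construction the mean ratio over
those centres is exactly 1; this identity is asserted for every
generated session and is the quantity `scripts/acceptance.py` reports.
A zero baseline mean (a motionless limb) raises a degenerate-baseline
error rather than producing infinities.

**Blocks and limb roles.**  Six half-open 2-min blocks — B [0, 120),
P1 [120, 240) … P5 [600, 720) s — summarise each series by its
arithmetic mean over window centres in the block.  Markers are mapped to
roles relative to the tether: connected arm (ConA), unconnected arm
(UncA), ipsilateral and contralateral leg (IpsiL, ContL), so left- and
right-tethered infants are directly comparable.

**Units.**  Millimetres and seconds throughout; displacement rates are
mm/s.  This is a package convention — reported experimental figures of
this kind often leave the unit implicit.

## Time-series K-means (clustering)

Features are each subject's four-limb baseline-ratio curves down-sampled
to 1 Hz by decimation at integer-second centres (4 × 720 values for the
default session).  No further scaling is applied: the baseline ratio is
already normalised per limb, and z-scoring would erase exactly the
amplitude differences the clustering is meant to find.

The objective is plain Euclidean K-means cost over the concatenated
(limb × time) vector, k = 4 by default.  Lloyd iterations start from a
uniformly random assignment (with every cluster guaranteed one seed
member), stop when assignments no longer change, and assert that the
objective never increases.  Ten random restarts are run and the best
objective kept; ties in nearest-centre assignment break to the lowest
cluster index, and an emptied cluster is reseeded at the subject
farthest from its centre (deterministic given the seed).  On cohorts of
n ≤ 8 the best-of-restarts objective equals the exhaustive-enumeration
minimum (tested), and scikit-learn's k-means++ never finds a better
objective on test instances.

Semantic archetype labels are assigned from the cluster-mean curves with
configurable thresholds (ConA play mean ≥ 1.5 → *arm increase*; both
legs > 1.5 → *all-limb increase*; largest ConA final block > 2.5 →
*arm more increase*; otherwise *no increase*), with collisions resolved
in the priority order arm-more > all-limb > arm > none.  The thresholds
echo the conventional 1.5× learning criterion; they describe centres,
not individuals, and two centres may legitimately share a label.

Note a structural property of Euclidean K-means on these curves: the
*arm-more-increase* family spans a wide amplitude range (ω₀ between 0.3
and 0.8 maps to final ratios from ≈ 2.5 to ≈ 4.2), so in cohorts where
all clusters are the same small size the optimum may split that family
rather than separate the two nearly-flat families.  With cluster
proportions like the study design emulates (55/25/15/5 %), separating
the flat clusters is cheaper in the objective and ground truth is
recovered (Rand index ≥ 0.9 in the recovery test).

## Infant–mobile model (dynamics_model)

The limb is a van der Pol oscillator with a Duffing term; with γ < 0 < α
it settles on a limit cycle of amplitude ≈ 2√(−γ/α) = 1 — the model's
picture of spontaneous movement.  The mobile is a damped harmonic
oscillator forced by the limb when connected (c = 2); its motion feeds
the slow variable δ, which raises the limb's effective frequency
√(ω₀² + δx²) and hence its movement rate.  Because baseline speed scales
with ω₀ while the feedback-driven increment does not, low-ω₀ infants
(slow, low-amplitude spontaneous movement) show the largest *relative*
increase: the single parameter ω₀ reproduces the ordering of the four
behavioural archetypes, and simulated final-block ratios decrease
strictly across the cluster mean ω₀ values 0.55 < 1.15 < 1.65 < 3.05.

Parameters default to γ = −0.25, α = 1, ε = 1, Ω₀ = 2.2, a = 0.13,
κ = 0.007 (the learning gain *a* is deliberately identical across
simulated infants — individual differences enter only through ω₀).

Numerical choices:

* **Integrator** — fixed-step classical RK4 at dt = 0.01 model-time
  units, implemented as a numba kernel with an identical vectorised
  numpy fallback (the two agree to 10⁻¹²; ensembles integrate in
  parallel).  Correctness is checked against `scipy.solve_ivp` RK45 at
  rtol 10⁻¹⁰, and halving dt changes final-block simulated ratios by
  < 1 % (tested).
* **Time map** — 1 model unit = 1 s: 120 units baseline (c = 0) then
  600 units play (c = 2), so simulated and measured curves share a time
  axis.  Configurable.
* **Initial conditions** — x = 1, ẋ = y = ẏ = δ = 0, preceded by a
  60-unit c = 0 burn-in (discarded) so the baseline phase starts on the
  limit cycle rather than mid-transient.  x = 0 exactly is a fixed
  point; it produces a motionless limb and a degenerate-baseline error
  downstream, by design.
* **Speed proxy** — the simulated "speed" is |ẋ(t)|, the model's
  velocity magnitude, fed through the *same* displacement-rate and
  baseline-ratio code as experimental data.  The baseline ratio is
  invariant to the unit of x, so this choice only has to be monotone in
  movement vigour.
* **Cluster simulations** — n infants with ω₀ drawn iid from a uniform
  range of width 0.5; curves are averaged pointwise.  A member whose
  integration blows up is excluded and logged; if more than 10 % fail
  the run raises.
* **ω₀ fitting** — grid search over candidate range means (default
  0.55 … 3.05 in steps of 0.25), scoring the mean squared deviation from
  the target curve over play-phase integer seconds; ties break toward
  the smaller candidate.  Self-recovery is within one grid step
  (tested).

## Synthetic cohorts (synthetic_data)

Each limb's 3-D position is `rest + scale · x(t) · unit_direction` plus
isotropic Gaussian jitter.  The downstream measures consume only speed
magnitude, so the embedding direction is immaterial; one ω₀ per infant
is drawn and shared by all four limbs, which are decorrelated through
randomised initial conditions.  Per-limb coupling gains scale c during
play: the connected arm couples at full strength, the unconnected arm
likewise (both arms increase in the increasing archetypes), and the legs
couple at 0.5 only in the all-limb-increase archetype.  The generative
mechanism of unconnected-limb increases in real infants is unknown; this
attenuation scheme is a package choice that produces the observed limb
patterns, not a claim about the mechanism.

Archetype baseline levels (60/30/45/25 mm/s for clusters 1–4) encode the
empirical ordering that the *no-increase* cluster moves most at baseline
and the *arm-(more-)increase* clusters least; when a baseline level is
set, the embedding scale is calibrated so the limb's baseline mean speed
matches it.  Marker jitter defaults to 0.2 mm per coordinate — the
accuracy class of optical motion capture.  Note that jitter enters the
speed floor as √2 · σ · f_s per axis (≈ 8.5 mm/s at 0.2 mm, 60 Hz), so
it *dilutes* baseline ratios; analyses of real recordings face the same
floor.

Cohort generation derives one seed per session from the master seed via
`numpy.random.SeedSequence`; identical specs and seeds give bit-identical
cohorts.  Default composition mirrors a large mobile-paradigm study:
185 infants, 102/47/27/9 per archetype, 90/95 per age group, sides
counterbalanced and ages interleaved under the quotas.

What the generator does **not** emulate: fussing/crying and attrition,
non-stationary arousal, within-session strategy switches and the rhythmic
increase–decrease cycles individual infants show, movement-quality
changes, marker dropout, or any age-group difference (ages are labels
only).  Passing tests therefore certify the *pipeline machinery* —
normalisation identities, clustering optimality, model behaviour,
statistical calibration — not fidelity of any particular infant's curve.

## Group statistics (group_stats)

The split-plot (mixed-design) ANOVA partitions sums of squares with the
between effect tested against subjects-within-groups (df = N − g) and
the within effect and interaction against the subject × phase residual
(df = (p − 1)(N − g)); unequal group sizes use weighted (cell-size)
means, matching `pingouin.mixed_anova` to 10⁻⁸ on balanced and
unbalanced tables (tested).  No sphericity correction is applied by
default, so degrees of freedom match the classical table; a
Greenhouse–Geisser option exists.  The decomposition identity
SS_total = Σ effects + Σ errors holds to 10⁻⁹ relative on every analysed
table, and under a pure-null simulation the empirical type-I error at
α = 0.01 falls within [0.005, 0.02] (2000 replicates, tested).

Partial η² = SS_effect/(SS_effect + SS_error); its 95 % CI inverts the
noncentral-F CDF at the observed F (lower bound clipped at 0,
η² = λ/(λ + df₁ + df₂ + 1)).  For F(5, 915) = 42.90 this yields
[0.144, 0.231] to within 0.005 — the interval style such studies print.

Tukey HSD uses the studentised-range distribution with Tukey–Kramer
standard errors for unequal n; for two groups it reduces exactly to the
pooled-variance t test (q = √2·|t|).  Applied to the within factor it
uses the omnibus subject × phase error term and df — the convention of
reporting repeated-measures post-hocs on the pooled within error.
Simple-main-effect families divide α = 0.01 by the number of slices
(Bonferroni); phase-at-group slices reuse the omnibus within error,
group-at-phase slices are per-phase one-way ANOVAs.

Through-origin regression (play vs baseline block means) is
coef = Σxy/Σx²; the learner flag is "any play-block ConA ratio ≥ 1.5",
boundary inclusive.

## Problem sizes and runtime

Tests run on scaled-down cohorts chosen to keep the full suite under a
minute of compute while preserving the structures being tested: 8–20
sessions for cohort-level tests, ensembles of 9–24 for cluster
simulations, a coarse 3-point grid for the orchestration test's ω₀ fit
(the dedicated recovery test uses the full 0.25-step grid), and 2000
replicates for ANOVA calibration.  The default `RunConfig` reproduces
the full 185-infant composition and runs in a few minutes.

## Known limitations

* The archetype labelling thresholds are heuristics over cluster means;
  near-threshold centres (e.g. all-limb increases diluted by measurement
  noise) can be labelled as a neighbouring archetype.
* K-means with Euclidean distance is scale-sensitive across time points
  and cannot represent elongated clusters; the wide arm-more-increase
  family is recovered reliably only under study-like cluster
  proportions (see above).
* The ω₀ fit conditions on all other model parameters being the study
  values; it is a one-parameter projection, not a full model fit.
* The noncentral-F CI for partial η² is one of several published
  constructions; alternatives differ in the λ → η² mapping by O(1/N).
* Baseline-level and noise defaults are package conventions chosen for
  realism, not measured population values.
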