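# Methods

## The model

Five species S1..S5 interact through the Jungle tournament: each species
invades every lower-ranked species it can reach, and the bottom species
invades only the top one.  The ten directed predator->prey pairs are

    S1 -> S2, S3, S4;  S2 -> S3, S4, S5;  S3 -> S4, S5;  S4 -> S5;  S5 -> S1,

each carrying a strictly positive invasion rate `K[i,j]` (dimensionless,
per pairwise encounter).  Two named sub-families reduce the ten rates to
interpretable parameters:

* **Two-parameter family** (`example1_network(p, s)`): primary food
  (the next-lower level) at rate 1, every other prey ("sub-food") at a
  single rate `p`, bottom-to-top inhibition `K[5,1] = s`.
* **Three-parameter family** (`example2_network(p1, p2, s)`): primary
  food at 1, second-level prey at `p1`, third-level prey at `p2`,
  inhibition `s`.

Zero or negative rates are rejected at construction: the analytic
classification below requires strict signs, and a zero rate changes the
premises of its proof rather than being a harmless limit.

## Mean-field layer

Well-mixed densities obey the pairwise zero-sum replicator equations
`dx/dt = x * ((K - K^T) x)`; total density is conserved term by term.
The degree-2 rate combinations

    A = K13 K25 + K23 K51 - K12 K35
    B = K14 K25 + K24 K51 - K12 K45
    C = K14 K35 + K34 K51 - K13 K45

fully determine the asymptotic survivor set when none vanishes:
A>0 ∧ B>0 → {S1,S2,S5};  A<0 ∧ C>0 → {S1,S3,S5};  B<0 ∧ C<0 → {S1,S4,S5};
AB<0 ∧ AC>0 → all five.  These four conditions partition the eight strict
sign patterns of (A,B,C) exactly (asserted by enumeration in the tests).
On the measure-zero boundaries the classifier reports `BOUNDARY` and
draws no dynamical conclusion.  The boundary tolerance defaults to
1e-12 × max(K)², since A, B, C are degree-2 polynomials in the rates.

Each three-species regime carries a Lyapunov function, e.g.
V = x1^K25 · x2^K51 · x5^K12 with dV/dt = V·(A x3 + B x4) ≥ 0 in the
first regime.  (One exponent is sometimes written as a rate "K[1,5]"
that does not exist in the ten-edge topology; the only reading that
makes the dV/dt identity hold algebraically — we verified it
symbolically — is K[5,1], which is what this package implements.)  In
the five-species regime the exponent vector (E, C, −B, A, D), with

    D = K14 K23 + K12 K34 - K13 K24
    E = K23 K45 + K25 K34 - K24 K35

(sign-flipped when A < 0), is a null vector of K − K^T, so
V4 = x1^E x2^C x3^{−B} x4^A x5^D is a motion invariant; both facts are
checked numerically in the tests, and sign lemmas relating D and E to
A, B, C guarantee every exponent is positive in the coexistence regime.

### Numerical choices

* `integrate` works in density space with DOP853 at rel_tol 1e-9 /
  abs_tol 1e-12 by default; sampled states are renormalized onto the
  simplex and the pre-renormalization drift (|Σx−1|, observed ~1e-15 at
  defaults) is kept as a diagnostic.  Small interpolation negatives are
  clipped inside a guard band of 100·(abs_tol+rel_tol); anything larger
  raises.
* `ode_survivors`, the empirical cross-check of the classifier,
  integrates in **log-density** space: decay of a doomed species becomes
  a benign linear drift, so there is no step-size collapse near the
  absorbing boundary.  The network is first rescaled so its largest rate
  is 1 (time-scale covariance makes this a pure change of units).
* Extinction in finite time is asymptotic, so survivors are read off a
  trailing window: a species is extinct when its maximum density over
  the trailing **half** of the samples is below 1e-3.  The window is
  half (not a small tail) because near regime boundaries the surviving
  trio settles onto a large-amplitude cycle whose low-density dwells can
  occupy a sizable fraction of the run.
* The horizon defaults to 500 time units, stretched to 30/min(|A|,|B|,|C|)
  (unit-scale invariants) when the smallest invariant is small — the
  average decay rate of a doomed species is proportional to it.  If the
  alive set still is not one of the four admissible survivor sets the
  horizon doubles (up to 2^6×): survivors can legitimately dwell at
  astronomically small densities (their lower bound from the conserved
  quantity can be far below any fixed threshold), and the only cure is a
  window longer than the cycle.  With these rules the classifier and the
  integrated dynamics agree on 200/200 random networks whose invariants
  are bounded away from zero by 0.05.

## Phase analysis

Region maps label parameter-plane grids with the classifier; resolution
only affects rendering, since each cell is classified exactly.  For the
three-parameter family the five-species region in the (p2, s) plane lies
between the line s = p1(1−p2) (A=0) and the parabola s = (1−p2²)/p1
(B=0); its area over the unit p2-strip is

    Area(p1) = ∫₀¹ | p1(1−p2) − (1−p2²)/p1 | dp2 .

The two curves cross inside the strip at p2 = p1²−1, which lies in (0,1)
exactly when 1 < p1 < √2; the piecewise regime split is therefore at 1
and √2.  On that interval the closed form is
−p1⁵/3 + 2p1³ − (7/2)p1 + 2/p1, validated against adaptive quadrature
(`scipy.integrate.quad` with the kink passed as a breakpoint, abs. error
≤ 1e-10) to 1e-8 on 50 points.  Minimizing it (bounded scalar
minimization, argument tolerance 1e-9) gives P = 1.1488, i.e. 1.149 to
three decimals; P² is the relevant root of 10x³ − 36x² + 21x + 12 = 0,
the first-order condition cleared of denominators.  Area is strictly
decreasing for p1 ≤ 1 and increasing for p1 ≥ √2 (central differences on
the quadrature oracle).

## Lattice layer

An L×L periodic lattice (L ≥ 3 so the eight Moore neighbors are
distinct) is fully occupied; one elementary update draws a focal site
and one Moore neighbor uniformly, and if the two species differ the
pair's predator replaces the prey with probability k[pred, prey].  L²
updates form one Monte Carlo step (MCS).  Probabilities come from a
network by global normalization k = K/ΣK over the ten pairs, or can be
overridden explicitly.

* **Pair convention (default):** predation is resolved within the
  unordered pair — whichever of the two drawn individuals is the
  predator may act.  The focal-only alternative (only the focal
  individual acts) is an exact time rescale by 2 and is provided as a
  switch.
* Asynchronous random sequential updating, drawing with replacement.
* Extinction times are exact: species counts are maintained
  incrementally and checked after every MCS, independent of the density
  recording stride (default 10 MCS).
* Once a single species remains the lattice is absorbing and remaining
  steps are skipped; `min_alive=5` turns this into an abort at the first
  extinction, used to screen cheaply for fully coexisting realizations.
* The update kernel is numba-compiled and uses an explicit xorshift64*
  stream (seeded through a splitmix64 scramble); one 64-bit draw encodes
  focal row, column and neighbor direction.  It sustains roughly 6×10⁷
  elementary updates/s on one CPU, and runs are bit-for-bit reproducible
  across platforms.  Scan cells derive their seeds from
  (base_seed, i, j) via `numpy.random.SeedSequence`, so parameter scans
  are reproducible and embarrassingly parallel.

### What the experiments show, and at what sizes

* With all raw rates equal (normalized to k = 0.1 per pair), S3 and S4
  die out at a few hundred MCS on a 200×200 lattice (median ≈ 350 over
  seeds) and the surviving trio S1, S2, S5 cycles indefinitely —
  matching the mean-field prediction.  Note the normalization matters
  here: with every replacement *probability* forced to 1 the same
  extinctions happen ~10× sooner (≈ 30 MCS), simply because each
  attempted update then always fires.
* At the two-parameter coexistence point (p=0.5, s=1.2), habitat size
  governs survival: at L=100 two species (which two is run-dependent)
  are typically gone within a few thousand MCS; the fraction of
  realizations keeping all five species for 20000 MCS rises steeply with
  L (≈0/6 at 200, ≈3/6 at 300, ≈5/6 at 400 in our seeds).  The early
  hazard is the globally synchronized transient: the mean-field dip of
  x3 reaches ~6×10⁻⁴, i.e. a handful of individuals at L ≤ 200, before
  spatial decorrelation can protect the minority.
* Density-fluctuation scaling is a statement about the coexisting
  quasi-steady state, so it is evaluated on realizations conditioned on
  all five species surviving (`find_coexisting_run`); the standard
  deviation of x1 over the trailing half of 20000 MCS then decreases
  monotonically across L ∈ {200, 400, 800}.  Unconditioned, the L=200
  entry would measure a different attractor (a three-species state) and
  the comparison would be meaningless.
* The coarse outcome scan over the (p, s) plane uses a 5×5 grid at
  L=100 and 2×10⁴ MCS — small enough for a desk run, large enough that
  the qualitative phases (five-species coexistence, the two trio
  phases, and single-species fixation at small p and s) all appear.
  The full-resolution version of that diagram (L=400, 10⁵ MCS, dense
  grid) is the same computation scaled up via `phase_scan`.

## Synthetic fixtures

Random networks draw their ten rates log-uniformly on [0.1, 10] — two
decades, both signs of A, B, C well represented — with rejection until
min(|A|,|B|,|C|) exceeds a requested margin; case-conditioned generators
rejection-sample these until a requested sign regime holds.  All
generators are pure functions of their seed.  What the fixtures do *not*
emulate: empirically calibrated rate magnitudes for any real ecosystem,
and rate heterogeneity beyond two decades.  Tests passing on these
fixtures therefore certify the mathematics and the simulation machinery,
not the fit of the Jungle topology to any particular community.

## Known limitations

* The analytic classifier speaks only to the well-mixed limit; on the
  lattice, finite-size fluctuations produce outcomes it cannot predict
  (single-species fixation, habitat-size-dependent extinction).
* The survivor read-out from finite trajectories is threshold-based and
  can in principle misread a survivor whose limit cycle dwells below
  threshold for longer than the (repeatedly doubled) window; the
  doubling cap is 2^6.
* No trophic loss (the interactions are zero-sum replacements), no
  mobility/exchange moves, no empty sites, and only the five-species
  Jungle topology; these are modelling scope decisions, not numerical
  approximations.
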