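# Methods

## The automaton and its two rule layers

The model system is Conway's Game of Life: an infinite square grid of
binary cells updated synchronously under a totalistic rule over the Moore
8-neighborhood. The default rule is B3/S23 — birth on exactly three live
neighbors, survival on two or three; the neighborhood choice follows
Conway's standard game (the informal rule text says only "neighbors").
The package treats the rule set as two coupled layers: the *existential*
layer that creates initial counters (pattern files, soups, scribbles) and
the *conditional* layer that regulates them (the update rule). Nothing in
the conditional layer references absolute position or time, which is why
translation, rotation and reflection equivariance hold exactly and are
asserted as properties.

The engine is sparse: the universe is a set of live integer coordinates,
and one update examines only live cells and their neighbors. For any rule
without birth-on-zero this candidate-set method is provably identical to
a dense scan (a cell with zero live neighbors can never change state);
rules with 0 in the birth set are rejected rather than approximated.
Equivalence with an independently written dense boolean-array engine is
asserted on 100 random 16×16 soups over 50 generations each. Two
topologies exist: the unbounded plane (default, required for spaceship
displacement to be meaningful) and a width×height torus whose wrap
applies to neighbor lookups only; the torus makes global recurrence
well-defined for ecosystem experiments since its state space is finite.

## Classification

Cycle detection is by hash map, not Floyd/Brent: a single pass stores
each translation-canonical state (live set normalized to its bounding-box
origin) with its generation and offset, so the transient and the minimal
period are both recovered on the first repeat; memory is bounded by the
generation budget. Two modes are deliberately distinct:

- `classify_exact` reports the first recurrence of the *initial* state —
  the right question for "is this pattern an oscillator/spaceship";
- `classify_fate` reports the first repeat of *any* state — the right
  question for "what does this pattern become", and the one that captures
  adhesion-like transients (L-tromino → block, transient 1).

A pattern that splinters into diverging parts (the R-pentomino's escaping
gliders) never repeats a global canonical state; it is reported
`unresolved` rather than forced into a class, and a bounding-box limit
(default 2048) flags runaway growth instead of simulating it forever.
The default generation budget is 1000, comfortably above the classical
long-period examples (an oscillator of 173 generations is quoted in the
older literature; no specific pattern accompanies the citation, so no
test asserts it).

Object extraction partitions live cells into Chebyshev-linked components.
The default link radius 1 is plain 8-connectivity; it is configurable
because visual object identity and 8-connectivity disagree for some
ships — the LWSS/MWSS/HWSS phases carry cells a knight's move from the
hull, so censuses that must count whole ships use radius 2. Radius
arithmetic is literal: two blocks with two empty columns between them
have closest-cell Chebyshev distance 3 and merge only at radius ≥ 3.

Enumerating all six fixed triominoes records what actually happens to
three-cell seeds: the four L-orientations adhere into blocks, the two
straight ones become blinkers, none dies. (Folklore sometimes calls the
L-tromino the only surviving triomino; the enumeration shows the straight
triomino also persists, as an oscillator.)

## Landscape experiments

Soups are pure functions of their spec (grid, density, mode, seed) via
`numpy.random.default_rng`. Bernoulli mode fills cells independently at
the given density; the default reference density is 0.35, a conventional
choice dense enough to ignite sustained activity and sparse enough not to
self-extinguish immediately. Scribble mode emulates an analog hand-drawn
stroke mapped onto the grid: a fixed number of seeded random walks of a
single-cell brush, each roughly one grid perimeter long, stepping
uniformly over the 8 directions. The point being modeled is sensitivity
to initial conditions — differences that decide the outcome are not
visible in the scribble — so the walk's distribution is fixed and
documented rather than tuned.

Censuses record, per generation, the population, the births and deaths of
the step that produced that generation, the object count, and per-object
classifications. Per-object classification inside time series uses a
reduced budget of 64 generations: mid-transient debris rarely recurs and
would otherwise burn the full budget every generation, while settled ash
(blocks, blinkers, the standard ships) is identified well within 64. The
conservation identity `population(t) = population(t−1) + births − deaths`
is asserted on every recorded trajectory.

Global stabilization detection hashes the translation-*sensitive* state:
at ecosystem scale position matters (a glider drifting off is change, not
recurrence), whereas individual objects are classified up to translation.
Collisions place two patterns at a chosen offset (overlap rejected), run
to global cycle entry or budget, and census the survivors; outcomes are
deterministic in the offset. Escape detection reports an object the first
time its bounding box clears the initial region plus margin, provided it
classifies as a spaceship; reported escapees are simulated forward in
isolation so the same ship is not re-reported every generation.

The reference soup experiment (32×32 torus, density 0.35, seed 20160614,
125 generations) is frozen as a golden-master CSV generated by this
package and cross-checked against the dense oracle for population, births
and deaths; the experiment's parameters are the package's own, chosen
once, as the original free-evolution illustrations published no grid,
density or seed.

The box-counting dimension overlays grids of box size `s` on the
pattern's bounding box, counts occupied boxes `N(s)`, and reports the
least-squares slope of `log N(s)` against `log(1/s)`. It is a descriptive
scaling statistic over the probed size range, not an asymptotic fractal
dimension: sensible box sizes must be small relative to the pattern
extent, and a minimum of two distinct sizes is enforced.

## Ring-of-cells stability analysis

The reaction–diffusion analysis uses the discrete cellular case — N
identical cells in a ring exchanging m morphogens with nearest neighbors
— rather than the continuous circle; the discrete Laplacian's eigenvalues
`−4 sin²(πk/N)` give mode matrices `M_k = J − 4 sin²(πk/N) diag(μ)` with
`J` the reaction Jacobian at the homogeneous equilibrium and `μ ≥ 0` the
exchange rates. Only linear stability is computed; nonlinear pattern
formation is out of scope. Damping is computed through `min(k, N−k)` so
the `k ↔ N−k` ring symmetry is exact in floating point.

Per mode, the dominant eigenvalue (largest real part; ties to larger
|imaginary part|) fixes two labels: *stationary* vs *oscillatory* by
whether its imaginary part exceeds tolerance, and *growing/decaying/
marginal* by the sign of its real part against tolerance. Tolerances
default to 1e−9 scaled by `1 + ‖J‖`. Wavelength classes are realized as
configurable fractions of N — `min(k, N−k)/N ≤ 0.05` is extremely long,
`≥ 0.45` extremely short, otherwise finite — because the underlying
qualitative categories carry no numeric boundary. The system-level class
is the dominant mode over all k (ties to smallest k): a growing
stationary finite mode is the classic diffusion-driven instability
(pattern that freezes, the still-life analogue), a growing oscillatory
one a wave instability (the blinker analogue).

`scan_for_oscillatory_finite` samples Jacobian entries uniform in [−1, 1]
and diffusion rates uniform in [0, 1] on a default 20-cell ring and
counts models whose *dominant* mode is growing, oscillatory and of finite
wavelength. For m = 2 the count is structurally zero: a complex pair of a
real 2×2 matrix has real part trace/2, and diffusion only lowers the
trace as k grows, so an oscillatory pair at finite k is always dominated
by k = 0. For m = 3 hits exist but are rare under this sampling measure
(on the order of a few per 10⁴ samples), so the fixture-finding scan uses
3×10⁴ samples; one discovered model is frozen in the test suite and must
reclassify as oscillatory-growing-finite. This is an empirical probe of
the morphogen-count threshold, not a proof.

## Synthetic data and what passing tests show

All inputs are generated: canonical patterns are embedded bitmaps
verified by simulation (the glider must translate (1,1) per 4
generations, the ships (±2,0) per 4), soups and scribbles come from
seeded RNGs, and ring models are either textbook linearizations or
scan-discovered. The soups emulate the *protocol* of free-evolution
experiments, not any particular published run; consequently the
golden-master census is a regression anchor plus an independent
dense-oracle check, not a claim about external data. Passing tests show
the implementation is exact with respect to the rule semantics and
self-consistent across two independent engines; they do not calibrate
against laboratory biology, which enters only as analogy.

## Known limitations

- No Hashlife-style acceleration; budgets keep default runs in seconds.
- Fate classification on the unbounded plane cannot resolve patterns
  whose parts diverge (reported `unresolved`, by design).
- The scribble emulation is one concrete reproducible stand-in for an
  inherently irreproducible analog gesture.
- The ring analysis is linear; it predicts onset and class of
  instability, not the final nonlinear pattern.
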