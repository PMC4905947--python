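# lifelab

A laboratory for studying how two coupled layers of rules generate
biological-looking form in Conway's Game of Life, together with the
reaction–diffusion typology it parallels. The package is aimed at
theoretical and computational biologists who use cellular automata as
heuristic models of development and ecology: the *existential* layer
(whatever places the initial live cells — a drawn pattern, a random soup,
a scribbled stroke) plays the role of genetic specification, while the
*conditional* layer (the B3/S23 update applied identically everywhere)
plays the role of epigenetic regulation. Everything interesting — still
lifes, oscillators, moving ships, whole ecosystems of interacting debris —
is emergent from their interaction.

## What it computes

**Engine.** A sparse, exact implementation of the totalistic update rule
on the unbounded plane or a torus. For a live cell with `n` Moore
neighbors and rule B*B*/S*S*:

- survival: cell persists iff `n ∈ S` (isolation death for `n ≤ 1`,
  overpopulation death for `n ≥ 4` under S23);
- birth: an empty cell turns on iff `n ∈ B` (exactly 3 under B3);
- all updates synchronous; `|live(t+1)| = |live(t)| + births − deaths`.

**Classifier.** The taxonomy of emergent forms. A pattern whose
translation-canonical state first recurs at generation `t` with net offset
`d` is a still life (`t = 1, d = 0`), an oscillator of period `t`
(`t ≥ 2, d = 0`) or a spaceship (`d ≠ 0`); `classify_fate` additionally
finds the cycle a pattern *falls into* and the transient length (the
L-tromino becomes a block after one step).

**Landscape experiments.** Seeded Bernoulli soups and scribble strokes,
free evolution with per-generation censuses (births, deaths, object counts
and kinds), global stabilization detection, mover-escape tracking, pattern
collisions, and a box-counting estimate of the fractal dimension
`D = d log N(s) / d log(1/s)` of any configuration.

**Turing ring.** Linear stability of an m-morphogen reaction–diffusion
system on an N-cell ring. Mode `k` evolves under
`M_k = J − 4 sin²(πk/N)·diag(μ)`; each mode is classed stationary vs
oscillatory (dominant eigenvalue real vs complex) and extremely-long /
finite / extremely-short wavelength (k relative to N). A random-model scan
probes the claim that growing oscillatory modes at *finite* wavelength
require at least three morphogens.

## Worked example

```python
from lifelab import fixture, classify_exact, classify_fate

print(classify_exact(fixture("blinker")))
# Classification(kind='oscillator', period=2, displacement=(0, 0), ...)
print(classify_exact(fixture("glider")))
# Classification(kind='spaceship', period=4, displacement=(1, 1), ...)
print(classify_fate(fixture("l_tromino")))
# Classification(kind='still_life', period=1, displacement=(0, 0), transient=1, ...)
```

The blinker returns to its starting state every 2 generations in place;
the glider returns every 4 generations shifted one cell diagonally (speed
c/4); the L-tromino is not itself stable but "adheres" — its three cells
induce a fourth that binds them into a block from generation 1 onward.

Longer narratives live in `examples/`: `classify_menagerie.py` (the whole
fixture table), `soup_census.py` (a 125-generation random-soup census and
the ash's box-counting dimension), `glider_collision.py` (two gliders
annihilating into a block) and `turing_ring.py` (stationary vs oscillatory
ring instabilities). A thin CLI offers the same experiments from a shell:

```sh
lifelab classify glider.rle --mode exact
lifelab soup --width 32 --height 32 --density 0.35 --seed 1 --census-csv out.csv
lifelab ring --config ring.yaml --out-csv modes.csv
```

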