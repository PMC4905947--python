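"""Soup, scribble, collision and free-evolution experiments.

This is the "laboratory" layer: seeded random initial conditions evolve
freely while a per-generation census tracks the observables that map onto
developmental processes — births (division), deaths (cell death), moving
objects (cell movement), object counts and kinds. Global stabilization is
detected on the translation-*sensitive* state: at the ecosystem scale,
where an object sits matters, unlike at the organism scale where objects
are classified up to translation.

Stochastic inputs (soups, scribbles) are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from lifelab.engine import LIFE, Rule, Universe, normalize, run, step, translate
from lifelab.classify import Census, classify_exact, extract_objects
from lifelab.patterns import Pattern

Coord = Tuple[int, int]

#: Per-object classification budget used inside census time series. Soup
#: debris mid-transient rarely recurs, so a short budget keeps the scan
#: cheap; settled ash (blocks, blinkers, gliders) is identified well
#: within it.
DEFAULT_CLASSIFY_BUDGET = 64


@dataclass(frozen=True)
class SoupSpec:
    """Recipe for a reproducible random initial condition.

    ``bernoulli`` fills each cell independently with probability
    ``density``. ``scribble`` emulates a hand-drawn analog stroke mapped
    onto the grid: ``strokes`` seeded random walks of a single-cell
    brush, each roughly one grid perimeter long, stepping uniformly over
    the 8 directions. Identical specs produce identical soups, bit for
    bit — the differences that matter downstream are never visible in
    the initial conditions.
    """

    width: int
    height: int
    density: float = 0.35
    mode: str = "bernoulli"
    strokes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError(f"density must be in [0, 1], got {self.density}")
        if self.mode not in ("bernoulli", "scribble"):
            raise ValueError(f"unknown soup mode {self.mode!r}")
        if self.strokes < 1:
            raise ValueError("strokes must be positive")


def make_soup(spec: SoupSpec, torus: bool = True) -> Universe:
    """Generate the initial universe a spec describes.

    Experiments default to a bounded torus so global recurrence is well
    defined; pass ``torus=False`` for an unbounded plane seeded with the
    same cells.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height
    if spec.mode == "bernoulli":
        grid = rng.random((h, w)) < spec.density
        cells = frozenset((int(x), int(y)) for y, x in zip(*np.nonzero(grid)))
    else:  # scribble
        length = 2 * (w + h)
        cells_set = set()
        for _ in range(spec.strokes):
            x = int(rng.integers(0, w))
            y = int(rng.integers(0, h))
            cells_set.add((x, y))
            for _ in range(length):
                dx, dy = _SCRIBBLE_DIRS[int(rng.integers(0, 8))]
                x = (x + dx) % w
                y = (y + dy) % h
                cells_set.add((x, y))
        cells = frozenset(cells_set)
    return Universe(cells, torus=(w, h) if torus else None)


_SCRIBBLE_DIRS = (
    (-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1),
)


@dataclass(frozen=True)
class CensusRecord:
    """One generation's observables.

    ``births``/``deaths`` are the changes of the step that *produced*
    this generation (zero for generation 0), so
    ``population(t) = population(t-1) + births(t) - deaths(t)`` holds
    along any record sequence.
    """

    generation: int
    population: int
    births: int
    deaths: int
    n_objects: int
    kinds: Census


_KIND_COLUMNS = ("still_life", "oscillator", "spaceship", "dies_out", "unresolved")


def records_to_frame(records: Sequence[CensusRecord]) -> pd.DataFrame:
    """Census time series as a DataFrame (one kind-count column per kind)."""
    rows = []
    for r in records:
        by_kind = r.kinds.by_kind
        row = {
            "generation": r.generation,
            "population": r.population,
            "births": r.births,
            "deaths": r.deaths,
            "n_objects": r.n_objects,
        }
        for k in _KIND_COLUMNS:
            row[f"n_{k}"] = by_kind.get(k, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def free_evolution(
    universe: Universe,
    rule: Rule = LIFE,
    n_generations: int = 125,
    link_radius: int = 1,
    classify_budget: int = DEFAULT_CLASSIFY_BUDGET,
) -> List[CensusRecord]:
    """Evolve freely, recording a census every generation (0..n)."""
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    records = []

    def record(u: Universe, births: int, deaths: int) -> None:
        objs = extract_objects(u, link_radius)
        cen = Census()
        for pat, _ in objs:
            cen.add(classify_exact(pat, rule, classify_budget))
        records.append(
            CensusRecord(u.generation, u.population, births, deaths, len(objs), cen)
        )

    record(universe, 0, 0)
    current = universe
    for _ in range(n_generations):
        current, delta = step(current, rule)
        record(current, len(delta.births), len(delta.deaths))
    return records


def detect_stabilization(
    universe: Universe, rule: Rule = LIFE, max_generations: int = 1000
) -> Optional[Tuple[int, int]]:
    """First entry into a global cycle, as (entry generation, period).

    The hash map keys on the position-sensitive live set: a lone glider
    drifting across an unbounded plane never repeats a global state and
    the run comes back ``None`` (unresolved), by design.
    """
    seen: Dict[frozenset, int] = {universe.live: 0}
    current = universe
    for t in range(1, max_generations + 1):
        current, _ = step(current, rule)
        if current.live in seen:
            entry = seen[current.live]
            return entry, t - entry
        seen[current.live] = t
    return None


def detect_escapes(
    trajectory: Sequence[Universe],
    initial_region: Tuple[int, int, int, int],
    margin: int = 2,
    rule: Rule = LIFE,
    link_radius: int = 1,
    classify_budget: int = DEFAULT_CLASSIFY_BUDGET,
) -> List[Tuple[int, Pattern]]:
    """Movers that leave the original space.

    Reports ``(generation, pattern)`` for each object whose bounding box
    first lies entirely outside ``initial_region`` (inclusive
    ``(xmin, ymin, xmax, ymax)``) expanded by ``margin`` and which
    classifies as a spaceship. Each escapee is reported once: after its
    first sighting it is simulated forward in isolation and its
    predicted positions are not re-reported.
    """
    if not trajectory:
        raise ValueError("trajectory must be nonempty")
    xmin, ymin, xmax, ymax = initial_region
    xmin -= margin
    ymin -= margin
    xmax += margin
    ymax += margin
    n_gens = len(trajectory)
    claimed: List[set] = [set() for _ in range(n_gens)]
    events: List[Tuple[int, Pattern]] = []
    for idx, u in enumerate(trajectory):
        for pat, (ox, oy) in extract_objects(u, link_radius):
            w, h = pat.extent
            inside = not (ox > xmax or oy > ymax or ox + w - 1 < xmin or oy + h - 1 < ymin)
            if inside:
                continue
            abs_cells = translate(pat.cells, (ox, oy))
            if abs_cells in claimed[idx]:
                continue
            cls = classify_exact(pat, rule, classify_budget)
            if cls.kind != "spaceship":
                continue
            events.append((u.generation, pat))
            # Claim this object's future positions so it is not re-reported.
            iso = Universe(abs_cells)
            for j in range(idx, n_gens):
                claimed[j].add(iso.live)
                iso, _ = step(iso, rule)
    return events


@dataclass(frozen=True)
class CollisionOutcome:
    """Deterministic result of placing two patterns and letting them run."""

    offset: Coord
    generations_to_stability: Optional[int]
    period: Optional[int]
    survivor_census: Census
    population_final: int

    def to_dict(self) -> dict:
        return {
            "offset": list(self.offset),
            "generations_to_stability": self.generations_to_stability,
            "period": self.period,
            "survivor_census": self.survivor_census.to_records(),
            "population_final": self.population_final,
        }


def collide(
    a: Pattern,
    b: Pattern,
    offset: Coord,
    rule: Rule = LIFE,
    max_generations: int = 1000,
    link_radius: int = 1,
    classify_budget: int = DEFAULT_CLASSIFY_BUDGET,
) -> CollisionOutcome:
    """Place ``a`` at the origin and ``b`` at ``offset``; run to stabilization.

    The outcome — destruction, transformation or peaceful coexistence of
    the two shapes — is fully determined by the offset, yet generally
    unpredictable without running the rules. Overlapping placements are
    rejected; choose a non-overlapping offset.
    """
    cells_a = a.cells
    cells_b = translate(b.cells, offset)
    if cells_a & cells_b:
        raise ValueError(f"patterns overlap at offset {offset}")
    u = Universe(cells_a | cells_b)
    stab = detect_stabilization(u, rule, max_generations)
    if stab is None:
        final = run(u, rule, max_generations)[-1]
        entry = period = None
    else:
        entry, period = stab
        final = run(u, rule, entry)[-1]
    cen = Census()
    for pat, _ in extract_objects(final, link_radius):
        cen.add(classify_exact(pat, rule, classify_budget))
    return CollisionOutcome(tuple(offset), entry, period, cen, final.population)


def box_counting_dimension(
    universe: Universe, box_sizes: Sequence[int]
) -> Tuple[float, Dict[int, int]]:
    """Box-counting (Minkowski) dimension estimate of the live set.

    Overlays grids of boxes of each size on the pattern's bounding box,
    counts boxes containing at least one live cell, and fits
    log(count) against log(1/size) by least squares. A filled square
    estimates near 2, a line near 1, a dust of isolated cells near 0;
    intermediate slopes indicate self-similar scaling over the range of
    sizes probed.
    """
    sizes = sorted(set(int(s) for s in box_sizes))
    if len(sizes) < 2:
        raise ValueError("need at least 2 distinct box sizes")
    if any(s < 1 for s in sizes):
        raise ValueError("box sizes must be positive")
    if not universe.live:
        raise ValueError("box-counting dimension of an empty universe is undefined")
    cells, _ = normalize(universe.live)
    counts: Dict[int, int] = {}
    for s in sizes:
        counts[s] = len({(x // s, y // s) for x, y in cells})
    log_inv = np.log([1.0 / s for s in sizes])
    log_n = np.log([counts[s] for s in sizes])
    slope = float(np.polyfit(log_inv, log_n, 1)[0])
    return slope, counts
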