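"""Taxonomy of emergent forms: still lifes, oscillators, spaceships, die-outs.

Two classification modes are provided because "is periodic" and "becomes
periodic" are different questions:

* :func:`classify_exact` asks whether the pattern *as given* recurs — the
  first return of the initial shape (up to translation) fixes the kind,
  period and displacement.
* :func:`classify_fate` tracks every state visited and reports the cycle
  the pattern eventually falls into, together with the transient length —
  e.g. the L-tromino, which is not itself stable but closes into a block
  after one step (the adhesion motif: the three cells induce a fourth
  that binds them permanently).

Objects are classified in isolation on the unbounded plane; interactions
between objects belong to the landscape experiments.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from lifelab.engine import LIFE, Rule, Universe, normalize, step
from lifelab.patterns import Pattern

Coord = Tuple[int, int]

KINDS = ("dies_out", "still_life", "oscillator", "spaceship", "unresolved")

#: Default search budget; comfortably beyond the longest period quoted for
#: simple oscillators in the classical literature (173 generations).
DEFAULT_MAX_GENERATIONS = 1000

#: Bounding-box side beyond which a pattern is declared growing rather than
#: simulated further (unbounded growth proof is out of scope).
DEFAULT_GROWTH_LIMIT = 2048


@dataclass(frozen=True)
class Classification:
    """Outcome of a pattern classification.

    ``period`` is the minimal recurrence time; ``displacement`` the net
    translation per period (nonzero only for spaceships); ``transient``
    the number of generations before periodic behavior (for die-outs, the
    generation the universe first became empty). ``growth`` flags a
    pattern abandoned because its bounding box blew past the limit.
    """

    kind: str
    period: Optional[int] = None
    displacement: Optional[Coord] = None
    transient: int = 0
    generations_examined: int = 0
    growth: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "still_life" and (self.period != 1 or self.displacement != (0, 0)):
            raise ValueError("still_life requires period 1 and zero displacement")
        if self.kind == "oscillator" and (
            self.period is None or self.period < 2 or self.displacement != (0, 0)
        ):
            raise ValueError("oscillator requires period >= 2 and zero displacement")
        if self.kind == "spaceship" and (self.displacement in (None, (0, 0))):
            raise ValueError("spaceship requires nonzero displacement")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "period": self.period,
            "displacement": list(self.displacement) if self.displacement else None,
            "transient": self.transient,
            "generations_examined": self.generations_examined,
            "growth": self.growth,
        }


def _kind_of_cycle(period: int, displacement: Coord) -> str:
    if displacement != (0, 0):
        return "spaceship"
    return "still_life" if period == 1 else "oscillator"


def _too_big(u: Universe, limit: int) -> bool:
    box = u.bounding_box()
    if box is None:
        return False
    return (box[2] - box[0] + 1) > limit or (box[3] - box[1] + 1) > limit


def classify_exact(
    pattern: Pattern,
    rule: Rule = LIFE,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
    growth_limit: int = DEFAULT_GROWTH_LIMIT,
) -> Classification:
    """Classify a pattern by the first recurrence of its *initial* state.

    The pattern is simulated on the unbounded plane; at each generation
    its translation-canonical form is compared with the initial one. The
    first match at generation ``t`` with net offset ``d`` gives:
    still life (t = 1, d = 0), oscillator (t >= 2, d = 0) or spaceship
    (d != 0, period t, minimal by first-hit). If the universe empties the
    pattern dies out; if the initial state never returns the result is
    unresolved (the pattern may still settle into some *other* cycle —
    that question belongs to :func:`classify_fate`).
    """
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    if not pattern.cells:
        return Classification("dies_out", transient=0, generations_examined=0)
    initial = pattern.cells  # already normalized
    u = pattern.to_universe()
    origin = (0, 0)
    for t in range(1, max_generations + 1):
        u, _ = step(u, rule)
        if not u.live:
            return Classification("dies_out", transient=t, generations_examined=t)
        if _too_big(u, growth_limit):
            return Classification("unresolved", generations_examined=t, growth=True)
        cells, offset = normalize(u.live)
        if cells == initial:
            d = (offset[0] - origin[0], offset[1] - origin[1])
            return Classification(
                _kind_of_cycle(t, d), period=t, displacement=d,
                transient=0, generations_examined=t,
            )
    return Classification("unresolved", generations_examined=max_generations)


def classify_fate(
    pattern: Pattern,
    rule: Rule = LIFE,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
    growth_limit: int = DEFAULT_GROWTH_LIMIT,
) -> Classification:
    """Classify the cycle a pattern eventually falls into.

    A hash map from translation-canonical state to (generation, offset)
    detects the first repeat of *any* state in one pass; the repeat fixes
    the cycle's period and per-period displacement, and the generation of
    the cycle's first occurrence is the transient. Patterns that splinter
    into several diverging objects (escaping gliders, say) never repeat a
    global canonical state and come back unresolved.
    """
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    if not pattern.cells:
        return Classification("dies_out", transient=0, generations_examined=0)
    u = pattern.to_universe()
    seen: Dict[frozenset, Tuple[int, Coord]] = {pattern.cells: (0, (0, 0))}
    for t in range(1, max_generations + 1):
        u, _ = step(u, rule)
        if not u.live:
            return Classification("dies_out", transient=t, generations_examined=t)
        if _too_big(u, growth_limit):
            return Classification("unresolved", generations_examined=t, growth=True)
        cells, offset = normalize(u.live)
        if cells in seen:
            t0, off0 = seen[cells]
            period = t - t0
            d = (offset[0] - off0[0], offset[1] - off0[1])
            return Classification(
                _kind_of_cycle(period, d), period=period, displacement=d,
                transient=t0, generations_examined=t,
            )
        seen[cells] = (t, offset)
    return Classification("unresolved", generations_examined=max_generations)


def extract_objects(
    universe: Universe, link_radius: int = 1
) -> List[Tuple[Pattern, Coord]]:
    """Partition the live set into connected objects.

    Two cells belong to the same object when their Chebyshev distance is
    at most ``link_radius`` (radius 1 is ordinary 8-connectivity; larger
    radii merge closely adjacent pseudo-objects that interact). Each
    component is returned as a normalized :class:`Pattern` together with
    the offset that places it back in the universe. Components are
    ordered by their top-left corner for determinism.
    """
    if link_radius < 1:
        raise ValueError("link_radius must be >= 1")
    remaining = set(universe.live)
    torus = universe.torus
    offsets = [
        (dx, dy)
        for dx in range(-link_radius, link_radius + 1)
        for dy in range(-link_radius, link_radius + 1)
        if (dx, dy) != (0, 0)
    ]
    components: List[frozenset] = []
    while remaining:
        seed = min(remaining)
        stack = [seed]
        remaining.discard(seed)
        comp = {seed}
        while stack:
            x, y = stack.pop()
            for dx, dy in offsets:
                nb = (x + dx, y + dy)
                if torus is not None:
                    nb = (nb[0] % torus[0], nb[1] % torus[1])
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        components.append(frozenset(comp))
    out = []
    for comp in components:
        cells, offset = normalize(comp)
        out.append((Pattern(cells), offset))
    out.sort(key=lambda po: (po[1][1], po[1][0]))
    return out


@dataclass
class Census:
    """Per-object tally of the taxonomy over one universe.

    Counts are keyed by (kind, period, displacement); convenience views
    aggregate by kind alone or by (kind, period).
    """

    counts: Counter = field(default_factory=Counter)

    def add(self, c: Classification) -> None:
        self.counts[(c.kind, c.period, c.displacement)] += 1

    @property
    def by_kind(self) -> Dict[str, int]:
        agg: Counter = Counter()
        for (kind, _, _), n in self.counts.items():
            agg[kind] += n
        return dict(agg)

    @property
    def by_kind_period(self) -> Dict[Tuple[str, Optional[int]], int]:
        agg: Counter = Counter()
        for (kind, period, _), n in self.counts.items():
            agg[(kind, period)] += n
        return dict(agg)

    @property
    def n_objects(self) -> int:
        return sum(self.counts.values())

    def to_records(self) -> List[dict]:
        recs = [
            {
                "kind": kind,
                "period": period,
                "displacement": list(disp) if disp else None,
                "count": n,
            }
            for (kind, period, disp), n in self.counts.items()
        ]
        recs.sort(key=lambda r: (r["kind"], r["period"] or 0, str(r["displacement"])))
        return recs

    def to_json(self) -> str:
        return json.dumps(self.to_records(), indent=2)


def census(
    universe: Universe,
    rule: Rule = LIFE,
    link_radius: int = 1,
    max_generations: int = DEFAULT_MAX_GENERATIONS,
) -> Census:
    """Extract objects and classify each in isolation on its own plane."""
    result = Census()
    for pat, _ in extract_objects(universe, link_radius):
        result.add(classify_exact(pat, rule, max_generations))
    return result
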