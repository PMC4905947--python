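"""Sparse, topology-aware Game of Life update engine.

The universe is a set of live integer coordinates rather than a dense
array, so patterns can roam an unbounded plane: only live cells and their
Moore neighbors are ever examined, which is exactly equivalent to a dense
scan for any rule without birth-on-zero. A bounded torus topology is
available for ecosystem-scale experiments where global recurrence must be
well defined.

Updates are synchronous: every birth and death in a generation is decided
from the previous generation's state alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple

Coord = Tuple[int, int]

#: Moore 8-neighborhood offsets (Chebyshev distance 1).
MOORE_OFFSETS: Tuple[Coord, ...] = tuple(
    (dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)
)

#: Sentinel hash reported for an empty universe (no cells to normalize).
EMPTY_HASH = 0x9E3779B97F4A7C15


@dataclass(frozen=True)
class Rule:
    """A totalistic birth/survival rule.

    A dead cell becomes live when its live-neighbor count is in
    ``birth_counts``; a live cell persists when its count is in
    ``survival_counts``. Conway's standard rule is B3/S23: birth on
    exactly three neighbors, survival on two or three. Isolation death
    (one neighbor or none) and overpopulation death (four or more) are
    the complement of the survival set.
    """

    birth_counts: frozenset = frozenset({3})
    survival_counts: frozenset = frozenset({2, 3})
    name: str = "B3/S23"

    def __post_init__(self) -> None:
        object.__setattr__(self, "birth_counts", frozenset(self.birth_counts))
        object.__setattr__(self, "survival_counts", frozenset(self.survival_counts))
        valid = set(range(9))
        if not set(self.birth_counts) <= valid or not set(self.survival_counts) <= valid:
            raise ValueError("neighbor counts must be subsets of {0,...,8}")

    @classmethod
    def from_string(cls, text: str) -> "Rule":
        """Parse B/S notation such as ``"B3/S23"`` (case-insensitive)."""
        parts = text.strip().split("/")
        if len(parts) != 2:
            raise ValueError(f"not B/S rule notation: {text!r}")
        b, s = parts[0].strip(), parts[1].strip()
        if not b.upper().startswith("B") or not s.upper().startswith("S"):
            raise ValueError(f"not B/S rule notation: {text!r}")
        try:
            births = frozenset(int(c) for c in b[1:])
            survivals = frozenset(int(c) for c in s[1:])
        except ValueError as exc:
            raise ValueError(f"not B/S rule notation: {text!r}") from exc
        return cls(births, survivals, text.strip().upper())

    def __str__(self) -> str:
        b = "".join(str(n) for n in sorted(self.birth_counts))
        s = "".join(str(n) for n in sorted(self.survival_counts))
        return f"B{b}/S{s}"


#: Conway's standard rule.
LIFE = Rule()


@dataclass(frozen=True)
class Universe:
    """A generation of the automaton: live cells, topology, clock.

    ``torus=None`` selects the unbounded plane; ``torus=(width, height)``
    wraps neighbor lookups (and only neighbor lookups) modulo the grid.
    Coordinates are 0-based, x rightward, y downward.
    """

    live: frozenset = frozenset()
    torus: Optional[Tuple[int, int]] = None
    generation: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "live", frozenset(self.live))
        if self.torus is not None:
            w, h = self.torus
            if w < 1 or h < 1:
                raise ValueError(f"torus dimensions must be positive, got {self.torus}")
            for (x, y) in self.live:
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError(f"cell {(x, y)} outside torus {self.torus}")
        if self.generation < 0:
            raise ValueError("generation must be nonnegative")

    @property
    def population(self) -> int:
        return len(self.live)

    def bounding_box(self) -> Optional[Tuple[int, int, int, int]]:
        """(min_x, min_y, max_x, max_y) of the live set, or None if empty."""
        if not self.live:
            return None
        xs = [x for x, _ in self.live]
        ys = [y for _, y in self.live]
        return min(xs), min(ys), max(xs), max(ys)


@dataclass(frozen=True)
class StepDelta:
    """The cells born and the cells that died in one synchronous update.

    This is the information content of the two-color bookkeeping in the
    board-game presentation: marks placed on birth sites and doubled
    marks on dying counters before the board is updated all at once.
    """

    births: frozenset = frozenset()
    deaths: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "births", frozenset(self.births))
        object.__setattr__(self, "deaths", frozenset(self.deaths))


def _wrap(cell: Coord, torus: Tuple[int, int]) -> Coord:
    w, h = torus
    return (cell[0] % w, cell[1] % h)


def neighbor_count(universe: Universe, cell: Coord) -> int:
    """Number of live cells among the 8 Moore neighbors of ``cell``.

    Under torus topology neighbor coordinates wrap; the queried cell
    itself must lie inside the torus.
    """
    x, y = cell
    if universe.torus is not None:
        w, h = universe.torus
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"cell {cell} outside torus bounds {universe.torus}")
        return sum(
            1 for dx, dy in MOORE_OFFSETS if ((x + dx) % w, (y + dy) % h) in universe.live
        )
    return sum(1 for dx, dy in MOORE_OFFSETS if (x + dx, y + dy) in universe.live)


def step(universe: Universe, rule: Rule = LIFE) -> Tuple[Universe, StepDelta]:
    """One synchronous update of the whole universe.

    Candidate-set method: only live cells and their neighbors can change
    state, so only those are examined. Rules with 0 in the birth set
    would light up the entire infinite background and are rejected.
    """
    if 0 in rule.birth_counts:
        raise NotImplementedError("birth-on-zero rules have no sparse representation")
    counts: Counter = Counter()
    torus = universe.torus
    if torus is not None:
        w, h = torus
        for (x, y) in universe.live:
            for dx, dy in MOORE_OFFSETS:
                counts[((x + dx) % w, (y + dy) % h)] += 1
    else:
        for (x, y) in universe.live:
            for dx, dy in MOORE_OFFSETS:
                counts[(x + dx, y + dy)] += 1
    live = universe.live
    survivors = {c for c in live if counts.get(c, 0) in rule.survival_counts}
    births = frozenset(
        c for c, n in counts.items() if n in rule.birth_counts and c not in live
    )
    deaths = frozenset(live - survivors)
    new_live = frozenset(survivors) | births
    nxt = Universe(new_live, torus, universe.generation + 1)
    return nxt, StepDelta(births, deaths)


def run(universe: Universe, rule: Rule = LIFE, n_generations: int = 0) -> list:
    """Trajectory of ``n_generations + 1`` states, starting with the input."""
    if n_generations < 0:
        raise ValueError("n_generations must be nonnegative")
    traj = [universe]
    current = universe
    for _ in range(n_generations):
        current, _ = step(current, rule)
        traj.append(current)
    return traj


def normalize(cells: Iterable[Coord]) -> Tuple[frozenset, Coord]:
    """Translate a cell set so its bounding box sits at the origin.

    Returns ``(normalized_cells, offset)`` with
    ``cells = {c + offset for c in normalized_cells}``. The empty set
    normalizes to itself with offset (0, 0).
    """
    cells = frozenset(cells)
    if not cells:
        return cells, (0, 0)
    ox = min(x for x, _ in cells)
    oy = min(y for _, y in cells)
    return frozenset((x - ox, y - oy) for x, y in cells), (ox, oy)


def translate(cells: Iterable[Coord], offset: Coord) -> frozenset:
    """Shift every cell by ``offset``."""
    ox, oy = offset
    return frozenset((x + ox, y + oy) for x, y in cells)


def canonical_hash(universe: Universe, translation_invariant: bool = False) -> int:
    """Hash of the live set, optionally up to translation.

    With ``translation_invariant`` the live set is normalized to its
    bounding-box origin first, so two copies of the same shape anywhere
    on the plane hash alike. The empty universe gets a fixed sentinel.
    """
    if not universe.live:
        return EMPTY_HASH
    cells = normalize(universe.live)[0] if translation_invariant else universe.live
    return hash(cells)
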