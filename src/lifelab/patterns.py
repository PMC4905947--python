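"""Life pattern formats (RLE, plaintext) and the canonical fixture library.

The RLE dialect is the de-facto Golly/LifeWiki convention: optional ``#``
comment lines, an optional ``x = ..., y = ...[, rule = ...]`` header, then
a body of ``<count><tag>`` runs with tags ``b`` (dead), ``o`` (alive),
``$`` (end of row), terminated by ``!``. Plaintext (".cells") uses ``.``
for dead, ``O`` for alive and ``!`` comment lines; blank lines are rows of
dead cells, not separators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Tuple

from lifelab.engine import Rule, Universe, normalize

Coord = Tuple[int, int]


class PatternFormatError(ValueError):
    """Raised for malformed pattern text; carries line/column context."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f" at line {line}" + (f", column {column}" if column is not None else "")
        super().__init__(message + loc)
        self.line = line
        self.column = column


@dataclass(frozen=True)
class Pattern:
    """A named shape, normalized so its bounding box starts at (0, 0)."""

    cells: frozenset
    name: str = ""
    rule_hint: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", normalize(self.cells)[0])

    @property
    def population(self) -> int:
        return len(self.cells)

    @property
    def extent(self) -> Tuple[int, int]:
        """(width, height) of the bounding box; (0, 0) when empty."""
        if not self.cells:
            return (0, 0)
        return (
            max(x for x, _ in self.cells) + 1,
            max(y for _, y in self.cells) + 1,
        )

    def to_universe(
        self, offset: Coord = (0, 0), torus: Optional[Tuple[int, int]] = None
    ) -> Universe:
        """Place the pattern in a fresh universe at generation 0."""
        ox, oy = offset
        return Universe(frozenset((x + ox, y + oy) for x, y in self.cells), torus=torus)


_HEADER_RE = re.compile(
    r"^\s*x\s*=\s*(\d+)\s*,\s*y\s*=\s*(\d+)\s*(?:,\s*rule\s*=\s*(\S+)\s*)?$",
    re.IGNORECASE,
)


def parse_rle(text: str) -> Pattern:
    """Decode an RLE pattern string.

    Raises :class:`PatternFormatError` (with line/column) for malformed
    run counts, a body exceeding the declared extents, or a missing
    ``!`` terminator. A ``#N`` comment, when present, names the pattern.
    """
    name = ""
    rule_hint: Optional[str] = None
    declared: Optional[Tuple[int, int]] = None
    body_lines: list[Tuple[int, str]] = []  # (1-based line number, text)
    in_body = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not in_body:
            if not line:
                continue
            if line.startswith("#"):
                if line[1:2] == "N":
                    name = line[2:].strip()
                continue
            m = _HEADER_RE.match(line)
            if m:
                declared = (int(m.group(1)), int(m.group(2)))
                if m.group(3):
                    rule_hint = m.group(3)
                in_body = True
                continue
            # No header: this line starts the body.
            in_body = True
        body_lines.append((lineno, line))

    cells: set[Coord] = set()
    x = y = 0
    count_str = ""
    terminated = False
    for lineno, line in body_lines:
        if terminated:
            break
        for col, ch in enumerate(line, start=1):
            if ch.isdigit():
                count_str += ch
                continue
            n = int(count_str) if count_str else 1
            if count_str and n == 0:
                raise PatternFormatError("run count of zero", lineno, col)
            count_str = ""
            if ch in ("b", "B", "."):
                x += n
            elif ch in ("o", "O", "*"):
                for i in range(n):
                    cells.add((x + i, y))
                x += n
            elif ch == "$":
                y += n
                x = 0
            elif ch == "!":
                terminated = True
                break
            elif ch.isspace():
                continue
            else:
                raise PatternFormatError(f"unexpected character {ch!r}", lineno, col)
        if count_str and not terminated:
            raise PatternFormatError("run count split across lines", lineno, len(line))
    if not terminated:
        raise PatternFormatError("missing '!' terminator", len(text.splitlines()) or 1)
    if declared is not None and cells:
        w = max(cx for cx, _ in cells) + 1
        h = max(cy for _, cy in cells) + 1
        if w > declared[0] or h > declared[1]:
            raise PatternFormatError(
                f"body extent {w}x{h} exceeds declared x = {declared[0]}, y = {declared[1]}"
            )
    return Pattern(frozenset(cells), name=name, rule_hint=rule_hint)


def write_rle(pattern: Pattern, rule: Rule | str | None = None) -> str:
    """Encode a pattern as RLE with an ``x = ..., y = ..., rule = ...`` header.

    Round-trip contract: ``parse_rle(write_rle(p)).cells == p.cells``.
    """
    if rule is None:
        rule_str = pattern.rule_hint or "B3/S23"
    else:
        rule_str = str(rule)
    w, h = pattern.extent
    lines = []
    if pattern.name:
        lines.append(f"#N {pattern.name}")
    lines.append(f"x = {w}, y = {h}, rule = {rule_str}")
    if not pattern.cells:
        lines.append("!")
        return "\n".join(lines) + "\n"

    def runs():
        rows: dict[int, list[int]] = {}
        for cx, cy in pattern.cells:
            rows.setdefault(cy, []).append(cx)
        prev_row = 0
        for cy in sorted(rows):
            if cy > prev_row:
                yield (cy - prev_row, "$")
            prev_row = cy
            xs = sorted(rows[cy])
            cursor = 0
            i = 0
            while i < len(xs):
                j = i
                while j + 1 < len(xs) and xs[j + 1] == xs[j] + 1:
                    j += 1
                if xs[i] > cursor:
                    yield (xs[i] - cursor, "b")
                yield (j - i + 1, "o")
                cursor = xs[j] + 1
                i = j + 1
        yield (1, "!")

    body = "".join(("" if n == 1 else str(n)) + tag for n, tag in runs())
    # Wrap long bodies at ~70 characters, never splitting a run.
    chunks = re.findall(r"\d*[bo$!]", body)
    line = ""
    for chunk in chunks:
        if len(line) + len(chunk) > 70:
            lines.append(line)
            line = ""
        line += chunk
    if line:
        lines.append(line)
    return "\n".join(lines) + "\n"


def parse_plaintext(text: str) -> Pattern:
    """Decode dots-and-Os plaintext (".cells" style)."""
    name = ""
    cells: set[Coord] = set()
    y = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if line.startswith("!"):
            if line[1:].strip().lower().startswith("name:"):
                name = line.split(":", 1)[1].strip()
            continue
        for col, ch in enumerate(line):
            if ch in ("O", "o", "*"):
                cells.add((col, y))
            elif ch in (".", " "):
                continue
            else:
                raise PatternFormatError(f"illegal character {ch!r}", lineno, col + 1)
        y += 1
    return Pattern(frozenset(cells), name=name)


def write_plaintext(pattern: Pattern) -> str:
    """Encode a pattern as dots-and-Os plaintext."""
    lines = []
    if pattern.name:
        lines.append(f"!Name: {pattern.name}")
    w, h = pattern.extent
    for y in range(h):
        lines.append("".join("O" if (x, y) in pattern.cells else "." for x in range(w)))
    return "\n".join(lines) + ("\n" if lines else "")


# Canonical fixtures, given as plaintext bitmaps. The four movers are the
# standard glider and the light-, middle- and heavyweight spaceships.
_FIXTURE_TEXT = {
    "block": "OO\nOO",
    "blinker": "OOO",
    "l_tromino": "O.\nOO",
    "glider": ".O.\n..O\nOOO",
    "lwss": ".O..O\nO....\nO...O\nOOOO.",
    "mwss": "...O..\n.O...O\nO.....\nO....O\nOOOOO.",
    "hwss": "...OO..\n.O....O\nO......\nO.....O\nOOOOOO.",
    "r_pentomino": ".OO\nOO.\n.O.",
}

FIXTURE_NAMES = tuple(sorted(_FIXTURE_TEXT))


def fixture(name: str) -> Pattern:
    """Look up a canonical pattern by name.

    Available: block, blinker, l_tromino, glider, lwss, mwss, hwss,
    r_pentomino.
    """
    key = name.strip().lower()
    if key not in _FIXTURE_TEXT:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    pat = parse_plaintext(_FIXTURE_TEXT[key])
    return Pattern(pat.cells, name=key, rule_hint="B3/S23")
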