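"""Physical keyboard layouts and the inter-key distance used by the motor-error rule.

A layout is a flat grid: each primary key has an integer row and a (possibly
fractional, for the space bar) column, with unit spacing and no horizontal
stagger.  Capitals, accented characters and shifted symbols are "secondary
characters" that inherit the coordinates of the key that produces them, so
``A`` sits where ``a`` sits and ``ç`` where ``c`` sits.

Distance between two keys is 1 for any grid-adjacent pair (Chebyshev distance
one, diagonals included) and the plain Euclidean grid distance otherwise.
Characters that are on neither map (Greek letters, emoji, ...) are placed at
the mean position of all keys, so every distance query is answerable.
"""

from __future__ import annotations

import csv
import logging
import math
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

logger = logging.getLogger(__name__)

_LAYOUT_FILES = {
    "en": ("layout_en.tsv", "secondary_en.tsv"),
    "es": ("layout_es.tsv", "secondary_es.tsv"),
}


class LayoutError(ValueError):
    """Raised for malformed or empty layout definitions."""


@dataclass
class KeyboardLayout:
    """Grid coordinates per primary key plus a secondary->primary map."""

    language: str
    positions: dict[str, tuple[float, float]]
    secondary_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.positions:
            raise LayoutError("layout has no keys")
        seen: dict[tuple[float, float], str] = {}
        for key, pos in self.positions.items():
            if pos in seen:
                raise LayoutError(f"keys {seen[pos]!r} and {key!r} share position {pos}")
            seen[pos] = key
        for sec, prim in self.secondary_map.items():
            if prim not in self.positions:
                raise LayoutError(f"secondary {sec!r} maps to unknown key {prim!r}")
        self._mean: tuple[float, float] | None = None
        self._unknown_seen: set[str] = set()

    # -- resolution ---------------------------------------------------------

    def normalize(self, ch: str) -> str:
        """Map a character to its primary key character.

        Falls back through the secondary map, lowercasing, and diacritic
        stripping; characters that still resolve to nothing are returned
        unchanged (and remembered as unknown).
        """
        if ch in self.positions:
            return ch
        if ch in self.secondary_map:
            return self.secondary_map[ch]
        low = ch.lower()
        if low != ch:
            return self.normalize(low)
        base = _strip_diacritics(ch)
        if base != ch and (base in self.positions or base in self.secondary_map):
            return self.normalize(base)
        if ch not in self._unknown_seen:
            self._unknown_seen.add(ch)
            logger.debug("character %r not on %s layout", ch, self.language)
        return ch

    def is_known(self, ch: str) -> bool:
        return self.normalize(ch) in self.positions

    def position(self, ch: str) -> tuple[float, float] | None:
        return self.positions.get(self.normalize(ch))

    def mean_position(self) -> tuple[float, float]:
        """Arithmetic mean of all primary-key coordinates."""
        if self._mean is None:
            rows = [p[0] for p in self.positions.values()]
            cols = [p[1] for p in self.positions.values()]
            self._mean = (sum(rows) / len(rows), sum(cols) / len(cols))
        return self._mean

    # -- metric -------------------------------------------------------------

    def distance(self, from_char: str, to_char: str) -> float:
        """Keyboard distance from one character's key to another's.

        Same key -> 0; grid-adjacent (diagonals included) -> exactly 1;
        otherwise Euclidean.  Either endpoint may be unknown, in which case
        it is placed at the keyboard's mean position and the plain Euclidean
        distance is returned (two unknowns therefore give 0).
        """
        p_from = self.position(from_char)
        p_to = self.position(to_char)
        if p_from is None or p_to is None:
            a = p_from if p_from is not None else self.mean_position()
            b = p_to if p_to is not None else self.mean_position()
            return math.dist(a, b)
        if p_from == p_to:
            return 0.0
        dr = abs(p_from[0] - p_to[0])
        dc = abs(p_from[1] - p_to[1])
        if dr <= 1.0 and dc <= 1.0:
            return 1.0
        return math.dist(p_from, p_to)

    def neighbours(self, ch: str) -> list[str]:
        """Primary keys at distance exactly 1 from ``ch`` (sorted, deterministic)."""
        p = self.position(ch)
        if p is None:
            return []
        prim = self.normalize(ch)
        out = [
            k
            for k, q in self.positions.items()
            if k != prim and abs(q[0] - p[0]) <= 1.0 and abs(q[1] - p[1]) <= 1.0
        ]
        return sorted(out)

    def coverage_report(self, text: Iterable[str]) -> set[str]:
        """Characters of ``text`` that do not resolve to any key (logged)."""
        missing = {ch for ch in text if not self.is_known(ch)}
        for ch in sorted(missing):
            logger.warning("stimulus character %r unresolved on %s layout", ch, self.language)
        return missing

    # -- construction -------------------------------------------------------

    @classmethod
    def from_files(cls, language: str, layout_path, secondary_path=None) -> "KeyboardLayout":
        positions = _read_layout_table(layout_path)
        secondary = _read_secondary_table(secondary_path) if secondary_path else {}
        return cls(language, positions, secondary)


def _strip_diacritics(ch: str) -> str:
    decomp = unicodedata.normalize("NFD", ch)
    stripped = "".join(c for c in decomp if not unicodedata.combining(c))
    return stripped or ch


def _read_layout_table(path) -> dict[str, tuple[float, float]]:
    positions: dict[str, tuple[float, float]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        if reader.fieldnames is None or not {"key", "row", "col"} <= set(reader.fieldnames):
            raise LayoutError(f"{path}: expected columns key, row, col")
        for rec in reader:
            positions[rec["key"]] = (float(rec["row"]), float(rec["col"]))
    return positions


def _read_secondary_table(path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        if reader.fieldnames is None or not {"secondary", "primary"} <= set(reader.fieldnames):
            raise LayoutError(f"{path}: expected columns secondary, primary")
        for rec in reader:
            mapping[rec["secondary"]] = rec["primary"]
    return mapping


def load_layout(language: str) -> KeyboardLayout:
    """Load a packaged layout ("en" UK-QWERTY or "es" Spanish-ISO QWERTY)."""
    try:
        layout_file, secondary_file = _LAYOUT_FILES[language]
    except KeyError:
        raise LayoutError(f"no packaged layout for language {language!r}") from None
    data = resources.files("typeslip.data")
    with resources.as_file(data / layout_file) as lp, resources.as_file(data / secondary_file) as sp:
        return KeyboardLayout.from_files(language, lp, sp)
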