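"""Motor / habit / other classification of extracted typing errors.

Two sequential rules, both strict inequalities so that ties fall through:

* **motor** — the erroneous key is closer (on the keyboard grid) to the
  previously pressed key than the intended key is:
  ``d(prev, typed) < d(prev, target)``.
* **habit** — not a motor error, and the typed character is more probable
  than the intended one under the character language model given the four
  preceding characters of the intended sentence:
  ``p(typed | context) > p(target | context)``.

Everything else is **other**.  Errors with no typed character (a deletion
was the first mismatch) or no target character (an insertion was) cannot be
scored by either rule and are labelled other; errors with no preceding
keypress skip the motor rule and go straight to the habit comparison.  All
four intermediate quantities are retained so every decision is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .alignment import ErrorRecord
from .keyboard import KeyboardLayout

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Missing layout/LM for the data at hand."""


@dataclass
class LabeledError:
    record: ErrorRecord
    label: str  # motor | habit | other
    d_prev_typed: Optional[float] = None
    d_prev_target: Optional[float] = None
    p_typed: Optional[float] = None
    p_target: Optional[float] = None


@dataclass
class ParticipantErrorRates:
    participant_id: str
    n_errors: int
    n_motor: int
    n_habit: int
    motor_rate: float
    habit_rate: Optional[float]  # None when every error was motor


def classify(record: ErrorRecord, layout: KeyboardLayout, lm,
             context_source: str = "target") -> LabeledError:
    """Label one error record; see module docstring for the two rules."""
    if layout is None or lm is None:
        raise ConfigurationError("both a keyboard layout and a language model are required")
    if context_source not in ("target", "typed"):
        raise ConfigurationError(f"unknown context source {context_source!r}")
    typed, target, prev = record.typed_char, record.target_char, record.prev_char
    if typed is None or target is None:
        return LabeledError(record, "other")
    d_pt = d_pg = None
    if prev is not None:
        d_pt = layout.distance(prev, typed)
        d_pg = layout.distance(prev, target)
        if d_pt < d_pg:
            return LabeledError(record, "motor", d_pt, d_pg)
    context = record.target_context if context_source == "target" else record.typed_context
    p_t = lm.cond_prob(typed, context)
    p_g = lm.cond_prob(target, context)
    label = "habit" if p_t > p_g else "other"
    return LabeledError(record, label, d_pt, d_pg, p_t, p_g)


def classify_all(records: Sequence[ErrorRecord], layout: KeyboardLayout, lm,
                 context_source: str = "target") -> list[LabeledError]:
    return [classify(r, layout, lm, context_source) for r in records]


def rates(labeled: Sequence[LabeledError]) -> list[ParticipantErrorRates]:
    """Per-participant motor and habit rates.

    motor_rate = motor errors / all errors; habit_rate = habit errors /
    non-motor errors (absent when every error was motor).  Participants
    contributing no errors simply produce no row.
    """
    by_pid: dict[str, list[LabeledError]] = {}
    for le in labeled:
        by_pid.setdefault(le.record.participant_id, []).append(le)
    out = []
    for pid in sorted(by_pid):
        errs = by_pid[pid]
        n = len(errs)
        n_motor = sum(le.label == "motor" for le in errs)
        n_habit = sum(le.label == "habit" for le in errs)
        habit_rate = n_habit / (n - n_motor) if n > n_motor else None
        out.append(ParticipantErrorRates(pid, n, n_motor, n_habit, n_motor / n, habit_rate))
    return out
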