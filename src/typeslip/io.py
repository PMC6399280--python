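"""Keypress logs, stimulus lists and participant tables.

The on-disk log is one keypress per row (TSV or CSV by extension, header
required) with columns ``participant_id, sentence_id, key, t_ms``.  Named
keys are capitalized (``SPACE``, ``BACKSPACE``, ``SHIFT``); SHIFT carries no
character and is dropped on read.  Timestamps are milliseconds since session
start and must be non-decreasing within a sentence.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

NAMED_KEYS = {"SPACE": " "}
DROPPED_KEYS = {"SHIFT"}


class FormatError(ValueError):
    """Malformed input file (missing columns, unparseable rows)."""


class ValidationError(ValueError):
    """Well-formed file with invalid content (e.g. time going backwards)."""


@dataclass
class KeypressEvent:
    key: str  # single character, or a named key such as "BACKSPACE"
    t_ms: float
    iki_ms: Optional[float] = None

    @property
    def char(self) -> Optional[str]:
        """The character this keypress produces (None for named non-printing keys)."""
        if len(self.key) == 1:
            return self.key
        return NAMED_KEYS.get(self.key)


@dataclass
class TypingSession:
    participant_id: str
    language: str
    stimuli: list[str]
    events: dict[int, list[KeypressEvent]] = field(default_factory=dict)

    def typed_text(self, sentence_id: int) -> str:
        return "".join(e.char for e in self.events.get(sentence_id, []) if e.char is not None)


@dataclass
class ParticipantRecord:
    participant_id: str
    group: str  # "patient" | "control"
    updrs: int
    language: str

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValidationError(f"unknown group {self.group!r}")
        if self.updrs < 0 or int(self.updrs) != self.updrs:
            raise ValidationError("updrs must be a non-negative integer")
        self.updrs = int(self.updrs)


# -- stimuli ----------------------------------------------------------------

def read_stimuli(path) -> list[str]:
    """Plain text, one sentence per line, indexed from 0; blank lines dropped."""
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_stimuli(sentences: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(s + "\n")


# -- keypress logs ----------------------------------------------------------

def _delimiter(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_sessions(path, stimuli: list[str] | dict[str, list[str]],
                  languages: Optional[dict[str, str]] = None) -> list[TypingSession]:
    """Read a keypress log into per-participant sessions.

    ``stimuli`` is either a single sentence list shared by all participants
    or a mapping ``participant_id -> sentence list``; ``languages`` maps
    participants to "en"/"es" (default "en").  Events are grouped per
    participant and sentence, SHIFT events dropped, and timestamps validated
    to be non-decreasing within each sentence.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    sessions: dict[str, TypingSession] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(path), quoting=csv.QUOTE_NONE)
        required = {"participant_id", "sentence_id", "key", "t_ms"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: header must contain {sorted(required)}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                pid = rec["participant_id"]
                sid = int(rec["sentence_id"])
                key = rec["key"]
                t = float(rec["t_ms"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from None
            if sid < 0:
                raise ValidationError(f"{path}:{lineno}: negative sentence_id")
            if key in DROPPED_KEYS:
                continue
            sess = sessions.get(pid)
            if sess is None:
                stim = stimuli[pid] if isinstance(stimuli, dict) else stimuli
                lang = (languages or {}).get(pid, "en")
                sess = sessions[pid] = TypingSession(pid, lang, list(stim))
            sess.events.setdefault(sid, []).append(KeypressEvent(key, t))
    for sess in sessions.values():
        for sid, events in sess.events.items():
            if sid >= len(sess.stimuli):
                raise ValidationError(
                    f"participant {sess.participant_id}: sentence_id {sid} "
                    f"outside stimulus list of length {len(sess.stimuli)}")
            for prev, cur in zip(events, events[1:]):
                if cur.t_ms < prev.t_ms:
                    raise ValidationError(
                        f"participant {sess.participant_id}, sentence {sid}: "
                        f"timestamp decreases at t={cur.t_ms}")
    return sorted(sessions.values(), key=lambda s: s.participant_id)


def write_sessions(sessions: Iterable[TypingSession], path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path), lineterminator="\n", quoting=csv.QUOTE_NONE, quotechar=None)
        writer.writerow(["participant_id", "sentence_id", "key", "t_ms"])
        for sess in sessions:
            for sid in sorted(sess.events):
                for ev in sess.events[sid]:
                    t = int(ev.t_ms) if float(ev.t_ms).is_integer() else ev.t_ms
                    writer.writerow([sess.participant_id, sid, ev.key, t])


# -- participant tables ------------------------------------------------------

def read_participants(path) -> list[ParticipantRecord]:
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(path), quoting=csv.QUOTE_NONE)
        required = {"participant_id", "group", "updrs", "language"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: header must contain {sorted(required)}")
        out = []
        for lineno, rec in enumerate(reader, start=2):
            try:
                out.append(ParticipantRecord(rec["participant_id"], rec["group"],
                                             int(rec["updrs"]), rec["language"]))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_participants(records: Iterable[ParticipantRecord], path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path), lineterminator="\n", quoting=csv.QUOTE_NONE, quotechar=None)
        writer.writerow(["participant_id", "group", "updrs", "language"])
        for r in records:
            writer.writerow([r.participant_id, r.group, r.updrs, r.language])


# -- preprocessing -----------------------------------------------------------

def preprocess_corrections(session: TypingSession, mode: str = "resolve") -> TypingSession:
    """Handle backspace events.

    ``resolve`` (default) applies each backspace, deleting the previously
    typed character, so the surviving events spell the final on-screen text;
    ``literal`` merely drops the backspace events and keeps every typed
    character.  A backspace with nothing before it is a logged no-op.
    """
    if mode not in ("literal", "resolve"):
        raise ValueError(f"unknown correction mode {mode!r}")
    out = TypingSession(session.participant_id, session.language, list(session.stimuli))
    for sid, events in session.events.items():
        kept: list[KeypressEvent] = []
        for ev in events:
            if ev.key == "BACKSPACE":
                if mode == "resolve":
                    if kept:
                        kept.pop()
                    else:
                        logger.warning(
                            "participant %s sentence %d: backspace at sentence start ignored",
                            session.participant_id, sid)
                continue
            kept.append(replace(ev))
        out.events[sid] = kept
    return out


def compute_ikis(session: TypingSession) -> TypingSession:
    """Populate interkey intervals: iki = t - t_prev within each sentence.

    The first event of each sentence has no interval.
    """
    out = TypingSession(session.participant_id, session.language, list(session.stimuli))
    for sid, events in session.events.items():
        new = []
        for i, ev in enumerate(events):
            iki = None if i == 0 else ev.t_ms - events[i - 1].t_ms
            new.append(replace(ev, iki_ms=iki))
        out.events[sid] = new
    return out
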