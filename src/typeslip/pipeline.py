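"""End-to-end orchestration: sessions -> aligned errors -> labelled tables.

This module chains the stages together for whole cohorts and produces the
two flat tables every downstream statistic consumes:

* a **keypress table** (one row per typed keypress that has an interkey
  interval) with a category: ``correct`` for keypresses in matching
  alignment columns, ``error`` for the single scored first-mismatch keypress
  of a mismatching token, and ``unscored`` for everything else (keypresses
  after the error within a mismatching token, and word-boundary columns that
  were mistyped — neither correct nor errorful);
* an **error table** (one row per extracted, classified error) carrying the
  label and the four intermediate quantities of the classification rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as kio
from .alignment import AlignmentParams, ErrorRecord, align, extract_error, pair_tokens
from .classifier import LabeledError, classify_all
from .keyboard import KeyboardLayout

CORRECT, ERROR, UNSCORED = "correct", "error", "unscored"


@dataclass
class SentenceAnalysis:
    sentence_id: int
    typed: str  # normalized typed text
    target: str  # normalized target text
    ikis: list[Optional[float]]
    categories: list[str]  # per typed character
    errors: list[ErrorRecord] = field(default_factory=list)


def analyze_session(
    session: kio.TypingSession,
    layout: KeyboardLayout,
    correction_mode: str = "resolve",
    params: AlignmentParams = AlignmentParams(),
) -> list[SentenceAnalysis]:
    """Align every sentence of a session and extract its errors."""
    session = kio.preprocess_corrections(session, mode=correction_mode)
    session = kio.compute_ikis(session)
    out: list[SentenceAnalysis] = []
    for sid in sorted(session.events):
        events = session.events[sid]
        typed_raw = "".join(e.char for e in events if e.char is not None)
        if len(typed_raw) != len(events):  # named keys with no character remain?
            events = [e for e in events if e.char is not None]
        typed = "".join(layout.normalize(c) for c in typed_raw)
        target = "".join(layout.normalize(c) for c in session.stimuli[sid])
        ikis = [e.iki_ms for e in events]
        if not typed:
            out.append(SentenceAnalysis(sid, typed, target, ikis, []))
            continue
        cols = align(typed, target, params)
        pairs = pair_tokens(cols)
        categories = [UNSCORED] * len(typed)
        # word-boundary columns belong to no token: correct only if matched
        in_token = set()
        for pair in pairs:
            for c in pair.columns:
                if c.typed_index is not None:
                    in_token.add(c.typed_index)
        for c in cols:
            if c.typed_index is not None and c.typed_index not in in_token:
                categories[c.typed_index] = CORRECT if c.op == "match" else UNSCORED
        errors: list[ErrorRecord] = []
        for pair in pairs:
            if not pair.is_error:
                for c in pair.columns:
                    if c.typed_index is not None:
                        categories[c.typed_index] = CORRECT
                continue
            rec = extract_error(pair, target, ikis, typed,
                                session.participant_id, sid)
            err_col = next(c for c in pair.columns if c.op != "match")
            past_error = False
            for c in pair.columns:
                if c is err_col:
                    past_error = True
                    if c.typed_index is not None:
                        categories[c.typed_index] = ERROR
                    continue
                if c.typed_index is None:
                    continue
                categories[c.typed_index] = UNSCORED if past_error else (
                    CORRECT if c.op == "match" else UNSCORED)
            if rec is not None:
                errors.append(rec)
        out.append(SentenceAnalysis(sid, typed, target, ikis, categories, errors))
    return out


def keypress_frame(
    analyses_by_session: dict[str, list[SentenceAnalysis]],
    participants: Sequence[kio.ParticipantRecord],
) -> pd.DataFrame:
    """One row per keypress that has an IKI, across a cohort."""
    meta = {p.participant_id: p for p in participants}
    rows_pid, rows_sid, rows_idx = [], [], []
    rows_iki, rows_cat = [], []
    for pid, analyses in analyses_by_session.items():
        for sa in analyses:
            for idx, (iki, cat) in enumerate(zip(sa.ikis, sa.categories)):
                if iki is None:
                    continue
                rows_pid.append(pid)
                rows_sid.append(sa.sentence_id)
                rows_idx.append(idx)
                rows_iki.append(iki)
                rows_cat.append(cat)
    df = pd.DataFrame({
        "participant_id": rows_pid,
        "sentence_id": np.asarray(rows_sid, dtype=np.int64),
        "typed_index": np.asarray(rows_idx, dtype=np.int64),
        "iki_ms": np.asarray(rows_iki, dtype=float),
        "category": pd.Categorical(rows_cat, categories=[CORRECT, ERROR, UNSCORED]),
    })
    df["group"] = df["participant_id"].map(lambda p: meta[p].group if p in meta else None)
    df["language"] = df["participant_id"].map(lambda p: meta[p].language if p in meta else None)
    return df


def error_frame(labeled: Sequence[LabeledError]) -> pd.DataFrame:
    """Auditable one-row-per-error table with the intermediate quantities."""
    rows = []
    for le in labeled:
        r = le.record
        rows.append({
            "participant_id": r.participant_id,
            "sentence_id": r.sentence_id,
            "typed_index": r.typed_index,
            "target_char": r.target_char,
            "typed_char": r.typed_char,
            "prev_char": r.prev_char,
            "iki_ms": r.iki_ms,
            "target_context": r.target_context,
            "typed_context": r.typed_context,
            "label": le.label,
            "d_prev_typed": le.d_prev_typed,
            "d_prev_target": le.d_prev_target,
            "p_typed": le.p_typed,
            "p_target": le.p_target,
        })
    cols = ["participant_id", "sentence_id", "typed_index", "target_char", "typed_char",
            "prev_char", "iki_ms", "target_context", "typed_context", "label",
            "d_prev_typed", "d_prev_target", "p_typed", "p_target"]
    return pd.DataFrame(rows, columns=cols)


def run_profile_cohort(spec, seed: int, resources=None, percentile: float = 99.5,
                       correction_mode: str = "resolve") -> pd.DataFrame:
    """Simulate a cohort and run the full pipeline; returns participant summaries.

    ``spec`` is a list of ``(TypistProfile, n)`` pairs.  The percentile IKI
    filter is computed within this cohort, per language.
    """
    from . import synth
    from .stats import filter_ikis, summarize

    res = resources if resources is not None else synth.default_resources()
    sessions, parts, _ = synth.simulate_cohort(spec, seed=seed, resources_=res)
    languages = sorted({p.language for p in parts})
    layouts = {lang: res.layout(lang) for lang in languages}
    lms = {lang: res.lm(lang) for lang in languages}
    kp, err = classify_cohort(sessions, layouts, lms, parts,
                              correction_mode=correction_mode)
    filtered = filter_ikis(kp, err, percentile=percentile)
    return summarize(filtered, parts)


def classify_cohort(
    sessions: Sequence[kio.TypingSession],
    layouts: dict[str, KeyboardLayout],
    lms: dict[str, object],
    participants: Sequence[kio.ParticipantRecord],
    correction_mode: str = "resolve",
    context_source: str = "target",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run alignment + classification for a cohort.

    Returns ``(keypress_table, error_table)``; layouts and language models
    are keyed by language code.
    """
    analyses: dict[str, list[SentenceAnalysis]] = {}
    labeled: list[LabeledError] = []
    for sess in sessions:
        layout = layouts[sess.language]
        lm = lms[sess.language]
        sa = analyze_session(sess, layout, correction_mode=correction_mode)
        analyses[sess.participant_id] = sa
        recs = [r for s in sa for r in s.errors]
        labeled.extend(classify_all(recs, layout, lm, context_source=context_source))
    return keypress_frame(analyses, participants), error_frame(labeled)
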