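"""Global alignment of typed text to its stimulus and extraction of typing errors.

Each typed sentence is aligned to its target with the Needleman-Wunsch
algorithm (match +1, substitution -1, insertion/deletion -2), producing two
equal-length sequences in which every column is a match, a substitution, an
insertion (typed character against a gap) or a deletion (gap against a target
character).  Typed characters are then paired with target words by walking the
alignment backwards and cutting a token boundary at every target-side space
that is aligned to a real typed character; a target space aligned to a gap
does not cut, so its flanking words merge into a single token.  A token pair
whose typed side differs from its target word contains exactly one scored
error: the first non-matching column in the token, together with the
previously typed character, that keypress's interkey interval, and the four
preceding characters of the target sentence.

The DP fill is compiled with numba when available (a pure-Python fill is used
otherwise); the traceback tie-break prefers diagonal over up (deletion) over
left (insertion), which makes the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

GAP = None  # gap marker inside AlignedColumn

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass(frozen=True)
class AlignmentParams:
    """Column scores; the defaults are the analysis's published values."""

    match: float = 1.0
    substitution: float = -1.0
    indel: float = -2.0

    def __post_init__(self) -> None:
        if not (self.match > self.substitution > self.indel):
            raise ValueError("require match > substitution > indel")


@dataclass(frozen=True)
class AlignedColumn:
    """One column of a global alignment.

    ``typed_index`` / ``target_index`` are positions in the original
    (ungapped) sequences, present on the non-gap side(s).
    """

    typed: Optional[str]
    target: Optional[str]
    op: str  # match | substitution | insertion | deletion
    typed_index: Optional[int] = None
    target_index: Optional[int] = None


@dataclass
class TokenPair:
    """A typed token paired with its target word (or merged word run)."""

    typed_token: str
    target_word: str
    columns: list[AlignedColumn] = field(repr=False, default_factory=list)

    @property
    def is_error(self) -> bool:
        return self.typed_token != self.target_word


@dataclass
class ErrorRecord:
    """One extracted typing error: the first mismatch of a mismatching token."""

    participant_id: str
    sentence_id: int
    target_char: Optional[str]
    typed_char: Optional[str]
    prev_char: Optional[str]
    iki_ms: Optional[float]
    target_context: str  # up to 4 preceding characters of the target sentence
    typed_context: str = ""  # up to 4 preceding typed characters
    typed_index: Optional[int] = None
    target_index: Optional[int] = None


@njit(cache=True)
def _nw_fill(a_codes, b_codes, match, sub, indel):  # pragma: no cover - numba
    n, m = len(a_codes), len(b_codes)
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    for j in range(m + 1):
        H[0, j] = indel * j
    for i in range(1, n + 1):
        H[i, 0] = indel * i
        for j in range(1, m + 1):
            s = match if a_codes[i - 1] == b_codes[j - 1] else sub
            best = H[i - 1, j - 1] + s
            up = H[i - 1, j] + indel
            if up > best:
                best = up
            left = H[i, j - 1] + indel
            if left > best:
                best = left
            H[i, j] = best
    return H


def _nw_fill_py(a_codes, b_codes, match, sub, indel):
    n, m = len(a_codes), len(b_codes)
    H = np.empty((n + 1, m + 1))
    H[0, :] = indel * np.arange(m + 1)
    for i in range(1, n + 1):
        H[i, 0] = indel * i
        row_prev = H[i - 1]
        row = H[i]
        for j in range(1, m + 1):
            s = match if a_codes[i - 1] == b_codes[j - 1] else sub
            row[j] = max(row_prev[j - 1] + s, row_prev[j] + indel, row[j - 1] + indel)
    return H


def align(
    typed: str,
    target: str,
    params: AlignmentParams = AlignmentParams(),
    normalize: Optional[Callable[[str], str]] = None,
) -> list[AlignedColumn]:
    """Globally align ``typed`` to ``target``; returns the column list.

    ``normalize`` (e.g. ``layout.normalize``) is applied to both sequences
    before comparison so that secondary characters match their primaries; the
    *normalized* characters populate the columns, since all downstream rules
    operate on primary keys.  Empty sequences are handled as pure gap runs.
    Tie-break: diagonal, then up (deletion), then left (insertion).
    """
    if normalize is not None:
        typed = "".join(normalize(c) for c in typed)
        target = "".join(normalize(c) for c in target)
    n, m = len(typed), len(target)
    if n == 0:
        return [AlignedColumn(GAP, target[j], "deletion", None, j) for j in range(m)]
    if m == 0:
        return [AlignedColumn(typed[i], GAP, "insertion", i, None) for i in range(n)]

    joint = {c: i for i, c in enumerate(dict.fromkeys(typed + target))}
    a = np.array([joint[c] for c in typed], dtype=np.int32)
    b = np.array([joint[c] for c in target], dtype=np.int32)
    fill = _nw_fill if _HAVE_NUMBA else _nw_fill_py
    H = fill(a, b, params.match, params.substitution, params.indel)

    cols: list[AlignedColumn] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = params.match if typed[i - 1] == target[j - 1] else params.substitution
            if H[i, j] == H[i - 1, j - 1] + s:
                op = "match" if typed[i - 1] == target[j - 1] else "substitution"
                cols.append(AlignedColumn(typed[i - 1], target[j - 1], op, i - 1, j - 1))
                i, j = i - 1, j - 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + params.indel:
            cols.append(AlignedColumn(typed[i - 1], GAP, "insertion", i - 1, None))
            i -= 1
            continue
        cols.append(AlignedColumn(GAP, target[j - 1], "deletion", None, j - 1))
        j -= 1
    cols.reverse()
    return cols


def alignment_score(columns: Sequence[AlignedColumn],
                    params: AlignmentParams = AlignmentParams()) -> float:
    score = {"match": params.match, "substitution": params.substitution,
             "insertion": params.indel, "deletion": params.indel}
    return sum(score[c.op] for c in columns)


def pair_tokens(columns: Sequence[AlignedColumn]) -> list[TokenPair]:
    """Cut the alignment into (typed token, target word) pairs.

    Moving backwards from the end, a boundary is cut wherever a target-side
    space is aligned to anything but a gap; the boundary column belongs to
    neither token.  A target space aligned to a gap (deleted space) does not
    cut, so the two words it separates merge into one pair whose target side
    retains the internal space.
    """
    pairs: list[TokenPair] = []
    span: list[AlignedColumn] = []
    for col in reversed(columns):
        if col.target == " " and col.typed is not GAP:
            pairs.append(_make_pair(span))
            span = []
        else:
            span.append(col)
    pairs.append(_make_pair(span))
    pairs.reverse()
    return pairs


def _make_pair(rev_span: list[AlignedColumn]) -> TokenPair:
    cols = list(reversed(rev_span))
    typed_token = "".join(c.typed for c in cols if c.typed is not GAP)
    target_word = "".join(c.target for c in cols if c.target is not GAP)
    return TokenPair(typed_token, target_word, cols)


def extract_error(
    pair: TokenPair,
    target_sentence: str,
    ikis: Optional[Sequence[Optional[float]]] = None,
    typed_sentence: str = "",
    participant_id: str = "",
    sentence_id: int = 0,
) -> Optional[ErrorRecord]:
    """The single scored error of a mismatching token pair, or None.

    The error is the first non-matching column of the token.  ``prev_char``
    is the character typed immediately before it (possibly in the previous
    word); ``iki_ms`` is that keypress's interkey interval (absent for a
    deletion, which has no keypress).  ``target_context`` is drawn from the
    intended sentence, ``typed_context`` from what was actually typed.
    """
    if not pair.is_error:
        return None
    err = next((c for c in pair.columns if c.op != "match"), None)
    if err is None:  # equal multisets but shifted? cannot happen with NW costs
        return None
    t_idx = err.typed_index
    g_idx = err.target_index
    if g_idx is None:
        # insertion: context position is where the next target char would go
        pos = pair.columns.index(err)
        later = [c.target_index for c in pair.columns[pos + 1:] if c.target_index is not None]
        g_ctx_end = later[0] if later else len(target_sentence)
    else:
        g_ctx_end = g_idx
    target_context = target_sentence[max(0, g_ctx_end - 4):g_ctx_end]
    if t_idx is None:
        prev_idx = _last_typed_index_before(pair, err)
    else:
        prev_idx = t_idx - 1 if t_idx > 0 else None
    prev_char = typed_sentence[prev_idx] if (prev_idx is not None and typed_sentence) else None
    typed_context = typed_sentence[max(0, t_idx - 4):t_idx] if t_idx is not None else (
        typed_sentence[max(0, prev_idx + 1 - 4):prev_idx + 1] if prev_idx is not None else "")
    iki = None
    if t_idx is not None and ikis is not None and t_idx < len(ikis):
        iki = ikis[t_idx]
    return ErrorRecord(
        participant_id=participant_id,
        sentence_id=sentence_id,
        target_char=err.target,
        typed_char=err.typed,
        prev_char=prev_char,
        iki_ms=iki,
        target_context=target_context,
        typed_context=typed_context,
        typed_index=t_idx,
        target_index=g_idx,
    )


def _last_typed_index_before(pair: TokenPair, err: AlignedColumn) -> Optional[int]:
    last = None
    for c in pair.columns:
        if c is err:
            break
        if c.typed_index is not None:
            last = c.typed_index
    if last is not None:
        return last
    # error at the very start of the token: previous keypress is the last
    # typed character before the token (e.g. the boundary space), which the
    # caller exposes through typed_index ordering; reconstruct from columns.
    first_typed = next((c.typed_index for c in pair.columns if c.typed_index is not None), None)
    if first_typed is not None and first_typed > 0:
        return first_typed - 1
    return None
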