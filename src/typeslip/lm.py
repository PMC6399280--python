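"""Character n-gram language model with back-off smoothing.

The habit-slip rule compares the conditional probability of the typed
character with that of the intended character, each given the preceding
four characters.  That comparison is supplied by an order-5 character model
with Witten-Bell interpolated back-off:

    p(w | c) = (n(c w) + T(c) * p(w | c'))  /  (N(c) + T(c))

where ``c'`` drops the oldest context character, ``N(c)`` is the total count
of continuations of context ``c`` and ``T(c)`` the number of *distinct*
continuations.  The recursion bottoms out in a uniform distribution over the
vocabulary, so every in-vocabulary character receives strictly positive mass
and, for each context, probabilities over the vocabulary sum to one exactly.
Out-of-vocabulary characters fall through every level with zero count and
receive the residual-uniform floor; they are flagged, not rejected.

Training text is normalized per line: lowercased, whitespace collapsed to
single spaces, digit-only lines dropped, diacritics preserved.  Each line is
padded with ``order - 1`` start symbols, so queries with short contexts are
well defined.  Models round-trip through the standard ARPA file format.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable

logger = logging.getLogger(__name__)

START = "\x02"  # sentence-boundary padding symbol; context-only, never predicted


class TrainingError(ValueError):
    """Raised when a model cannot be estimated (e.g. empty corpus)."""


def normalize_text(line: str) -> str:
    """Normalize one line of training text (lowercase, collapse whitespace)."""
    line = re.sub(r"\s+", " ", line.strip().lower())
    return line


@dataclass
class CharNGramLM:
    """Witten-Bell back-off character model of a fixed order (default 5)."""

    order: int
    counts: list[Counter] = field(repr=False)  # counts[k]: (k+1)-gram tuples -> count
    context_totals: list[Counter] = field(repr=False)  # N(c) per context, per order
    context_types: list[Counter] = field(repr=False)  # T(c) per context, per order
    vocabulary: frozenset[str] = frozenset()
    smoothing: str = "witten-bell"

    def __post_init__(self) -> None:
        self._vocab_sorted = sorted(self.vocabulary)
        self._cache: dict[tuple[str, str], float] = {}
        self._oov_seen: set[str] = set()

    # -- queries ------------------------------------------------------------

    def cond_prob(self, ch: str, context: str = "") -> float:
        """p(ch | last ``order - 1`` characters of ``context``), start-padded.

        Strictly positive for every in-vocabulary character; an
        out-of-vocabulary ``ch`` gets the uniform back-off floor and is
        flagged once in the log.
        """
        ctx = self._pad(context)
        if ch not in self.vocabulary and ch not in self._oov_seen:
            self._oov_seen.add(ch)
            logger.debug("out-of-vocabulary character %r queried", ch)
        key = (ch, ctx)
        hit = self._cache.get(key)
        if hit is None:
            hit = self._cache[key] = self._prob(ch, ctx)
        return hit

    def argmax(self, context: str = "") -> str:
        """Most probable in-vocabulary character after ``context`` (ties: lexicographic)."""
        return max(self._vocab_sorted, key=lambda ch: (self.cond_prob(ch, context), ch))

    def logprob10(self, ch: str, context: str = "") -> float:
        return math.log10(self.cond_prob(ch, context))

    def _pad(self, context: str) -> str:
        n = self.order - 1
        context = context[-n:] if n else ""
        if len(context) < n:
            context = START * (n - len(context)) + context
        return context

    def _prob(self, ch: str, ctx: str) -> float:
        # recursive interpolated Witten-Bell; ctx already padded to order-1
        p = 1.0 / max(len(self.vocabulary), 1)
        for k in range(self.order):  # k = context length of this level
            c = ctx[len(ctx) - k:] if k else ""
            n_c = self.context_totals[k][c]
            t_c = self.context_types[k][c]
            if n_c == 0:
                continue  # unseen context: pass lower-order estimate through
            n_cw = self.counts[k][(c, ch)]
            p = (n_cw + t_c * p) / (n_c + t_c)
        return p

    # -- training -----------------------------------------------------------

    @classmethod
    def train(cls, corpus: Iterable[str] | str, order: int = 5) -> "CharNGramLM":
        """Estimate a model from an iterable of text lines (or one string).

        Deterministic: identical corpora give identical models.
        """
        if order < 1:
            raise TrainingError("order must be >= 1")
        if isinstance(corpus, str):
            corpus = corpus.splitlines() or [corpus]
        counts = [Counter() for _ in range(order)]
        totals = [Counter() for _ in range(order)]
        types_sets: list[dict[str, set]] = [dict() for _ in range(order)]
        vocab: set[str] = set()
        n_lines = 0
        pad = START * (order - 1)
        for raw in corpus:
            line = normalize_text(raw)
            if not line or line.isdigit():
                continue
            n_lines += 1
            vocab.update(line)
            padded = pad + line
            for i in range(order - 1, len(padded)):
                ch = padded[i]
                for k in range(order):
                    c = padded[i - k:i]
                    key = (c, ch)
                    counts[k][key] += 1
                    totals[k][c] += 1
                    types_sets[k].setdefault(c, set()).add(ch)
        if n_lines == 0 or not vocab:
            raise TrainingError("corpus is empty after normalization")
        types = [Counter({c: len(s) for c, s in level.items()}) for level in types_sets]
        return cls(order=order, counts=counts, context_totals=totals,
                   context_types=types, vocabulary=frozenset(vocab))

    @classmethod
    def train_file(cls, path, order: int = 5) -> "CharNGramLM":
        with open(path, encoding="utf-8") as fh:
            return cls.train(fh, order=order)

    # -- ARPA serialization --------------------------------------------------

    def to_arpa(self, fh: IO[str]) -> None:
        """Write the model in ARPA back-off format.

        Probabilities for listed n-grams are the full interpolated estimates;
        the back-off weight of a context is its Witten-Bell interpolation
        weight T/(N+T), so an ARPA reader reconstructs cond_prob exactly.
        """
        def bow_of(context: str) -> float | None:
            ln = len(context)
            if ln >= self.order:
                return None
            n_ctx, t_ctx = self.context_totals[ln][context], self.context_types[ln][context]
            if n_ctx == 0:
                return None  # unseen context: pass-through (implicit weight 1)
            return math.log10(t_ctx / (n_ctx + t_ctx))

        grams: list[list[tuple[str, float, float | None]]] = []
        for k in range(self.order):
            seen = set()
            level = []
            for (c, ch), cnt in sorted(self.counts[k].items()):
                if cnt == 0:
                    continue
                ngram = c + ch
                seen.add(ngram)
                level.append((ngram, math.log10(self._interp_at(ch, c, k)),
                              bow_of(ngram)))
            # contexts that occur only via boundary padding (e.g. pure start
            # symbols) are not themselves observed n-grams but still need
            # their back-off weight recorded; use the conventional dummy prob
            if k + 1 < self.order:
                for c, n_c in sorted(self.context_totals[k + 1].items()):
                    if n_c > 0 and c not in seen:
                        level.append((c, -99.0, bow_of(c)))
            grams.append(level)
        # out-of-vocabulary floor: residual uniform mass at the unigram level
        n0, t0 = self.context_totals[0][""], self.context_types[0][""]
        unk_lp = math.log10((t0 / (n0 + t0)) / max(len(self.vocabulary), 1))
        grams[0].append(("<unk>", unk_lp, None))
        fh.write("\\data\\\n")
        for k, level in enumerate(grams):
            fh.write(f"ngram {k + 1}={len(level)}\n")
        for k, level in enumerate(grams):
            fh.write(f"\n\\{k + 1}-grams:\n")
            for ngram, lp, bow in level:
                toks = ngram if ngram == "<unk>" else " ".join(_arpa_token(c) for c in ngram)
                if bow is None:
                    fh.write(f"{lp:.10f}\t{toks}\n")
                else:
                    fh.write(f"{lp:.10f}\t{toks}\t{bow:.10f}\n")
        fh.write("\n\\end\\\n")

    def _interp_at(self, ch: str, ctx: str, k: int) -> float:
        """Interpolated probability using at most a length-k context."""
        p = 1.0 / max(len(self.vocabulary), 1)
        for j in range(k + 1):
            c = ctx[len(ctx) - j:] if j else ""
            n_c = self.context_totals[j][c]
            t_c = self.context_types[j][c]
            if n_c == 0:
                continue
            n_cw = self.counts[j][(c, ch)]
            p = (n_cw + t_c * p) / (n_c + t_c)
        return p

    def save_arpa(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            self.to_arpa(fh)


def _arpa_token(ch: str) -> str:
    if ch == " ":
        return "<sp>"
    if ch == START:
        return "<s>"
    return ch


def _arpa_untoken(tok: str) -> str:
    if tok == "<sp>":
        return " "
    if tok == "<s>":
        return START
    return tok


class ArpaLM:
    """Back-off model read from an ARPA file; same query surface as CharNGramLM."""

    def __init__(self, order: int, logprobs: dict[str, float], bows: dict[str, float],
                 vocabulary: frozenset[str], unk_logprob: float | None = None):
        self.order = order
        self.logprobs = logprobs
        self.bows = bows
        self.vocabulary = vocabulary
        self.unk_logprob = unk_logprob
        self._vocab_sorted = sorted(vocabulary)
        self.smoothing = "arpa"

    @classmethod
    def load(cls, path) -> "ArpaLM":
        logprobs: dict[str, float] = {}
        bows: dict[str, float] = {}
        order = 0
        vocab: set[str] = set()
        unk_lp: float | None = None
        with open(path, encoding="utf-8") as fh:
            section = 0
            for line in fh:
                line = line.rstrip("\n")
                m = re.match(r"\\(\d+)-grams:", line)
                if m:
                    section = int(m.group(1))
                    order = max(order, section)
                    continue
                if not line or line.startswith("\\") or line.startswith("ngram "):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    continue
                lp = float(parts[0])
                if parts[1] == "<unk>":
                    unk_lp = lp
                    continue
                ngram = "".join(_arpa_untoken(t) for t in parts[1].split(" "))
                logprobs[ngram] = lp
                if len(parts) > 2:
                    bows[ngram] = float(parts[2])
                if section == 1 and ngram != START:
                    vocab.add(ngram)
        if not logprobs:
            raise TrainingError(f"{path}: no n-grams found")
        return cls(order, logprobs, bows, frozenset(vocab), unk_logprob=unk_lp)

    def cond_prob(self, ch: str, context: str = "") -> float:
        n = self.order - 1
        ctx = context[-n:] if n else ""
        if len(ctx) < n:
            ctx = START * (n - len(ctx)) + ctx
        return 10.0 ** self._logprob(ch, ctx)

    def argmax(self, context: str = "") -> str:
        return max(self._vocab_sorted, key=lambda ch: (self.cond_prob(ch, context), ch))

    def _logprob(self, ch: str, ctx: str) -> float:
        if not ctx:
            lp = self.logprobs.get(ch)
            if lp is not None:
                return lp
            if self.unk_logprob is not None:
                return self.unk_logprob
            # uniform floor over vocabulary
            return -math.log10(max(len(self.vocabulary), 1))
        full = ctx + ch
        lp = self.logprobs.get(full)
        if lp is not None:
            return lp
        return self.bows.get(ctx, 0.0) + self._logprob(ch, ctx[1:])
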