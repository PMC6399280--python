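"""Synthetic copy-typing cohorts with ground-truth error mechanisms.

Each simulated typist copy-types the packaged stimulus sentences.  Keypress
intervals are log-normal around a per-typist median (itself log-normally
dispersed around the profile median, emulating between-participant speed
differences); errorful keypresses are slowed by a multiplicative factor.
Each keypress is independently turned into a substitution error with
probability ``p_error``, by one of three mechanisms:

* ``motor`` — a uniformly chosen key adjacent (grid distance 1) to the
  previously typed key;
* ``habit`` — the language model's most probable character given the four
  preceding target characters (redrawn as ``uniform`` when the model's
  argmax *is* the intended character, and recorded as such);
* ``uniform`` — a uniformly random key.

With ``speed_coupling > 0`` the habit mechanism's odds are multiplied by
``1 + speed_coupling`` on keypresses whose drawn interval is below the
profile's nominal median — faster keypresses, and faster typists, slip into
habits more often, emulating the habit-specific speed-accuracy trade-off.

The packaged default profiles (``english-control``, ``english-patient``,
``spanish-control``, ``spanish-patient``) carry calibration constants chosen
once, by grid search over this generator, so that the cohort means measured
by the *full analysis pipeline* reproduce the published per-group error
rates and interkey intervals; the constants and the search provenance live
in ``data/profiles.json`` (see ``scripts/calibrate_profiles.py``).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from . import io as kio
from .keyboard import KeyboardLayout, load_layout
from .lm import CharNGramLM

MECHANISMS = ("motor", "habit", "uniform")


class ProfileError(ValueError):
    pass


@dataclass
class TypistProfile:
    """Generating parameters for one participant group x language cell."""

    name: str
    group: str  # "patient" | "control"
    language: str  # "en" | "es"
    iki_median_ms: float  # nominal median interval of a correct keypress
    iki_log_sd: float  # within-typist log-sd of intervals
    iki_between_sd: float  # log-sd of the per-typist median around the nominal
    error_slowing: float  # multiplicative slowing of errorful keypresses (>1)
    p_error: float  # per-keypress substitution probability
    mechanism_mix: dict[str, float]  # over motor/habit/uniform, sums to 1
    mix_jitter_sd: float = 0.0  # log-normal per-typist jitter of the mix
    speed_coupling: float = 0.0  # extra habit odds on fast keypresses (>= 0)
    updrs_mean: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.mechanism_mix.values()) - 1.0) > 1e-9:
            raise ProfileError(f"{self.name}: mechanism_mix must sum to 1")
        if not all(0 <= v <= 1 for v in self.mechanism_mix.values()):
            raise ProfileError(f"{self.name}: mechanism weights must be in [0, 1]")
        if set(self.mechanism_mix) - set(MECHANISMS):
            raise ProfileError(f"{self.name}: unknown mechanisms "
                               f"{set(self.mechanism_mix) - set(MECHANISMS)}")
        if not 0 <= self.p_error <= 1:
            raise ProfileError(f"{self.name}: p_error must be in [0, 1]")
        if self.speed_coupling < 0 or self.error_slowing <= 0 or self.updrs_mean < 0:
            raise ProfileError(f"{self.name}: invalid parameter")


@dataclass
class GroundTruthError:
    participant_id: str
    sentence_id: int
    typed_index: int
    mechanism: str
    target_char: str
    typed_char: str


@dataclass
class TypistTruth:
    """Per-typist realized parameters and per-error mechanism labels."""

    participant_id: str
    mechanism_mix: dict[str, float]
    iki_median_ms: float
    errors: list[GroundTruthError] = field(default_factory=list)


class SimResources:
    """Lazily loaded, cached layouts / language models / stimuli per language."""

    def __init__(self):
        self._layouts: dict[str, KeyboardLayout] = {}
        self._lms: dict[str, CharNGramLM] = {}
        self._stimuli: dict[str, list[str]] = {}

    def layout(self, language: str) -> KeyboardLayout:
        if language not in self._layouts:
            self._layouts[language] = load_layout(language)
        return self._layouts[language]

    def lm(self, language: str) -> CharNGramLM:
        if language not in self._lms:
            path = resources.files("typeslip.data") / f"corpus_{language}.txt"
            with resources.as_file(path) as p:
                self._lms[language] = CharNGramLM.train_file(p, order=5)
        return self._lms[language]

    def stimuli(self, language: str) -> list[str]:
        if language not in self._stimuli:
            path = resources.files("typeslip.data") / f"stimuli_{language}.txt"
            with resources.as_file(path) as p:
                self._stimuli[language] = kio.read_stimuli(p)
        return self._stimuli[language]

    def set(self, language: str, *, layout=None, lm=None, stimuli=None) -> "SimResources":
        if layout is not None:
            self._layouts[language] = layout
        if lm is not None:
            self._lms[language] = lm
        if stimuli is not None:
            self._stimuli[language] = list(stimuli)
        return self


_shared_resources: Optional[SimResources] = None


def default_resources() -> SimResources:
    global _shared_resources
    if _shared_resources is None:
        _shared_resources = SimResources()
    return _shared_resources


def simulate_typist(
    profile: TypistProfile,
    stimuli: Sequence[str],
    layout: KeyboardLayout,
    lm,
    rng: np.random.Generator,
    participant_id: str = "sim-000",
    _argmax_cache: Optional[dict] = None,
) -> tuple[kio.TypingSession, TypistTruth]:
    """Simulate one typist copy-typing ``stimuli``; byte-identical per seed."""
    argmax_cache = _argmax_cache if _argmax_cache is not None else {}
    median_i = profile.iki_median_ms * math.exp(rng.normal(0.0, profile.iki_between_sd)) \
        if profile.iki_between_sd > 0 else profile.iki_median_ms
    if profile.mix_jitter_sd > 0:
        w = {m: profile.mechanism_mix.get(m, 0.0) *
             math.exp(rng.normal(0.0, profile.mix_jitter_sd)) for m in MECHANISMS}
        tot = sum(w.values())
        mix_i = {m: v / tot for m, v in w.items()}
    else:
        mix_i = {m: profile.mechanism_mix.get(m, 0.0) for m in MECHANISMS}

    keys = sorted(layout.positions)
    session = kio.TypingSession(participant_id, profile.language, list(stimuli))
    truth = TypistTruth(participant_id, mix_i, median_i)
    for sid, sentence in enumerate(stimuli):
        target = "".join(layout.normalize(c) for c in sentence)
        events: list[kio.KeypressEvent] = []
        t = 0.0
        prev: Optional[str] = None
        for i, intended in enumerate(target):
            iki = median_i * math.exp(rng.normal(0.0, profile.iki_log_sd))
            typed = intended
            mechanism = None
            if rng.random() < profile.p_error:
                mechanism = _draw_mechanism(mix_i, profile, iki, prev, rng)
                typed, mechanism = _draw_error_char(
                    mechanism, intended, prev, target, i, layout, lm, keys,
                    rng, argmax_cache)
                iki *= profile.error_slowing
            if i == 0:
                t = 0.0
            else:
                t += iki
            key = "SPACE" if typed == " " else typed
            events.append(kio.KeypressEvent(key, float(round(t))))
            if mechanism is not None:
                truth.errors.append(GroundTruthError(
                    participant_id, sid, i, mechanism, intended, typed))
            prev = typed
        session.events[sid] = events
    return session, truth


def _draw_mechanism(mix, profile, iki, prev, rng) -> str:
    wm = mix["motor"] if prev is not None else 0.0
    wh = mix["habit"]
    if profile.speed_coupling > 0 and iki < profile.iki_median_ms:
        wh *= 1.0 + profile.speed_coupling
    wu = mix["uniform"]
    tot = wm + wh + wu
    if tot <= 0:
        return "uniform"
    u = rng.random() * tot
    if u < wm:
        return "motor"
    if u < wm + wh:
        return "habit"
    return "uniform"


def _draw_error_char(mechanism, intended, prev, target, i, layout, lm, keys,
                     rng, argmax_cache) -> tuple[str, str]:
    if mechanism == "motor":
        cands = [k for k in layout.neighbours(prev) if k != intended]
        if cands:
            return cands[rng.integers(len(cands))], "motor"
        mechanism = "uniform"
    if mechanism == "habit":
        context = target[max(0, i - 4):i]
        top = argmax_cache.get(context)
        if top is None:
            top = argmax_cache[context] = lm.argmax(context)
        if top != intended:
            return top, "habit"
        mechanism = "uniform"
    cands = [k for k in keys if k != intended]
    return cands[rng.integers(len(cands))], "uniform"


def simulate_cohort(
    spec: Sequence[tuple[TypistProfile, int]],
    seed: int,
    resources_: Optional[SimResources] = None,
    id_prefix: str = "",
) -> tuple[list[kio.TypingSession], list[kio.ParticipantRecord], list[TypistTruth]]:
    """Simulate ``n`` typists per profile; UPDRS ~ Poisson(updrs_mean).

    Patient UPDRS draws are truncated below 20 (early-stage inclusion
    criterion).  Deterministic given ``seed``.
    """
    res = resources_ if resources_ is not None else default_resources()
    rng = np.random.default_rng(seed)
    sessions, records, truths = [], [], []
    argmax_caches: dict[str, dict] = {}
    for profile, n in spec:
        stim = res.stimuli(profile.language)
        layout = res.layout(profile.language)
        lm = res.lm(profile.language)
        cache = argmax_caches.setdefault(profile.language, {})
        for i in range(n):
            pid = f"{id_prefix}{profile.name}-{i:03d}"
            sess, truth = simulate_typist(profile, stim, layout, lm, rng, pid,
                                          _argmax_cache=cache)
            updrs = int(rng.poisson(profile.updrs_mean))
            if profile.group == "patient":
                while updrs >= 20:
                    updrs = int(rng.poisson(profile.updrs_mean))
            sessions.append(sess)
            records.append(kio.ParticipantRecord(pid, profile.group, updrs,
                                                 profile.language))
            truths.append(truth)
    return sessions, records, truths


# -- packaged profiles -------------------------------------------------------

def load_default_profiles() -> dict[str, TypistProfile]:
    """The four calibrated group x language profiles shipped with the package."""
    path = resources.files("typeslip.data") / "profiles.json"
    with resources.as_file(path) as p, open(p, encoding="utf-8") as fh:
        raw = json.load(fh)
    out = {}
    for name, params in raw.items():
        if name.startswith("_"):
            continue
        out[name] = TypistProfile(name=name, **params)
    return out


def get_profile(name: str) -> TypistProfile:
    profiles = load_default_profiles()
    try:
        return profiles[name]
    except KeyError:
        raise ProfileError(
            f"unknown profile {name!r}; available: {sorted(profiles)}") from None


# -- ground truth serialization ---------------------------------------------

def write_ground_truth(truths: Sequence[TypistTruth], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE, quotechar=None)
        writer.writerow(["participant_id", "sentence_id", "typed_index",
                         "mechanism", "target_char", "typed_char"])
        for t in truths:
            for e in t.errors:
                writer.writerow([e.participant_id, e.sentence_id, e.typed_index,
                                 e.mechanism, e.target_char, e.typed_char])


def read_ground_truth(path) -> list[GroundTruthError]:
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE):
            out.append(GroundTruthError(rec["participant_id"], int(rec["sentence_id"]),
                                        int(rec["typed_index"]), rec["mechanism"],
                                        rec["target_char"], rec["typed_char"]))
    return out
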