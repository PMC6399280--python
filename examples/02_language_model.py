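"""Train a character 5-gram model and inspect the habit statistic.

The habit-slip rule compares p(typed | 4 preceding characters) with
p(target | same context) under a back-off smoothed character model.  This
script trains a model on the packaged English corpus, prints the comparison
for the canonical "thing"-for-"think" slip, and round-trips the model
through the standard ARPA format.
"""

import tempfile
from pathlib import Path

from typeslip import ArpaLM, default_resources

lm = default_resources().lm("en")  # order-5, Witten-Bell back-off
print(f"vocabulary: {len(lm.vocabulary)} characters, order {lm.order}\n")

context = "thin"
for ch in ("g", "k", "e"):
    print(f"p({ch!r} | ...{context!r}) = {lm.cond_prob(ch, context):.5f}")
print(f"most probable continuation: {lm.argmax(context)!r}\n")

# back-off in action: an unseen context falls back to shorter ones
print(f"p('e' | 'xqzw') = {lm.cond_prob('e', 'xqzw'):.5f}  (unseen context)")
print(f"p('e' | '')     = {lm.cond_prob('e', ''):.5f}  (sentence start)\n")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "english.arpa"
    lm.save_arpa(path)
    loaded = ArpaLM.load(path)
    a, b = lm.cond_prob("g", context), loaded.cond_prob("g", context)
    print(f"ARPA round trip: {path.stat().st_size // 1024} KiB, "
          f"p(g|thin) {a:.8f} -> {b:.8f}")

# On natural English text "ing" is so frequent that g beats k after "thin" --
# the statistical signature of an over-learned keystroke habit.
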