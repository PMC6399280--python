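"""Align a typed sentence to its stimulus and classify the errors.

A typist meaning to write "i think the results are clear" slips into the
more habitual "thing" and also hits a key next to the one intended.  The
pipeline aligns the typed text to the target, extracts one error per
mismatching word, and labels each one motor / habit / other.
"""

from typeslip import CharNGramLM, load_layout
from typeslip.alignment import align, extract_error, pair_tokens
from typeslip.classifier import classify

layout = load_layout("en")
# a character model dominated by the habitual word: p(g|thin) >> p(k|thin)
lm = CharNGramLM.train(["every thing went fine", "one thing led to another",
                        "i think about every thing", "that thing was the thing",
                        "keep it clean", "a clean house", "clean hands", "come clean"],
                       order=5)

target = "i think the results are clear"
typed = "i thing the resjlts are clean"  # two slips of habit, one of aim

columns = align(typed, target)
ikis = [None] + [220.0] * (len(typed) - 1)

print(f"target: {target}")
print(f"typed : {typed}\n")
for pair in pair_tokens(columns):
    record = extract_error(pair, target, ikis, typed)
    if record is None:
        continue
    labeled = classify(record, layout, lm)
    print(f"word {pair.target_word!r}: typed {record.typed_char!r} for "
          f"{record.target_char!r} after {record.prev_char!r}")
    print(f"  d(prev,typed)={labeled.d_prev_typed}  d(prev,target)={labeled.d_prev_target}")
    if labeled.p_typed is not None:
        print(f"  p(typed|ctx)={labeled.p_typed:.4g}  p(target|ctx)={labeled.p_target:.4g}")
    print(f"  -> {labeled.label}\n")

# 'g' for 'k' after "thin" is a habit-shaped slip, but on QWERTY 'g' is also
# adjacent to the previous key 'n', so the motor rule (applied first, per the
# published procedure) captures it.  'j' for 'u' is a plain adjacent-key
# motor slip.  'n' for 'r' after "clea" is spatially implausible yet highly
# probable under the model trained on "clean"-heavy text: a habit slip.
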