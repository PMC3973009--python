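"""Topic identification on a tiny document, with and without decay.

Builds a six-word toy lexicon in which three economy words share the item
'oil', reads a short document, and ranks topics under three regimes:
no decay (pure frequency), rapid decay without short-term memory (most
activation is lost), and rapid decay with a 3-word buffer (recurring shared
items are protected and survive).
"""

import readtopics as rt

lexicon = rt.ToyLexicon(
    entries={
        "crude": ["oil", "petroleum", "barrel"],
        "opec": ["oil", "cartel", "export"],
        "energy": ["oil", "power", "fuel"],
        "weather": ["rain", "cloud"],
        "lunch": ["meal", "food"],
        "train": ["railway", "travel"],
    }
)
text = "Crude opec energy weather crude lunch opec energy train crude opec."
tokens = rt.normalize_document(text, lexicon)

for stm, eta, label in [(0, 0.0, "no decay, no STM (frequency baseline)"),
                        (0, 1.0, "rapid decay, no STM"),
                        (3, 1.0, "rapid decay, 3-word STM")]:
    params = rt.ReadParams(stm_capacity=stm, decay_rate=eta)
    ranking = rt.process_document(tokens, params, lexicon, k=5)
    shown = ", ".join(f"{item}={act:g}" for item, act in ranking) or "(nothing retained)"
    print(f"stm={stm} eta={eta:>4}: {shown}    <- {label}")

print()
print("'oil' is retrieved by three different words, so it dominates the")
print("baseline; rapid decay erases it without STM, while a small buffer")
print("keeps the recently read words' items active long enough to recur.")
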