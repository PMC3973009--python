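"""Item extraction: turn a dictionary entry into 'ideas'.

Loads the packaged two-sense WordNet 2.1 noun entry for "gold" and extracts
its item list — every unique word from the synonym sets, definitions,
example glosses and direct hypernyms, minus stop words and overly general
"undesirable" words.  These items are the model's surrogate for the loosely
organized ideas a reader's long-term memory would activate.
"""

import readtopics as rt

backend = rt.packaged_gold_senses()
entry = rt.lookup_items("gold", backend, rt.default_stopwords(), rt.default_undesirable())

print(f"items retrieved for {entry.word!r} ({len(entry.items)} unique):")
print("  " + ", ".join(entry.items))
print()
print("Each item can now accumulate activation whenever any word whose entry")
print("contains it is read; recurring items become the document's topics.")
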