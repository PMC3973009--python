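"""The STM-capacity x decay-rate sweep on a planted-theme corpus.

Generates the 30-document synthetic regression corpus (3 themes of 4 words,
2 shared items per theme, 60% theme tokens, 200 tokens per document), runs
the sweep, and prints the total top-5 match counts.  The no-decay / no-STM
cell is the upper-quality control baseline; rapid decay (eta=1) with no STM
destroys quality, and a 6-word buffer restores it.
"""

import readtopics as rt

corpus = rt.generate_corpus(rt.SynthSpec(seed=0))
grid = rt.SweepGrid(stm_values=(0, 2, 4, 6), decay_values=(0.0, 1.0, 5.0, 25.0))
result = rt.run_sweep(corpus.documents, corpus.gold, grid, corpus.lexicon)

print(f"baseline (stm=0, eta=0): top5={result.baseline_top5} next5={result.baseline_next5}")
print()
print(result.table.to_string(index=False))
print()
print("Reading the table: 60 = both planted topics of every document ranked")
print("in the top five.  At eta=1 (rapid decay) and stm=0 every item returns")
print("to rest before it can accumulate, so the total collapses; with a")
print("buffer of a few words the planted items stay protected and the total")
print("returns to the baseline.  At eta=25 decay is too slow to matter.")
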