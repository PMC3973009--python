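"""Quality evaluation by direct string-match counts.

Scores a ranked 10-topic list against an unordered human gold standard:
matches are counted separately for ranks 1-5 and ranks 6-10, and topics
below rank 10 never count.  Matching is exact full-string (case-insensitive),
so a multiword gold topic can never match a single-word item.
"""

import readtopics as rt

ranked = ["bank", "company", "rates", "dollar", "Canada",
          "oil", "sand", "Alberta", "exploitation", "financing"]
ranking = [(item, float(10 - i)) for i, item in enumerate(ranked)]
gold = {"dollar", "price", "corporation", "oil", "business", "bank"}

counts = rt.count_matches(ranking, gold)
print("ranked topics :", ", ".join(ranked))
print("gold standard :", ", ".join(sorted(gold)))
print(f"top-5 matches : {counts.top5}   (bank, dollar)")
print(f"next-5 matches: {counts.next5}   (oil)")
print(f"top-10 total  : {counts.top10}")
print()
print("Corpus quality is the plain sum of these per-document counts:")
print("aggregate ->", rt.aggregate([counts, rt.MatchCounts(0, 3)]))
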