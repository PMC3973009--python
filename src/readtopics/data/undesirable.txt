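# Undesirable dictionary items: words too general or too frequent in
# dictionary definitions to be useful topics.  They are removed from item
# lists (not from document text).  This list is intentionally small and
# extensible: add one word per line.
thing
person
time
agency
cause
object
# Frequent definitional verbs/participles that masquerade as items.
used
made
make
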