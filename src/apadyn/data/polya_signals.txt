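# Ordered polyA-signal hexamer catalog (DNA alphabet; priority = order).
# Seeded from the cited PolyASite signal set -- verify against PolyASite
# before substituting your own list.  AAUAAA/AUUAAA reported first.
AATAAA
ATTAAA
TATAAA
AGTAAA
AATACA
CATAAA
AATATA
GATAAA
AATGAA
AAGAAA
ACTAAA
AATAGA
ATTACA
AACAAA
ATTATA
AACAAG
AATAAG
TTTAAA
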