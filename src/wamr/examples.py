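"""Packaged worked example: one utterance with its reference phonetic
transcription, the raw classifier and memory output strings, and their
bigram-simplified forms, in the dense (no-separator) phone-string dialect.

Shipped so the evaluation metrics can be exercised end-to-end without any
external corpus; see :func:`wamr.evaluation.tokenize`.
"""

from __future__ import annotations

EXAMPLE_ORTHOGRAPHIC = "Este es el resultado de ese trabajo"

#: Reference phonetic transcription of the utterance (27 phones).
EXAMPLE_TRANSCRIPTION = "esteselresultadodesetr(abaxo"

#: Raw per-window classifier output (225 phones).
EXAMPLE_NETWORK_OUTPUT = (
    "fpndddgieegeeeeeigggsssssttttdeeeeedsssddggeeeeer(r(llrrrrrrrraaaaae"
    "ssssssffuuuubblllllllldpptttttr(r(aaaaaaaaaaaaooooooooodddddddddddee"
    "eeeeeeeeennngsssseeeeedppppppttr(r(r(r(aaaaaaabbboaaaaaaaaaxxxxxxxxx"
    "xxxxxxxxxooooooooafdsdddfpppp"
)

#: Raw memory-system output for the same utterance (178 phones).
EXAMPLE_MEMORY_OUTPUT = (
    "dddieeeeeeiigsssstttdeeeeesssdieeeer(r(llr(rrrrrrraaaar(ssssuuuubbll"
    "llllllptttttr(r(aaaaaaaaaaaaoooooooooddddddddddeeeeeeeeeeessseeeepppp"
    "ttr(r(r(r(aaaaaaabbbaaaaaaaaxxxxxxxxxxxxxxxoooooopp"
)

#: Bigram-simplified classifier output (41 phones).
EXAMPLE_SIMPLIFIED_NETWORK = "ndiegigstdeser(aesfubltr(r(addeensptr(r(abaxad"

#: Bigram-simplified memory output (37 phones).
EXAMPLE_SIMPLIFIED_MEMORY = "digstdeesdier(ar(ubltr(r(addeesetr(r(abaxop"
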