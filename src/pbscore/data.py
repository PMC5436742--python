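"""Published input constants for the Gracilaria chilensis apc genes.

The PCR primers used to amplify the genes of the allophycocyanin core
subunits (apcA/apcB for the major α/β subunits, apcD/apcF for αII/β18).
Sense primers are written 5'→3' and start at the initiator ATG; antisense
primers are stored as printed (3'→5' left to right).  GC content and
melting temperatures are orientation-independent for the Wallace rule.
"""

PRIMERS: dict[str, str] = {
    "apcA_sense": "atgagtattattactaaatcaatcgttaatgctgatgcagaagctcgg",
    "apcA_antisense": "ttactgcattgcacctaatgtataatcaaaataaaatcct",
    "apcB_sense": "atgcaagatgctattacttctgtaattaatgcagctgatgtacaagg",
    "apcB_antisense": "ctagcttaaaccagaacaaatataatcaaaatatactccc",
    "apcD_sense": "atgagcttagttagccaaattattttaaatgcagataatgaattaagat",
    "apcD_antisense": "ttatgacataccttgtattataaaatcaaagtagggttct",
    "apcF_sense": "atgcaagacgctattactacaattttaaatcgatatgatttaacaggaaa",
    "apcF_antisense": "ttagatatcttcttcgcttaagtttttaattatatattgaaatggttcaa",
}
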