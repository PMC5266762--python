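"""Published primer catalog.

The clade-specific mcrA qPCR/phylogeny primers and the GOM Arc I 16S rRNA
primers for 'Ca. Methanoperedens nitroreducens', together with widely used
general mcrA community primers, all written 5'->3' as published. Binding
windows are the published 1-based coordinates on the respective marker gene
of 'Ca. M. nitroreducens'.
"""

from __future__ import annotations

from .primers import Primer

__all__ = [
    "MCRA_159F",
    "MCRA_345R",
    "MCRA_169F",
    "MCRA_1360R",
    "AAA_641F",
    "AAA_834R",
    "QPCR_PAIR",
    "PHYLOGENY_PAIR",
    "SSU_PAIR",
    "CLADE_PRIMERS",
    "GENERAL_MCRA_PRIMERS",
    "BINDING_SITES",
    "ALL_PRIMERS",
]

# Methanoperedens-specific mcrA primers
MCRA_159F = Primer("McrA159F", "AAAGTGCGGAGCAGCAATCACC", "forward")
MCRA_345R = Primer("McrA345R", "TCGTCCCATTCCTGCTGCATTGC", "reverse")
MCRA_169F = Primer("McrA169F", "GCAGCAATCACCAAGAAGAGAGG", "forward")
MCRA_1360R = Primer("McrA1360R", "TGCCTCTTTGTGGAGGTACATGGA", "reverse")

# GOM Arc I clade 16S rRNA primers (originally FISH probes)
AAA_641F = Primer("AAA641F", "ACTGDTAGGCTTGGGACC", "forward")
AAA_834R = Primer("AAA834R", "ATGCGGTCGCACCGCACCTG", "reverse")

#: short-amplicon pair for qPCR quantification (186 bp product, paper convention)
QPCR_PAIR = (MCRA_159F, MCRA_345R)
#: long-amplicon pair for phylogenetic analysis (1191 bp)
PHYLOGENY_PAIR = (MCRA_169F, MCRA_1360R)
#: 16S rRNA clade pair (212 bp)
SSU_PAIR = (AAA_641F, AAA_834R)

CLADE_PRIMERS = [MCRA_159F, MCRA_345R, MCRA_169F, MCRA_1360R, AAA_641F, AAA_834R]

# General methanogen/ANME mcrA community primers from the literature
GENERAL_MCRA_PRIMERS = [
    Primer("ML-F", "GGTGGTGTMGGATTCACACARTAYGCWACAGC", "forward"),
    Primer("ML-R", "TTCATTGCRTAGTTWGGRTAGTT", "reverse"),
    Primer("McrAF", "TAYGAYCARATHTGGYT", "forward"),
    Primer("McrAR", "ACRTTCATNGCRTARTT", "reverse"),
    Primer("ME1F", "GCMATGCARATHGGWATGTC", "forward"),
    Primer("ME2R", "TCATKGCRTAGTTDGGRTAGT", "reverse"),
    Primer("ME3F", "GGTGGHGTMGGWTTCACACA", "forward"),
    Primer("ANME2cd-F", "GCTCTACGACCAGATMTGGCTTGG", "forward"),
    Primer("ANME2cd-R", "CCGTAGTACGTGAAGTCATCCAGCA", "reverse"),
    Primer("TypeE-F", "CHCTGGAAGATCACTTCGGTGGTTC", "forward"),
    Primer("TypeE-R", "RTATCCGAAGAARCCSAGTCKRCC", "reverse"),
    Primer("ANME1-F", "TGGTTCGGAACGTACATGTC", "forward"),
    Primer("ANME1-R", "TCTYYTCCAGRATGTCCATG", "reverse"),
    Primer("ME3MF", "ATGTCNGGTGGHGTMGGSTTYAC", "forward"),
    Primer("ME3MF-3", "ATGAGCGGTGGTGTCGGTTTCAC", "forward"),
]

ALL_PRIMERS = CLADE_PRIMERS + GENERAL_MCRA_PRIMERS

#: published 1-based binding windows on the marker gene (mcrA; 16S for AAA primers)
BINDING_SITES: dict[str, tuple[int, int]] = {
    "McrA159F": (159, 181),
    "McrA345R": (322, 345),
    "McrA169F": (169, 192),
    "McrA1360R": (1336, 1360),
    "AAA641F": (576, 593),
    "AAA834R": (768, 788),
    "ML-F": (1021, 1053),
    "ML-R": (1468, 1491),
    "McrAF": (988, 1005),
    "McrAR": (1477, 1491),
    "ME1F": (727, 747),
    "ME2R": (1469, 1490),
    "ME3F": (1036, 1056),
    "ANME2cd-F": (984, 1008),
    "ANME2cd-R": (1058, 1083),
    "TypeE-F": (1220, 1245),
    "TypeE-R": (1363, 1387),
    "ANME1-F": (1000, 1020),
    "ANME1-R": (1562, 1582),
    "ME3MF": (1015, 1038),
    "ME3MF-3": (1015, 1038),
}
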