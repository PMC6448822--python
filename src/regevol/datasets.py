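"""Published motif-position data for the DRO1-like gene set.

The signed AuxRE position lists below are the published per-gene TGTCTC/TGTC
coordinates for promoters (negative, ATG-anchored) and introns (positive) of
17 DRO1-like orthologs, transcribed as printed.  They are the standard input
for the gain/loss ledger: feeding the promoter TGTC lists of the three
progenitor->homoeolog pairs into :func:`regevol.gainloss.build_ledger` yields
deltas +1 (TuDRO1->TaADRO1), +1 (AsDRO1->TaBDRO1) and -1 (AtaDRO1->TaDDRO1).

Note one internal inconsistency of the source: its prose says TaBDRO1 has
"6+7" TGTCs (promoter+introns) and TaDDRO1 "4+7", while its table prints 6
intronic positions for TaBDRO1 and 3 promoter positions for TaDDRO1.  The
table lists are authoritative here (see docs/methods.md).
"""

from __future__ import annotations

from .motifscan import MotifTally, tally_from_positions
from .seqio import INTRON, PROMOTER

#: gene -> motif -> {"promoter": [...], "intron": [...]} signed positions.
AUXRE_POSITIONS: dict[str, dict[str, dict[str, list[int]]]] = {
    "AtDRO1": {
        "TGTCTC": {"promoter": [-1287], "intron": []},
        "TGTC": {"promoter": [-36, -634, -1196, -1851], "intron": [233]},
    },
    "SiDRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-167, -1414, -1427, -1677], "intron": []},
    },
    "SbDRO1": {
        "TGTCTC": {"promoter": [-1486], "intron": [77]},
        "TGTC": {"promoter": [-769, -823, -1099],
                 "intron": [221, 609, 632, 804, 1037, 2164]},
    },
    "OsDRO1": {
        "TGTCTC": {"promoter": [-375], "intron": []},
        "TGTC": {"promoter": [-91],
                 "intron": [631, 653, 731, 755, 777, 852, 2618]},
    },
    "ZmDRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-309, -501, -607, -770, -994],
                 "intron": [308, 1080, 1382, 1586, 2052, 2857, 2888]},
    },
    "TuDRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-772],
                 "intron": [72, 452, 838, 1044, 1059, 1147, 1397]},
    },
    "TaADRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-772, -853],
                 "intron": [72, 453, 1046, 1061, 1149, 1406]},
    },
    "AtaDRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-372, -1708, -1726, -1827],
                 "intron": [510, 676, 852, 886, 901, 977, 1245]},
    },
    "TaDDRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-1708, -1726, -1827],
                 "intron": [510, 676, 852, 886, 901, 977, 1245]},
    },
    "AsDRO1": {
        "TGTCTC": {"promoter": [-1802], "intron": []},
        "TGTC": {"promoter": [-367, -753, -809, -938, -1785],
                 "intron": [513, 827, 848, 882, 897, 1002, 1015]},
    },
    "TaBDRO1": {
        "TGTCTC": {"promoter": [-1251], "intron": []},
        "TGTC": {"promoter": [-742, -798, -926, -1738, -1749, -1841],
                 "intron": [509, 824, 845, 879, 894, 999]},
    },
    "HvDRO1": {
        "TGTCTC": {"promoter": [-1967, -1977], "intron": []},
        "TGTC": {"promoter": [-364, -1330, -1747],
                 "intron": [392, 757, 791, 902]},
    },
    "BdDRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-825],
                 "intron": [254, 382, 677, 684, 862, 1018, 1268]},
    },
    "AtrDRO1": {
        "TGTCTC": {"promoter": [-1333], "intron": []},
        "TGTC": {"promoter": [-818],
                 "intron": [1071, 1155, 4031, 4055, 4574]},
    },
    "OtDRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-205, -350, -929, -1281, -1843], "intron": []},
    },
    "SmDRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-107, -388, -587, -1412, -1669], "intron": []},
    },
    "PpDRO1": {
        "TGTCTC": {"promoter": [], "intron": []},
        "TGTC": {"promoter": [-851, -875, -1482, -1591],
                 "intron": [36, 355, 1669]},
    },
}

#: The three progenitor -> wheat-homoeolog edges (A, B and D subgenomes).
TRITICI_LINEAGES: list[tuple[str, str, str]] = [
    ("TuDRO1", "TaADRO1", "A"),
    ("AsDRO1", "TaBDRO1", "B"),
    ("AtaDRO1", "TaDDRO1", "D"),
]

#: Qualitative root-tip expression of the wheat homoeologs (+ weaker ... +++ stronger).
EXPRESSION_RANKS: dict[str, str] = {
    "TaADRO1": "+++",
    "TaDDRO1": "++",
    "TaBDRO1": "+",
}


def auxre_tallies() -> dict[str, MotifTally]:
    """The published position lists as :class:`MotifTally` objects per gene."""
    tallies: dict[str, MotifTally] = {}
    for gene, motifs in AUXRE_POSITIONS.items():
        positions = {}
        for motif, regions in motifs.items():
            if regions["promoter"]:
                positions[(motif, PROMOTER)] = regions["promoter"]
            if regions["intron"]:
                positions[(motif, INTRON)] = regions["intron"]
        tallies[gene] = tally_from_positions(gene, positions)
    return tallies
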