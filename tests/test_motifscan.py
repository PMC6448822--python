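"""IUPAC scanning, composite elements and Table-1-style reporting."""

import numpy as np
import pytest

from regevol import motifscan, synthetic
from regevol.motifscan import (
    BUILTIN_MOTIFS,
    MotifHit,
    MotifPattern,
    IUPAC_SETS,
    detect_composite,
    read_table1_report,
    scan_gene,
    scan_iupac,
    tally,
    tally_from_positions,
    write_table1_report,
)
from regevol.seqio import INTRON, PROMOTER, LocusRecord


def naive_scan(sequence, pattern):
    """Position-by-position sliding-window oracle (sequence N matches nothing)."""
    hits = []
    for i in range(len(sequence) - len(pattern) + 1):
        if all(
            base != "N" and base in IUPAC_SETS[code]
            for base, code in zip(sequence[i:], pattern)
        ):
            hits.append(i)
    return hits


class TestScanIupac:
    def test_carg_n10_instance_matches_canonical_pattern(self):
        assert scan_iupac("CCAAATATGG", BUILTIN_MOTIFS["CArG"]) == [0]

    def test_pattern_longer_than_sequence(self):
        assert scan_iupac("TGT", BUILTIN_MOTIFS["TGTCTC"]) == []

    def test_sequence_n_matches_nothing(self):
        assert scan_iupac("TGNC", BUILTIN_MOTIFS["TGTC"]) == []
        assert scan_iupac("CCNAATATGG", BUILTIN_MOTIFS["CArG"]) == []

    def test_overlapping_matches_all_reported(self):
        assert scan_iupac("TGTCTGTC", "TGTC") == [0, 4]
        assert scan_iupac("AAAA", "AA") == [0, 1, 2]

    def test_invalid_iupac_code_rejected(self):
        with pytest.raises(ValueError, match="'U'"):
            MotifPattern("bad", "TGUC")

    def test_agrees_with_sliding_window_oracle(self):
        rng = np.random.default_rng(21)
        patterns = ["TGTCTC", "TGTC", "ATTTTCTT", "CCWWWWWWGG"]
        for _ in range(25):
            seq = "".join("ACGTN"[b] for b in rng.choice(5, size=2000, p=[0.24] * 4 + [0.04]))
            for pat in patterns:
                assert scan_iupac(seq, pat) == naive_scan(seq, pat)


def _planted_locus():
    """atg=2000, TGTCTC at index 1625 (-375), TGTC at +631 inside intron 1."""
    rng = np.random.default_rng(5)
    fam = synthetic.simulate_regulatory_family(
        plant_spec=(("TGTCTC", -375), ("TGTC", 631)),
        seed=5,
    )
    return fam.loci["progenitor"]


class TestScanGene:
    def test_planted_promoter_hit_at_minus_375(self):
        hits = [h for h in scan_gene(_planted_locus()) if h.motif_name == "TGTCTC"]
        assert len(hits) == 1
        assert hits[0].position == -375
        assert hits[0].region == PROMOTER

    def test_planted_intronic_hit_at_plus_631(self):
        hits = [h for h in scan_gene(_planted_locus())
                if h.motif_name == "TGTC" and h.region == INTRON]
        assert [h.position for h in hits] == [631]

    def test_no_t_means_no_hits(self):
        locus = LocusRecord(id="g", sequence="C" * 50 + "ATG" + "CAG" * 20,
                            atg_index=50, exons=[(50, 113)])
        hits = scan_gene(locus, [BUILTIN_MOTIFS["TGTCTC"], BUILTIN_MOTIFS["TGTC"]])
        assert hits == []

    def test_hits_upstream_of_promoter_window_dropped(self):
        seq = "TGTCTC" + "A" * 94 + "ATG" + "C" * 12
        locus = LocusRecord(id="g", sequence=seq, atg_index=100, exons=[(100, 115)])
        assert scan_gene(locus, [BUILTIN_MOTIFS["TGTCTC"]], promoter_length=50) == []
        hits = scan_gene(locus, [BUILTIN_MOTIFS["TGTCTC"]], promoter_length=100)
        assert [h.position for h in hits] == [-100]

    def test_both_strands_reports_reverse_complement_occurrences(self):
        # GAGACA is the reverse complement of TGTCTC
        seq = "A" * 94 + "GAGACA" + "ATG" + "C" * 12
        locus = LocusRecord(id="g", sequence=seq, atg_index=100, exons=[(100, 115)])
        fwd = scan_gene(locus, [BUILTIN_MOTIFS["TGTCTC"]])
        assert fwd == []
        both = scan_gene(locus, [BUILTIN_MOTIFS["TGTCTC"]], both_strands=True)
        assert [(h.position, h.strand) for h in both] == [(-6, "-")]

    def test_shift_covariance(self):
        # moving the planted motif by k shifts its signed coordinate by k
        for offset in (-900, -500, -123):
            fam = synthetic.simulate_regulatory_family(
                plant_spec=(("TGTCTC", offset),), seed=9
            )
            hits = [h for h in scan_gene(fam.loci["progenitor"])
                    if h.motif_name == "TGTCTC"]
            assert [h.position for h in hits] == [offset]


class TestDetectComposite:
    def _hit(self, motif, pos, length):
        return MotifHit(gene_id="g", motif_name=motif, position=pos,
                        region=PROMOTER, length=length, matched="N" * length)

    def test_coupling_upstream_within_window(self):
        hits = [self._hit("AuxRE-like", -210, 8), self._hit("TGTC", -40, 4)]
        out = detect_composite(hits)
        assert len(out) == 1
        assert out[0].gap == -40 - (-210 + 8)

    def test_no_coupling_no_composites(self):
        hits = [self._hit("TGTC", -40, 4), self._hit("TGTCTC", -300, 6)]
        assert detect_composite(hits) == []

    def test_coupling_downstream_not_paired(self):
        hits = [self._hit("AuxRE-like", -30, 8), self._hit("TGTC", -400, 4)]
        assert detect_composite(hits) == []

    def test_gap_beyond_window_not_paired(self):
        hits = [self._hit("AuxRE-like", -800, 8), self._hit("TGTC", -40, 4)]
        assert detect_composite(hits, window=250) == []
        assert len(detect_composite(hits, window=1000)) == 1

    def test_agrees_with_all_pairs_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            hits = []
            for _ in range(int(rng.integers(0, 12))):
                motif = ["TGTC", "TGTCTC", "AuxRE-like"][int(rng.integers(3))]
                length = {"TGTC": 4, "TGTCTC": 6, "AuxRE-like": 8}[motif]
                pos = int(rng.integers(-2000, -1))
                hits.append(self._hit(motif, pos, length))
            expected = set()
            for c in hits:
                if c.motif_name != "AuxRE-like":
                    continue
                for a in hits:
                    if a.motif_name not in ("TGTC", "TGTCTC"):
                        continue
                    gap = a.linear() - (c.linear() + c.length)
                    if 0 <= gap <= 250:
                        expected.add((c.position, a.position, gap))
            got = {(x.coupling_hit.position, x.auxre_hit.position, x.gap)
                   for x in detect_composite(hits)}
            assert got == expected

    def test_mixed_genes_rejected(self):
        a = self._hit("TGTC", -40, 4)
        b = MotifHit(gene_id="other", motif_name="AuxRE-like", position=-210,
                     region=PROMOTER, length=8, matched="ATTTTCTT")
        with pytest.raises(ValueError, match="multiple genes"):
            detect_composite([a, b])


class TestTally:
    def test_published_tabdro1_promoter_list_counts_six(self):
        positions = [-742, -798, -926, -1738, -1749, -1841]
        hits = [
            MotifHit(gene_id="TaBDRO1", motif_name="TGTC", position=p,
                     region=PROMOTER, length=4, matched="TGTC")
            for p in positions
        ]
        t = tally(hits)
        assert t.count("TGTC", PROMOTER) == 6
        assert t.positions[("TGTC", PROMOTER)] == sorted(positions)

    def test_empty_hit_list_gives_zero_tally(self):
        t = tally([], gene_id="g1")
        assert t.counts == {}
        assert t.count("TGTC", PROMOTER) == 0

    def test_counts_match_per_region_recount(self, tritici):
        for gene, locus in tritici.loci.items():
            hits = scan_gene(locus)
            t = tally(hits, gene_id=gene)
            for key, count in t.counts.items():
                assert count == sum(1 for h in hits if (h.motif_name, h.region) == key)
                assert count == len(t.positions[key])

    def test_order_invariance(self):
        hits = [
            MotifHit(gene_id="g", motif_name="TGTC", position=p, region=PROMOTER,
                     length=4, matched="TGTC")
            for p in (-10, -500, -90)
        ]
        t1, t2 = tally(hits), tally(list(reversed(hits)))
        assert t1.counts == t2.counts and t1.positions == t2.positions

    def test_mixed_gene_ids_rejected(self):
        hits = [
            MotifHit(gene_id=g, motif_name="TGTC", position=-10, region=PROMOTER,
                     length=4, matched="TGTC")
            for g in ("a", "b")
        ]
        with pytest.raises(ValueError, match="multiple genes"):
            tally(hits)


class TestTable1Report:
    def test_gene_with_no_hits_renders_dashes(self, tmp_path):
        p = tmp_path / "t1.tsv"
        write_table1_report([tally([], gene_id="g1")], p)
        assert p.read_text().splitlines()[1] == "g1\t-\t-\t-\t-"

    def test_planted_hit_renders_signed_position(self, tmp_path):
        t = tally_from_positions("g", {("TGTCTC", PROMOTER): [-375],
                                       ("TGTC", INTRON): [631]})
        p = tmp_path / "t1.tsv"
        write_table1_report([t], p)
        row = p.read_text().splitlines()[1].split("\t")
        assert row == ["g", "-375", "-", "-", "+631"]

    def test_write_then_read_round_trip(self, tmp_path, tritici):
        tallies = [tally(scan_gene(l), gene_id=g) for g, l in tritici.loci.items()]
        p = tmp_path / "t1.tsv"
        write_table1_report(tallies, p)
        parsed = {t.gene_id: t for t in read_table1_report(p)}
        for t in tallies:
            keys = [k for k in t.counts
                    if k[1] in (PROMOTER, INTRON) and k[0] in ("TGTCTC", "TGTC")]
            for key in keys:
                assert parsed[t.gene_id].positions[key] == t.positions[key]

    def test_empty_tally_list_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no tallies"):
            write_table1_report([], tmp_path / "x.tsv")
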