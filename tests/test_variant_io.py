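"""File-format round trips, multi-allelic decomposition, validation."""

from pathlib import Path

import networkx as nx
import pandas as pd
import pytest

from trioburden.rate_model import default_rate_table
from trioburden.variant_io import (
    GeneSet,
    Genotype,
    SampleCall,
    Trio,
    TrioVariantRecord,
    read_annotations,
    read_gene_set,
    read_network,
    read_ped,
    read_rate_table,
    read_trio_vcf,
    write_annotations,
    write_gene_set,
    write_ped,
    write_rate_table,
    write_trio_vcf,
)

TRIO = Trio("FAM1", "FAM1-C", "FAM1-M", "FAM1-F", is_case=True)


def _call(gt, ref_reads, alt_reads, depth):
    return SampleCall(gt=gt, ref_reads=ref_reads, alt_reads=alt_reads, depth=depth)


def _record(pos=1000, ref="G", alt="A", child_gt=Genotype.HET,
            mother_gt=Genotype.HOM_REF, father_gt=Genotype.HOM_REF):
    return TrioVariantRecord(
        chrom="12", pos=pos, ref=ref, alt=alt,
        child=_call(child_gt, 15, 13, 30),
        mother=_call(mother_gt, 40, 0, 41),
        father=_call(father_gt, 38, 1, 40),
    )


class TestRecordInvariants:
    def test_reads_cannot_exceed_depth(self):
        with pytest.raises(ValueError, match="exceed"):
            _call(Genotype.HET, 20, 20, 30)

    def test_alt_must_differ_from_ref(self):
        with pytest.raises(ValueError, match="alt allele"):
            _record(ref="G", alt="G")

    def test_variant_key_convention(self):
        assert _record(pos=2613692, ref="G", alt="A").variant_key == "12-2613692-G-A"


class TestVcfRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        records = [
            _record(pos=500),
            _record(pos=900, ref="T", alt="TAC"),
            _record(pos=1200, father_gt=Genotype.MISSING),
        ]
        path = tmp_path / "trio.vcf"
        write_trio_vcf(path, records, TRIO)
        back = read_trio_vcf(path, TRIO)
        assert back == sorted(records, key=lambda r: r.pos)

    def test_missing_genotype_preserved(self, tmp_path):
        path = tmp_path / "m.vcf"
        write_trio_vcf(path, [_record(father_gt=Genotype.MISSING)], TRIO)
        (rec,) = read_trio_vcf(path, TRIO)
        assert rec.father.gt is Genotype.MISSING

    def test_sample_missing_from_vcf(self, tmp_path):
        path = tmp_path / "t.vcf"
        write_trio_vcf(path, [_record()], TRIO)
        other = Trio("FAM2", "X-C", "X-M", "X-F")
        with pytest.raises(ValueError, match="missing from"):
            read_trio_vcf(path, other)


MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">
##contig=<ID=7>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tFAM1-C\tFAM1-M\tFAM1-F
7\t5000\t.\tA\tG,T\t.\tPASS\t.\tGT:AD:DP\t1/2:2,14,16:32\t0/1:20,18,0:38\t0/2:22,0,19:41
"""


def test_multiallelic_site_decomposes_into_biallelic_records(tmp_path):
    path = tmp_path / "tri.vcf"
    path.write_text(MULTIALLELIC_VCF)
    records = read_trio_vcf(path, TRIO)
    assert len(records) == 2
    g_rec = next(r for r in records if r.alt == "G")
    t_rec = next(r for r in records if r.alt == "T")
    assert (g_rec.chrom, g_rec.pos) == (t_rec.chrom, t_rec.pos) == ("7", 5000)
    # child 1/2: het for each alt; mother 0/1: het for G only
    assert g_rec.child.gt is Genotype.HET and t_rec.child.gt is Genotype.HET
    assert g_rec.mother.gt is Genotype.HET and t_rec.mother.gt is Genotype.HOM_REF
    assert g_rec.father.gt is Genotype.HOM_REF and t_rec.father.gt is Genotype.HET
    # per-allele depths come from the matching AD entries
    assert (g_rec.child.ref_reads, g_rec.child.alt_reads) == (2, 14)
    assert (t_rec.child.ref_reads, t_rec.child.alt_reads) == (2, 16)


class TestPed:
    def test_round_trip(self, tmp_path):
        trios = [TRIO, Trio("FAM2", "FAM2-C", "FAM2-M", "FAM2-F", is_case=False)]
        path = tmp_path / "cohort.ped"
        write_ped(path, trios)
        assert read_ped(path) == trios
        assert len(path.read_text().strip().splitlines()) == 6  # 3 rows per trio

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.ped"
        path.write_text("FAM1\tA\t0\t0\t1\t1\nFAM1\tB\t0\t0\n")
        with pytest.raises(ValueError, match="bad.ped:2"):
            read_ped(path)


class TestGeneSets:
    def test_duplicates_collapsed(self, tmp_path):
        path = tmp_path / "set.tsv"
        path.write_text("gene\nSCN1A\nRYR2\nSCN1A\n")
        gs = read_gene_set(path)
        assert gs.members == ("SCN1A", "RYR2")

    def test_empty_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("gene\n")
        with pytest.raises(ValueError, match="empty"):
            read_gene_set(path)

    def test_round_trip(self, tmp_path):
        gs = GeneSet("acmg", ("RYR2", "TNNI3", "KCNH2"))
        path = tmp_path / "acmg.tsv"
        write_gene_set(path, gs)
        assert read_gene_set(path, "acmg") == gs


def test_rate_table_round_trip(tmp_path):
    table = default_rate_table()
    path = tmp_path / "rates.tsv"
    write_rate_table(path, table)
    back = read_rate_table(path)
    assert back.to_frame().equals(table.to_frame())


class TestAnnotations:
    def _frame(self):
        return pd.DataFrame(
            [
                dict(variant_key="12-2613692-G-A", gene="CACNA1C", effect="missense",
                     score=24.0, clinvar="pathogenic", loeuf=0.2),
            ]
        )

    def test_round_trip(self, tmp_path):
        path = tmp_path / "ann.tsv"
        write_annotations(path, self._frame())
        back = read_annotations(path)
        assert back.iloc[0]["gene"] == "CACNA1C"

    def test_bad_effect_reports_line(self, tmp_path):
        frame = self._frame()
        frame.loc[0, "effect"] = "nonsense-mediated"
        path = tmp_path / "ann.tsv"
        frame.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match=":2"):
            read_annotations(path)


class TestNetwork:
    def test_self_loops_and_duplicates_collapsed(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("gene_a\tgene_b\nA\tB\nB\tA\nA\tA\n")
        g = read_network(path)
        assert g.number_of_edges() == 1
        assert set(g.nodes) == {"A", "B"}

    def test_clique(self, tmp_path):
        path = tmp_path / "net.tsv"
        lines = ["gene_a\tgene_b"]
        nodes = ["A", "B", "C", "D"]
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                lines.append(f"{a}\t{b}")
        path.write_text("\n".join(lines) + "\n")
        g = read_network(path)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 6

    def test_isolated_node_retained_via_node_file(self, tmp_path):
        net = tmp_path / "net.tsv"
        net.write_text("A\tB\n")
        nodes = tmp_path / "nodes.tsv"
        nodes.write_text("gene\nA\nB\nLONER\n")
        g = read_network(net, nodes)
        assert "LONER" in g.nodes and g.degree["LONER"] == 0
        # independent parse: same graph via networkx edge list reader
        ref = nx.read_edgelist(net, delimiter="\t")
        assert set(ref.edges) == set(g.edges)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_network(path)
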