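"""Format readers/writers: validation, error reporting, round-tripping."""

import pytest

from bovitf import data_io
from bovitf.errors import FormatError, RowError
from bovitf.records import DomainHit, GeneRecord, GoAnnotation, InteractionRecord


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGeneDomains:
    def test_rows_group_by_gene(self, tmp_path):
        p = _write(
            tmp_path,
            "g.tsv",
            "gene_id\tbiotype\tinterpro_id\tentry_type\tstart\tend\n"
            "g1\tprotein_coding\tIPR000001\tdomain\t10\t50\n"
            "g1\tprotein_coding\tIPR000002\tdomain\t60\t90\n"
            "g2\tpseudogene\tIPR000003\tfamily\t5\t25\n",
        )
        records = data_io.read_gene_domains(p)
        assert [r.gene_id for r in records] == ["g1", "g2"]
        assert len(records[0].domain_hits) == 2
        assert records[1].biotype == "pseudogene"

    def test_hits_sorted_by_start(self, tmp_path):
        p = _write(
            tmp_path,
            "g.tsv",
            "gene_id\tbiotype\tinterpro_id\tentry_type\tstart\tend\n"
            "g1\tprotein_coding\tIPR000002\tdomain\t60\t90\n"
            "g1\tprotein_coding\tIPR000001\tdomain\t10\t50\n",
        )
        (rec,) = data_io.read_gene_domains(p)
        assert [h.interpro_id for h in rec.domain_hits] == ["IPR000001", "IPR000002"]

    def test_missing_column_names_it(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "gene_id\tbiotype\tinterpro_id\tstart\tend\ng1\tx\ti\t1\t2\n")
        with pytest.raises(FormatError, match="entry_type"):
            data_io.read_gene_domains(p)

    @pytest.mark.parametrize(
        "start,end,match",
        [("ten", "50", "non-integer"), ("50", "10", "invalid interval")],
    )
    def test_bad_coordinates_carry_line_number(self, tmp_path, start, end, match):
        p = _write(
            tmp_path,
            "g.tsv",
            "gene_id\tbiotype\tinterpro_id\tentry_type\tstart\tend\n"
            f"g1\tprotein_coding\tIPR000001\tdomain\t{start}\t{end}\n",
        )
        with pytest.raises(RowError, match="line 2"):
            data_io.read_gene_domains(p)
        with pytest.raises(RowError, match=match):
            data_io.read_gene_domains(p)

    def test_round_trip_identity(self, tmp_path):
        genes = [
            GeneRecord("g1", "protein_coding", domain_hits=(
                DomainHit("IPR000001", "domain", 1, 40),
                DomainHit("IPR000009", "family", 50, 99),
            )),
            GeneRecord("g2", "pseudogene"),  # no domains: empty hit list survives
        ]
        p = tmp_path / "rt.tsv"
        data_io.write_gene_domains(genes, p)
        assert data_io.read_gene_domains(p) == genes


class TestMitab:
    HEADER_LINE = (
        'uniprotkb:{a}\tuniprotkb:{b}\t-\t-\t-\t-\tpsi-mi:"MI:0018"(two hybrid)\t-\t-\t'
        "taxid:9913\ttaxid:9913\t{itype}\tpsi-mi:intact\t-\t-"
    )

    def test_mi_code_extracted(self, tmp_path):
        line = self.HEADER_LINE.format(
            a="P001", b="P002", itype='psi-mi:"MI:0915"(physical association)'
        )
        p = _write(tmp_path, "i.mitab", line + "\n")
        result = data_io.read_mitab(p)
        assert result.records[0].mi_type == "MI:0915"
        assert result.records[0].id_a == "P001"

    def test_empty_file_yields_empty_list(self, tmp_path):
        p = _write(tmp_path, "i.mitab", "")
        result = data_io.read_mitab(p)
        assert result.records == [] and result.n_skipped == 0

    def test_malformed_lines_skipped_and_counted(self, tmp_path):
        good = self.HEADER_LINE.format(
            a="P001", b="P002", itype='psi-mi:"MI:0407"(direct interaction)'
        )
        bad_type = self.HEADER_LINE.format(a="P003", b="P004", itype="garbage")
        lines = [good] * 8 + [bad_type, "too\tfew\tcolumns"]
        p = _write(tmp_path, "i.mitab", "\n".join(lines) + "\n")
        result = data_io.read_mitab(p)
        assert len(result.records) == 8
        assert result.n_skipped == 2

    def test_round_trip(self, tmp_path):
        records = [
            InteractionRecord("P001", "P002", "MI:0915", "intact"),
            InteractionRecord("P003", "P003", "MI:0407", "intact"),  # self-interaction kept
        ]
        p = tmp_path / "rt.mitab"
        data_io.write_mitab(records, p)
        assert data_io.read_mitab(p).records == records


class TestGaf:
    def _gaf_row(self, protein, go_id, aspect, code, qualifier=""):
        return "\t".join(
            ["UniProtKB", protein, protein, qualifier, go_id, "PMID:1", code, "",
             aspect, protein, "", "protein", "taxon:9606", "20170101", "UniProt"]
        )

    def test_aspect_mapped_and_evidence_preserved(self, tmp_path):
        p = _write(
            tmp_path, "a.gaf",
            "!gaf-version: 2.2\n" + self._gaf_row("P1", "GO:0005634", "C", "IDA") + "\n",
        )
        (ann,) = data_io.read_gaf(p)
        assert ann == GoAnnotation("P1", "GO:0005634", "CC", "IDA")

    def test_not_qualified_rows_excluded(self, tmp_path):
        rows = [
            self._gaf_row("P1", "GO:0005634", "C", "IDA", "NOT|located_in"),
            self._gaf_row("P2", "GO:0003713", "F", "IEA", "enables"),
        ]
        p = _write(tmp_path, "a.gaf", "\n".join(rows) + "\n")
        anns = data_io.read_gaf(p)
        assert [a.protein_id for a in anns] == ["P2"]

    def test_unknown_aspect_is_row_error(self, tmp_path):
        p = _write(tmp_path, "a.gaf", self._gaf_row("P1", "GO:1", "Z", "IDA") + "\n")
        with pytest.raises(RowError, match="aspect"):
            data_io.read_gaf(p)

    def test_synthetic_gaf_not_rows_counted(self, tmp_path):
        rows = [self._gaf_row(f"P{i}", "GO:0005634", "C", "IEA") for i in range(45)]
        rows += [self._gaf_row(f"N{i}", "GO:0005634", "C", "IEA", "NOT") for i in range(5)]
        p = _write(tmp_path, "a.gaf", "\n".join(rows) + "\n")
        assert len(data_io.read_gaf(p)) == 45


class TestExpressionMatrix:
    def test_negative_fpkm_rejected(self, tmp_path):
        p = _write(
            tmp_path, "e.tsv",
            "isoform_id\tgene_id\tliver\theart\niso1\tg1\t-1.0\t2.0\n",
        )
        with pytest.raises(FormatError, match="negative"):
            data_io.read_expression_matrix(p)

    def test_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {"gene_id": ["g1", "g1"], "liver": [1.5, 0.0], "heart": [0.0, 3.25]},
            index=pd.Index(["iso1", "iso2"], name="isoform_id"),
        )
        p = tmp_path / "e.tsv"
        data_io.write_expression_matrix(df, p)
        back = data_io.read_expression_matrix(p)
        pd.testing.assert_frame_equal(back, df)


def test_generated_bundle_passes_all_readers(tiny_world):
    """Every file the generator emits is total under its paired reader."""
    _, paths, _ = tiny_world
    data_io.read_gene_domains(paths["genes"])
    data_io.read_gene_domains(paths["human_genes"])
    data_io.read_census(paths["census"])
    data_io.read_updates(paths["census_updates"])
    data_io.read_orthology(paths["orthology"])
    data_io.read_similarity_hits(paths["hits"])
    data_io.read_registry(paths["reference_dbds"])
    data_io.read_domain_function(paths["domain_function"])
    data_io.read_family_map(paths["family_map"])
    data_io.read_clade_map(paths["clade_map"])
    assert data_io.read_mitab(paths["interactions"]).n_skipped == 0
    data_io.read_gaf(paths["annotations"])
    data_io.read_id_mapping(paths["id_mapping"])
    data_io.read_expression_matrix(paths["expression"])
    data_io.read_pairs(paths["pairs"])
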