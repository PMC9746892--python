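"""MITAB parsing, round-trips, dataset summaries and anomaly flags."""

import math

import pytest

from ppintopo.fixtures import make_mitab_fixture
from ppintopo.mitab import (
    InteractionRecord,
    MitabParseError,
    flag_anomalies,
    read_edgelist,
    read_mitab,
    summarize_dataset,
    write_mitab,
)

MITAB25_LINE = (
    "uniprotkb:P04637\tuniprotkb:P38936\t-\t-\t-\t-\t"
    'psi-mi:"MI:0018"(two hybrid)\t-\tpubmed:10999999\t'
    "taxid:9606(human)\ttaxid:9606(human)\t-\t-\tintact:EBI-0000001\t"
    "intact-miscore:0.58"
)


def _write(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadMitab:
    def test_parses_one_record_per_data_line(self, tmp_path):
        path = _write(
            tmp_path,
            "three.tsv",
            ["#header"] + [MITAB25_LINE.replace("P38936", f"P0000{i}") for i in range(3)],
        )
        records = read_mitab(path)
        assert len(records) == 3
        assert [r.id_b for r in records] == ["P00000", "P00001", "P00002"]
        assert all(r.id_a == "P04637" for r in records)

    def test_intact_miscore_field_is_parsed(self, tmp_path):
        path = _write(tmp_path, "score.tsv", [MITAB25_LINE])
        (record,) = read_mitab(path)
        assert record.mi_score == 0.58
        assert record.taxid_a == 9606
        assert record.publication_id == "pubmed:10999999"

    def test_missing_token_maps_to_absent(self, tmp_path):
        line = MITAB25_LINE.replace("intact-miscore:0.58", "-").replace(
            "taxid:9606(human)\ttaxid:9606(human)", "-\t-"
        )
        path = _write(tmp_path, "missing.tsv", [line])
        (record,) = read_mitab(path)
        assert record.mi_score is None
        assert record.taxid_a is None and record.taxid_b is None

    def test_mitab25_has_no_interactor_types(self, tmp_path):
        path = _write(tmp_path, "m25.tsv", [MITAB25_LINE])
        (record,) = read_mitab(path, dialect="mitab25")
        assert record.type_a is None and record.type_b is None

    def test_wrong_column_count_raises_with_line_number(self, tmp_path):
        path = _write(tmp_path, "bad.tsv", [MITAB25_LINE, "only\tthree\tcols"])
        with pytest.raises(MitabParseError) as exc_info:
            read_mitab(path)
        assert exc_info.value.line_number == 2

    def test_malformed_lines_can_be_skipped(self, tmp_path):
        path = _write(tmp_path, "bad.tsv", [MITAB25_LINE, "only\tthree\tcols"])
        assert len(read_mitab(path, on_error="skip")) == 1

    def test_roundtrip_preserves_every_field(self, tmp_path):
        records = [
            InteractionRecord(
                id_a="P00001", id_b="Q99999", interaction_id="intact:EBI-1",
                type_a="protein", type_b="small molecule",
                taxid_a=9606, taxid_b=10090,
                detection_method='psi-mi:"MI:0018"(two hybrid)',
                publication_id="pubmed:123", mi_score=0.44,
            ),
            InteractionRecord(id_a="A", id_b="B"),
        ]
        out = tmp_path / "roundtrip.tsv"
        write_mitab(records, out)
        assert read_mitab(out) == records

    def test_edgelist_fallback(self, tmp_path):
        path = _write(tmp_path, "edges.tsv", ["# comment", "A\tB", "B\tC"])
        records = read_edgelist(path)
        assert [(r.id_a, r.id_b) for r in records] == [("A", "B"), ("B", "C")]
        assert records[0].mi_score is None


class TestRecordInvariants:
    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            InteractionRecord(id_a="A", id_b="B", mi_score=1.5)

    def test_empty_identifier_rejected(self):
        with pytest.raises(ValueError):
            InteractionRecord(id_a="", id_b="B")


class TestSummarize:
    def _records(self):
        return [
            InteractionRecord(id_a="A", id_b="B", type_a="protein", type_b="protein",
                              mi_score=0.4, detection_method="m1", taxid_a=9606),
            InteractionRecord(id_a="A", id_b="C", type_a="protein", type_b="gene",
                              mi_score=0.6, detection_method="m1", taxid_a=9606),
        ]

    def test_score_mean_ignores_absent(self):
        records = self._records() + [InteractionRecord(id_a="X", id_b="Y")]
        assert summarize_dataset(records).score_mean == pytest.approx(0.5)

    def test_type_histogram_counts_interactor_occurrences(self):
        summary = summarize_dataset(self._records())
        assert summary.type_histogram["gene"] == 1
        assert summary.type_histogram["protein"] == 3
        assert sum(summary.type_histogram.values()) == 2 * summary.n_records

    def test_method_and_score_histograms_sum_to_records(self):
        records = self._records() + [InteractionRecord(id_a="X", id_b="Y")]
        summary = summarize_dataset(records)
        assert sum(summary.method_histogram.values()) == summary.n_records
        assert sum(summary.score_histogram.values()) == summary.n_records

    def test_permutation_invariance(self):
        records = self._records() * 3
        forward = summarize_dataset(records)
        backward = summarize_dataset(records[::-1])
        assert forward == backward

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_dataset([])

    def test_all_scores_missing_gives_nan_mean(self):
        summary = summarize_dataset([InteractionRecord(id_a="A", id_b="B")])
        assert math.isnan(summary.score_mean)


class TestFlagAnomalies:
    def test_clean_human_protein_records_raise_no_flags(self):
        records = [
            InteractionRecord(id_a="A", id_b="B", type_a="protein", type_b="protein",
                              taxid_a=9606, taxid_b=9606)
        ]
        report = flag_anomalies(records, 9606)
        assert report.n_non_protein == 0
        assert report.n_non_reference_taxon == 0

    def test_small_molecule_interactor_flagged_once(self):
        records = [
            InteractionRecord(id_a="DRUG", id_b="B", type_a="small molecule",
                              type_b="protein", taxid_a=9606, taxid_b=9606),
            InteractionRecord(id_a="DRUG", id_b="C", type_a="small molecule",
                              type_b="protein", taxid_a=9606, taxid_b=9606),
        ]
        report = flag_anomalies(records, 9606)
        assert report.non_protein == {"DRUG": "small molecule"}

    def test_foreign_taxid_flagged(self):
        records = [
            InteractionRecord(id_a="Prkn", id_b="B", taxid_a=10090, taxid_b=9606,
                              type_a="protein", type_b="protein"),
        ]
        report = flag_anomalies(records, 9606)
        assert report.non_reference_taxon == {"Prkn": 10090}

    def test_absent_taxid_reported_as_unknown(self):
        report = flag_anomalies([InteractionRecord(id_a="A", id_b="B")], 9606)
        assert report.unknown_taxon == ["A", "B"]

    def test_flag_counts_monotone_under_added_records(self):
        base = [
            InteractionRecord(id_a="A", id_b="B", type_a="gene", type_b="protein")
        ]
        extra = base + [
            InteractionRecord(id_a="C", id_b="D", type_a="dsDNA", type_b="protein")
        ]
        assert flag_anomalies(extra, 9606).n_non_protein >= flag_anomalies(base, 9606).n_non_protein


class TestSyntheticMitabEndToEnd:
    def test_fixture_summary_reflects_injected_metadata(self, tmp_path):
        path = tmp_path / "fx.tsv"
        make_mitab_fixture(30, path, n_non_protein=3, n_non_human=2,
                           n_missing_scores=5, seed=3)
        records = read_mitab(path)
        summary = summarize_dataset(records)
        assert summary.n_records == 30
        assert summary.score_histogram["missing"] == 5
        report = flag_anomalies(records, 9606)
        assert report.n_non_protein >= 1
        assert report.n_non_reference_taxon >= 1
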