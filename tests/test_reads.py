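"""Read-table classification: kingdom filter, percentages, class rules."""

import pandas as pd
import pytest

from herbauth import (
    ReadTable,
    classify,
    default_class_map,
    esa_read_table,
    filter_kingdom,
    load_class_map,
    read_percentages,
)


def _table(rows, sample="s1"):
    return ReadTable(sample_id=sample,
                     data=pd.DataFrame(rows, columns=["taxon", "kingdom", "reads"]))


@pytest.fixture(scope="module")
def class_map():
    return default_class_map()


class TestFilterKingdom:
    def test_removes_non_plant_rows(self):
        t = _table([("Origanum vulgare", "Plantae", 100),
                    ("Aspergillus niger", "Fungi", 50),
                    ("Homo sapiens", "Animalia", 5)])
        out = filter_kingdom(t)
        assert out.data["taxon"].tolist() == ["Origanum vulgare"]
        assert out.total_reads == 100

    def test_idempotent(self):
        t = _table([("A", "Plantae", 10), ("B", "Plantae", 20)])
        once = filter_kingdom(t)
        twice = filter_kingdom(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_empty_result_allowed(self):
        t = _table([("Aspergillus niger", "Fungi", 50)])
        assert filter_kingdom(t).total_reads == 0


class TestReadPercentages:
    def test_even_split(self):
        pct = read_percentages(_table([("A", "Plantae", 50), ("B", "Plantae", 50)]))
        assert pct.data["read_pct"].tolist() == [50.0, 50.0]

    def test_zero_count_taxon(self):
        pct = read_percentages(_table([("A", "Plantae", 1), ("B", "Plantae", 0)]))
        assert pct.data["read_pct"].tolist() == [100.0, 0.0]

    def test_retained_denominator_sums_to_100(self):
        pct = read_percentages(esa_read_table())
        assert pct.data["read_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_reference_fixture_bindweed_share(self):
        # the listed rows sum to 13,270 reads; bindweed's 3,771 reads are
        # 28.4% of that retained total
        pct = read_percentages(esa_read_table())
        row = pct.data.set_index("taxon").loc["Convolvulus spp."]
        assert row["reads"] == 3771
        assert pct.denominator_total == 13_270
        assert row["read_pct"] == pytest.approx(100 * 3771 / 13_270, abs=1e-9)
        assert row["read_pct"] == pytest.approx(28.417, abs=5e-3)

    def test_all_denominator_requires_total(self):
        t = _table([("A", "Plantae", 10)])
        with pytest.raises(ValueError):
            read_percentages(t, denominator="all")
        pct = read_percentages(t, denominator="all", all_total=100)
        assert pct.data["read_pct"].tolist() == [10.0]

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            read_percentages(_table([("A", "Plantae", 0)]))


class TestClassMap:
    @pytest.mark.parametrize("taxon,expected", [
        ("Origanum vulgare", "ingredient"),
        ("Origanum majorana", "adulterant"),
        ("Chenopodium album", "contaminant"),
        ("Olea europaea", "adulterant"),
        ("Panax stipuleanatus", "noise"),
    ])
    def test_published_scheme_lookups(self, class_map, taxon, expected):
        assert class_map.lookup(taxon) == expected

    def test_genus_wildcard_fallback(self, class_map):
        # a species absent from the map inherits its genus "spp." entry
        assert class_map.lookup("Chenopodium quinoa") == "contaminant"
        assert class_map.lookup("Cistus incanus") == "adulterant"

    def test_case_and_whitespace_normalisation(self, class_map):
        assert class_map.lookup("  olea   EUROPAEA ") == "adulterant"

    def test_unknown_taxon_none(self, class_map):
        assert class_map.lookup("Quercus robur") is None

    def test_malformed_class_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("taxon\tclass_label\nOlea europaea\tbulking\n")
        with pytest.raises(ValueError):
            load_class_map(bad)


class TestClassify:
    def test_adulterant_any_reads_confirmed(self, class_map):
        # an adulterant at well under 1% of reads still goes to ddPCR
        t = _table([("Olea europaea", "Plantae", 4),
                    ("Origanum vulgare", "Plantae", 996)])
        out = classify(read_percentages(t), class_map)
        row = out.data.set_index("taxon").loc["Olea europaea"]
        assert row["class_label"] == "adulterant"
        assert row["action"] == "confirm_ddPCR"
        assert row["read_pct"] < 1.0

    def test_contaminant_rule_strictly_above_threshold(self, class_map):
        # 3% bindweed: low-read contaminant, no confirmation; and exactly
        # 5.0% still counts as low (the rule is strictly greater-than)
        for conv_reads, total in ((30, 1000), (50, 1000)):
            t = _table([("Convolvulus spp.", "Plantae", conv_reads),
                        ("Origanum vulgare", "Plantae", total - conv_reads)])
            out = classify(read_percentages(t), class_map)
            assert out.data.set_index("taxon").loc["Convolvulus spp.", "action"] \
                == "none"
        t = _table([("Convolvulus spp.", "Plantae", 51),
                    ("Origanum vulgare", "Plantae", 949)])
        out = classify(read_percentages(t), class_map)
        assert out.data.set_index("taxon").loc["Convolvulus spp.", "action"] \
            == "confirm_ddPCR"

    def test_noise_never_confirmed(self, class_map):
        t = _table([("Panax stipuleanatus", "Plantae", 800),
                    ("Origanum vulgare", "Plantae", 200)])
        out = classify(read_percentages(t), class_map)
        assert out.data.set_index("taxon").loc["Panax stipuleanatus", "action"] \
            == "none"

    def test_unknown_taxon_defaults_to_noise_with_flag(self, class_map):
        t = _table([("Quercus robur", "Plantae", 10),
                    ("Origanum vulgare", "Plantae", 90)])
        out = classify(read_percentages(t), class_map)
        assert out.data.set_index("taxon").loc["Quercus robur", "class_label"] \
            == "noise"
        assert "unmapped_taxa" in out.flags


class TestReferenceFixture:
    def test_detected_adulterant_set(self, class_map):
        # in the quality-control blend, exactly four adulterant-class taxa
        # carry reads; sumac (an adulterant-class species) has zero reads
        out = classify(read_percentages(filter_kingdom(esa_read_table())),
                       class_map)
        df = out.data
        detected = set(df.loc[(df["class_label"] == "adulterant")
                              & (df["reads"] >= 1), "taxon"])
        assert detected == {"Cistus spp.", "Myrtus communis",
                            "Olea europaea", "O. majorana"}
        sumac = df.set_index("taxon").loc["Rhus coriaria"]
        assert sumac["reads"] == 0 and sumac["action"] == "none"

    def test_elevated_contaminants_flagged(self, class_map):
        out = classify(read_percentages(filter_kingdom(esa_read_table())),
                       class_map)
        df = out.data.set_index("taxon")
        confirmed = set(df.loc[df["action"] == "confirm_ddPCR"].index)
        # every >5% contaminant and every detected adulterant, nothing else
        contaminants_above = set(
            df.loc[(df["class_label"] == "contaminant")
                   & (df["read_pct"] > 5.0)].index)
        adulterants_detected = set(
            df.loc[(df["class_label"] == "adulterant") & (df["reads"] >= 1)].index)
        assert confirmed == contaminants_above | adulterants_detected
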