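"""Ingest: fixture validation, web assembly, round trips."""

import numpy as np
import pandas as pd
import pytest

from quillnet.ingest import (
    InteractionWeb,
    OccurrenceRecord,
    build_web,
    load_tables,
    normalize_habitat,
)


class TestLoadTables:
    def test_taxon_counts(self, tables):
        assert len(tables.mites) == 25
        # hosts fixture covers all recorded hosts incl. parrots and the
        # jambu record that carries counts but sits outside the web
        assert len(tables.hosts) >= 66

    def test_afrotropical_treron_record_present(self, tables):
        recs = [
            r
            for r in tables.interactions
            if r.mite == "Meitingsunes columbicus" and r.host == "Treron waalia"
        ]
        assert len(recs) == 1
        assert "Afro" in recs[0].regions

    def test_unknown_counts_preserved_as_missing(self, tables):
        nas = [r for r in tables.occurrences if r.examined is None]
        assert nas, "literature rows without prevalence must survive ingest"
        assert all(r.infested is None for r in nas)

    def test_empty_occurrence_file_is_identity_case(self, tmp_path, tables):
        import shutil
        from quillnet.ingest import data_path

        for name in ("mites", "hosts", "interactions", "niches", "noninfested"):
            shutil.copy(data_path(f"{name}.tsv"), tmp_path / f"{name}.tsv")
        (tmp_path / "occurrences.tsv").write_text(
            "host\texamined\tinfested\tip\tci_low\tci_high\tmite\thabitat\tnote\n"
        )
        t = load_tables(tmp_path)
        assert t.occurrences == []

    def test_duplicate_rows_deduplicated_against_line_scan(self, tmp_path):
        import shutil
        from quillnet.ingest import data_path

        for name in ("mites", "hosts", "interactions", "niches", "noninfested"):
            shutil.copy(data_path(f"{name}.tsv"), tmp_path / f"{name}.tsv")
        src = data_path("occurrences.tsv").read_text().splitlines()
        doubled = src + src[1:]
        (tmp_path / "occurrences.tsv").write_text("\n".join(doubled) + "\n")
        t = load_tables(tmp_path)
        # oracle: unique (mite, host, habitat) triples from a naive scan
        naive = set()
        for line in src[1:]:
            f = line.split("\t")
            naive.add((f[6], f[0], normalize_habitat(f[7])))
        assert len(t.occurrences) == len(naive)

    def test_subfamily_contradiction_rejected(self, tmp_path):
        import shutil
        from quillnet.ingest import data_path

        for name in ("hosts", "interactions", "occurrences", "niches", "noninfested"):
            shutil.copy(data_path(f"{name}.tsv"), tmp_path / f"{name}.tsv")
        text = data_path("mites.tsv").read_text().replace(
            "Gunabopicobia zumpti\tGunabopicobia\tPicobiinae",
            "Gunabopicobia zumpti\tGunabopicobia\tSyringophilinae",
        )
        (tmp_path / "mites.tsv").write_text(text)
        with pytest.raises(ValueError, match="Picobiinae"):
            load_tables(tmp_path)


class TestHabitatNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("under-tail cov.", ("under-tail covert",)),
            ("coverts", ("covert",)),
            ("under and upper-tail cov.", ("under-tail covert", "upper-tail covert")),
            ("secondaries, covert", ("secondaries", "covert")),
            ("-", ("unknown",)),
        ],
    )
    def test_synonym_map(self, raw, expected):
        assert normalize_habitat(raw) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            normalize_habitat("down feathers")


class TestBuildWeb:
    def test_dimensions_match_survey(self, web, tables):
        assert web.shape == (25, 65)
        full = build_web(
            tables.interactions, tables.occurrences, hosts=tables.hosts,
            include_parrots=True,
        )
        assert full.shape == (25, 68)

    def test_counted_weight_uses_infested_column(self, tables):
        cweb = build_web(
            tables.interactions, tables.occurrences, hosts=tables.hosts, weighting="counts"
        )
        i = cweb.parasites.index("Peristerophila mucuya")
        j = cweb.hosts.index("Columbina talpacoti")
        assert cweb.W[i, j] == 8

    def test_literature_only_records_score_one(self, counts_web):
        i = counts_web.parasites.index("Gunabopicobia zumpti")
        j = counts_web.hosts.index("Streptopelia capicola")
        assert counts_web.W[i, j] == 1

    def test_every_mite_species_is_a_row(self, web, tables):
        assert sorted(web.parasites) == sorted(tables.mites)

    def test_marginal_totals_consistent(self, web):
        assert web.row_totals.sum() == pytest.approx(web.col_totals.sum())
        assert web.row_totals.sum() == pytest.approx(web.total)

    def test_round_trip_tsv(self, web, tmp_path):
        path = tmp_path / "web.tsv"
        web.write_tsv(path)
        again = InteractionWeb.read_tsv(path)
        assert again.parasites == web.parasites
        assert again.hosts == web.hosts
        np.testing.assert_allclose(again.W, web.W)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            InteractionWeb(["a", "b"], ["x"], np.array([[1.0], [0.0]]))

    def test_unknown_taxon_raises_key_error(self, tables):
        from quillnet.ingest import InteractionRecord

        recs = list(tables.interactions) + [InteractionRecord("Gunabopicobia zumpti", "Nosuchbird x")]
        with pytest.raises(KeyError):
            build_web(recs, hosts=tables.hosts)

    def test_no_double_counting_of_literature_records(self, tables, counts_web):
        # pairs observed with counts must not gain the literature score
        i = counts_web.parasites.index("Peristerophila columbae")
        j = counts_web.hosts.index("Streptopelia turtur")
        assert counts_web.W[i, j] == 4  # counted infested individuals only
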