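"""Capability profiling: parsing, detectors, determinism, oracle equivalence."""

import numpy as np
import pytest

import becath as b
from becath.capability_profiler import AnnotationParseError, GeneRecord

from .oracle import (
    oracle_cr_verdicts,
    oracle_crispr_present,
    oracle_dehalogenase_counts,
    oracle_hydrogenases,
    oracle_m00122,
    oracle_m00567,
    oracle_m00924,
)


class TestParsing:
    def test_empty_file_parses_to_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert b.parse_annotation(path) == []

    def test_tsv_round_trip(self, tmp_path):
        records = [
            GeneRecord("L1", "rdha", "reductive dehalogenase", 99.6, "33"),
            GeneRecord("L2", "", "hypothetical protein"),
            GeneRecord("L3", "cas3", "CRISPR-associated helicase Cas3", 96.65),
        ]
        path = tmp_path / "three.tsv"
        b.write_feature_tsv(records, path)
        assert b.parse_annotation(path) == records

    def test_transcribed_inventory_parses_to_29_records(self, dehalogenase_records):
        assert len(dehalogenase_records) == 29

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("locus_id\tgene\tproduct\nL1-only-one-field\n")
        with pytest.raises(AnnotationParseError, match=":2:"):
            b.parse_annotation(path)

    def test_duplicate_locus_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("L1\trdha\tx\nL1\trdha\ty\n")
        with pytest.raises(AnnotationParseError, match="duplicate"):
            b.parse_annotation(path)

    def test_gff3_dialect(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "ctg1\tannot\tgene\t1\t900\t.\t+\t.\tID=gene1\n"
            "ctg1\tannot\tCDS\t1\t900\t.\t+\t0\t"
            "ID=cds1;Parent=gene1;locus_tag=L1;gene=rdhA;product=reductive dehalogenase\n"
            "ctg1\tannot\tCDS\t1000\t1500\t.\t+\t0\t"
            "ID=cds2;locus_tag=L2;product=hypothetical protein\n"
        )
        path = tmp_path / "g.gff3"
        path.write_text(gff)
        records = b.parse_annotation(path, dialect="gff3")
        assert [r.locus_id for r in records] == ["L1", "L2"]
        assert records[0].gene_symbol == "rdha"

    def test_identity_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="percent_identity"):
            GeneRecord("L1", "", "x", 140.0)


class TestDehalogenases:
    def test_transcribed_inventory_counts(self, dehalogenase_records):
        counts = b.classify_dehalogenases(dehalogenase_records)
        assert counts == {
            "catalytic_rdhA": 13,
            "anchor_rdhB": 1,
            "hypothetical_dehalogenase": 14,
            "haloacid_dehalogenase": 1,
            "total": 29,
        }

    def test_no_dehalogenase_keywords_all_zero(self):
        records = [GeneRecord("L1", "gyra", "DNA gyrase subunit A")]
        assert b.classify_dehalogenases(records)["total"] == 0

    def test_anchor_precedence_over_catalytic(self):
        record = GeneRecord(
            "L1", "", "reductive dehalogenase membrane-anchoring subunit RdhB"
        )
        counts = b.classify_dehalogenases([record])
        assert counts["anchor_rdhB"] == 1 and counts["catalytic_rdhA"] == 0

    def test_each_record_counted_once(self, dehalogenase_records):
        counts = b.classify_dehalogenases(dehalogenase_records)
        assert counts["total"] == sum(
            v for k, v in counts.items() if k != "total"
        ) <= len(dehalogenase_records)


class TestCrispr:
    def test_transcribed_fixture_present_with_four_cas_hits(self, crispr_records):
        verdict = b.detect_crispr_cas(crispr_records)
        assert verdict["present"] is True
        assert len(verdict["gene_hits"]) == 4
        assert verdict["auxiliary_hits"] == ["MBF4482400"]

    def test_lexa_alone_is_not_sufficient(self):
        records = [GeneRecord("L1", "", "LexA family transcriptional regulator")]
        verdict = b.detect_crispr_cas(records)
        assert verdict["present"] is False
        assert verdict["auxiliary_hits"] == ["L1"]

    def test_empty_genome_absent(self):
        assert b.detect_crispr_cas([])["present"] is False


class TestPathwayCompleteness:
    def test_downstream_cobalamin_complete(self, cobalamin_records, marker_catalogs):
        assert (
            b.pathway_completeness(cobalamin_records, marker_catalogs["m00122"]) == 1.0
        )

    def test_upstream_counts_cbi_genes_without_forcing_verdict(
        self, cobalamin_records, marker_catalogs
    ):
        # cbiD, cbiE plus the four ring-methylation cob genes: 6 of 16 blocks
        up = b.pathway_completeness(cobalamin_records, marker_catalogs["m00924"])
        assert up == pytest.approx(6 / 16)

    def test_removing_one_block_gene_lowers_by_one_over_n(
        self, cobalamin_records, marker_catalogs
    ):
        cat = marker_catalogs["m00122"]
        n = len(cat.blocks)
        without_cobn = [r for r in cobalamin_records if r.gene_symbol != "cobn"]
        assert b.pathway_completeness(without_cobn, cat) == pytest.approx(1 - 1 / n)

    def test_empty_catalog_rejected(self):
        from becath.capability_profiler import MarkerCatalog

        with pytest.raises(ValueError, match="blocks"):
            b.pathway_completeness([], MarkerCatalog(name="empty"))

    def test_methanogen_complement_is_complete(self, methanogen_records):
        assert b.methanogenesis_completeness(methanogen_records) == 1.0

    def test_mcr_block_removal_counts(self, methanogen_records, marker_catalogs):
        n = len(marker_catalogs["m00567"].blocks)
        without_mcr = [
            r for r in methanogen_records if not r.gene_symbol.startswith("mcr")
        ]
        assert b.methanogenesis_completeness(without_mcr) == pytest.approx(1 - 1 / n)

    def test_dechlorinator_methanogenesis_incomplete(self, dmccartyi_genome):
        assert b.methanogenesis_completeness(dmccartyi_genome) < 1.0

    def test_btuf_transport_detected(self, cobalamin_records):
        assert b.cobalamin_verdict(cobalamin_records)["btuF_transport"] is True


class TestHydrogenases:
    def test_transcribed_fixture_has_five_complexes_and_no_hup(
        self, hydrogenase_records
    ):
        found = b.detect_hydrogenase_complexes(hydrogenase_records)
        assert found == {"Hyp", "Hyc", "Hym", "Vhu", "Ech"}
        assert "Hup" not in found

    def test_fused_symbol_does_not_leak_into_hup(self):
        record = GeneRecord("L1", "hypC/hybG/hupF", "hydrogenase formation chaperone")
        assert b.detect_hydrogenase_complexes([record]) == {"Hyp"}

    def test_hup_detected_when_planted(self):
        record = GeneRecord("L1", "hupL", "uptake hydrogenase large subunit")
        assert b.detect_hydrogenase_complexes([record]) == {"Hup"}

    def test_empty_genome(self):
        assert b.detect_hydrogenase_complexes([]) == set()


class TestCrReduction:
    def test_methanogen_with_full_machinery(self):
        records = b.generate_genome("m_formicicum_like", n_decoys=10, seed=0)
        verdict = b.cr_reduction_verdict(records)
        assert verdict["extracellular"] is True
        assert verdict["intracellular"] is True
        assert len(verdict["evidence"]["abc_atp_dependent"]) == 16
        assert len(verdict["evidence"]["abc_permeases"]) == 17

    def test_methanogen_without_cytochrome_or_reductase(self):
        records = b.generate_genome("m_arboriphilus_like", n_decoys=10, seed=0)
        verdict = b.cr_reduction_verdict(records)
        assert verdict["extracellular"] is False  # mtrCAB but no cytochrome
        assert verdict["intracellular"] is False  # ABC system but no npdG
        assert all(verdict["evidence"]["mtrCAB"].values())

    def test_empty_genome_both_false(self):
        verdict = b.cr_reduction_verdict([])
        assert verdict["extracellular"] is False
        assert verdict["intracellular"] is False


class TestProfileGenome:
    def test_dechlorinator_synthesis(self, dmccartyi_genome):
        report = b.profile_genome(dmccartyi_genome, genome_id="dmccartyi")
        assert report.dehalogenase_inventory["total"] == 29
        assert report.crispr["present"] is True
        assert report.cobalamin["downstream_M00122_completeness"] == 1.0
        assert report.methanogenesis_M00567_completeness < 1.0
        assert report.cr_reduction["extracellular"] is False
        assert report.cr_reduction["intracellular"] is False

    def test_empty_genome_all_negative(self):
        report = b.profile_genome([], genome_id="empty")
        assert report.dehalogenase_inventory["total"] == 0
        assert report.crispr["present"] is False
        assert report.hydrogenase_complexes == []
        assert report.methanogenesis_M00567_completeness == 0.0

    def test_json_round_trip(self, dmccartyi_genome):
        report = b.profile_genome(dmccartyi_genome)
        back = b.CapabilityReport.from_json(report.to_json())
        assert back == report

    def test_order_independence(self, dmccartyi_genome):
        report = b.profile_genome(dmccartyi_genome)
        reversed_report = b.profile_genome(list(reversed(dmccartyi_genome)))
        assert report.to_json() == reversed_report.to_json()


def _random_genome(rng, pool, max_records=50):
    n = int(rng.integers(0, max_records + 1))
    picks = rng.integers(0, len(pool), size=n)
    return [
        GeneRecord(f"R{i:04d}", pool[j][0], pool[j][1]) for i, j in enumerate(picks)
    ]


class TestOracleEquivalence:
    def test_profiler_matches_brute_force_oracle(self, marker_pool, marker_catalogs):
        """On random small genomes, every verdict equals an independently
        coded naive re-scan."""
        rng = np.random.default_rng(20240917)
        for _ in range(100):
            records = _random_genome(rng, marker_pool)
            report = b.profile_genome(records, marker_catalogs)
            assert report.dehalogenase_inventory == oracle_dehalogenase_counts(records)
            assert report.crispr["present"] == oracle_crispr_present(records)
            assert report.cobalamin["downstream_M00122_completeness"] == pytest.approx(
                oracle_m00122(records)
            )
            assert report.cobalamin["upstream_M00924_completeness"] == pytest.approx(
                oracle_m00924(records)
            )
            assert report.methanogenesis_M00567_completeness == pytest.approx(
                oracle_m00567(records)
            )
            assert set(report.hydrogenase_complexes) == oracle_hydrogenases(records)
            extra, intra = oracle_cr_verdicts(records)
            assert report.cr_reduction["extracellular"] == extra
            assert report.cr_reduction["intracellular"] == intra


class TestMonotonicity:
    def test_adding_records_never_weakens_verdicts(self, marker_pool, marker_catalogs):
        rng = np.random.default_rng(4242)
        for _ in range(200):
            base = _random_genome(rng, marker_pool, max_records=30)
            extra = [
                GeneRecord(f"X{i:04d}", s, p)
                for i, (s, p) in enumerate(
                    marker_pool[j] for j in rng.integers(0, len(marker_pool), size=5)
                )
            ]
            before = b.profile_genome(base, marker_catalogs)
            after = b.profile_genome(base + extra, marker_catalogs)
            for key, value in before.dehalogenase_inventory.items():
                assert after.dehalogenase_inventory[key] >= value
            assert after.crispr["present"] >= before.crispr["present"]
            for key in (
                "upstream_M00924_completeness",
                "downstream_M00122_completeness",
            ):
                assert after.cobalamin[key] >= before.cobalamin[key]
            assert after.cobalamin["btuF_transport"] >= before.cobalamin["btuF_transport"]
            assert (
                after.methanogenesis_M00567_completeness
                >= before.methanogenesis_M00567_completeness
            )
            assert set(after.hydrogenase_complexes) >= set(
                before.hydrogenase_complexes
            )
            for route in ("extracellular", "intracellular"):
                assert after.cr_reduction[route] >= before.cr_reduction[route]
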