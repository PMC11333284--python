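import pytest

from rareburden.cohort_db import Transcript, Variant
from rareburden.region_analysis import (
    classify_inheritance,
    highlight_regions,
    map_to_cdna,
    per_base_table,
)

PLUS = Transcript("G", "TX", "chr1", 1001, 1141, "+")
MINUS = Transcript("G", "TX", "chr1", 1001, 1141, "-")


def _var(pos, ref, alt):
    return Variant("chr1", pos, ref, alt, "G", "TX", 1, 100, 1e-6)


class TestMapToCdna:
    def test_plus_strand_snv_at_span_start(self):
        cv = map_to_cdna(_var(1001, "A", "G"), PLUS)
        assert (cv.n_start, cv.n_end, cv.kind) == (1, 1, "substitution")
        assert cv.hgvs_n == "n.1A>G"

    def test_minus_strand_snv_at_genomic_start_maps_to_transcript_end(self):
        cv = map_to_cdna(_var(1001, "A", "G"), MINUS)
        assert cv.n_start == MINUS.length == 141
        assert cv.hgvs_n == "n.141T>C"  # complemented alleles

    @pytest.mark.parametrize("tx", [PLUS, MINUS])
    def test_substitution_round_trip(self, tx):
        for gpos in (1001, 1050, 1141):
            cv = map_to_cdna(_var(gpos, "A", "G"), tx)
            if tx.strand == "+":
                back = tx.start + cv.n_start - 1
            else:
                back = tx.end - cv.n_start + 1
            assert back == gpos

    def test_minus_strand_insertion_renders_canonical_name(self):
        # insertion between cDNA 64 and 65 on the minus strand: genomic anchor
        # at end - 64, inserted base reverse-complemented
        seq = "G" * 141  # no T downstream: no 3' shift possible
        pos = MINUS.end - 64
        cv = map_to_cdna(_var(pos, "C", "CA"), MINUS, sequence=seq)
        assert cv.hgvs_n == "n.64_65insT"
        assert list(cv.footprint) == [64]

    def test_insertion_right_shifts_through_homopolymer(self):
        #        123456789
        seq = "ACGTTTTACG" + "A" * 131
        # inserting T before the TTTT run (after base 3) must shift to after base 7
        pos = PLUS.start + 3 - 1
        cv = map_to_cdna(_var(pos, "G", "GT"), PLUS, sequence=seq)
        assert cv.hgvs_n == "n.7_8insT"

    def test_deletion_right_shifts_and_spans(self):
        seq = "ACGTTTTACG" + "A" * 131
        # deleting the first T of the run normalizes to the last T (base 7)
        pos = PLUS.start + 3 - 1  # anchor G at base 3, deletes base 4
        cv = map_to_cdna(_var(pos, "GT", "G"), PLUS, sequence=seq)
        assert cv.hgvs_n == "n.7del"
        # multi-base deletion without shift context
        cv2 = map_to_cdna(_var(PLUS.start + 7, "ACG", "A"), PLUS)
        assert cv2.kind == "deletion" and (cv2.n_start, cv2.n_end) == (9, 10)
        assert cv2.hgvs_n == "n.9_10del"

    def test_delins(self):
        cv = map_to_cdna(_var(1010, "AC", "TG"), PLUS)
        assert cv.kind == "delins"
        assert cv.hgvs_n == "n.10_11delinsTG"

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError):
            map_to_cdna(_var(2000, "A", "G"), PLUS)


class TestClassifyInheritance:
    @pytest.mark.parametrize(
        "child,mother,father,expected,de_novo",
        [
            (1, 0, 0, "de_novo", True),
            (1, 1, 0, "inherited_maternal", False),
            (1, 0, 1, "inherited_paternal", False),
            (1, 0, None, "unknown", False),
            (1, None, 0, "unknown", False),
            (2, None, None, "unknown", False),
        ],
    )
    def test_truth_table(self, child, mother, father, expected, de_novo):
        call = classify_inheritance(child, mother, father)
        assert call.call == expected
        assert call.de_novo_origin == de_novo

    def test_mosaic_override_keeps_de_novo_origin(self):
        call = classify_inheritance(1, 0, 0, mosaic_overrides={"father"})
        assert call.call == "mosaic_parent"
        assert call.de_novo_origin

    def test_non_carrier_child_rejected(self):
        for gt in (0, None):
            with pytest.raises(ValueError):
                classify_inheritance(gt, 0, 0)


class TestPerBaseTable:
    def test_counts_and_naa(self, region_cohort):
        _, db, truth = region_cohort
        seq = truth["genes"]["RNUT1"]["sequence"]
        table = per_base_table(db, "RNUT1", 1e-4, sequence=seq).df
        # insertion (3 carriers) at its left flank 64, SNV (2 carriers) at 65
        assert table.loc[64, "affected_de_novo"] == 3
        assert table.loc[65, "affected_de_novo"] == 2
        assert table.loc[65, "naa"] == 1 and table.loc[64, "naa"] == 1
        assert table.loc[76, "affected_de_novo"] == 2
        for b in (61, 71, 72, 80):
            assert table.loc[b, "unaffected"] == 1
        # no carriers at all outside the constructed bases
        assert table.loc[100:141].sum().sum() == 0

    def test_affected_strata_sum_to_affected_carriers(self, small_cohort):
        _, db, truth = small_cohort
        gene = truth["causal_gene"]
        seq = truth["genes"][gene]["sequence"]
        table = per_base_table(db, gene, 1e-4, sequence=seq).df
        strata = ["affected_de_novo", "affected_inherited", "affected_unknown"]
        affected_total = table[strata].sum(axis=1)
        # recompute total affected carriers per base independently
        from rareburden.region_analysis import map_to_cdna as mc

        tx = db.transcripts[gene]
        expected = {b: 0 for b in range(1, tx.length + 1)}
        for v in db.gene_variants(gene):
            if v.pmaf >= 1e-4:
                continue
            cv = mc(v, tx, seq)
            for pid in db.carriers(v.key):
                if db.participants[pid].affected:
                    for b in cv.footprint:
                        expected[b] += 1
        for b, n in expected.items():
            assert affected_total.loc[b] == n

    def test_no_variants_gives_zero_table(self, small_cohort):
        _, db, _ = small_cohort
        from rareburden.cohort_db import Transcript

        db.transcripts["EMPTY2"] = Transcript("EMPTY2", "TXE2", "chr9", 1, 50, "+")
        table = per_base_table(db, "EMPTY2", 1e-4).df
        assert len(table) == 50 and table.sum().sum() == 0
        del db.transcripts["EMPTY2"]

    def test_masked_parent_yields_unknown_stratum(self, small_cohort):
        _, db, truth = small_cohort
        gene = truth["causal_gene"]
        masked = {
            pid: c for pid, c in truth["carriers"].items()
            if c["masked_parents"] and c["affected"]
        }
        if not masked:
            pytest.skip("no masked-parent carrier in this bundle")
        seq = truth["genes"][gene]["sequence"]
        table = per_base_table(db, gene, 1e-4, sequence=seq).df
        assert table["affected_unknown"].sum() >= len(masked)


class TestHighlightRegions:
    def test_reproduces_two_hotspot_intervals(self, region_cohort):
        _, db, truth = region_cohort
        seq = truth["genes"]["RNUT1"]["sequence"]
        table = per_base_table(db, "RNUT1", 1e-4, sequence=seq)
        regions = highlight_regions(table, truth["seed_bases"])
        assert regions == [tuple(r) for r in truth["expected_regions"]]
        assert regions == [(62, 70), (73, 79)]

    def test_no_unaffected_anywhere_gives_full_span(self, small_cohort):
        _, db, _ = small_cohort
        from rareburden.cohort_db import Transcript
        from rareburden.region_analysis import PerBaseTable
        import pandas as pd

        tx = Transcript("T", "TX", "chr9", 1, 30, "+")
        df = pd.DataFrame(
            0,
            index=pd.RangeIndex(1, 31, name="base"),
            columns=["affected_de_novo", "affected_inherited", "affected_unknown",
                     "unaffected", "naa"],
        )
        table = PerBaseTable(tx, df)
        assert highlight_regions(table, [10]) == [(1, 30)]

    def test_two_seeds_in_one_clean_stretch_merge(self, region_cohort):
        _, db, truth = region_cohort
        seq = truth["genes"]["RNUT1"]["sequence"]
        table = per_base_table(db, "RNUT1", 1e-4, sequence=seq)
        assert highlight_regions(table, [63, 68]) == [(62, 70)]

    def test_seed_with_unaffected_carriers_rejected(self, region_cohort):
        _, db, truth = region_cohort
        seq = truth["genes"]["RNUT1"]["sequence"]
        table = per_base_table(db, "RNUT1", 1e-4, sequence=seq)
        with pytest.raises(ValueError):
            highlight_regions(table, [71])

    def test_output_intervals_disjoint_sorted_and_seeded(self, region_cohort):
        _, db, truth = region_cohort
        seq = truth["genes"]["RNUT1"]["sequence"]
        table = per_base_table(db, "RNUT1", 1e-4, sequence=seq)
        seeds = [64, 76, 78]
        regions = highlight_regions(table, seeds)
        for (a1, b1), (a2, b2) in zip(regions, regions[1:]):
            assert b1 < a2  # disjoint and sorted
        for lo, hi in regions:
            assert any(lo <= s <= hi for s in seeds)
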