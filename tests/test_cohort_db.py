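import math

import pytest
from cyvcf2 import VCF
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import beta as beta_dist

from rareburden.cohort_db import (
    CohortDB,
    build_db,
    compute_pmaf,
    impute_class_term,
    nda_affected,
    qualifying_variants,
    select_cases_controls,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000000>\n"
    '##INFO=<ID=EXTAC,Number=A,Type=Integer,Description="ext ac">\n'
    '##INFO=<ID=EXTAN,Number=1,Type=Integer,Description="ext an">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_inputs(tmp_path, vcf_body, ped_rows, pheno_rows, transcripts):
    samples = sorted({r[1] for r in ped_rows})
    vcf = tmp_path / "c.vcf"
    header_samples = vcf_body.pop("samples")
    vcf.write_text(
        VCF_HEADER
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(header_samples)
        + "\n"
        + "".join(vcf_body["records"])
    )
    ped = tmp_path / "c.ped"
    ped.write_text("".join("\t".join(map(str, r)) + "\n" for r in ped_rows))
    pheno = tmp_path / "c.tsv"
    lines = ["participant_id\thpo_terms\ticd10\tclasses\tsolved_status\n"]
    for r in pheno_rows:
        lines.append("\t".join(r) + "\n")
    pheno.write_text("".join(lines))
    tx = tmp_path / "t.tsv"
    tx_lines = ["gene\ttranscript_id\tchrom\tstart\tend\tstrand\n"]
    for r in transcripts:
        tx_lines.append("\t".join(map(str, r)) + "\n")
    tx.write_text("".join(tx_lines))
    return vcf, ped, pheno, tx


@pytest.fixture
def trio_inputs(tmp_path):
    ped = [
        ("FAM1", "S1", "S2", "S3", 1, 2),
        ("FAM1", "S2", 0, 0, 1, 1),
        ("FAM1", "S3", 0, 0, 2, 1),
    ]
    pheno = [
        ("S1", "TO:0000101", "", "ID", "unsolved"),
        ("S2", "", "", "", "unknown"),
        ("S3", "", "", "", "unknown"),
    ]
    tx = [("G1", "TX1", "chr1", 100, 240, "+")]
    body = {
        "samples": ["S1", "S2", "S3"],
        "records": [
            "chr1\t150\t.\tA\tG\t.\tPASS\tEXTAC=0;EXTAN=100000\tGT\t0/1\t0/0\t0/0\n",
            "chr1\t500\t.\tC\tT\t.\tPASS\tEXTAC=0;EXTAN=100000\tGT\t0/1\t0/0\t0/0\n",
        ],
    }
    return write_inputs(tmp_path, body, ped, pheno, tx)


class TestBuildDb:
    def test_in_span_variant_stored_sparsely(self, trio_inputs):
        db = build_db(*trio_inputs)
        assert len(db.variants) == 1
        v = next(iter(db.variants.values()))
        assert (v.chrom, v.pos, v.ref, v.alt, v.gene) == ("chr1", 150, "A", "G", "G1")
        assert db.genotypes[v.key] == {"S1": 1}
        assert v.ac == 1 and v.an == 6

    def test_out_of_span_variant_dropped(self, trio_inputs):
        db = build_db(*trio_inputs)
        assert all(v.pos != 500 for v in db.variants.values())

    def test_vcf_sample_missing_from_ped_rejected(self, tmp_path):
        ped = [("FAM1", "S1", 0, 0, 1, 2)]
        pheno = [("S1", "", "", "ID", "unsolved")]
        tx = [("G1", "TX1", "chr1", 100, 240, "+")]
        body = {
            "samples": ["S1", "SX"],
            "records": [
                "chr1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\n",
            ],
        }
        files = write_inputs(tmp_path, body, ped, pheno, tx)
        with pytest.raises(ValueError, match="SX"):
            build_db(*files)

    def test_non_pass_record_skipped(self, tmp_path):
        ped = [("FAM1", "S1", 0, 0, 1, 2)]
        pheno = [("S1", "", "", "ID", "unsolved")]
        tx = [("G1", "TX1", "chr1", 100, 240, "+")]
        body = {
            "samples": ["S1"],
            "records": [
                "chr1\t150\t.\tA\tG\t.\tLowQual\t.\tGT\t0/1\n",
            ],
        }
        db = build_db(*write_inputs(tmp_path, body, ped, pheno, tx))
        assert not db.variants

    def test_missing_genotype_recorded(self, tmp_path):
        ped = [("FAM1", "S1", 0, 0, 1, 2), ("FAM2", "S2", 0, 0, 1, 1)]
        pheno = [("S1", "", "", "ID", "unsolved"), ("S2", "", "", "", "unknown")]
        tx = [("G1", "TX1", "chr1", 100, 240, "+")]
        body = {
            "samples": ["S1", "S2"],
            "records": ["chr1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t./.\n"],
        }
        db = build_db(*write_inputs(tmp_path, body, ped, pheno, tx))
        v = next(iter(db.variants.values()))
        assert db.genotypes[v.key]["S2"] is None
        assert db.dosage("S2", v.key, missing_as=0) == 0
        assert db.dosage("S2", v.key, missing_as=None) is None
        assert v.an == 2  # only S1 called

    def test_multiallelic_decomposes_like_presplit(self, tmp_path):
        ped = [("F1", "S1", 0, 0, 1, 2), ("F2", "S2", 0, 0, 1, 1), ("F3", "S3", 0, 0, 1, 1)]
        pheno = [("S1", "", "", "ID", "unsolved")] + [
            (s, "", "", "", "unknown") for s in ("S2", "S3")
        ]
        tx = [("G1", "TX1", "chr1", 100, 240, "+")]
        multi = {
            "samples": ["S1", "S2", "S3"],
            "records": ["chr1\t150\t.\tA\tG,ACT\t.\tPASS\t.\tGT\t0/1\t0/2\t2/2\n"],
        }
        split = {
            "samples": ["S1", "S2", "S3"],
            "records": [
                "chr1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n",
                "chr1\t150\t.\tA\tACT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n",
            ],
        }
        d1 = tmp_path / "multi"
        d2 = tmp_path / "split"
        d1.mkdir(), d2.mkdir()
        db_multi = build_db(*write_inputs(d1, multi, ped, pheno, tx))
        db_split = build_db(*write_inputs(d2, split, ped, pheno, tx))
        assert set(db_multi.variants) == set(db_split.variants)
        for key in db_multi.variants:
            assert db_multi.genotypes[key] == db_split.genotypes[key]

    def test_dosage_round_trip_against_vcf(self, small_cohort):
        bundle, db, _ = small_cohort
        vcf = VCF(str(bundle.vcf))
        samples = vcf.samples
        n_checked = 0
        for rec in vcf:
            key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
            if key not in db.variants:
                continue
            for i, g in enumerate(rec.genotypes):
                expected = None if g[0] < 0 else sum(1 for a in g[:-1] if a == 1)
                got = db.dosage(samples[i], key, missing_as=None)
                assert got == expected
                n_checked += 1
        assert n_checked > 0


class TestPmaf:
    def test_beta_1_3_upper_quantile(self):
        # closed form: P(X <= q) = 1 - (1-q)^3 for Beta(1,3)
        expected = 1 - 0.01 ** (1 / 3)
        assert compute_pmaf(0, 2) == pytest.approx(expected, abs=1e-9)
        assert compute_pmaf(0, 2) == pytest.approx(0.7846, abs=1e-4)

    def test_all_alt_is_near_one(self):
        assert compute_pmaf(10, 10) > 0.6
        assert compute_pmaf(10, 10) >= beta_dist.ppf(0.99, 11, 1) - 1e-12

    def test_singleton_in_large_cohort_passes_dominant_filter(self):
        assert compute_pmaf(1, 100_000) < 1e-4

    @pytest.mark.parametrize("ac,an", [(0, 2), (1, 100), (3, 50), (10, 1000)])
    def test_matches_quadrature_oracle(self, ac, an):
        a, b = ac + 1, an - ac + 1
        norm = math.exp(
            math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
        )
        q = compute_pmaf(ac, an)
        mass, _ = integrate.quad(
            lambda x: x ** (a - 1) * (1 - x) ** (b - 1) / norm, 0, q
        )
        assert mass == pytest.approx(0.99, abs=1e-6)

    def test_max_over_external_sources(self):
        internal_only = compute_pmaf(0, 100_000)
        with_common_external = compute_pmaf(0, 100_000, external_counts=[(50, 1000)])
        assert with_common_external > internal_only
        assert with_common_external == pytest.approx(
            float(beta_dist.ppf(0.99, 51, 951)), abs=1e-12
        )

    @given(
        an=st.integers(min_value=2, max_value=500),
        ac1=st.integers(min_value=0, max_value=499),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ac(self, an, ac1):
        ac1 = min(ac1, an - 1)
        assert compute_pmaf(ac1 + 1, an) > compute_pmaf(ac1, an)

    def test_zero_an_rejected(self):
        with pytest.raises(ValueError):
            compute_pmaf(0, 0)


class TestQualifyingVariants:
    def test_threshold_extremes(self, small_cohort):
        _, db, truth = small_cohort
        gene = truth["causal_gene"]
        assert qualifying_variants(db, gene, 0.0) == []
        assert len(qualifying_variants(db, gene, 1.0)) == len(db.gene_variants(gene))

    def test_rare_subset_sorted_by_position(self, small_cohort):
        _, db, _ = small_cohort
        for gene in db.transcripts:
            vs = qualifying_variants(db, gene, 1e-4)
            assert all(v.pmaf < 1e-4 for v in vs)
            assert [v.pos for v in vs] == sorted(v.pos for v in vs)

    def test_unknown_gene_rejected(self, small_cohort):
        _, db, _ = small_cohort
        with pytest.raises(KeyError):
            qualifying_variants(db, "NOPE", 1.0)


def _mini_db(rows):
    """rows: (pid, family, classes, affected)."""
    from rareburden.cohort_db import Participant

    db = CohortDB()
    for pid, fam, classes, affected in rows:
        db.participants[pid] = Participant(
            id=pid, family_id=fam, affected=affected,
            disease_classes=set(classes),
        )
        db.vcf_samples.add(pid)
    return db


class TestSelectCasesControls:
    def test_one_case_per_family_and_parents_not_controls(self):
        db = _mini_db(
            [
                ("A1", "F1", {"ID"}, True), ("A2", "F1", set(), False),
                ("A3", "F1", set(), False),
                ("B1", "F2", {"ID"}, True), ("B2", "F2", set(), False),
                ("B3", "F2", set(), False),
            ]
        )
        cases, controls = select_cases_controls(db, "ID")
        assert cases == ["A1", "B1"]
        assert controls == []

    def test_singleton_controls(self):
        db = _mini_db(
            [("A1", "F1", {"ID"}, True)]
            + [(f"C{i}", f"U{i}", set(), False) for i in range(3)]
        )
        cases, controls = select_cases_controls(db, "ID")
        assert cases == ["A1"]
        assert sorted(controls) == ["C0", "C1", "C2"]

    def test_two_affected_siblings_deterministic_tiebreak(self):
        db = _mini_db(
            [("A2", "F1", {"ID"}, True), ("A1", "F1", {"ID"}, True)]
        )
        for _ in range(3):
            cases, _ = select_cases_controls(db, "ID")
            assert cases == ["A1"]  # lexicographically smallest class member

    def test_no_case_class_rejected(self):
        db = _mini_db([("A1", "F1", set(), False)])
        with pytest.raises(ValueError):
            select_cases_controls(db, "ID")

    def test_row_order_invariance(self):
        rows = [
            ("A1", "F1", {"ID"}, True), ("A2", "F1", set(), False),
            ("Z9", "U1", set(), False), ("Z1", "U1", set(), False),
        ]
        out1 = select_cases_controls(_mini_db(rows), "ID")
        out2 = select_cases_controls(_mini_db(rows[::-1]), "ID")
        assert out1 == out2


class TestPhenotypeHelpers:
    def test_impute_class_term(self, small_cohort):
        _, db, _ = small_cohort
        impute_class_term(db, "ID", "TO:0000101")
        for p in db.participants.values():
            if "ID" in p.disease_classes:
                assert "TO:0000101" in p.hpo_terms

    def test_impute_leaves_others_untouched(self):
        from rareburden.cohort_db import Participant

        db = CohortDB()
        db.participants["x"] = Participant(id="x", family_id="f")
        impute_class_term(db, "ID", "TO:0000101")
        assert db.participants["x"].hpo_terms == set()

    def test_nda_descendant_term_counts(self, small_cohort, tmp_path):
        from rareburden.cohort_db import Participant
        from rareburden.ontology import load_obo
        from rareburden.synthetic_data import NDA_TERM

        bundle, _, _ = small_cohort
        graph = load_obo(bundle.obo)
        p = Participant(id="x", family_id="f", hpo_terms={"TO:0000102"})  # ID descendant
        assert nda_affected(p, set(), NDA_TERM, graph)
        assert not nda_affected(p, set(), NDA_TERM, graph=None)

    def test_nda_icd10_prefix(self):
        from rareburden.cohort_db import Participant

        p = Participant(id="x", family_id="f", icd10_codes={"F70.9"})
        assert nda_affected(p, {"F70"}, "TO:0000100")
        assert not nda_affected(p, {"F80"}, "TO:0000100")

    def test_neither_term_nor_code(self):
        from rareburden.cohort_db import Participant

        p = Participant(id="x", family_id="f")
        assert not nda_affected(p, {"F70"}, "TO:0000100")


class TestSqliteRoundTrip:
    def test_round_trip_preserves_everything(self, small_cohort, tmp_path):
        _, db, _ = small_cohort
        path = tmp_path / "cohort.db"
        db.to_sqlite(path)
        back = CohortDB.from_sqlite(path)
        assert set(back.participants) == set(db.participants)
        assert back.variants == db.variants
        assert back.genotypes == db.genotypes
        assert back.transcripts == db.transcripts
        assert back.vcf_samples == db.vcf_samples
        p0 = sorted(db.participants)[0]
        assert vars(back.participants[p0]) == vars(db.participants[p0])
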