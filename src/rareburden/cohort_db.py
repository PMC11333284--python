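"""Compact case-control cohort store built from VCF + PED + phenotype tables.

The store ("rareservoir-lite") holds rare variants overlapping a configured
set of transcripts, sparse genotype dosages, pedigree structure, and per
participant phenotype annotations (HPO terms, ICD10 codes, disease-class
labels, solved status).  Rarity is expressed as a probabilistic minor allele
frequency (pMAF): an upper posterior quantile of the population allele
frequency under a flat-prior Beta model, so that sparsely observed variants
are not mistaken for rare merely because few alleles were sampled.

Reference allele-count sources (gnomAD-style) can be carried in the VCF INFO
fields ``EXTAC``/``EXTAN`` (per alternate allele).  When present they define
the stored pMAF; otherwise the internal cohort counts are used.  Basing the
rarity filter on external reference counts matters in a case-enriched cohort:
a fully penetrant recurrent pathogenic variant can be common *within* the
study while remaining essentially absent from the population.
"""

from __future__ import annotations

import sqlite3
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.stats import beta as beta_dist

__all__ = [
    "Participant",
    "Variant",
    "Transcript",
    "CohortDB",
    "build_db",
    "compute_pmaf",
    "qualifying_variants",
    "select_cases_controls",
    "impute_class_term",
    "nda_affected",
]

SOLVED_STATUSES = {"solved", "partially_solved", "unsolved", "unknown"}


@dataclass
class Participant:
    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affected: bool = False
    disease_classes: set[str] = field(default_factory=set)
    hpo_terms: set[str] = field(default_factory=set)
    icd10_codes: set[str] = field(default_factory=set)
    solved_status: str = "unknown"

    @property
    def annotated(self) -> bool:
        return bool(
            self.hpo_terms
            or self.icd10_codes
            or self.disease_classes
            or self.solved_status != "unknown"
        )


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based, VCF convention (anchor base for indels)
    ref: str
    alt: str
    gene: str
    transcript_id: str
    ac: int
    an: int
    pmaf: float

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class Transcript:
    gene: str
    transcript_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class CohortDB:
    """In-memory cohort database with sparse genotype storage."""

    def __init__(self):
        self.participants: dict[str, Participant] = {}
        self.variants: dict[str, Variant] = {}
        # variant key -> {participant: dosage}; only non-reference and missing
        # (None) genotypes are stored
        self.genotypes: dict[str, dict[str, int | None]] = {}
        self.transcripts: dict[str, Transcript] = {}
        self.vcf_samples: set[str] = set()

    # -- access helpers -------------------------------------------------
    def dosage(self, participant_id: str, variant_key: str, missing_as: int | None = 0):
        """Allele dosage; ``missing_as`` substitutes for missing calls.

        Participants absent from the VCF are reported as missing.
        """
        if participant_id not in self.vcf_samples:
            return missing_as if missing_as is not None else None
        d = self.genotypes.get(variant_key, {}).get(participant_id, 0)
        return missing_as if d is None else d

    def carriers(self, variant_key: str) -> list[str]:
        return sorted(
            pid
            for pid, d in self.genotypes.get(variant_key, {}).items()
            if d is not None and d > 0
        )

    def genotype_matrix(self, variants, sample_ids, missing_as: int = 0) -> np.ndarray:
        """Dense (n_samples, n_variants) dosage matrix."""
        g = np.zeros((len(sample_ids), len(variants)), dtype=np.int8)
        index = {pid: i for i, pid in enumerate(sample_ids)}
        for j, v in enumerate(variants):
            key = v.key if isinstance(v, Variant) else v
            for pid, d in self.genotypes.get(key, {}).items():
                i = index.get(pid)
                if i is not None:
                    g[i, j] = missing_as if d is None else d
        return g

    def gene_variants(self, gene: str) -> list[Variant]:
        if gene not in self.transcripts:
            raise KeyError(f"gene {gene!r} not in transcript table")
        return sorted(
            (v for v in self.variants.values() if v.gene == gene),
            key=lambda v: (v.pos, v.ref, v.alt),
        )

    # -- persistence ----------------------------------------------------
    SCHEMA = """
    CREATE TABLE participant (
        id TEXT PRIMARY KEY, family_id TEXT, father_id TEXT, mother_id TEXT,
        sex TEXT, affected INTEGER, disease_classes TEXT, hpo_terms TEXT,
        icd10_codes TEXT, solved_status TEXT, in_vcf INTEGER);
    CREATE TABLE variant (
        key TEXT PRIMARY KEY, chrom TEXT, pos INTEGER, ref TEXT, alt TEXT,
        gene TEXT, transcript_id TEXT, ac INTEGER, an INTEGER, pmaf REAL);
    CREATE TABLE genotype (
        variant_key TEXT, participant_id TEXT, dosage INTEGER,
        PRIMARY KEY (variant_key, participant_id));
    CREATE TABLE transcript (
        gene TEXT PRIMARY KEY, transcript_id TEXT, chrom TEXT,
        start INTEGER, end INTEGER, strand TEXT);
    """

    def to_sqlite(self, path) -> None:
        con = sqlite3.connect(path)
        try:
            con.executescript("DROP TABLE IF EXISTS participant;"
                              "DROP TABLE IF EXISTS variant;"
                              "DROP TABLE IF EXISTS genotype;"
                              "DROP TABLE IF EXISTS transcript;")
            con.executescript(self.SCHEMA)
            con.executemany(
                "INSERT INTO participant VALUES (?,?,?,?,?,?,?,?,?,?,?)",
                [
                    (
                        p.id, p.family_id, p.father_id, p.mother_id, p.sex,
                        int(p.affected), ";".join(sorted(p.disease_classes)),
                        ";".join(sorted(p.hpo_terms)),
                        ";".join(sorted(p.icd10_codes)), p.solved_status,
                        int(p.id in self.vcf_samples),
                    )
                    for p in self.participants.values()
                ],
            )
            con.executemany(
                "INSERT INTO variant VALUES (?,?,?,?,?,?,?,?,?,?)",
                [
                    (v.key, v.chrom, v.pos, v.ref, v.alt, v.gene,
                     v.transcript_id, v.ac, v.an, v.pmaf)
                    for v in self.variants.values()
                ],
            )
            con.executemany(
                "INSERT INTO genotype VALUES (?,?,?)",
                [
                    (vk, pid, -1 if d is None else d)
                    for vk, by_pid in self.genotypes.items()
                    for pid, d in by_pid.items()
                ],
            )
            con.executemany(
                "INSERT INTO transcript VALUES (?,?,?,?,?,?)",
                [
                    (t.gene, t.transcript_id, t.chrom, t.start, t.end, t.strand)
                    for t in self.transcripts.values()
                ],
            )
            con.commit()
        finally:
            con.close()

    @classmethod
    def from_sqlite(cls, path) -> "CohortDB":
        db = cls()
        con = sqlite3.connect(path)
        try:
            for row in con.execute("SELECT * FROM participant"):
                (pid, fam, fa, mo, sex, aff, classes, hpo, icd, solved, in_vcf) = row
                db.participants[pid] = Participant(
                    id=pid, family_id=fam, father_id=fa or None,
                    mother_id=mo or None, sex=sex, affected=bool(aff),
                    disease_classes=set(filter(None, classes.split(";"))),
                    hpo_terms=set(filter(None, hpo.split(";"))),
                    icd10_codes=set(filter(None, icd.split(";"))),
                    solved_status=solved,
                )
                if in_vcf:
                    db.vcf_samples.add(pid)
            for row in con.execute("SELECT * FROM variant"):
                key, chrom, pos, ref, alt, gene, tx, ac, an, pmaf = row
                db.variants[key] = Variant(chrom, pos, ref, alt, gene, tx, ac, an, pmaf)
            for vk, pid, d in con.execute("SELECT * FROM genotype"):
                db.genotypes.setdefault(vk, {})[pid] = None if d < 0 else d
            for gene, tx, chrom, start, end, strand in con.execute(
                "SELECT * FROM transcript"
            ):
                db.transcripts[gene] = Transcript(gene, tx, chrom, start, end, strand)
        finally:
            con.close()
        return db

    def export_participants_tsv(self, path) -> None:
        rows = [
            {
                "participant_id": p.id,
                "family_id": p.family_id,
                "affected": int(p.affected),
                "classes": ";".join(sorted(p.disease_classes)),
                "hpo_terms": ";".join(sorted(p.hpo_terms)),
                "icd10": ";".join(sorted(p.icd10_codes)),
                "solved_status": p.solved_status,
            }
            for p in sorted(self.participants.values(), key=lambda p: p.id)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compute_pmaf(
    ac: int,
    an: int,
    external_counts: list[tuple[int, int]] | None = None,
    quantile: float = 0.99,
) -> float:
    """Probabilistic MAF: upper posterior quantile of the allele frequency.

    Under a flat Beta(1, 1) prior and ``ac`` alternate alleles among ``an``
    called alleles, the posterior is Beta(ac + 1, an - ac + 1); the pMAF is its
    ``quantile`` upper quantile, maximized over the given count source and any
    additional ``external_counts`` sources.
    """
    if an <= 0:
        raise ValueError("an must be positive")
    if not 0 <= ac <= an:
        raise ValueError(f"require 0 <= ac <= an, got ac={ac}, an={an}")
    sources = [(ac, an)] + list(external_counts or [])
    best = 0.0
    for s_ac, s_an in sources:
        if s_an <= 0:
            raise ValueError("an must be positive in every count source")
        q = float(beta_dist.ppf(quantile, s_ac + 1, s_an - s_ac + 1))
        best = max(best, q)
    return best


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix, keeping at least one base each (VCF anchor)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


class _TranscriptIndex:
    def __init__(self, transcripts: dict[str, Transcript]):
        self.by_chrom: dict[str, list[Transcript]] = {}
        for t in transcripts.values():
            self.by_chrom.setdefault(t.chrom, []).append(t)
        for txs in self.by_chrom.values():
            txs.sort(key=lambda t: t.start)
        self.starts = {c: [t.start for t in txs] for c, txs in self.by_chrom.items()}

    def overlapping(self, chrom: str, start: int, end: int) -> Transcript | None:
        txs = self.by_chrom.get(chrom)
        if not txs:
            return None
        i = bisect_right(self.starts[chrom], end)
        for t in txs[:i]:
            if t.end >= start:
                return t
        return None


def read_transcripts(path) -> dict[str, Transcript]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "transcript_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript table missing columns {sorted(missing)}")
    out: dict[str, Transcript] = {}
    for i, row in df.iterrows():
        try:
            t = Transcript(
                gene=row["gene"], transcript_id=row["transcript_id"],
                chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"],
            )
            if t.strand not in {"+", "-"} or t.end < t.start:
                raise ValueError
        except (TypeError, ValueError):
            raise ValueError(f"malformed transcript row at line {i + 2} of {path}")
        out[t.gene] = t
    return out


def read_ped(path) -> dict[str, Participant]:
    out: dict[str, Participant] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"malformed PED row at line {lineno} of {path}")
            fam, pid, father, mother, sex, aff = fields
            out[pid] = Participant(
                id=pid,
                family_id=fam,
                father_id=None if father in ("0", "") else father,
                mother_id=None if mother in ("0", "") else mother,
                sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                affected=aff == "2",
            )
    # parent ids must reference members of the same family
    for p in out.values():
        for parent in (p.father_id, p.mother_id):
            if parent is not None and parent in out:
                if out[parent].family_id != p.family_id:
                    raise ValueError(
                        f"parent {parent} of {p.id} is in family "
                        f"{out[parent].family_id}, expected {p.family_id}"
                    )
    return out


def _apply_phenotypes(participants: dict[str, Participant], path) -> None:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"participant_id", "hpo_terms", "icd10", "classes", "solved_status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        pid = row["participant_id"]
        p = participants.get(pid)
        if p is None:
            raise ValueError(
                f"phenotype row at line {i + 2} of {path} references "
                f"unknown participant {pid!r}"
            )
        p.hpo_terms = set(filter(None, row["hpo_terms"].split(";")))
        p.icd10_codes = set(filter(None, row["icd10"].split(";")))
        p.disease_classes = set(filter(None, row["classes"].split(";")))
        status = row["solved_status"] or "unknown"
        if status not in SOLVED_STATUSES:
            raise ValueError(
                f"invalid solved_status {status!r} at line {i + 2} of {path}"
            )
        p.solved_status = status


def build_db(
    vcf_path,
    ped_path,
    phenotype_path,
    transcripts_path,
    require_pass: bool = True,
    pmaf_quantile: float = 0.99,
) -> CohortDB:
    """Assemble a CohortDB from the four standard input files.

    Only variants overlapping a listed transcript are stored; multi-allelic
    records are decomposed into one variant per alternate allele with allele
    trimming.  Genotypes are stored sparsely (non-reference and missing only).
    """
    db = CohortDB()
    db.transcripts = read_transcripts(transcripts_path)
    db.participants = read_ped(ped_path)
    _apply_phenotypes(db.participants, phenotype_path)
    tindex = _TranscriptIndex(db.transcripts)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in db.participants]
    if unknown:
        raise ValueError(f"VCF samples absent from PED: {unknown[:5]}")
    db.vcf_samples = set(samples)

    for rec in vcf:
        if require_pass and rec.FILTER is not None:
            continue
        gts = rec.genotypes  # [allele1, allele2, phased] per sample
        ext_ac = rec.INFO.get("EXTAC")
        ext_an = rec.INFO.get("EXTAN")
        n_alts = len(rec.ALT)
        if ext_ac is not None and n_alts == 1 and not isinstance(ext_ac, tuple):
            ext_ac = (ext_ac,)
        for ai, alt in enumerate(rec.ALT, start=1):
            pos, ref, alt_t = _trim_alleles(rec.POS, rec.REF, alt)
            tx = tindex.overlapping(rec.CHROM, pos, pos + len(ref) - 1)
            if tx is None:
                continue
            dosages: dict[str, int | None] = {}
            ac = 0
            an = 0
            for s_i, g in enumerate(gts):
                alleles = list(g[:-1])
                if any(a < 0 for a in alleles):
                    dosages[samples[s_i]] = None
                    continue
                an += len(alleles)
                d = sum(1 for a in alleles if a == ai)
                ac += d
                if d > 0:
                    dosages[samples[s_i]] = d
            if ac == 0 or an == 0:
                continue
            if ext_ac is not None and ext_an is not None:
                pmaf = compute_pmaf(
                    int(ext_ac[ai - 1]), int(ext_an), quantile=pmaf_quantile
                )
            else:
                pmaf = compute_pmaf(ac, an, quantile=pmaf_quantile)
            v = Variant(
                chrom=rec.CHROM, pos=pos, ref=ref, alt=alt_t, gene=tx.gene,
                transcript_id=tx.transcript_id, ac=ac, an=an, pmaf=pmaf,
            )
            if v.key in db.variants:
                continue
            db.variants[v.key] = v
            db.genotypes[v.key] = dosages
    return db


def qualifying_variants(db: CohortDB, gene: str, threshold: float) -> list[Variant]:
    """Variants of ``gene`` with pMAF strictly below ``threshold``, by position."""
    return [v for v in db.gene_variants(gene) if v.pmaf < threshold]


def select_cases_controls(db: CohortDB, case_class: str) -> tuple[list[str], list[str]]:
    """One case per case-class family; one control per remaining family.

    The case is the lexicographically smallest case-class member of each
    family containing at least one.  Control families are those containing no
    selected case (equivalently, no case-class member); within each, the
    preferred member is genotyped, then phenotype-annotated, then smallest id.
    The two sets are disjoint and mutually unrelated by construction.
    """
    by_family: dict[str, list[Participant]] = {}
    for p in db.participants.values():
        by_family.setdefault(p.family_id, []).append(p)
    cases: list[str] = []
    control_families: list[str] = []
    for fam in sorted(by_family):
        members = by_family[fam]
        class_members = sorted(
            p.id for p in members if case_class in p.disease_classes
        )
        if class_members:
            cases.append(class_members[0])
        else:
            control_families.append(fam)
    if not cases:
        raise ValueError(f"no participants assigned to class {case_class!r}")
    controls: list[str] = []
    for fam in control_families:
        chosen = min(
            by_family[fam],
            key=lambda p: (p.id not in db.vcf_samples, not p.annotated, p.id),
        )
        controls.append(chosen.id)
    return cases, controls


def impute_class_term(db: CohortDB, class_label: str, term_id: str) -> CohortDB:
    """Ensure every member of a disease class carries its defining HPO term."""
    for p in db.participants.values():
        if class_label in p.disease_classes:
            p.hpo_terms.add(term_id)
    return db


def nda_affected(
    participant: Participant,
    icd10_prefix_set,
    nda_term: str,
    graph=None,
) -> bool:
    """Affection by the broad phenotype definition: the umbrella HPO term (or a
    descendant of it) or a diagnostic-code prefix match.

    With an ontology graph the descendant check uses ancestral closure;
    without one only the literal term is checked (appropriate for
    already-closed annotation sets).
    """
    if graph is not None:
        has_term = any(
            nda_term in graph.ancestors(t)
            for t in participant.hpo_terms
            if t in graph.terms
        )
    else:
        has_term = nda_term in participant.hpo_terms
    if has_term:
        return True
    return any(
        code.startswith(prefix)
        for code in participant.icd10_codes
        for prefix in icd10_prefix_set
    )
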