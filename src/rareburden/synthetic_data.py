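"""Seeded generator of complete synthetic trio cohorts for the whole pipeline.

The generator emulates the statistical structure of a national rare-disease
sequencing programme in which a short single-exon noncoding gene harbors a
dominant de novo mutational hotspot:

* case trios whose probands carry recurrent de novo hotspot variants at a
  configurable rate, with parental genotypes homozygous reference unless
  masked missing;
* incomplete penetrance (a carrier is affected with probability
  ``penetrance``);
* correlated phenotype profiles: causal carriers share a multi-term HPO-style
  annotation signature (ID, microcephaly, hypotonia, seizures, short stature,
  motor delay analogues) on top of background noise terms, inducing the
  phenotypic homogeneity signal the permutation test must detect;
* a baseline diagnostic solve rate among non-carrier cases (carrier cases are
  never solved, producing the solved-case depletion signal);
* an unrelated control pool and exchangeable background rare variation in
  neutral genes, annotated with gnomAD-style external allele counts in the
  VCF INFO fields ``EXTAC``/``EXTAN``.

Everything is reproducible from the config seed; a ``truth.json`` record of
carriers, sequences and assignments accompanies each bundle for testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SimConfig",
    "Bundle",
    "simulate_cohort",
    "simulate_null_panel",
    "simulate_region_fixture",
    "toy_ontology_obo",
    "NDA_TERM",
    "ID_TERM",
    "CAUSAL_PROFILE",
]

# ---------------------------------------------------------------------------
# toy ontology (HPO-style, ~50 terms, single root, one diamond)

NDA_TERM = "TO:0000100"
ID_TERM = "TO:0000101"

_TOY_TERMS: list[tuple[str, str, list[str]]] = [
    ("TO:0000001", "Phenotypic abnormality", []),
    ("TO:0000010", "Abnormality of the nervous system", ["TO:0000001"]),
    ("TO:0000100", "Neurodevelopmental abnormality", ["TO:0000010"]),
    ("TO:0000101", "Intellectual disability", ["TO:0000100"]),
    ("TO:0000102", "Severe intellectual disability", ["TO:0000101"]),
    ("TO:0000103", "Neurodevelopmental delay", ["TO:0000100"]),
    ("TO:0000104", "Motor delay", ["TO:0000103", "TO:0000301"]),
    ("TO:0000105", "Delayed speech and language development", ["TO:0000103"]),
    ("TO:0000110", "Seizure", ["TO:0000010"]),
    ("TO:0000111", "Generalized-onset seizure", ["TO:0000110"]),
    ("TO:0000112", "Focal-onset seizure", ["TO:0000110"]),
    ("TO:0000120", "Abnormal brain morphology", ["TO:0000010"]),
    ("TO:0000121", "Cerebral atrophy", ["TO:0000120"]),
    ("TO:0000122", "Thin corpus callosum", ["TO:0000120"]),
    ("TO:0000300", "Abnormality of movement", ["TO:0000010"]),
    ("TO:0000301", "Abnormal central motor function", ["TO:0000300"]),
    ("TO:0000302", "Ataxia", ["TO:0000301"]),
    ("TO:0000303", "Dystonia", ["TO:0000301"]),
    ("TO:0000200", "Abnormality of the musculature", ["TO:0000001"]),
    ("TO:0000201", "Abnormal muscle tone", ["TO:0000200"]),
    ("TO:0000202", "Hypotonia", ["TO:0000201"]),
    ("TO:0000203", "Generalized hypotonia", ["TO:0000202"]),
    ("TO:0000204", "Hypertonia", ["TO:0000201"]),
    ("TO:0000400", "Growth abnormality", ["TO:0000001"]),
    ("TO:0000401", "Short stature", ["TO:0000400"]),
    ("TO:0000402", "Proportionate short stature", ["TO:0000401"]),
    ("TO:0000403", "Failure to thrive", ["TO:0000400"]),
    ("TO:0000404", "Tall stature", ["TO:0000400"]),
    ("TO:0000500", "Abnormality of head or neck", ["TO:0000001"]),
    ("TO:0000501", "Abnormality of the head", ["TO:0000500"]),
    ("TO:0000502", "Abnormality of skull size", ["TO:0000501"]),
    ("TO:0000503", "Microcephaly", ["TO:0000502"]),
    ("TO:0000504", "Macrocephaly", ["TO:0000502"]),
    ("TO:0000510", "Abnormality of the face", ["TO:0000500"]),
    ("TO:0000511", "Abnormality of the mouth", ["TO:0000510"]),
    ("TO:0000512", "Abnormality of upper lip vermillion", ["TO:0000511"]),
    ("TO:0000513", "Drooling", ["TO:0000511"]),
    ("TO:0000514", "Hypertelorism", ["TO:0000510"]),
    ("TO:0000600", "Abnormality of the eye", ["TO:0000001"]),
    ("TO:0000601", "Strabismus", ["TO:0000600"]),
    ("TO:0000602", "Myopia", ["TO:0000600"]),
    ("TO:0000700", "Abnormality of the cardiovascular system", ["TO:0000001"]),
    ("TO:0000701", "Ventricular septal defect", ["TO:0000700"]),
    ("TO:0000702", "Atrial septal defect", ["TO:0000700"]),
    ("TO:0000800", "Abnormality of the skeletal system", ["TO:0000001"]),
    ("TO:0000801", "Scoliosis", ["TO:0000800"]),
    ("TO:0000802", "Joint hypermobility", ["TO:0000800"]),
    ("TO:0000900", "Abnormality of the immune system", ["TO:0000001"]),
    ("TO:0000901", "Recurrent infections", ["TO:0000900"]),
    ("TO:0000910", "Abnormality of the skin", ["TO:0000001"]),
    ("TO:0000911", "Eczema", ["TO:0000910"]),
    ("TO:0000920", "Abnormality of the endocrine system", ["TO:0000001"]),
    ("TO:0000921", "Hypothyroidism", ["TO:0000920"]),
]

#: shared annotation signature of causal carriers
CAUSAL_PROFILE = (
    "TO:0000101",  # intellectual disability
    "TO:0000503",  # microcephaly
    "TO:0000203",  # generalized hypotonia
    "TO:0000110",  # seizure
    "TO:0000402",  # proportionate short stature
    "TO:0000104",  # motor delay
)

#: background annotation pool with draw weights (arbitrary units)
_BACKGROUND_POOL: list[tuple[str, float]] = [
    ("TO:0000102", 1.0), ("TO:0000105", 3.0), ("TO:0000111", 1.0),
    ("TO:0000112", 1.0), ("TO:0000121", 1.0), ("TO:0000122", 0.5),
    ("TO:0000302", 1.0), ("TO:0000303", 0.5), ("TO:0000203", 1.5),
    ("TO:0000204", 0.8), ("TO:0000401", 1.5), ("TO:0000403", 1.0),
    ("TO:0000404", 0.3), ("TO:0000503", 1.5), ("TO:0000504", 0.5),
    ("TO:0000512", 0.3), ("TO:0000513", 0.3), ("TO:0000514", 0.8),
    ("TO:0000601", 1.5), ("TO:0000602", 1.0), ("TO:0000701", 0.5),
    ("TO:0000702", 0.5), ("TO:0000801", 1.0), ("TO:0000802", 0.8),
    ("TO:0000901", 1.0), ("TO:0000911", 0.8), ("TO:0000921", 0.5),
    ("TO:0000110", 2.0), ("TO:0000104", 2.0),
]


def toy_ontology_obo() -> str:
    lines = ["format-version: 1.2", "ontology: to", ""]
    for tid, name, parents in _TOY_TERMS:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        for p in parents:
            lines.append(f"is_a: {p}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """All generative parameters of a synthetic cohort."""

    n_case_trios: int = 500
    n_control_families: int = 5000
    transcript_length: int = 141
    causal_gene: bool = True
    hotspot: tuple[int, ...] = (63, 65, 66, 74, 76, 77)
    recurrent_insertion_after: int = 64  # n.64_65insT analogue
    recurrent_insertion_base: str = "T"
    recurrent_fraction: float = 0.7  # carriers with the recurrent variant
    de_novo_rate: float = 0.05  # hotspot carrier rate among case probands
    penetrance: float = 0.9
    background_rare_rate: float = 0.001  # per gene per participant
    baseline_solved_rate: float = 0.201
    n_background_genes: int = 9
    profile_term_prob: float = 0.85
    background_terms_mean: float = 2.0
    carrier_noise_terms_mean: float = 1.0
    id_omission_rate: float = 0.1  # ID term missing despite ID class
    nda_omission_rate: float = 0.03  # ICD10-only coding of an affected proband
    icd10_rate: float = 0.1
    missing_parent_rate: float = 0.1
    mosaic_parent: bool = True
    external_an: int = 152108
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.recurrent_fraction, self.de_novo_rate, self.penetrance,
            self.background_rare_rate, self.baseline_solved_rate,
            self.profile_term_prob, self.id_omission_rate,
            self.nda_omission_rate, self.icd10_rate, self.missing_parent_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        bad = [b for b in self.hotspot if not 1 <= b <= self.transcript_length]
        if bad:
            raise ValueError(f"hotspot positions outside transcript: {bad}")
        if not 1 <= self.recurrent_insertion_after < self.transcript_length:
            raise ValueError("recurrent insertion flank outside transcript")


@dataclass
class Bundle:
    directory: Path
    vcf: Path
    ped: Path
    phenotypes: Path
    transcripts: Path
    obo: Path
    truth: Path
    mosaic: Path


@dataclass(frozen=True)
class _Gene:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # transcript orientation, 5'->3'


_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _genomic_ref(gene: _Gene, pos: int) -> str:
    if gene.strand == "+":
        return gene.sequence[pos - gene.start]
    return gene.sequence[gene.end - pos].translate(_COMP)


def _snv_record(gene: _Gene, n: int, alt_t: str) -> tuple[int, str, str]:
    """Genomic (pos, ref, alt) of a substitution given in transcript coords."""
    if gene.strand == "+":
        pos = gene.start + n - 1
        return pos, gene.sequence[n - 1], alt_t
    pos = gene.end - n + 1
    return pos, gene.sequence[n - 1].translate(_COMP), alt_t.translate(_COMP)


def _insertion_record(gene: _Gene, left_flank: int, motif_t: str) -> tuple[int, str, str]:
    """Genomic (pos, ref, alt) of an insertion between cDNA left_flank and +1."""
    if gene.strand == "+":
        pos = gene.start + left_flank - 1
        ref = gene.sequence[left_flank - 1]
        return pos, ref, ref + motif_t
    pos = gene.end - left_flank  # genomic base left of the gap
    ref = _genomic_ref(gene, pos)
    return pos, ref, ref + _revcomp(motif_t)


class _VariantPool:
    """Accumulates (pos, ref, alt) records with carrier genotypes."""

    def __init__(self):
        self.records: dict[tuple[str, int, str, str], dict] = {}

    def add(self, gene: _Gene, pos: int, ref: str, alt: str, sample: str,
            dosage: int = 1, extac: int = 0) -> str:
        key = (gene.chrom, pos, ref, alt)
        rec = self.records.setdefault(
            key, {"genotypes": {}, "extac": extac, "missing": set()}
        )
        rec["genotypes"][sample] = max(rec["genotypes"].get(sample, 0), dosage)
        return f"{gene.chrom}:{pos}:{ref}:{alt}"

    def mask(self, gene: _Gene, pos: int, ref: str, alt: str, sample: str) -> None:
        self.records[(gene.chrom, pos, ref, alt)]["missing"].add(sample)


def _write_vcf(path: Path, pool: _VariantPool, samples: list[str], contigs, external_an: int) -> None:
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, length in contigs:
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##INFO=<ID=EXTAC,Number=A,Type=Integer,'
                 'Description="External reference alternate allele count">\n')
        fh.write('##INFO=<ID=EXTAN,Number=1,Type=Integer,'
                 'Description="External reference total allele number">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (chrom, pos, ref, alt), rec in sorted(pool.records.items()):
            info = f"EXTAC={rec['extac']};EXTAN={external_an}"
            gts = []
            for s in samples:
                if s in rec["missing"]:
                    gts.append("./.")
                else:
                    gts.append(gt_str[rec["genotypes"].get(s, 0)])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t"
                     + "\t".join(gts) + "\n")


def _write_ped(path: Path, rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_phenotypes(path: Path, rows: list[dict]) -> None:
    cols = ["participant_id", "hpo_terms", "icd10", "classes", "solved_status"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(r[c] for c in cols) + "\n")


def _write_transcripts(path: Path, genes: list[_Gene]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\ttranscript_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.name}\tTX_{g.name}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def _make_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_Gene]:
    genes = []
    names = []
    if cfg.causal_gene:
        names.append(("RNUT1", "-"))
    for i in range(cfg.n_background_genes):
        names.append((f"NCG{i + 1:03d}", "+" if i % 2 == 0 else "-"))
    for i, (name, strand) in enumerate(names):
        start = 100_000 + i * 10_000
        seq = "".join(rng.choice(list(_BASES), size=cfg.transcript_length))
        if cfg.causal_gene and i == 0:
            # keep the recurrent insertion unshiftable so its rendering and
            # per-base footprint stay at the configured flank
            flank = cfg.recurrent_insertion_after
            if seq[flank] == cfg.recurrent_insertion_base:
                swap = "A" if cfg.recurrent_insertion_base != "A" else "C"
                seq = seq[:flank] + swap + seq[flank + 1:]
        genes.append(
            _Gene(name, "chr1", start, start + cfg.transcript_length - 1, strand, seq)
        )
    return genes


def _draw_background_terms(rng: np.random.Generator, mean: float) -> set[str]:
    pool_terms = [t for t, _ in _BACKGROUND_POOL]
    weights = np.array([w for _, w in _BACKGROUND_POOL])
    weights = weights / weights.sum()
    k = min(rng.poisson(mean), len(pool_terms))
    if k == 0:
        return set()
    picks = rng.choice(len(pool_terms), size=k, replace=False, p=weights)
    return {pool_terms[i] for i in picks}


def simulate_cohort(config: SimConfig, out_dir) -> Bundle:
    """Emit a consistent VCF/PED/phenotype/transcripts/OBO bundle.

    Byte-identical across runs for the same config (the seed drives every
    random choice and all outputs are written in sorted order).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = _make_genes(config, rng)
    causal = genes[0] if config.causal_gene else None
    pool = _VariantPool()
    ped_rows: list[tuple] = []
    pheno_rows: list[dict] = []
    truth_carriers: dict[str, dict] = {}
    mosaic_rows: list[tuple[str, str]] = []
    samples: list[str] = []

    recurrent_key = None
    if causal is not None:
        ins_pos, ins_ref, ins_alt = _insertion_record(
            causal, config.recurrent_insertion_after, config.recurrent_insertion_base
        )
        recurrent_key = f"{causal.chrom}:{ins_pos}:{ins_ref}:{ins_alt}"

    # --- case trios ---------------------------------------------------
    first_unmasked_de_novo: str | None = None
    for i in range(config.n_case_trios):
        fam = f"F{i + 1:05d}"
        proband, father, mother = f"{fam}_P", f"{fam}_D", f"{fam}_M"
        samples += [proband, father, mother]

        is_carrier = causal is not None and rng.random() < config.de_novo_rate
        variant_key = None
        masked_parents: list[str] = []
        if is_carrier:
            if rng.random() < config.recurrent_fraction:
                pos, ref, alt = ins_pos, ins_ref, ins_alt
            else:
                n = int(rng.choice(list(config.hotspot)))
                ref_t = causal.sequence[n - 1]
                alt_t = str(rng.choice([b for b in _BASES if b != ref_t]))
                pos, ref, alt = _snv_record(causal, n, alt_t)
            variant_key = pool.add(causal, pos, ref, alt, proband, extac=0)
            for parent in (father, mother):
                if rng.random() < config.missing_parent_rate:
                    pool.add(causal, pos, ref, alt, parent, dosage=0)
                    pool.mask(causal, pos, ref, alt, parent)
                    masked_parents.append(parent)
            if (
                config.mosaic_parent
                and not masked_parents
                and first_unmasked_de_novo is None
            ):
                first_unmasked_de_novo = proband
                mosaic_rows.append((father, variant_key))

        affected = (rng.random() < config.penetrance) if is_carrier else True

        # phenotype annotation
        if affected:
            terms = {NDA_TERM}
            classes = "ID"
            if rng.random() >= config.id_omission_rate:
                terms.add(ID_TERM)
            if is_carrier:
                for t in CAUSAL_PROFILE:
                    if rng.random() < config.profile_term_prob:
                        terms.add(t)
                terms |= _draw_background_terms(rng, config.carrier_noise_terms_mean)
            else:
                terms |= _draw_background_terms(rng, config.background_terms_mean)
            icd10 = set()
            if rng.random() < config.icd10_rate:
                icd10.add("F70.9")
            if rng.random() < config.nda_omission_rate:
                terms.discard(NDA_TERM)
                icd10.add("F79")
            if is_carrier:
                solved = "unsolved"
            else:
                solved = (
                    "solved"
                    if rng.random() < config.baseline_solved_rate
                    else "unsolved"
                )
        else:
            terms = _draw_background_terms(rng, 1.0)
            classes = ""
            icd10 = set()
            solved = "unknown"

        ped_rows.append((fam, proband, father, mother, 1 if i % 2 == 0 else 2,
                         2 if affected else 1))
        ped_rows.append((fam, father, 0, 0, 1, 1))
        ped_rows.append((fam, mother, 0, 0, 2, 1))
        pheno_rows.append({
            "participant_id": proband,
            "hpo_terms": ";".join(sorted(terms)),
            "icd10": ";".join(sorted(icd10)),
            "classes": classes,
            "solved_status": solved,
        })
        for parent, sex_terms in ((father, None), (mother, None)):
            pheno_rows.append({
                "participant_id": parent,
                "hpo_terms": ";".join(sorted(_draw_background_terms(rng, 0.5))),
                "icd10": "",
                "classes": "",
                "solved_status": "unknown",
            })
        if is_carrier:
            truth_carriers[proband] = {
                "variant": variant_key,
                "affected": affected,
                "masked_parents": masked_parents,
                "de_novo": True,
            }

    # --- unrelated controls -------------------------------------------
    for i in range(config.n_control_families):
        fam = f"C{i + 1:06d}"
        pid = f"{fam}_1"
        samples.append(pid)
        ped_rows.append((fam, pid, 0, 0, 1 if i % 2 == 0 else 2, 1))
        pheno_rows.append({
            "participant_id": pid,
            "hpo_terms": ";".join(sorted(_draw_background_terms(rng, 1.0))),
            "icd10": "",
            "classes": "",
            "solved_status": "unknown",
        })

    # --- background rare variation ------------------------------------
    for gene in genes:
        hits = rng.random(len(samples)) < config.background_rare_rate
        for s_i in np.nonzero(hits)[0]:
            n = int(rng.integers(1, config.transcript_length + 1))
            ref_t = gene.sequence[n - 1]
            alt_t = str(rng.choice([b for b in _BASES if b != ref_t]))
            pos, ref, alt = _snv_record(gene, n, alt_t)
            u = rng.random()
            if u < 0.6:
                extac = 0
            elif u < 0.8:
                extac = 1 + int(rng.poisson(1.0))
            else:
                extac = 20 + int(rng.poisson(20.0))
            key = (gene.chrom, pos, ref, alt)
            if key in pool.records:
                extac = pool.records[key]["extac"]
            pool.add(gene, pos, ref, alt, samples[s_i], extac=extac)

    # --- emit ----------------------------------------------------------
    bundle = Bundle(
        directory=out,
        vcf=out / "cohort.vcf",
        ped=out / "cohort.ped",
        phenotypes=out / "phenotypes.tsv",
        transcripts=out / "transcripts.tsv",
        obo=out / "toy.obo",
        truth=out / "truth.json",
        mosaic=out / "mosaic.tsv",
    )
    _write_vcf(bundle.vcf, pool, samples, [("chr1", 1_000_000)], config.external_an)
    _write_ped(bundle.ped, ped_rows)
    _write_phenotypes(bundle.phenotypes, pheno_rows)
    _write_transcripts(bundle.transcripts, genes)
    bundle.obo.write_text(toy_ontology_obo())
    with open(bundle.mosaic, "w") as fh:
        fh.write("parent_id\tvariant_key\n")
        for parent, key in mosaic_rows:
            fh.write(f"{parent}\t{key}\n")
    truth = {
        "config": dataclasses.asdict(config),
        "genes": {
            g.name: {"chrom": g.chrom, "start": g.start, "end": g.end,
                     "strand": g.strand, "sequence": g.sequence}
            for g in genes
        },
        "causal_gene": causal.name if causal else None,
        "recurrent_variant": recurrent_key,
        "carriers": truth_carriers,
        "mosaic": [list(r) for r in mosaic_rows],
    }
    bundle.truth.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return bundle


def simulate_null_panel(config: SimConfig, n_genes: int, out_dir) -> Bundle:
    """Bundle of ``n_genes`` with exchangeable case/control rare-variant rates."""
    if config.causal_gene:
        config = dataclasses.replace(config, causal_gene=False)
    config = dataclasses.replace(config, n_background_genes=n_genes)
    return simulate_cohort(config, out_dir)


# ---------------------------------------------------------------------------
# deterministic per-base/region fixture


def simulate_region_fixture(out_dir, seed: int = 0) -> Bundle:
    """Cohort whose causal-gene carrier pattern mirrors a two-region hotspot.

    Affected trio probands carry de novo rare alleles at cDNA bases 62–70 and
    73–79 of a 141-base minus-strand transcript (an insertion after base 64
    and recurrent substitutions at 65 and 76 among them), while unaffected
    singletons carry rare alleles at bases 61, 71, 72 and 80.  Seed-and-extend
    over bases free of unaffected carriers therefore yields exactly the
    closed intervals [62, 70] and [73, 79].
    """
    cfg = SimConfig(
        n_case_trios=0, n_control_families=0, causal_gene=True,
        n_background_genes=0, seed=seed,
    )
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = _make_genes(cfg, rng)
    gene = genes[0]
    pool = _VariantPool()
    ped_rows: list[tuple] = []
    pheno_rows: list[dict] = []
    samples: list[str] = []

    affected_bases = (
        [(64, "ins", 3), (65, "snv", 2), (76, "snv", 2)]
        + [(b, "snv", 1) for b in (62, 63, 66, 67, 68, 69, 70, 73, 74, 75, 77, 78, 79)]
    )
    fam_no = 0
    for n, kind, n_carriers in affected_bases:
        if kind == "ins":
            pos, ref, alt = _insertion_record(gene, n, "T")
        else:
            ref_t = gene.sequence[n - 1]
            alt_t = "A" if ref_t != "A" else "G"
            pos, ref, alt = _snv_record(gene, n, alt_t)
        extac = 1 if n == 76 else 0
        for _ in range(n_carriers):
            fam_no += 1
            fam = f"R{fam_no:04d}"
            proband, father, mother = f"{fam}_P", f"{fam}_D", f"{fam}_M"
            samples += [proband, father, mother]
            pool.add(gene, pos, ref, alt, proband, extac=extac)
            ped_rows += [
                (fam, proband, father, mother, 1, 2),
                (fam, father, 0, 0, 1, 1),
                (fam, mother, 0, 0, 2, 1),
            ]
            pheno_rows.append({
                "participant_id": proband,
                "hpo_terms": ";".join(sorted({NDA_TERM, ID_TERM})),
                "icd10": "", "classes": "ID", "solved_status": "unsolved",
            })
            for parent in (father, mother):
                pheno_rows.append({
                    "participant_id": parent, "hpo_terms": "", "icd10": "",
                    "classes": "", "solved_status": "unknown",
                })

    for n in (61, 71, 72, 80):
        ref_t = gene.sequence[n - 1]
        alt_t = "C" if ref_t != "C" else "T"
        pos, ref, alt = _snv_record(gene, n, alt_t)
        fam_no += 1
        fam = f"U{fam_no:04d}"
        pid = f"{fam}_1"
        samples.append(pid)
        pool.add(gene, pos, ref, alt, pid, extac=0)
        ped_rows.append((fam, pid, 0, 0, 2, 1))
        pheno_rows.append({
            "participant_id": pid, "hpo_terms": "", "icd10": "",
            "classes": "", "solved_status": "unknown",
        })

    bundle = Bundle(
        directory=out,
        vcf=out / "cohort.vcf",
        ped=out / "cohort.ped",
        phenotypes=out / "phenotypes.tsv",
        transcripts=out / "transcripts.tsv",
        obo=out / "toy.obo",
        truth=out / "truth.json",
        mosaic=out / "mosaic.tsv",
    )
    _write_vcf(bundle.vcf, pool, samples, [("chr1", 1_000_000)], cfg.external_an)
    _write_ped(bundle.ped, ped_rows)
    _write_phenotypes(bundle.phenotypes, pheno_rows)
    _write_transcripts(bundle.transcripts, genes)
    bundle.obo.write_text(toy_ontology_obo())
    bundle.mosaic.write_text("parent_id\tvariant_key\n")
    truth = {
        "config": dataclasses.asdict(cfg),
        "genes": {
            gene.name: {"chrom": gene.chrom, "start": gene.start, "end": gene.end,
                        "strand": gene.strand, "sequence": gene.sequence}
        },
        "causal_gene": gene.name,
        "seed_bases": [64, 65, 76],
        "expected_regions": [[62, 70], [73, 79]],
    }
    bundle.truth.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return bundle
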