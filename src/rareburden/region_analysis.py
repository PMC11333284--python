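"""Transcript-coordinate variant mapping, trio inheritance and per-base tables.

Variants stored in genomic (VCF) coordinates are mapped onto the cDNA of a
single-exon transcript, strand-aware, and rendered in HGVS ``n.`` notation
(with 3'-most normalization of indels when the transcript sequence is
available).  Trio genotypes classify each affected carrier's allele as de novo
(both parents homozygous reference), inherited (a parent carries it) or of
unknown inheritance (a parental genotype is missing).  The per-base table
counts, for every cDNA base, carriers of rare alleles whose footprint covers
the base, stratified by affection and inheritance — the raw material for
delineating contiguous regions devoid of unaffected carriers around candidate
pathogenic positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_db import CohortDB, Transcript, Variant

__all__ = [
    "CdnaVariant",
    "InheritanceCall",
    "PerBaseTable",
    "map_to_cdna",
    "classify_inheritance",
    "per_base_table",
    "highlight_regions",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CdnaVariant:
    variant: Variant
    n_start: int
    n_end: int
    kind: str  # substitution | insertion | deletion | delins
    hgvs_n: str

    @property
    def footprint(self) -> range:
        """cDNA bases the allele covers; insertions count at the left flank."""
        if self.kind == "insertion":
            return range(self.n_start, self.n_start + 1)
        return range(self.n_start, self.n_end + 1)


@dataclass(frozen=True)
class InheritanceCall:
    child: str
    variant: str
    call: str  # de_novo | inherited_maternal | inherited_paternal | unknown | mosaic_parent
    de_novo_origin: bool = False


def _render_hgvs(kind: str, n_start: int, n_end: int, ref: str, alt: str) -> str:
    if kind == "substitution":
        return f"n.{n_start}{ref}>{alt}"
    if kind == "insertion":
        return f"n.{n_start}_{n_end}ins{alt}"
    if kind == "deletion":
        if n_start == n_end:
            return f"n.{n_start}del"
        return f"n.{n_start}_{n_end}del"
    if n_start == n_end:
        return f"n.{n_start}delins{alt}"
    return f"n.{n_start}_{n_end}delins{alt}"


def _shift3(seq: str, start: int, motif: str, is_insertion: bool) -> int:
    """Right-roll an indel to its 3'-most transcript position.

    ``start`` is the 1-based cDNA position of the first inserted/deleted base
    (for insertions, the base *after* the left flank).  Rolling is valid while
    the base at the current position equals the first base of the motif, in
    which case the motif rotates one step rightward.
    """
    motif = list(motif)
    length = len(motif)
    while True:
        probe = start + (length if not is_insertion else 0)
        # base that would move into the motif's tail after a one-step shift
        if is_insertion:
            if start > len(seq) or seq[start - 1] != motif[0]:
                break
        else:
            if probe > len(seq) or seq[probe - 1] != motif[0]:
                break
        motif.append(motif.pop(0))
        start += 1
    return start


def map_to_cdna(
    variant: Variant, transcript: Transcript, sequence: str | None = None
) -> CdnaVariant:
    """Strand-aware genomic-to-cDNA conversion with HGVS ``n.`` rendering.

    On the minus strand alleles are reverse-complemented and coordinates
    reflected (``n = end − pos + 1``).  With ``sequence`` (the transcript's own
    5'→3' sequence) insertions and deletions are normalized to their 3'-most
    equivalent position before rendering.
    """
    ref, alt = variant.ref, variant.alt
    g_start = variant.pos
    g_end = variant.pos + len(ref) - 1
    if g_end < transcript.start or g_start > transcript.end:
        raise ValueError(
            f"variant {variant.key} outside transcript {transcript.transcript_id}"
        )
    L = transcript.length

    if len(ref) == 1 and len(alt) == 1:
        kind = "substitution"
    elif len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
        kind = "insertion"
    elif len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
        kind = "deletion"
    else:
        kind = "delins"

    minus = transcript.strand == "-"

    def to_n(g: int) -> int:
        return (transcript.end - g + 1) if minus else (g - transcript.start + 1)

    if kind == "substitution":
        n = to_n(variant.pos)
        r, a = (_revcomp(ref), _revcomp(alt)) if minus else (ref, alt)
        hgvs = _render_hgvs(kind, n, n, r, a)
        return CdnaVariant(variant, n, n, kind, hgvs)

    if kind == "insertion":
        ins = alt[1:]
        # inserted between genomic pos and pos+1
        if minus:
            left = to_n(variant.pos + 1)  # smaller cDNA coordinate
            ins_t = _revcomp(ins)
        else:
            left = to_n(variant.pos)
            ins_t = ins
        if sequence is not None:
            shifted = _shift3(sequence, left + 1, ins_t, is_insertion=True)
            k = shifted - (left + 1)
            if k:
                ins_t = ins_t[k % len(ins_t):] + ins_t[: k % len(ins_t)]
                left = shifted - 1
        left = max(1, min(left, L - 1))
        hgvs = _render_hgvs("insertion", left, left + 1, "", ins_t)
        return CdnaVariant(variant, left, left + 1, "insertion", hgvs)

    if kind == "deletion":
        deleted = ref[1:]
        g_del_start, g_del_end = variant.pos + 1, variant.pos + len(ref) - 1
        if minus:
            n_start, n_end = to_n(g_del_end), to_n(g_del_start)
            del_t = _revcomp(deleted)
        else:
            n_start, n_end = to_n(g_del_start), to_n(g_del_end)
            del_t = deleted
        if sequence is not None:
            shifted = _shift3(sequence, n_start, del_t, is_insertion=False)
            d = shifted - n_start
            n_start, n_end = n_start + d, n_end + d
        n_start = max(1, n_start)
        n_end = min(L, n_end)
        hgvs = _render_hgvs("deletion", n_start, n_end, "", "")
        return CdnaVariant(variant, n_start, n_end, "deletion", hgvs)

    # delins
    if minus:
        n_start, n_end = to_n(g_end), to_n(g_start)
        alt_t = _revcomp(alt)
    else:
        n_start, n_end = to_n(g_start), to_n(g_end)
        alt_t = alt
    n_start = max(1, n_start)
    n_end = min(L, n_end)
    hgvs = _render_hgvs("delins", n_start, n_end, "", alt_t)
    return CdnaVariant(variant, n_start, n_end, "delins", hgvs)


def classify_inheritance(
    child_gt: int | None,
    mother_gt: int | None,
    father_gt: int | None,
    mosaic_overrides: frozenset | set = frozenset(),
    child: str = "",
    variant: str = "",
) -> InheritanceCall:
    """Classify one carried allele from trio dosages.

    Dosages are alternate-allele counts; ``None`` is a missing genotype.
    ``mosaic_overrides`` may contain ``"mother"``/``"father"`` for parents
    known (for example by read inspection) to be mosaic despite a homozygous
    reference call; this annotates a de novo call as ``mosaic_parent`` while
    retaining its de novo origin flag.
    """
    if child_gt is None or child_gt == 0:
        raise ValueError("inheritance classification requires a carrier child")
    if mother_gt is None or father_gt is None:
        return InheritanceCall(child, variant, "unknown")
    if mother_gt == 0 and father_gt == 0:
        if mosaic_overrides:
            return InheritanceCall(child, variant, "mosaic_parent", de_novo_origin=True)
        return InheritanceCall(child, variant, "de_novo", de_novo_origin=True)
    if mother_gt > 0:
        # both-parent carriage is classified maternal by convention; for
        # alleles rare enough to enter these analyses it does not arise
        return InheritanceCall(child, variant, "inherited_maternal")
    return InheritanceCall(child, variant, "inherited_paternal")


STRATA = ["affected_de_novo", "affected_inherited", "affected_unknown", "unaffected"]


@dataclass
class PerBaseTable:
    transcript: Transcript
    df: pd.DataFrame  # index: cDNA base 1..L; columns: STRATA + ["naa"]

    def to_tsv(self, path, external_alleles: set[str] | None = None) -> None:
        out = self.df.copy()
        out.insert(0, "base", out.index)
        out.to_csv(path, sep="\t", index=False)


def per_base_table(
    db: CohortDB,
    gene: str,
    rare_threshold: float = 1e-4,
    mosaic_overrides: set[tuple[str, str]] | None = None,
    sequence: str | None = None,
) -> PerBaseTable:
    """Per-cDNA-base carrier counts stratified by affection and inheritance.

    Every rare variant (pMAF below ``rare_threshold``) contributes each of its
    carriers to every base its cDNA footprint covers (insertions at the left
    flanking base; deletions at every deleted base).  ``mosaic_overrides`` is a
    set of ``(parent_id, variant_key)`` pairs; mosaic-parent calls retain their
    de novo origin and are counted with the de novo stratum.
    """
    tx = db.transcripts[gene]
    mosaic_overrides = mosaic_overrides or set()
    L = tx.length
    df = pd.DataFrame(
        0, index=pd.RangeIndex(1, L + 1, name="base"), columns=STRATA + ["naa"]
    )
    for v in db.gene_variants(gene):
        if v.pmaf >= rare_threshold:
            continue
        cv = map_to_cdna(v, tx, sequence)
        carriers = db.carriers(v.key)
        if not carriers:
            continue
        bases = [b for b in cv.footprint if 1 <= b <= L]
        for b in bases:
            df.loc[b, "naa"] += 1
        for pid in carriers:
            p = db.participants[pid]
            if not p.affected:
                stratum = "unaffected"
            else:
                mother = p.mother_id
                father = p.father_id
                m_gt = db.dosage(mother, v.key, missing_as=None) if mother else None
                f_gt = db.dosage(father, v.key, missing_as=None) if father else None
                overrides = set()
                if mother and (mother, v.key) in mosaic_overrides:
                    overrides.add("mother")
                if father and (father, v.key) in mosaic_overrides:
                    overrides.add("father")
                call = classify_inheritance(
                    db.dosage(pid, v.key), m_gt, f_gt, overrides, pid, v.key
                )
                if call.de_novo_origin:
                    stratum = "affected_de_novo"
                elif call.call == "unknown":
                    stratum = "affected_unknown"
                else:
                    stratum = "affected_inherited"
            for b in bases:
                df.loc[b, stratum] += 1
    return PerBaseTable(transcript=tx, df=df)


def highlight_regions(table: PerBaseTable, seed_bases) -> list[tuple[int, int]]:
    """Maximal runs of unaffected-carrier-free bases around each seed base.

    Each seed is extended left and right over consecutive bases with zero
    unaffected carriers (bases with no carriers at all extend too), stopping
    before any base with an unaffected carrier or at the transcript ends;
    overlapping extensions merge.  Returns sorted disjoint closed intervals in
    cDNA coordinates.
    """
    seeds = sorted(set(seed_bases))
    if not seeds:
        raise ValueError("at least one seed base is required")
    unaffected = table.df["unaffected"]
    L = len(unaffected)
    intervals = []
    for s in seeds:
        if not 1 <= s <= L:
            raise ValueError(f"seed base {s} outside transcript of length {L}")
        if unaffected.loc[s] > 0:
            raise ValueError(f"seed base {s} has unaffected carriers")
        lo = s
        while lo > 1 and unaffected.loc[lo - 1] == 0:
            lo -= 1
        hi = s
        while hi < L and unaffected.loc[hi + 1] == 0:
            hi += 1
        intervals.append((lo, hi))
    intervals.sort()
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def regions_to_bed(regions, transcript: Transcript, path) -> None:
    """Write highlighted regions as BED (0-based half-open, transcript coords)."""
    with open(path, "w") as fh:
        for lo, hi in regions:
            fh.write(f"{transcript.gene}\t{lo - 1}\t{hi}\n")
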