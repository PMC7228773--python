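"""Well-level variant evidence: parsing, filtering and training labels.

This module consumes the joint multi-sample VCF produced by calling
variants over 384 well-level alignments plus one merged sample, applies
the caller-quality, well-count and mappability filters, and assigns the
training labels used by the classifier:

* ``UTD`` ("unique to the well-level data", train label 0): a candidate confidently
  unsupported in both bulk tumor and bulk normal WGS — the union of
  amplification artefacts and true clone-specific mutations;
* ``HET_SNP`` (train label 1): a confident heterozygous germline SNP in
  the bulk normal (blood) sample — a guaranteed true variant;
* ``OTHER``: everything else, excluded from training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from intervaltree import IntervalTree

from .plate import DEFAULT_LAYOUT, PlateLayout

logger = logging.getLogger(__name__)

#: The 14 caller annotations carried per candidate, in canonical order.
QUAL_FIELDS: tuple[str, ...] = (
    "QUAL", "BRF", "FR", "HP", "HapScore", "MGOF", "MMLQ",
    "MQ", "QD", "SbPval", "NF", "NR", "TCF", "TCR",
)

# genotype codes
GT_MISSING = -1
GT_HOMREF = 0
GT_HET = 1
GT_HOMALT = 2

_GT_STR = {GT_HOMREF: "0/0", GT_HET: "0/1", GT_HOMALT: "1/1", GT_MISSING: "./."}
_STR_GT = {v: k for k, v in _GT_STR.items()}

LABEL_UTD = "UTD"
LABEL_HET_SNP = "HET_SNP"
LABEL_OTHER = "OTHER"


@dataclass(frozen=True)
class WellEvidence:
    """Read support and genotype call for one well at one locus."""

    well_index: int
    row: int
    col: int
    ref_reads: int
    var_reads: int
    genotype: int  # GT_* code

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.var_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class CandidateVariant:
    """One candidate site with caller annotations and per-well evidence.

    Per-well evidence is stored as dense arrays over the plate
    (``ref_reads[i]``, ``var_reads[i]``, ``genotypes[i]`` for well *i*)
    rather than 384 objects; :meth:`well` materialises a single
    :class:`WellEvidence` view.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    qual_fields: dict[str, float | None]
    ref_reads: np.ndarray  # (n_wells,) int
    var_reads: np.ndarray
    genotypes: np.ndarray  # (n_wells,) int8, GT_* codes
    merged_ref_reads: int | None = None
    merged_var_reads: int | None = None
    context21: str | None = None
    layout: PlateLayout = field(default=DEFAULT_LAYOUT, repr=False)

    def __post_init__(self) -> None:
        n = self.layout.n_wells
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int64)
        self.var_reads = np.asarray(self.var_reads, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        for arr in (self.ref_reads, self.var_reads, self.genotypes):
            if arr.shape != (n,):
                raise ValueError(f"per-well arrays must have shape ({n},)")
        if (self.ref_reads < 0).any() or (self.var_reads < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.context21 is not None and len(self.context21) != 21:
            raise ValueError("context21 must be exactly 21 bases")

    @property
    def variant_id(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def well(self, i: int) -> WellEvidence:
        row, col = self.layout.row_col(i)
        return WellEvidence(i, row, col, int(self.ref_reads[i]),
                            int(self.var_reads[i]), int(self.genotypes[i]))

    @property
    def wells(self) -> Iterator[WellEvidence]:
        return (self.well(i) for i in range(self.layout.n_wells))


@dataclass(frozen=True)
class WellCounts:
    """Tw = wells covering the locus; Vw = wells supporting the variant."""

    Tw: int
    Vw: int

    def __post_init__(self) -> None:
        if not 0 <= self.Vw <= self.Tw:
            raise ValueError("need 0 <= Vw <= Tw")


@dataclass(frozen=True)
class LabelledVariant:
    variant: CandidateVariant
    label: str  # LABEL_UTD / LABEL_HET_SNP / LABEL_OTHER

    @property
    def train_label(self) -> int | None:
        if self.label == LABEL_UTD:
            return 0
        if self.label == LABEL_HET_SNP:
            return 1
        return None


# ---------------------------------------------------------------------------
# filters


def quality_filter(
    v: CandidateVariant,
    *,
    min_qual: float = 60.0,
    min_fr: float = 0.1,
    max_hp: float = 4.0,
    min_qd: float = 10.0,
    max_sbpval: float = 0.95,
) -> bool:
    """Caller-quality filter: QUAL>60, FR>0.1, HP<=4, QD>10, SbPval<=0.95.

    Lower bounds are strict, upper bounds inclusive, exactly as stated.
    A missing annotation fails the filter (conservative).
    """
    q = v.qual_fields

    def _ok(name: str) -> float | None:
        x = q.get(name)
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return None
        return float(x)

    qual, fr, hp, qd, sb = (_ok(k) for k in ("QUAL", "FR", "HP", "QD", "SbPval"))
    if None in (qual, fr, hp, qd, sb):
        return False
    return qual > min_qual and fr > min_fr and hp <= max_hp and qd > min_qd and sb <= max_sbpval


def well_counts(v: CandidateVariant, min_reads: int = 1) -> WellCounts:
    """Count covering (Tw) and variant-supporting (Vw) wells."""
    total = v.ref_reads + v.var_reads
    return WellCounts(Tw=int((total >= min_reads).sum()),
                      Vw=int((v.var_reads >= min_reads).sum()))


def well_filter(wc: WellCounts, *, min_tw: int = 5, min_vw: int = 2,
                min_ratio: float = 0.1) -> bool:
    """Well-count filter: Tw>5, Vw>2 and Vw/Tw>0.1, all strict."""
    if wc.Tw == 0:
        return False
    return wc.Tw > min_tw and wc.Vw > min_vw and wc.Vw / wc.Tw > min_ratio


def load_mask(bed_path: str) -> dict[str, IntervalTree]:
    """Load a 0-based half-open BED mask into per-contig interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            s, e = int(start), int(end)
            if e > s:
                trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def mappability_mask(
    variants: Iterable[CandidateVariant],
    mask: str | Mapping[str, IntervalTree],
) -> Iterator[CandidateVariant]:
    """Drop variants that touch a masked interval.

    Masking is conservative at interval boundaries: a variant is removed
    when the mask overlaps either the 0-based position (pos - 1) or the
    boundary base at pos, so a site sitting on the edge of a poorly
    mappable region is excluded too.  Contigs absent from the mask are
    retained untouched.
    """
    trees = load_mask(mask) if isinstance(mask, str) else mask
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is not None and tree.overlaps(v.pos - 1, v.pos + 1):
            continue
        yield v


# ---------------------------------------------------------------------------
# bulk genotyping and labels


@dataclass(frozen=True)
class BulkCall:
    """Genotyping result for one candidate site in a bulk WGS sample."""

    genotype: int  # GT_* code
    depth: int
    var_reads: int
    gq: float | None


def load_bulk_genotypes(vcf_path: str, sample: str | None = None
                        ) -> dict[tuple[str, int, str, str], BulkCall]:
    """Read a single-sample genotyped VCF into a site -> BulkCall map.

    Expects Platypus-style FORMAT fields: GT plus NR (reads covering) and
    NV (reads supporting the variant); GQ when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    idx = 0 if sample is None else list(vcf.samples).index(sample)
    calls: dict[tuple[str, int, str, str], BulkCall] = {}
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT):
            gt = _gt_code_for_alt(rec.genotypes[idx], ai + 1)
            nr = _fmt_value(rec, "NR", idx, ai)
            nv = _fmt_value(rec, "NV", idx, ai)
            gq = _fmt_value(rec, "GQ", idx, 0)
            calls[(rec.CHROM, rec.POS, rec.REF, alt)] = BulkCall(
                genotype=gt,
                depth=int(nr) if nr is not None else 0,
                var_reads=int(nv) if nv is not None else 0,
                gq=float(gq) if gq is not None else None,
            )
    return calls


def label_variants(
    variants: Iterable[CandidateVariant],
    bulk_tumor: Mapping[tuple, BulkCall],
    bulk_normal: Mapping[tuple, BulkCall],
    *,
    min_bulk_depth: int = 10,
    het_gq_min: float = 30.0,
) -> Iterator[LabelledVariant]:
    """Assign UTD / HET_SNP / OTHER labels from bulk genotyping.

    UTD: homozygous-reference with zero variant reads and depth >=
    ``min_bulk_depth`` in *both* bulk samples (confidently unsupported).
    HET_SNP: heterozygous in the normal (blood) sample with genotype
    quality >= ``het_gq_min``.  Everything else, including sites absent
    from either bulk VCF, is OTHER.
    """
    for v in variants:
        key = v.variant_id
        tumor = bulk_tumor.get(key)
        normal = bulk_normal.get(key)
        if tumor is None or normal is None:
            logger.warning("site %s:%d %s>%s absent from a bulk VCF; labelled OTHER",
                           *key)
            yield LabelledVariant(v, LABEL_OTHER)
            continue
        unsupported = all(
            b.genotype == GT_HOMREF and b.var_reads == 0 and b.depth >= min_bulk_depth
            for b in (tumor, normal)
        )
        if unsupported:
            yield LabelledVariant(v, LABEL_UTD)
        elif (normal.genotype == GT_HET and normal.gq is not None
              and normal.gq >= het_gq_min):
            yield LabelledVariant(v, LABEL_HET_SNP)
        else:
            yield LabelledVariant(v, LABEL_OTHER)


# ---------------------------------------------------------------------------
# joint VCF I/O


def _gt_code_for_alt(genotype: list, alt_index: int) -> int:
    """Collapse a cyvcf2 genotype (e.g. [0, 1, False]) to a code w.r.t. one alt."""
    alleles = [a for a in genotype[:-1]]
    if not alleles or any(a is None or a < 0 for a in alleles):
        return GT_MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == 0:
        return GT_HOMREF
    if n_alt == len(alleles):
        return GT_HOMALT
    return GT_HET


def _fmt_value(rec, key: str, sample_idx: int, alt_idx: int):
    """Fetch one per-sample FORMAT value, tolerating per-alt arrays."""
    try:
        arr = rec.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    row = np.atleast_1d(arr[sample_idx])
    j = alt_idx if alt_idx < row.shape[0] else 0
    val = row[j]
    if val is None:
        return None
    f = float(val)
    if np.isnan(f) or f < 0:  # cyvcf2 encodes missing ints as large negatives
        return None
    return f


def _info_value(rec, key: str, alt_idx: int) -> float | None:
    val = rec.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, (tuple, list)):
        val = val[alt_idx] if alt_idx < len(val) else val[0]
    try:
        f = float(val)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f


def parse_joint_vcf(
    path: str,
    merged_sample: str,
    layout: PlateLayout = DEFAULT_LAYOUT,
    contexts: Mapping[tuple[str, int], str] | str | None = None,
) -> Iterator[CandidateVariant]:
    """Stream candidate variants from a joint 384-well + merged-sample VCF.

    Expects one sample column per well (named per ``layout``) plus the
    merged sample, and Platypus-style per-sample NR/NV counts.
    Multi-allelic records are decomposed into one candidate per alt
    allele; malformed records are skipped with a warning.

    ``contexts`` supplies the 21-base reference context per site, either
    as a mapping ``(chrom, pos) -> sequence`` or a FASTA path.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if merged_sample not in samples:
        raise ValueError(f"merged sample {merged_sample!r} not in VCF samples")
    if len(samples) < layout.n_wells + 1:
        raise ValueError(
            f"joint VCF needs >= {layout.n_wells + 1} samples, found {len(samples)}"
        )
    merged_idx = samples.index(merged_sample)
    well_of_sample = {}
    for si, name in enumerate(samples):
        if si == merged_idx:
            continue
        try:
            well_of_sample[si] = layout.sample_to_well(name)
        except KeyError:
            logger.warning("sample %s not in plate layout; ignored", name)

    fasta = None
    if isinstance(contexts, str):
        from pyfaidx import Fasta

        fasta = Fasta(contexts)

    n_wells = layout.n_wells
    for rec in vcf:
        try:
            for ai, alt in enumerate(rec.ALT):
                ref_arr = np.zeros(n_wells, dtype=np.int64)
                var_arr = np.zeros(n_wells, dtype=np.int64)
                gt_arr = np.full(n_wells, GT_MISSING, dtype=np.int8)
                for si, wi in well_of_sample.items():
                    nr = _fmt_value(rec, "NR", si, ai)
                    nv = _fmt_value(rec, "NV", si, ai)
                    if nr is None and nv is None:
                        continue  # missing sample -> (0, 0, missing)
                    nr = int(nr or 0)
                    nv = int(nv or 0)
                    var_arr[wi] = nv
                    ref_arr[wi] = max(nr - nv, 0)
                    gt_arr[wi] = _gt_code_for_alt(rec.genotypes[si], ai + 1)
                m_nr = _fmt_value(rec, "NR", merged_idx, ai)
                m_nv = _fmt_value(rec, "NV", merged_idx, ai)
                qf: dict[str, float | None] = {
                    "QUAL": float(rec.QUAL) if rec.QUAL is not None else None
                }
                for key in QUAL_FIELDS[1:]:
                    qf[key] = _info_value(rec, key, ai)
                ctx = None
                if fasta is not None:
                    seq = fasta[rec.CHROM][rec.POS - 11: rec.POS + 10]
                    ctx = str(seq).upper()
                elif contexts is not None:
                    ctx = contexts.get((rec.CHROM, rec.POS))
                yield CandidateVariant(
                    chrom=rec.CHROM, pos=rec.POS, ref_allele=rec.REF, alt_allele=alt,
                    qual_fields=qf, ref_reads=ref_arr, var_reads=var_arr,
                    genotypes=gt_arr,
                    merged_ref_reads=(int(max(m_nr - (m_nv or 0), 0))
                                      if m_nr is not None else None),
                    merged_var_reads=int(m_nv) if m_nv is not None else None,
                    context21=ctx, layout=layout,
                )
        except (ValueError, IndexError, TypeError) as exc:
            logger.warning("skipping malformed record %s:%s (%s)",
                           rec.CHROM, rec.POS, exc)


_VCF_INFO_KEYS = [k for k in QUAL_FIELDS if k != "QUAL"]


def write_joint_vcf(
    variants: Iterable[CandidateVariant],
    path: str,
    merged_sample: str = "Merged",
    layout: PlateLayout = DEFAULT_LAYOUT,
) -> None:
    """Write candidates back to a joint multi-sample VCF (v4.2, biallelic rows)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=NR,Number=1,Type=Integer,Description='
                 '"Reads covering the site">\n')
        fh.write('##FORMAT=<ID=NV,Number=1,Type=Integer,Description='
                 '"Reads supporting the variant">\n')
        for key in _VCF_INFO_KEYS:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                "FORMAT", *layout.sample_names, merged_sample]
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            qual = v.qual_fields.get("QUAL")
            info = ";".join(
                f"{k}={v.qual_fields[k]:g}"
                for k in _VCF_INFO_KEYS
                if v.qual_fields.get(k) is not None
            ) or "."
            fields = [
                v.chrom, str(v.pos), ".", v.ref_allele, v.alt_allele,
                f"{qual:g}" if qual is not None else ".", "PASS", info, "GT:NR:NV",
            ]
            for i in range(layout.n_wells):
                nr = int(v.ref_reads[i] + v.var_reads[i])
                fields.append(f"{_GT_STR[int(v.genotypes[i])]}:{nr}:{int(v.var_reads[i])}")
            m_ref = v.merged_ref_reads or 0
            m_var = v.merged_var_reads or 0
            m_gt = "0/1" if m_var > 0 and m_ref > 0 else ("1/1" if m_var > 0 else "0/0")
            fields.append(f"{m_gt}:{m_ref + m_var}:{m_var}")
            fh.write("\t".join(fields) + "\n")


def write_candidates_tsv(labelled: Iterable[LabelledVariant], path: str) -> None:
    """Write labelled, filtered candidates as a TSV summary."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tTw\tVw\tlabel\n")
        for lv in labelled:
            wc = well_counts(lv.variant)
            v = lv.variant
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t"
                     f"{wc.Tw}\t{wc.Vw}\t{lv.label}\n")
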