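"""Synthetic 384-well plate simulator with ground truth.

Emulates the generative process behind compartmentalised WGA
sequencing: ~200 pg of template (roughly 30 cell equivalents, so ~60
copies of each locus) is partitioned uniformly at random over 384
wells, each well is amplified and sequenced, and variants are called
per well.  Four variant classes are produced:

* ``HET_SNP`` — germline heterozygous: half of the locus copies carry
  the variant, so variant evidence scatters over ~25-30 wells;
* ``CLONAL`` — somatic but present in every template cell; identical
  read-distribution behaviour to a heterozygous SNP;
* ``CLONE_SPECIFIC`` — somatic and private to a fraction of the
  template cells; fewer variant-bearing wells, but still multi-well;
* ``ARTEFACT`` — a polymerase error on damaged template during
  amplification inside a single well.  Because the error arises on one
  strand of one molecule, the origin well reads *both* alleles (a
  dual-allelic compartment) and no other well shows the variant.  An
  optional contamination mode additionally smears low-level variant
  reads along the origin well's row or column (index hopping), which is
  how a minority of artefacts reach well counts that survive the
  well-count filters.

Every emitted candidate carries caller-style quality annotations drawn
from class-conditioned, deliberately overlapping distributions, so the
scalar quality filters alone cannot separate artefacts from true
variants — separation must come from the plate-distribution features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .plate import DEFAULT_LAYOUT, PlateLayout
from .welldata import (GT_HET, GT_HOMALT, GT_HOMREF, GT_MISSING,
                       CandidateVariant, well_counts)

CLASS_HET_SNP = "HET_SNP"
CLASS_CLONAL = "CLONAL"
CLASS_CLONE_SPECIFIC = "CLONE_SPECIFIC"
CLASS_ARTEFACT = "ARTEFACT"

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic plate.

    Defaults reflect the real assay: 60 locus copies (2 alleles x ~30
    cell equivalents in ~200 pg of DNA) over 384 wells, which keeps the
    chance that an occupied well holds a second molecule of the same
    locus below 10%; ~4 reads per template molecule per locus.
    """

    n_wells: int = 384
    genome_copies: int = 60
    n_het_snps: int = 3000
    n_clonal_somatic: int = 0
    n_clone_specific: int = 0
    clone_cell_fraction: float = 1.0
    n_artefacts: int = 1500
    artefact_strand_fraction: float = 0.5
    artefact_contaminated_fraction: float = 0.02
    contamination_extra_wells: float = 8.0   # mean smeared wells (4 + Poisson(4))
    contamination_read_mean: float = 2.5     # mean variant reads per smeared well
    artefact_mismapped_fraction: float = 0.02
    mismap_read_mean: float = 2.0            # mismapped reads per paralog molecule
    mean_reads_per_well_per_locus: float = 4.0
    locus_efficiency_shape: float = 1.3      # Gamma shape of per-locus yield, mean 1
    well_amplification_shape: float = 1.2    # Gamma shape of per-well/allele yield
    genotype_error: float = 0.05
    seed: int = 0
    layout: PlateLayout = field(default=DEFAULT_LAYOUT, repr=False)

    def __post_init__(self) -> None:
        for name in ("n_het_snps", "n_clonal_somatic", "n_clone_specific",
                     "n_artefacts", "genome_copies"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("clone_cell_fraction", "artefact_strand_fraction",
                     "artefact_contaminated_fraction", "genotype_error"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one emitted candidate."""

    variant_id: tuple
    true_class: str
    molecule_wells: tuple[int, ...]  # wells holding a variant template / smear
    artefact_origin_well: int | None = None
    artefact_subtype: str | None = None  # damage / contaminated / mismapped
    spiked: bool = False  # clonal variant deliberately mislabeled as UTD


# ---------------------------------------------------------------------------
# occupancy analytics (used by tests and the acceptance script)


def partition_locus(copies: int, n_wells: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """Multinomial allocation of locus copies over equally likely wells."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    return rng.multinomial(copies, np.full(n_wells, 1.0 / n_wells))


def double_occupancy_probability(copies: int, n_wells: int) -> float:
    """Exact P(a well holds >= 2 copies | it holds >= 1) under multinomial."""
    p = 1.0 / n_wells
    p0 = (1 - p) ** copies
    p1 = copies * p * (1 - p) ** (copies - 1)
    return (1.0 - p0 - p1) / (1.0 - p0)


def double_occupancy_poisson_limit(copies: int, n_wells: int) -> float:
    """Poisson-limit form 1 - lam*exp(-lam)/(1 - exp(-lam)), lam = copies/wells."""
    lam = copies / n_wells
    return 1.0 - lam * math.exp(-lam) / (1.0 - math.exp(-lam))


def expected_occupied_wells(copies: int, n_wells: int) -> float:
    """E[#wells holding >= 1 copy] = n * (1 - (1 - 1/n)^copies)."""
    return n_wells * (1.0 - (1.0 - 1.0 / n_wells) ** copies)


# ---------------------------------------------------------------------------
# quality-annotation generators

def _default_qual_fields(true_variant: bool, total_reads: int, var_reads: int,
                         rng: np.random.Generator) -> dict[str, float]:
    """Class-conditioned caller annotations with heavy overlap.

    'True' here covers germline, clonal and clone-specific variants;
    artefacts get modestly shifted distributions so that a useful but
    far-from-sufficient fraction fails the scalar quality filters.
    """
    if true_variant:
        qual = rng.normal(250.0, 80.0)
        fr = rng.normal(0.5, 0.12)
        hp = 1 + rng.poisson(0.7)
        qd = rng.normal(22.0, 6.0)
        sb = rng.beta(1.0, 2.0)
        mgof = rng.normal(4.0, 2.0)
        mq = rng.normal(59.0, 1.5)
    else:
        # candidates reaching the classifier already passed the scalar
        # quality filters upstream, which truncates the artefact tails:
        # only mildly shifted distributions remain
        qual = rng.normal(220.0, 80.0)
        fr = rng.normal(0.38, 0.12)
        hp = 1 + rng.poisson(0.9)
        qd = rng.normal(19.0, 6.0)
        sb = rng.beta(1.3, 1.5)
        mgof = rng.normal(6.0, 3.0)
        mq = rng.normal(57.5, 2.5)
    nf = rng.binomial(var_reads, 0.5) if var_reads else 0
    tcf = rng.binomial(total_reads, 0.5) if total_reads else 0
    return {
        "QUAL": max(qual, 1.0),
        "BRF": float(np.clip(rng.normal(0.05, 0.03), 0.0, 1.0)),
        "FR": float(np.clip(fr, 0.01, 1.0)),
        "HP": float(hp),
        "HapScore": float(1 + rng.poisson(0.3)),
        "MGOF": max(mgof, 0.0),
        "MMLQ": float(np.clip(rng.normal(35.0, 4.0), 0.0, 40.0)),
        "MQ": float(np.clip(mq, 0.0, 60.0)),
        "QD": max(qd, 0.1),
        "SbPval": float(sb),
        "NF": float(nf),
        "NR": float(var_reads - nf),
        "TCF": float(tcf),
        "TCR": float(total_reads - tcf),
    }


# ---------------------------------------------------------------------------
# per-variant simulation


def _call_genotypes(ref_reads: np.ndarray, var_reads: np.ndarray,
                    genotype_error: float, rng: np.random.Generator) -> np.ndarray:
    gts = np.full(ref_reads.shape, GT_MISSING, dtype=np.int8)
    covered = (ref_reads + var_reads) > 0
    gts[covered & (var_reads == 0)] = GT_HOMREF
    gts[covered & (var_reads > 0) & (ref_reads > 0)] = GT_HET
    gts[covered & (ref_reads == 0) & (var_reads > 0)] = GT_HOMALT
    if genotype_error > 0:
        flip = covered & (rng.random(ref_reads.shape) < genotype_error)
        for i in np.flatnonzero(flip):
            choices = [g for g in (GT_HOMREF, GT_HET, GT_HOMALT) if g != gts[i]]
            gts[i] = choices[rng.integers(len(choices))]
    return gts


def simulate_variant(true_class: str, cfg: SimConfig, rng: np.random.Generator,
                     chrom: str = "sim1", pos: int = 1000) -> tuple[CandidateVariant, SimTruth]:
    """Simulate one candidate of the given class, with ground truth."""
    n = cfg.n_wells
    mean = cfg.mean_reads_per_well_per_locus
    n_cells = cfg.genome_copies // 2

    if true_class == CLASS_ARTEFACT:
        n_var_copies = 0
    elif true_class == CLASS_CLONE_SPECIFIC:
        n_var_copies = int(round(cfg.clone_cell_fraction * n_cells))
    elif true_class in (CLASS_HET_SNP, CLASS_CLONAL):
        n_var_copies = n_cells
    else:
        raise ValueError(f"unknown class {true_class!r}")
    n_ref_copies = cfg.genome_copies - n_var_copies

    ref_mol = partition_locus(n_ref_copies, n, rng)
    var_mol = partition_locus(n_var_copies, n, rng)
    # WGA yield varies between loci (GC content, template accessibility):
    # a Gamma(mean 1) factor modulates the per-molecule read rate, giving
    # real-plate-like low-coverage tails
    eff = (rng.gamma(cfg.locus_efficiency_shape, 1.0 / cfg.locus_efficiency_shape)
           if cfg.locus_efficiency_shape > 0 else 1.0)
    # on top of that, hyperbranching amplification treats the molecules in
    # each well unevenly — an independent Gamma(mean 1) factor per well and
    # allele, so one allele of a double-occupied well can dominate or drop out
    if cfg.well_amplification_shape > 0:
        k = cfg.well_amplification_shape
        amp_ref = rng.gamma(k, 1.0 / k, size=n)
        amp_var = rng.gamma(k, 1.0 / k, size=n)
    else:
        amp_ref = amp_var = np.ones(n)
    ref_reads = rng.poisson(mean * eff * amp_ref * ref_mol)
    var_reads = rng.poisson(mean * eff * amp_var * var_mol)

    origin: int | None = None
    smear: list[int] = []
    subtype: str | None = None
    if true_class == CLASS_ARTEFACT:
        draw = rng.random()
        if draw < cfg.artefact_mismapped_fraction:
            # residual mis-mapping: reads from a diverged paralog carried on
            # one haplotype bleed variant evidence into its wells at a low
            # per-molecule rate — the multi-well artefact mode that can
            # survive the well-count filters
            subtype = "mismapped"
            par_mol = partition_locus(cfg.genome_copies // 2, n, rng)
            par_eff = (rng.gamma(cfg.locus_efficiency_shape,
                                 1.0 / cfg.locus_efficiency_shape)
                       if cfg.locus_efficiency_shape > 0 else 1.0)
            var_reads = var_reads + rng.poisson(
                cfg.mismap_read_mean * par_eff * par_mol)
            smear = [int(i) for i in np.flatnonzero(par_mol > 0)]
        else:
            subtype = "damage"
            candidates = np.flatnonzero(ref_reads > 0)
            if candidates.size == 0:
                candidates = np.flatnonzero(ref_mol > 0)
            if candidates.size:
                origin = int(rng.choice(candidates))
                depth = int(ref_reads[origin])
                err = int(rng.binomial(depth, cfg.artefact_strand_fraction))
                var_reads[origin] = err
                ref_reads[origin] = depth - err
                if draw < (cfg.artefact_mismapped_fraction
                           + cfg.artefact_contaminated_fraction):
                    subtype = "contaminated"
                    smear = _contaminate(origin, cfg, rng, var_reads)

    gts = _call_genotypes(ref_reads, var_reads, cfg.genotype_error, rng)
    total_var = int(var_reads.sum())
    total = int(ref_reads.sum()) + total_var
    qf = _default_qual_fields(true_class != CLASS_ARTEFACT, total, total_var, rng)

    flank = "".join(_BASES[i] for i in rng.integers(0, 4, size=20))
    ref_allele = _BASES[rng.integers(0, 4)]
    alt_allele = rng.choice([b for b in _BASES if b != ref_allele])
    context21 = flank[:10] + ref_allele + flank[10:]

    v = CandidateVariant(
        chrom=chrom, pos=pos, ref_allele=ref_allele, alt_allele=str(alt_allele),
        qual_fields=qf, ref_reads=ref_reads, var_reads=var_reads, genotypes=gts,
        merged_ref_reads=int(ref_reads.sum()), merged_var_reads=total_var,
        context21=context21, layout=cfg.layout,
    )
    if true_class == CLASS_ARTEFACT:
        wells: tuple[int, ...] = tuple([origin] if origin is not None else []) + tuple(smear)
    else:
        wells = tuple(int(i) for i in np.flatnonzero(var_mol > 0))
    return v, SimTruth(v.variant_id, true_class, wells, artefact_origin_well=origin,
                       artefact_subtype=subtype)


def _contaminate(origin: int, cfg: SimConfig, rng: np.random.Generator,
                 var_reads: np.ndarray) -> list[int]:
    """Smear low-level variant reads along the origin well's row or column."""
    layout = cfg.layout
    row, col = layout.row_col(origin)
    along_row = rng.random() < 0.5
    line = ([layout.well_index(row, c) for c in range(layout.n_cols)]
            if along_row else
            [layout.well_index(r, col) for r in range(layout.n_rows)])
    line = [w for w in line if w != origin]
    base_extra = max(int(cfg.contamination_extra_wells) - 4, 0)
    m = min(4 + int(rng.poisson(base_extra)), len(line))
    chosen = rng.choice(len(line), size=m, replace=False)
    touched = []
    lam = max(cfg.contamination_read_mean - 1.0, 0.0)
    for j in chosen:
        w = line[int(j)]
        var_reads[w] += 1 + rng.poisson(lam)
        touched.append(w)
    return touched


# ---------------------------------------------------------------------------
# whole-plate simulation


@dataclass
class SimPlate:
    """A simulated candidate set with truth and training labels.

    ``train_labels`` maps variant id to 0 (UTD: artefacts and planted
    clone-specific variants — the latter are the noisy labels), 1
    (heterozygous germline SNP) or None (clonal somatic; excluded from
    training, available for spiking studies).
    """

    config: SimConfig
    variants: list[CandidateVariant]
    truths: dict[tuple, SimTruth]
    train_labels: dict[tuple, int | None]

    def ids_with_label(self, label: int | None) -> list[tuple]:
        return [vid for vid, lab in self.train_labels.items() if lab == label]

    def variants_by_id(self) -> dict[tuple, CandidateVariant]:
        return {v.variant_id: v for v in self.variants}

    def write_truth_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\ttrue_class\ttrain_label\t"
                     "origin_well\tmolecule_wells\n")
            for v in self.variants:
                t = self.truths[v.variant_id]
                lab = self.train_labels[v.variant_id]
                fh.write("\t".join([
                    v.chrom, str(v.pos), v.ref_allele, v.alt_allele, t.true_class,
                    "." if lab is None else str(lab),
                    "." if t.artefact_origin_well is None else str(t.artefact_origin_well),
                    ",".join(map(str, t.molecule_wells)) or ".",
                ]) + "\n")

    def write_context_table(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tcontext21\n")
            for v in self.variants:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.context21}\n")

    def write_vcf(self, path: str, merged_sample: str = "Merged") -> None:
        from .welldata import write_joint_vcf

        write_joint_vcf(self.variants, path, merged_sample=merged_sample,
                        layout=self.config.layout)


def simulate_plate(cfg: SimConfig) -> SimPlate:
    """Simulate a full plate of candidates per the configured class counts."""
    rng = np.random.default_rng(cfg.seed)
    schedule = ([CLASS_HET_SNP] * cfg.n_het_snps
                + [CLASS_CLONAL] * cfg.n_clonal_somatic
                + [CLASS_CLONE_SPECIFIC] * cfg.n_clone_specific
                + [CLASS_ARTEFACT] * cfg.n_artefacts)
    rng.shuffle(schedule)
    variants: list[CandidateVariant] = []
    truths: dict[tuple, SimTruth] = {}
    labels: dict[tuple, int | None] = {}
    pos = 0
    for true_class in schedule:
        pos += int(rng.integers(200, 2000))
        v, t = simulate_variant(true_class, cfg, rng, chrom="sim1", pos=pos)
        variants.append(v)
        truths[v.variant_id] = t
        labels[v.variant_id] = {
            CLASS_HET_SNP: 1,
            CLASS_ARTEFACT: 0,
            CLASS_CLONE_SPECIFIC: 0,
            CLASS_CLONAL: None,
        }[true_class]
    return SimPlate(cfg, variants, truths, labels)


# ---------------------------------------------------------------------------
# spiking known somatic variants into the UTD pool


@dataclass(frozen=True)
class SpikeSet:
    """One spiked relabelling: clonal variants deliberately marked UTD."""

    ratio: float
    replicate: int
    utd_star_ids: tuple[tuple, ...]


def high_confidence_clonal_ids(plate: SimPlate, min_tw: int = 6,
                               min_ratio: float = 0.45) -> list[tuple]:
    """Clonal somatic variants with Tw > 6 and Vw/Tw > 0.45 (strict)."""
    by_id = plate.variants_by_id()
    out = []
    for vid, t in plate.truths.items():
        if t.true_class != CLASS_CLONAL:
            continue
        wc = well_counts(by_id[vid])
        if wc.Tw > min_tw and wc.Tw > 0 and wc.Vw / wc.Tw > min_ratio:
            out.append(vid)
    return out


def spike_utds(plate: SimPlate, ratios: list[float], n_replicates: int = 10,
               seed: int = 0) -> list[SpikeSet]:
    """Relabel floor(ratio * |UTD|) high-confidence clonal variants as UTD*.

    Returns one SpikeSet per (ratio, replicate); the plate itself is not
    modified.  Raises if the eligible clonal pool is too small.
    """
    rng = np.random.default_rng(seed)
    eligible = high_confidence_clonal_ids(plate)
    n_utd = len(plate.ids_with_label(0))
    out: list[SpikeSet] = []
    for ratio in ratios:
        k = int(math.floor(ratio * n_utd))
        if k > len(eligible):
            raise ValueError(
                f"ratio {ratio}: need {k} high-confidence clonal variants, "
                f"only {len(eligible)} eligible (short by {k - len(eligible)})"
            )
        for rep in range(n_replicates):
            if k == 0:
                out.append(SpikeSet(ratio, rep, ()))
                continue
            idx = rng.choice(len(eligible), size=k, replace=False)
            out.append(SpikeSet(ratio, rep,
                                tuple(eligible[int(i)] for i in sorted(idx))))
    return out
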