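"""Post-classification analyses: rainfall distances and kataegis calls.

A rainfall plot marks, for each somatic mutation (after the first on a
contig), the distance to the previous mutation against its genomic
position.  Runs of points at small inter-mutation distance indicate a
localized hyper-mutation (kataegis) event, classically strand-coordinated
C>T / C>G changes from APOBEC deamination — which is why each point
records its substitution type both as written on the reference strand
(keeping C>T and G>A distinct) and pyrimidine-collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def substitution_type(ref: str, alt: str) -> tuple[str, str]:
    """(reference-strand, pyrimidine-collapsed) substitution labels."""
    ref, alt = ref.upper(), alt.upper()
    strand = f"{ref}>{alt}"
    if ref in "CT":
        return strand, strand
    return strand, f"{_COMPLEMENT.get(ref, 'N')}>{_COMPLEMENT.get(alt, 'N')}"


@dataclass(frozen=True)
class RainfallPoint:
    chrom: str
    pos: int  # position of the second mutation of the pair, 1-based
    distance_to_previous: int
    mutation_class: str            # as written on the reference strand
    mutation_class_pyrimidine: str


def rainfall(mutations: list[tuple[str, int, str, str]]) -> list[RainfallPoint]:
    """Inter-mutation distances per contig, coloured by the second mutation.

    Input tuples are (chrom, pos, ref, alt) SNVs; duplicates are
    dropped.  Contigs with fewer than two mutations contribute no
    points.
    """
    seen = sorted(set(mutations))
    out: list[RainfallPoint] = []
    prev: tuple[str, int] | None = None
    for chrom, pos, ref, alt in seen:
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"rainfall expects SNVs, got {ref}>{alt} at {chrom}:{pos}")
        if prev is not None and prev[0] == chrom:
            strand, pyr = substitution_type(ref, alt)
            out.append(RainfallPoint(chrom, pos, pos - prev[1], strand, pyr))
        prev = (chrom, pos)
    return out


@dataclass(frozen=True)
class KataegisCluster:
    chrom: str
    start: int  # 1-based position of the first member mutation
    end: int
    n_mutations: int
    class_counts: tuple[tuple[str, int], ...]  # pyrimidine-collapsed


def cluster_flag(points: list[RainfallPoint], max_dist: int = 1000,
                 min_run: int = 5) -> list[KataegisCluster]:
    """Maximal runs of closely spaced mutations.

    A cluster is >= ``min_run`` consecutive mutations on one contig
    whose successive distances are all <= ``max_dist``.  A run of k
    rainfall points at small distance spans k+1 mutations.
    """
    clusters: list[KataegisCluster] = []
    run: list[RainfallPoint] = []

    def _flush() -> None:
        if not run:
            return
        n_mut = len(run) + 1
        if n_mut >= min_run:
            counts: dict[str, int] = {}
            for p in run:
                counts[p.mutation_class_pyrimidine] = counts.get(
                    p.mutation_class_pyrimidine, 0) + 1
            clusters.append(KataegisCluster(
                chrom=run[0].chrom,
                start=run[0].pos - run[0].distance_to_previous,
                end=run[-1].pos,
                n_mutations=n_mut,
                class_counts=tuple(sorted(counts.items())),
            ))
        run.clear()

    for p in points:
        close = p.distance_to_previous <= max_dist
        if run and (p.chrom != run[-1].chrom or not close
                    or p.pos - p.distance_to_previous != run[-1].pos):
            _flush()
        if close:
            run.append(p)
        else:
            _flush()
    _flush()
    return clusters


def write_rainfall_tsv(points: list[RainfallPoint], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tdistance_to_previous\tclass_strand\tclass_pyrimidine\n")
        for p in points:
            fh.write(f"{p.chrom}\t{p.pos}\t{p.distance_to_previous}\t"
                     f"{p.mutation_class}\t{p.mutation_class_pyrimidine}\n")


def write_cluster_bed(clusters: list[KataegisCluster], path: str) -> None:
    """0-based half-open BED of kataegis intervals."""
    with open(path, "w") as fh:
        for c in clusters:
            comp = ",".join(f"{k}:{n}" for k, n in c.class_counts)
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t"
                     f"kataegis_n{c.n_mutations}|{comp}\n")
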