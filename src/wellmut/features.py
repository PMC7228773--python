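"""The 41-dimensional feature representation of a candidate variant.

Each candidate is summarised by caller-quality annotations, local
sequence-context complexity, merged-sample read support, and a battery
of statistics over the 384-well evidence matrix that capture *how* the
variant-supporting reads are distributed across the plate.  True
variants come from template molecules scattered over many wells, while
amplification artefacts are concentrated in one (or a few, correlated)
wells — the distribution features make that contrast learnable.

Feature blocks, in fixed order:

1. the 14 caller annotations (QUAL .. TCR);
2. F20_1..F20_3 — cumulative frequency of the 1..3 most abundant
   nucleotides in the 20 flanking bases (context complexity);
3. Rmerge_refvar, Rmerge_var — merged-sample read support;
4. eight well counts conditioned on read support and genotype;
5. W_noref_var_gt_n for n = 0..5 — wells with variant-only evidence
   above a read-count ladder;
6. top-3 per-well read counts for the variant allele and for ref+var;
7. Max_c + Max_r (column/row concentration of variant wells) and
   W_var_any − (Max_c + Max_r).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .welldata import (GT_HET, GT_HOMALT, GT_HOMREF, QUAL_FIELDS,
                       CandidateVariant)

_W_NAMES = ("W_ref_novar", "W_ref_00", "W_ref_01", "W_var_any", "W_var_11",
            "W_var_01", "W_varonly_01", "W_refvar_any")


def feature_names(n_rmax_ranks: int = 3) -> list[str]:
    """Ordered feature names; 41 with the default 3 read-rank features."""
    return (
        list(QUAL_FIELDS)
        + ["F20_1", "F20_2", "F20_3"]
        + ["Rmerge_refvar", "Rmerge_var"]
        + list(_W_NAMES)
        + [f"W_noref_var_gt_{n}" for n in range(6)]
        + [f"Rmax_var_{k}" for k in range(1, n_rmax_ranks + 1)]
        + [f"Rmax_rv_{k}" for k in range(1, n_rmax_ranks + 1)]
        + ["MaxCR_sum", "W_var_minus_MaxCR"]
    )


FEATURE_NAMES: list[str] = feature_names()
N_FEATURES = len(FEATURE_NAMES)  # 41


def context_complexity(context21: str) -> tuple[float, float, float]:
    """Cumulative frequencies of the 1..3 most abundant flanking nucleotides.

    The centre base is excluded, leaving the 10 bp on either side of the
    variant; frequencies are proportions of those 20 bases.  Any IUPAC
    ambiguity code is pooled into a single fifth symbol.  A homopolymer
    flank scores (1, 1, 1); maximally mixed flanks score low — low
    complexity regions are artefact-prone.
    """
    if len(context21) != 21:
        raise ValueError(f"need a 21-base context, got {len(context21)} bases")
    flanks = (context21[:10] + context21[11:]).upper()
    counts = Counter("N" if b not in "ACGT" else b for b in flanks)
    top = sorted(counts.values(), reverse=True)
    top += [0] * (3 - len(top))
    f1 = top[0] / 20.0
    f2 = f1 + top[1] / 20.0
    f3 = f2 + top[2] / 20.0
    return (f1, f2, f3)


def merged_features(v: CandidateVariant, fallback_to_wells: bool = True
                    ) -> tuple[int, int]:
    """(total, variant-supporting) read counts in the merged sample.

    When the merged sample was not genotyped, optionally falls back to
    summing the per-well counts (the merged alignment is the pool of all
    wells).
    """
    if v.merged_ref_reads is None or v.merged_var_reads is None:
        if not fallback_to_wells:
            raise ValueError("merged read counts absent")
        ref = int(v.ref_reads.sum())
        var = int(v.var_reads.sum())
        return (ref + var, var)
    return (v.merged_ref_reads + v.merged_var_reads, v.merged_var_reads)


def _topk(values: np.ndarray, k: int) -> list[int]:
    order = np.sort(values)[::-1]
    out = [int(x) for x in order[:k]]
    out += [0] * (k - len(out))
    return out


def well_distribution_features(v: CandidateVariant, n_rmax_ranks: int = 3
                               ) -> dict[str, float]:
    """All plate-distribution features for one candidate."""
    ref = v.ref_reads
    var = v.var_reads
    gt = v.genotypes
    has_ref = ref > 0
    has_var = var > 0

    feats: dict[str, float] = {
        "W_ref_novar": int((has_ref & ~has_var).sum()),
        "W_ref_00": int((has_ref & (gt == GT_HOMREF)).sum()),
        "W_ref_01": int((has_ref & (gt == GT_HET)).sum()),
        "W_var_any": int(has_var.sum()),
        "W_var_11": int((has_var & (gt == GT_HOMALT)).sum()),
        "W_var_01": int((has_var & (gt == GT_HET)).sum()),
        "W_varonly_01": int((has_var & ~has_ref & (gt == GT_HET)).sum()),
        "W_refvar_any": int((has_ref & has_var).sum()),
    }
    for n in range(6):
        feats[f"W_noref_var_gt_{n}"] = int((~has_ref & (var > n)).sum())

    for k, val in enumerate(_topk(var, n_rmax_ranks), start=1):
        feats[f"Rmax_var_{k}"] = val
    for k, val in enumerate(_topk(ref + var, n_rmax_ranks), start=1):
        feats[f"Rmax_rv_{k}"] = val

    grid = has_var.reshape(v.layout.n_rows, v.layout.n_cols)
    max_c = int(grid.sum(axis=0).max())
    max_r = int(grid.sum(axis=1).max())
    feats["MaxCR_sum"] = max_c + max_r
    feats["W_var_minus_MaxCR"] = feats["W_var_any"] - feats["MaxCR_sum"]
    return feats


def assemble(v: CandidateVariant, n_rmax_ranks: int = 3) -> np.ndarray:
    """Build the full ordered feature vector for one candidate.

    Missing caller annotations become NaN here and are imputed during
    scaling (to the training-set minimum, the most pessimistic value
    after min-max scaling).
    """
    if v.context21 is None:
        raise ValueError(f"candidate {v.variant_id} has no 21-base context")
    vals: list[float] = []
    for key in QUAL_FIELDS:
        x = v.qual_fields.get(key)
        vals.append(np.nan if x is None else float(x))
    vals.extend(context_complexity(v.context21))
    vals.extend(merged_features(v))
    wd = well_distribution_features(v, n_rmax_ranks)
    names = feature_names(n_rmax_ranks)
    vals.extend(wd[name] for name in names[19:])
    out = np.asarray(vals, dtype=np.float64)
    assert out.shape == (len(names),)
    return out


@dataclass
class ScalingParams:
    """Per-feature min/max learned on a training set, for [0, 1] scaling."""

    minima: np.ndarray
    maxima: np.ndarray

    def to_dict(self) -> dict:
        return {"minima": self.minima.tolist(), "maxima": self.maxima.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(np.asarray(d["minima"], float), np.asarray(d["maxima"], float))


@dataclass
class FeatureMatrix:
    """Stacked feature vectors with ids and optional 0/1 training labels."""

    ids: list[tuple]
    X: np.ndarray  # (n_variants, n_features)
    labels: np.ndarray | None = None  # (n_variants,) 0/1
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError("X must be (n_variants, n_features)")
        if self.names is None:
            self.names = feature_names() if self.X.shape[1] == N_FEATURES else [
                f"f{i}" for i in range(self.X.shape[1])]

    @classmethod
    def from_variants(cls, variants, labels=None, n_rmax_ranks: int = 3
                      ) -> "FeatureMatrix":
        rows = [assemble(v, n_rmax_ranks) for v in variants]
        return cls(
            ids=[v.variant_id for v in variants],
            X=np.vstack(rows) if rows else np.empty((0, len(feature_names(n_rmax_ranks)))),
            labels=None if labels is None else np.asarray(labels),
            names=feature_names(n_rmax_ranks),
        )

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "variant_id", [":".join(map(str, i)) for i in self.ids])
        if self.labels is not None:
            df["label"] = self.labels
        return df


def fit_scaling(X: np.ndarray) -> ScalingParams:
    """Learn per-feature min/max on the training set, ignoring NaNs."""
    X = np.asarray(X, dtype=np.float64)
    with np.errstate(all="ignore"):
        mins = np.nanmin(X, axis=0)
        maxs = np.nanmax(X, axis=0)
    mins = np.where(np.isnan(mins), 0.0, mins)
    maxs = np.where(np.isnan(maxs), 0.0, maxs)
    return ScalingParams(minima=mins, maxima=maxs)


def apply_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Min-max scale to [0, 1] with clipping; NaN -> training minimum (0).

    A feature constant on the training set maps to 0 everywhere.
    """
    X = np.asarray(X, dtype=np.float64).copy()
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.broadcast_to(params.minima, X.shape)[nan_mask]
    span = params.maxima - params.minima
    safe = np.where(span > 0, span, 1.0)
    out = (X - params.minima) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)
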