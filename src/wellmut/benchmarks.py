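"""Desk-scale evaluation harnesses on simulated plates.

Three designs:

* :func:`run_benchmark` — train and score the classifier on one
  simulated plate and break the pass set down by ground truth
  (artefacts vs planted clone-specific variants), with SNP sensitivity
  measured on germline SNPs held out of every training subset.
* :func:`run_spiking_study` — the overfitting probe: known clonal
  somatic variants are deliberately mislabeled as UTD (UTD*) at
  UTD*/UTD ratios up to 10%, and their recovery rate is tracked.  A
  classifier that overfits its noisy 0 labels would lose UTD* recovery
  as the ratio grows.
* :func:`auc_vs_true_utd_fraction` — plants increasing fractions of
  true clone-specific variants among the UTDs and records the putative
  ROC AUC, which should fall monotonically: true variants among the
  UTDs behave like SNPs and drag the curve down.

The simulated plate stands for the post-calling candidate set, so the
training pool is built directly from the simulator's truth labels;
the upstream evidence filters are exercised by their own module tests
and by the VCF round-trip integration test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix, apply_scaling, fit_scaling
from .mutlx import (ModelSpec, MutLXResult, TrainingPool, run_mutlx)
from .simulate import (CLASS_ARTEFACT, CLASS_CLONE_SPECIFIC, SimConfig,
                       SimPlate, SpikeSet, simulate_plate, spike_utds)

logger = logging.getLogger(__name__)


@dataclass
class BenchResult:
    """Truth-resolved outcome of one classifier run on a simulated plate."""

    run_id: str
    n_utd_total: int
    n_utd_passed: int
    n_true_utd_passed: int
    n_artefact_passed: int
    n_true_utd_total: int
    n_artefact_total: int
    snp_sensitivity: float
    n_snp_holdout: int
    auc: float
    selected_cutoff: float
    cutoff_mode: str
    spiking: list[dict] = field(default_factory=list)

    @property
    def artefact_pass_rate(self) -> float:
        return (self.n_artefact_passed / self.n_artefact_total
                if self.n_artefact_total else 0.0)

    @property
    def true_utd_recovery(self) -> float:
        return (self.n_true_utd_passed / self.n_true_utd_total
                if self.n_true_utd_total else float("nan"))

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "run_id", "n_utd_total", "n_utd_passed", "n_true_utd_passed",
            "n_artefact_passed", "n_true_utd_total", "n_artefact_total",
            "snp_sensitivity", "n_snp_holdout", "auc", "selected_cutoff",
            "cutoff_mode")}
        d["artefact_pass_rate"] = self.artefact_pass_rate
        d["true_utd_recovery"] = self.true_utd_recovery
        if self.spiking:
            d["spiking"] = self.spiking
        return d


def run_benchmark(plate: SimPlate, spec: ModelSpec | None = None,
                  seed: int = 0, run_id: str = "bench",
                  extra_utd_ids: tuple = (),
                  snp_holdout_fraction: float = 0.2
                  ) -> tuple[BenchResult, MutLXResult]:
    """Full pipeline on one plate with truth-resolved bookkeeping.

    A ``snp_holdout_fraction`` share of the germline SNPs is withheld
    from the training pool entirely and only scored, so the reported
    SNP sensitivity is measured on variants no ensemble member ever
    saw during training or subset construction.
    """
    utd_ids = plate.ids_with_label(0) + list(extra_utd_ids)
    if not utd_ids:
        logger.warning("no UTD candidates; returning an empty result")
        empty = BenchResult(run_id, 0, 0, 0, 0, 0, 0, float("nan"), 0,
                            float("nan"), float("nan"), "none")
        return empty, None
    snp_ids_all = plate.ids_with_label(1)
    if not snp_ids_all:
        raise ValueError("plate has no germline SNPs to train on")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0]))
    n_hold = int(round(snp_holdout_fraction * len(snp_ids_all)))
    perm = rng.permutation(len(snp_ids_all))
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    snp_ids = [snp_ids_all[i] for i in train_idx]
    snp_hold_ids = [snp_ids_all[i] for i in hold_idx]

    by_id = plate.variants_by_id()
    fm_utd = FeatureMatrix.from_variants([by_id[i] for i in utd_ids])
    fm_snp = FeatureMatrix.from_variants([by_id[i] for i in snp_ids])
    fm_hold = FeatureMatrix.from_variants([by_id[i] for i in snp_hold_ids])
    scaling = fit_scaling(np.vstack([fm_utd.X, fm_snp.X]))
    pool = TrainingPool(utd_X=apply_scaling(fm_utd.X, scaling),
                        snp_X=apply_scaling(fm_snp.X, scaling))
    res = run_mutlx(pool, spec=spec, seed=seed, utd_ids=utd_ids, snp_ids=snp_ids)

    extra = set(extra_utd_ids)
    is_true = np.array([
        plate.truths[i].true_class == CLASS_CLONE_SPECIFIC or i in extra
        for i in utd_ids])
    is_artefact = np.array([
        plate.truths[i].true_class == CLASS_ARTEFACT for i in utd_ids])
    passed = res.scores_utd.passed

    if snp_hold_ids:
        from .mutlx import (call_variants, probability_scores,
                            uncertainty_scores)

        X_hold = apply_scaling(fm_hold.X, scaling)
        p_hold = probability_scores(res.ensemble.models, X_hold)
        u_hold = np.full(len(p_hold), np.nan)
        elig = np.flatnonzero(p_hold > 0.2)
        if elig.size:
            u_hold[elig] = uncertainty_scores(
                res.ensemble.models, X_hold[elig],
                seed=np.random.SeedSequence([seed, 0x401D]))
        hold_passed = call_variants(p_hold, u_hold, res.cutoff)
        sensitivity = float(hold_passed.mean())
    else:
        sensitivity = float("nan")

    bench = BenchResult(
        run_id=run_id,
        n_utd_total=len(utd_ids),
        n_utd_passed=int(passed.sum()),
        n_true_utd_passed=int(passed[is_true].sum()),
        n_artefact_passed=int(passed[is_artefact].sum()),
        n_true_utd_total=int(is_true.sum()),
        n_artefact_total=int(is_artefact.sum()),
        snp_sensitivity=sensitivity,
        n_snp_holdout=len(snp_hold_ids),
        auc=res.roc.auc,
        selected_cutoff=res.cutoff,
        cutoff_mode=res.mode,
    )
    return bench, res


def run_spiking_study(plate: SimPlate, ratios: list[float],
                      n_replicates: int = 10, spec: ModelSpec | None = None,
                      seed: int = 0) -> list[dict]:
    """Re-analyse the plate once per (ratio, replicate) spiked label set.

    Returns tidy rows with the UTD* recovery rate and the artefact
    false-positive count of each run.  The plate must carry no planted
    clone-specific variants, so the spiked ids are the only true UTDs.
    """
    if plate.config.n_clone_specific != 0:
        raise ValueError("spiking studies need a plate without planted "
                         "clone-specific variants")
    spikes = spike_utds(plate, ratios, n_replicates, seed=seed)
    rows = []
    for k, sp in enumerate(spikes):
        bench, _ = run_benchmark(
            plate, spec=spec, seed=seed + 1 + k,
            run_id=f"spike_r{sp.ratio:g}_rep{sp.replicate}",
            extra_utd_ids=sp.utd_star_ids)
        n_star = len(sp.utd_star_ids)
        recovery = bench.n_true_utd_passed / n_star if n_star else float("nan")
        rows.append({
            "ratio": sp.ratio, "replicate": sp.replicate, "n_utd_star": n_star,
            "utd_star_recovery": recovery,
            "artefact_fp": bench.n_artefact_passed,
            "auc": bench.auc,
        })
    return rows


def auc_vs_true_utd_fraction(fractions: list[float], n_replicates: int = 5,
                             base: SimConfig | None = None,
                             spec: ModelSpec | None = None,
                             seed: int = 0) -> list[dict]:
    """AUC of the putative ROC as true clone-specific UTDs are planted.

    ``fractions`` are target shares of the UTD pool that are genuinely
    clone-specific; the artefact count is held fixed and
    ``n_clone_specific`` solved as f/(1-f) * n_artefacts.

    The design is matched: within a replicate every fraction shares the
    same base plate (artefacts + SNPs), the same training seed, and a
    *nested* clone-specific set (the smaller fraction's variants are a
    prefix of the larger's).  Pairing removes the plate-to-plate and
    ensemble-seed variance from the fraction contrast, so the reported
    trend isolates the effect of the planted true-UTD load.
    """
    from dataclasses import replace

    from .simulate import (CLASS_CLONE_SPECIFIC, SimPlate, simulate_variant)

    base = base or SimConfig()
    for f in fractions:
        if not 0 <= f < 1:
            raise ValueError("fractions must be in [0, 1)")
    n_cs_of = {f: int(round(f / (1.0 - f) * base.n_artefacts))
               for f in fractions}
    max_cs = max(n_cs_of.values())
    rows = []
    for rep in range(n_replicates):
        base_cfg = replace(base, n_clone_specific=0, seed=seed + 1000 * rep)
        base_plate = simulate_plate(base_cfg)
        cs_rng = np.random.default_rng(
            np.random.SeedSequence([seed, rep, 0xC5]))
        cs_pool = []
        pos = 10**8  # separate coordinate range from the base plate
        for _ in range(max_cs):
            pos += int(cs_rng.integers(200, 2000))
            cs_pool.append(simulate_variant(CLASS_CLONE_SPECIFIC, base_cfg,
                                            cs_rng, chrom="sim1", pos=pos))
        for f in fractions:
            n_cs = n_cs_of[f]
            subset = cs_pool[:n_cs]
            plate = SimPlate(
                config=base_cfg,
                variants=base_plate.variants + [v for v, _ in subset],
                truths={**base_plate.truths,
                        **{v.variant_id: t for v, t in subset}},
                train_labels={**base_plate.train_labels,
                              **{v.variant_id: 0 for v, _ in subset}},
            )
            bench, _ = run_benchmark(plate, spec=spec, seed=seed + rep,
                                     run_id=f"frac{f:g}_rep{rep}")
            rows.append({"true_utd_fraction": f, "replicate": rep,
                         "n_clone_specific": n_cs, "auc": bench.auc})
    return rows
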