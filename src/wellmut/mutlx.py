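"""Noisy-label ensemble classification with dropout-based uncertainty.

The training pool pairs two imperfect label sets: candidates absent from
bulk WGS ("UTD", label 0 — mostly amplification artefacts, but salted
with an unknown fraction of genuine clone-specific mutations) and
heterozygous germline SNPs (label 1 — reliable true variants).  Because
the 0 labels are noisy, each of the 25 ensemble members is trained in
two steps:

1. train an initial model on a balanced subset (all UTDs + an
   equal-sized random SNP sample);
2. apply it to the *full* pool and temporarily prune apparently
   mislabeled rows — UTDs predicted > 0.7 and SNPs predicted < 0.3 —
   then rebuild a balanced subset from the pruned pool and train the
   final model on it.

Per candidate the ensemble yields a probability score (mean of the 25
predictions) and an uncertainty score (mean over members of the
variance of 100 test-time-dropout predictions).  An adaptive
uncertainty cutoff is chosen from a putative ROC built over uncertainty
cutoffs in [0, 0.25], and the final pass set is
``probability > 0.2 and uncertainty <= cutoff``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import MLP, ModelSpec, train_model

logger = logging.getLogger(__name__)

N_SUBSETS = 25
PRUNE_UTD_ABOVE = 0.7
PRUNE_SNP_BELOW = 0.3
P_SCORE_MIN = 0.2
UNCERTAINTY_GRID = np.linspace(0.0, 0.25, 251)
N_DROPOUT_ITER = 100


@dataclass
class TrainingPool:
    """Scaled feature rows for the two label classes."""

    utd_X: np.ndarray  # label 0
    snp_X: np.ndarray  # label 1

    def __post_init__(self) -> None:
        self.utd_X = np.atleast_2d(np.asarray(self.utd_X, dtype=np.float64))
        self.snp_X = np.atleast_2d(np.asarray(self.snp_X, dtype=np.float64))

    @property
    def n_utd(self) -> int:
        return self.utd_X.shape[0]

    @property
    def n_snp(self) -> int:
        return self.snp_X.shape[0]


def sample_snp_subset(n_snp: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a random SNP sample; with replacement only if forced."""
    if n_snp >= size:
        return rng.choice(n_snp, size=size, replace=False)
    logger.warning("only %d SNPs for a subset of %d; sampling with replacement",
                   n_snp, size)
    return rng.choice(n_snp, size=size, replace=True)


def make_balanced_subsets(pool: TrainingPool, n_subsets: int = N_SUBSETS,
                          seed: int | np.random.SeedSequence = 0
                          ) -> list[np.ndarray]:
    """SNP index sets for the balanced subsets (all UTDs are always in)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [sample_snp_subset(pool.n_snp, pool.n_utd, np.random.default_rng(child))
            for child in ss.spawn(n_subsets)]


def _stack_subset(pool: TrainingPool, snp_idx: np.ndarray,
                  utd_idx: np.ndarray | None = None):
    utd = pool.utd_X if utd_idx is None else pool.utd_X[utd_idx]
    X = np.vstack([utd, pool.snp_X[snp_idx]])
    y = np.concatenate([np.zeros(utd.shape[0]), np.ones(len(snp_idx))])
    return X, y


def prune_training_pool(pool: TrainingPool, model: MLP
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Surviving (utd_idx, snp_idx) after mislabel pruning on the full pool.

    UTDs the model scores above 0.7 look like true variants mislabeled
    as artefacts; SNPs scored below 0.3 look mislabeled in the other
    direction.  Both are removed *temporarily* — the pool itself is
    never mutated.
    """
    p_utd = model.predict_proba(pool.utd_X)
    p_snp = model.predict_proba(pool.snp_X)
    utd_keep = np.flatnonzero(~(p_utd > PRUNE_UTD_ABOVE))
    snp_keep = np.flatnonzero(~(p_snp < PRUNE_SNP_BELOW))
    return utd_keep, snp_keep


@dataclass
class Ensemble:
    """The 25 final models plus the subset bookkeeping of their training."""

    models: list[MLP]
    spec: ModelSpec
    snp_indices_used: np.ndarray  # union over all subsets, step 1 and 2
    n_pruned_utd: list[int] = field(default_factory=list)
    n_pruned_snp: list[int] = field(default_factory=list)


def two_step_fit(pool: TrainingPool, spec: ModelSpec,
                 seed: int | np.random.SeedSequence = 0,
                 n_subsets: int = N_SUBSETS) -> Ensemble:
    """Train the full two-step ensemble; a pure function of (pool, seed)."""
    if pool.n_utd == 0 or pool.n_snp == 0:
        raise ValueError("training pool needs rows of both labels")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    models: list[MLP] = []
    used: set[int] = set()
    pruned_utd: list[int] = []
    pruned_snp: list[int] = []
    for subset_ss in ss.spawn(n_subsets):
        s_sample1, s_train1, s_sample2, s_train2 = subset_ss.spawn(4)
        snp_idx1 = sample_snp_subset(pool.n_snp, pool.n_utd,
                                     np.random.default_rng(s_sample1))
        X1, y1 = _stack_subset(pool, snp_idx1)
        initial = train_model(X1, y1, spec, s_train1)
        utd_keep, snp_keep = prune_training_pool(pool, initial)
        pruned_utd.append(pool.n_utd - len(utd_keep))
        pruned_snp.append(pool.n_snp - len(snp_keep))
        if len(utd_keep) == 0:
            logger.warning("pruning removed every UTD; keeping the initial "
                           "model for this subset")
            models.append(initial)
            used.update(int(i) for i in snp_idx1)
            continue
        rng2 = np.random.default_rng(s_sample2)
        snp_idx2 = snp_keep[sample_snp_subset(len(snp_keep), len(utd_keep), rng2)]
        X2, y2 = _stack_subset(pool, snp_idx2, utd_idx=utd_keep)
        models.append(train_model(X2, y2, spec, s_train2))
        used.update(int(i) for i in snp_idx1)
        used.update(int(i) for i in snp_idx2)
    return Ensemble(models=models, spec=spec,
                    snp_indices_used=np.array(sorted(used), dtype=int),
                    n_pruned_utd=pruned_utd, n_pruned_snp=pruned_snp)


# ---------------------------------------------------------------------------
# scores


def probability_scores(models: list[MLP], X: np.ndarray) -> np.ndarray:
    """Mean over ensemble members of the predicted probabilities."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 0:
        return np.zeros(0)
    return np.mean([m.predict_proba(X) for m in models], axis=0)


def uncertainty_scores(models: list[MLP], X: np.ndarray,
                       n_iter: int = N_DROPOUT_ITER,
                       rates: tuple[float, float] | None = None,
                       seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Mean over members of the dropout-prediction variance.

    Per member: ``n_iter`` stochastic forward passes with fresh dropout
    masks; the population variance of those predictions is that member's
    uncertainty.  Bounded by 0.25 (a {0,1} half-half output).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 0:
        return np.zeros(0)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    variances = []
    for model, child in zip(models, ss.spawn(len(models))):
        preds = model.predict_dropout(X, n_iter=n_iter, rates=rates,
                                      rng=np.random.default_rng(child))
        variances.append(preds.var(axis=1))  # population variance
    return np.mean(variances, axis=0)


@dataclass
class EnsembleScores:
    """Per-variant outputs of the ensemble."""

    ids: list
    probability: np.ndarray
    uncertainty: np.ndarray
    passed: np.ndarray | None = None


# ---------------------------------------------------------------------------
# putative ROC and adaptive cutoff

MODE_HIGH_AUC = "high_auc"
MODE_LOW_AUC = "low_auc"


@dataclass
class UncertaintyRoc:
    """TPR-vs-normalised-UTD-count curve over uncertainty cutoffs.

    Built from candidates with probability score > 0.2 only.  When no
    true clone-specific variants are present every UTD is an artefact
    and this is a genuine ROC: a good model keeps SNP uncertainties low
    and artefact uncertainties high, so the AUC approaches 1.  True
    clone-specific variants among the UTDs drag the AUC down — they
    behave like SNPs.
    """

    cutoffs: np.ndarray
    tpr: np.ndarray          # fraction of eligible SNPs with u <= cutoff
    utd_count: np.ndarray
    utd_norm: np.ndarray
    auc: float
    n_eligible_snp: int
    n_eligible_utd: int


def build_roc(u_snp: np.ndarray, u_utd: np.ndarray,
              p_snp: np.ndarray | None = None, p_utd: np.ndarray | None = None,
              p_min: float = P_SCORE_MIN,
              grid: np.ndarray = UNCERTAINTY_GRID) -> UncertaintyRoc:
    """Sweep uncertainty cutoffs and integrate TPR against utd_norm.

    ``p_snp``/``p_utd`` gate eligibility at probability score > p_min;
    pass None to treat all inputs as eligible.
    """
    u_snp = np.asarray(u_snp, dtype=float)
    u_utd = np.asarray(u_utd, dtype=float)
    if p_snp is not None:
        u_snp = u_snp[np.asarray(p_snp) > p_min]
    if p_utd is not None:
        u_utd = u_utd[np.asarray(p_utd) > p_min]
    if u_snp.size == 0:
        raise ValueError("no eligible SNPs to build the curve")
    tpr = np.array([(u_snp <= c).mean() for c in grid])
    utd_count = np.array([(u_utd <= c).sum() for c in grid])
    if u_utd.size == 0:
        logger.warning("no eligible UTDs; defining AUC = 1.0")
        utd_norm = np.zeros_like(grid)
        auc = 1.0
    else:
        denom = max(int(utd_count[-1]), 1)
        utd_norm = utd_count / denom
        auc = float(np.trapezoid(tpr, utd_norm))
    return UncertaintyRoc(cutoffs=grid.copy(), tpr=tpr, utd_count=utd_count,
                          utd_norm=utd_norm, auc=auc,
                          n_eligible_snp=int(u_snp.size),
                          n_eligible_utd=int(u_utd.size))


def select_cutoff(roc: UncertaintyRoc, auc_threshold: float = 0.9,
                  tpr_target: float = 0.95) -> tuple[float, str]:
    """Adaptive uncertainty cutoff.

    Low AUC (true clone-specific variants likely present): the smallest
    cutoff reaching a 95% SNP TPR, favouring recovery.  High AUC (UTDs
    are essentially all artefacts): the operating point closest to the
    ideal corner (utd_norm 0, TPR 1), favouring artefact elimination.
    """
    if roc.auc < auc_threshold:
        ok = np.flatnonzero(roc.tpr >= tpr_target)
        if ok.size == 0:
            logger.warning("no cutoff reaches TPR %.2f; using the grid maximum",
                           tpr_target)
            return float(roc.cutoffs[-1]), MODE_LOW_AUC
        return float(roc.cutoffs[ok[0]]), MODE_LOW_AUC
    dist2 = roc.utd_norm ** 2 + (1.0 - roc.tpr) ** 2
    return float(roc.cutoffs[int(np.argmin(dist2))]), MODE_HIGH_AUC


def call_variants(probability: np.ndarray, uncertainty: np.ndarray,
                  cutoff: float, p_min: float = P_SCORE_MIN) -> np.ndarray:
    """Final pass/fail: high probability score AND low uncertainty score."""
    return (np.asarray(probability) > p_min) & (np.asarray(uncertainty) <= cutoff)


# ---------------------------------------------------------------------------
# convenience front-end


@dataclass
class MutLXResult:
    scores_utd: EnsembleScores
    scores_snp: EnsembleScores
    roc: UncertaintyRoc
    cutoff: float
    mode: str
    ensemble: Ensemble


def _eligible_uncertainty(models, X, p, seed) -> np.ndarray:
    """Uncertainty for rows passing the probability gate; NaN elsewhere.

    Rows with probability score <= 0.2 can never pass the final call and
    never enter the putative ROC, so their dropout passes are skipped.
    """
    u = np.full(X.shape[0], np.nan)
    idx = np.flatnonzero(p > P_SCORE_MIN)
    if idx.size:
        u[idx] = uncertainty_scores(models, X[idx], seed=seed)
    return u


def run_mutlx(pool: TrainingPool, spec: ModelSpec | None = None,
              seed: int = 0, utd_ids: list | None = None,
              snp_ids: list | None = None) -> MutLXResult:
    """Fit the ensemble on a pool and score that pool end to end."""
    spec = spec or ModelSpec(input_width=pool.utd_X.shape[1])
    ss = np.random.SeedSequence(seed)
    fit_ss, unc_ss = ss.spawn(2)
    ens = two_step_fit(pool, spec, seed=fit_ss)
    p_utd = probability_scores(ens.models, pool.utd_X)
    p_snp = probability_scores(ens.models, pool.snp_X)
    ss_utd, ss_snp = unc_ss.spawn(2)
    u_utd = _eligible_uncertainty(ens.models, pool.utd_X, p_utd, ss_utd)
    u_snp = _eligible_uncertainty(ens.models, pool.snp_X, p_snp, ss_snp)
    roc = build_roc(u_snp, u_utd, p_snp, p_utd)
    cutoff, mode = select_cutoff(roc)
    scores_utd = EnsembleScores(utd_ids or list(range(pool.n_utd)), p_utd, u_utd,
                                call_variants(p_utd, u_utd, cutoff))
    scores_snp = EnsembleScores(snp_ids or list(range(pool.n_snp)), p_snp, u_snp,
                                call_variants(p_snp, u_snp, cutoff))
    return MutLXResult(scores_utd, scores_snp, roc, cutoff, mode, ens)
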