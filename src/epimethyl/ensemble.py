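"""Adaptive bootstrap search over CpG biomarker panels scored by LDA.

The classifier at the heart of the pipeline: candidate panels of 15-40
CpG sites are drawn from the top-200 differential pool, each panel is
evaluated by 20 replicate linear-discriminant fits on random 8 control +
8 CP training splits with the held-out subjects as the validation set,
and a panel whose pooled sensitivity exceeds 98% and pooled specificity
exceeds 90% (strict) across the 20 replicates is retained as a "good"
model.  Periodically (about every 10,000 evaluations) the sites that
recur in good models have their sampling weights boosted so the search
concentrates on them.

With p (panel size) approaching or exceeding n (16 training subjects)
the pooled covariance is singular, so the discriminant uses convex
shrinkage toward its diagonal: (1 - lambda) * Sigma + lambda *
diag(Sigma), lambda default 0.5 (lambda = 1 is diagonal LDA).
Discriminant scores are affinely normalized so the between-class
midpoint maps to 5 and the class means to 4 (control) and 6 (CP); a
subject votes CP when its score is above 5, control below 5, and a
score of exactly 5 abstains.  Blinded subjects are classified by the
majority of all good-model replicate votes; vote fractions feed ROC
analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .datamodel import Group, MethylationMatrix, ValidationError

__all__ = [
    "LDAModel",
    "ReplicateEval",
    "CpGSetModel",
    "SearchState",
    "ClassMetrics",
    "ROCCurve",
    "fit_lda",
    "evaluate_model",
    "passes_gates",
    "search_models",
    "vote_classify",
    "compute_metrics",
    "roc_from_votes",
    "theoretical_roc",
    "models_to_json",
    "models_from_json",
    "SCORE_CENTER",
    "SENSITIVITY_GATE",
    "SPECIFICITY_GATE",
    "PANEL_RANGE_DEFAULT",
]

#: Normalized discriminant center point; CP votes are scores above it.
SCORE_CENTER = 5.0
#: Pooled-replicate gates a panel must strictly exceed to be "good".
SENSITIVITY_GATE = 0.98
SPECIFICITY_GATE = 0.90
PANEL_RANGE_DEFAULT = (15, 40)


# ---------------------------------------------------------------------
# LDA with center-5 normalization
# ---------------------------------------------------------------------


@dataclass
class LDAModel:
    """A fitted two-class discriminant over a fixed site panel.

    ``score(X)`` returns normalized scores with the training control
    mean at 4, the CP mean at 6 and the midpoint at 5; a degenerate fit
    (zero between-class separation along the discriminant) scores every
    subject exactly 5, i.e. abstains.
    """

    site_ids: tuple[str, ...]
    weights: np.ndarray
    control_mean_score: float
    cp_mean_score: float
    degenerate: bool = False

    def score(self, scores_matrix: np.ndarray) -> np.ndarray:
        """Normalized scores for subjects given a (n_subjects, n_sites)
        slice in this model's site order."""
        if self.degenerate:
            return np.full(scores_matrix.shape[0], SCORE_CENTER)
        raw = scores_matrix @ self.weights
        span = self.cp_mean_score - self.control_mean_score
        return 4.0 + 2.0 * (raw - self.control_mean_score) / span

    def predict_cp(self, scores_matrix: np.ndarray) -> np.ndarray:
        return self.score(scores_matrix) > SCORE_CENTER


def fit_lda(
    train_scores: np.ndarray,
    is_cp: np.ndarray,
    site_ids: tuple[str, ...] = (),
    ridge_lambda: float = 0.5,
) -> LDAModel:
    """Fisher discriminant with diagonal-shrunk pooled covariance.

    ``train_scores`` is (n_subjects, n_sites); ``is_cp`` the boolean
    class vector.  Raises when a class is missing.  Zero within-class
    scatter on a feature is handled by a small diagonal floor.
    """
    x = np.asarray(train_scores, dtype=float)
    y = np.asarray(is_cp, dtype=bool)
    if not y.any() or y.all():
        raise ValidationError("training set must contain both classes")
    if not 0.0 <= ridge_lambda <= 1.0:
        raise ValidationError("ridge_lambda must be in [0, 1]")
    x0, x1 = x[~y], x[y]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    n0, n1 = x0.shape[0], x1.shape[0]
    c0 = x0 - mu0
    c1 = x1 - mu1
    pooled = (c0.T @ c0 + c1.T @ c1) / max(n0 + n1 - 2, 1)
    diag = np.diag(np.diag(pooled))
    sigma = (1.0 - ridge_lambda) * pooled + ridge_lambda * diag
    floor = 1e-8 * max(float(np.trace(sigma)) / sigma.shape[0], 1.0)
    sigma = sigma + floor * np.eye(sigma.shape[0])
    try:
        w = np.linalg.solve(sigma, mu1 - mu0)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(sigma, mu1 - mu0, rcond=None)[0]
    m0, m1 = float(w @ mu0), float(w @ mu1)
    degenerate = not np.isfinite(m1 - m0) or abs(m1 - m0) < 1e-12
    return LDAModel(
        site_ids=tuple(site_ids),
        weights=w,
        control_mean_score=m0,
        cp_mean_score=m1,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------
# Panel evaluation
# ---------------------------------------------------------------------


@dataclass
class ReplicateEval:
    train_subject_ids: tuple[str, ...]
    tp: int
    fp: int
    tn: int
    fn: int
    lda: LDAModel


@dataclass
class CpGSetModel:
    site_ids: tuple[str, ...]
    replicates: list[ReplicateEval]
    sensitivity: float  # pooled over replicates
    specificity: float
    is_good: bool


def passes_gates(
    sensitivity: float,
    specificity: float,
    sens_gate: float = SENSITIVITY_GATE,
    spec_gate: float = SPECIFICITY_GATE,
) -> bool:
    """Strict inequalities: a pooled sensitivity of exactly 0.98 or
    specificity of exactly 0.90 does not qualify."""
    return sensitivity > sens_gate and specificity > spec_gate


def _labels_from(matrix: MethylationMatrix) -> np.ndarray:
    groups = matrix.groups
    if any(g is Group.UNKNOWN for g in groups):
        raise ValidationError("evaluation cohort contains unlabelled subjects")
    return np.array([g is Group.CP for g in groups], dtype=bool)


def evaluate_model(
    site_ids: tuple[str, ...],
    matrix: MethylationMatrix,
    rng: np.random.Generator,
    n_replicates: int = 20,
    train_per_group: int = 8,
    ridge_lambda: float = 0.5,
    sens_gate: float = SENSITIVITY_GATE,
    spec_gate: float = SPECIFICITY_GATE,
) -> CpGSetModel:
    """Score one panel by replicated random train/validation splits.

    Each replicate trains on ``train_per_group`` random subjects per
    class and scores the remaining subjects; sensitivity and specificity
    are pooled over the confusion counts of all replicates (robust to
    tiny per-replicate validation classes) and gated strictly.
    """
    index = matrix.site_index()
    try:
        rows = [index[sid] for sid in site_ids]
    except KeyError as exc:
        raise ValidationError(f"site {exc.args[0]!r} absent from matrix") from None
    y = _labels_from(matrix)
    cp_idx = np.nonzero(y)[0]
    ctrl_idx = np.nonzero(~y)[0]
    if len(cp_idx) < train_per_group + 1 or len(ctrl_idx) < train_per_group + 1:
        raise ValidationError(
            f"need at least {train_per_group + 1} subjects per class"
        )
    x = matrix.scores[rows, :].T  # subjects x panel
    subj_ids = matrix.subject_ids

    replicates: list[ReplicateEval] = []
    tp = fp = tn = fn = 0
    for _ in range(n_replicates):
        tr_cp = rng.choice(cp_idx, size=train_per_group, replace=False)
        tr_ct = rng.choice(ctrl_idx, size=train_per_group, replace=False)
        train = np.concatenate([tr_ct, tr_cp])
        mask = np.zeros(len(y), dtype=bool)
        mask[train] = True
        lda = fit_lda(x[mask], y[mask], site_ids=site_ids, ridge_lambda=ridge_lambda)
        pred = lda.predict_cp(x[~mask])
        truth = y[~mask]
        r_tp = int((pred & truth).sum())
        r_fp = int((pred & ~truth).sum())
        r_tn = int((~pred & ~truth).sum())
        r_fn = int((~pred & truth).sum())
        tp, fp, tn, fn = tp + r_tp, fp + r_fp, tn + r_tn, fn + r_fn
        replicates.append(
            ReplicateEval(
                train_subject_ids=tuple(subj_ids[i] for i in train),
                tp=r_tp,
                fp=r_fp,
                tn=r_tn,
                fn=r_fn,
                lda=lda,
            )
        )
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return CpGSetModel(
        site_ids=tuple(site_ids),
        replicates=replicates,
        sensitivity=sens,
        specificity=spec,
        is_good=passes_gates(sens, spec, sens_gate, spec_gate),
    )


# ---------------------------------------------------------------------
# Adaptive search
# ---------------------------------------------------------------------


@dataclass
class SearchState:
    pool: tuple[str, ...]
    weights: np.ndarray
    evaluations: int = 0
    n_good: int = 0
    reweight_interval: int = 10_000
    boost: float = 2.0
    seed: int | None = None


def search_models(
    pool: list[str],
    matrix: MethylationMatrix,
    budget: int,
    seed: int | None = None,
    panel_range: tuple[int, int] = PANEL_RANGE_DEFAULT,
    reweight_interval: int = 10_000,
    boost: float = 2.0,
    max_good: int | None = None,
    n_replicates: int = 20,
    train_per_group: int = 8,
    ridge_lambda: float = 0.5,
    sens_gate: float = SENSITIVITY_GATE,
    spec_gate: float = SPECIFICITY_GATE,
) -> tuple[list[CpGSetModel], SearchState]:
    """Adaptive bootstrap panel search.

    Loop: draw a panel size uniformly in ``panel_range``, draw that many
    distinct pool sites proportionally to the current weights, evaluate,
    and record good models (deduplicated by site set).  Every
    ``reweight_interval`` evaluations the pool sites appearing in good
    models more often than the pool median have their weights multiplied
    by ``boost`` and the weights are renormalized.  Deterministic given
    ``seed``; stops early once ``max_good`` distinct good models are
    found.  An exhausted budget with no good models returns an empty
    list, not an exception.
    """
    if budget < 1:
        raise ValidationError("search budget must be >= 1")
    lo, hi = panel_range
    if not 1 <= lo <= hi <= len(pool):
        raise ValidationError(
            f"panel range {panel_range} incompatible with pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    weights = np.full(len(pool), 1.0 / len(pool))
    pool_index = {sid: i for i, sid in enumerate(pool)}
    good: list[CpGSetModel] = []
    seen: set[frozenset[str]] = set()
    appearance = np.zeros(len(pool))
    state = SearchState(
        pool=tuple(pool),
        weights=weights,
        reweight_interval=reweight_interval,
        boost=boost,
        seed=seed,
    )
    for i in range(budget):
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(pool), size=k, replace=False, p=weights)
        site_ids = tuple(pool[j] for j in chosen)
        model = evaluate_model(
            site_ids,
            matrix,
            rng,
            n_replicates=n_replicates,
            train_per_group=train_per_group,
            ridge_lambda=ridge_lambda,
            sens_gate=sens_gate,
            spec_gate=spec_gate,
        )
        state.evaluations += 1
        if model.is_good:
            key = frozenset(site_ids)
            if key not in seen:
                seen.add(key)
                good.append(model)
                for sid in site_ids:
                    appearance[pool_index[sid]] += 1
        if max_good is not None and len(good) >= max_good:
            break
        if (i + 1) % reweight_interval == 0 and appearance.any():
            median = np.median(appearance)
            weights = weights * np.where(appearance > median, boost, 1.0)
            weights = weights / weights.sum()
            state.weights = weights
    state.n_good = len(good)
    state.weights = weights
    return good, state


# ---------------------------------------------------------------------
# Voting, metrics, ROC
# ---------------------------------------------------------------------


def vote_classify(
    models: list[CpGSetModel],
    blinded: MethylationMatrix,
    mode: str = "replay",
    training_matrix: MethylationMatrix | None = None,
    ridge_lambda: float = 0.5,
) -> pd.DataFrame:
    """Classify blinded subjects by majority vote of all good-model
    replicate LDAs.

    Each model contributes its replicate fits (``mode="replay"``, the
    default: the stored training-phase fits are applied as-is;
    ``mode="refit"`` refits each replicate from its stored training
    subjects on ``training_matrix``).  A score above 5 votes CP, below 5
    control, exactly 5 abstains.  Ties (including the all-abstain
    degenerate case) are classified control with a flag.

    Returns one row per blinded subject: ``votes_total`` (= replicates x
    models, always), ``votes_cp``, ``votes_control``, ``abstentions``,
    ``vote_fraction`` (CP votes / total), ``predicted``, ``tie_flag``.
    """
    if not models:
        raise ValidationError("vote classification needs at least one model")
    if mode not in {"replay", "refit"}:
        raise ValueError(f"unknown vote mode {mode!r}")
    if mode == "refit" and training_matrix is None:
        raise ValidationError("refit mode requires the training matrix")
    index = blinded.site_index()
    n_subj = blinded.n_subjects
    votes_cp = np.zeros(n_subj, dtype=int)
    votes_ctrl = np.zeros(n_subj, dtype=int)
    abstain = np.zeros(n_subj, dtype=int)
    total = 0
    for model in models:
        try:
            rows = [index[sid] for sid in model.site_ids]
        except KeyError as exc:
            raise ValidationError(
                f"blinded matrix lacks site {exc.args[0]!r}"
            ) from None
        x = blinded.scores[rows, :].T
        for rep in model.replicates:
            if mode == "replay":
                lda = rep.lda
            else:
                tm = training_matrix.select_subjects(rep.train_subject_ids)
                y = _labels_from(tm)
                tr_rows = [tm.site_index()[sid] for sid in model.site_ids]
                lda = fit_lda(
                    tm.scores[tr_rows, :].T,
                    y,
                    site_ids=model.site_ids,
                    ridge_lambda=ridge_lambda,
                )
            s = lda.score(x)
            votes_cp += s > SCORE_CENTER
            votes_ctrl += s < SCORE_CENTER
            abstain += s == SCORE_CENTER
            total += 1
    tie = votes_cp == votes_ctrl
    predicted = np.where(votes_cp > votes_ctrl, Group.CP.value, Group.CONTROL.value)
    return pd.DataFrame(
        {
            "subject_id": blinded.subject_ids,
            "votes_total": total,
            "votes_cp": votes_cp,
            "votes_control": votes_ctrl,
            "abstentions": abstain,
            "vote_fraction": votes_cp / total,
            "predicted": predicted,
            "tie_flag": tie,
        }
    )


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    def as_percent(self) -> dict[str, int]:
        """Display form: each rate as a percentage rounded to integer."""
        return {
            name: int(round(100.0 * getattr(self, name)))
            for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
            if np.isfinite(getattr(self, name))
        }


def compute_metrics(
    predicted: "np.ndarray | list",
    truth: "np.ndarray | list",
    positive: str = Group.CP.value,
) -> ClassMetrics:
    """Confusion counts and rates, CP as the positive class."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValidationError("predictions and truth must be non-empty and aligned")
    p = pred == positive
    t = true == positive
    return ClassMetrics(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_from_votes(
    vote_fractions: np.ndarray,
    truth: np.ndarray,
    positive: str = Group.CP.value,
) -> ROCCurve:
    """ROC from sweeping a threshold over the vote fractions; subjects
    at the threshold count as positive; trapezoidal AUC."""
    frac = np.asarray(vote_fractions, dtype=float)
    t = np.asarray(truth) == positive
    if t.all() or not t.any():
        raise ValidationError("ROC needs both classes in the truth labels")
    fpr, tpr, thr = _roc_curve(t.astype(int), frac, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_auc(fpr, tpr)))


def theoretical_roc(
    models: list[CpGSetModel],
    matrix: MethylationMatrix,
    n_bootstrap: int,
    seed: int | None = None,
    subset_size: int = 11,
) -> ROCCurve:
    """Maximum theoretical ROC from saturated bootstrap sampling of the
    labelled training cohort: random subject subsets are vote-classified
    with the stored fits and the pooled (fraction, label) pairs define
    the envelope curve."""
    if not models:
        raise ValidationError("theoretical ROC needs at least one model")
    if n_bootstrap < 1:
        raise ValidationError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(seed)
    y = _labels_from(matrix)
    subset_size = min(subset_size, matrix.n_subjects)
    fractions: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    ids = np.array(matrix.subject_ids)
    for _ in range(n_bootstrap):
        pick = rng.choice(matrix.n_subjects, size=subset_size, replace=False)
        sub = matrix.select_subjects(ids[pick])
        votes = vote_classify(models, sub)
        fractions.append(votes["vote_fraction"].to_numpy())
        labels.append(y[pick])
    frac = np.concatenate(fractions)
    lab = np.concatenate(labels)
    truth = np.where(lab, Group.CP.value, Group.CONTROL.value)
    return roc_from_votes(frac, truth)


# ---------------------------------------------------------------------
# Model store (structured text)
# ---------------------------------------------------------------------


def models_to_json(models: list[CpGSetModel], path) -> None:
    """Persist good models with enough detail to replay any evaluation:
    site ids, per-replicate training subjects, confusion counts, and the
    fitted discriminant parameters."""
    payload = []
    for m in models:
        payload.append(
            {
                "site_ids": list(m.site_ids),
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "is_good": m.is_good,
                "replicates": [
                    {
                        "train_subject_ids": list(r.train_subject_ids),
                        "tp": r.tp,
                        "fp": r.fp,
                        "tn": r.tn,
                        "fn": r.fn,
                        "weights": [float(w) for w in r.lda.weights],
                        "control_mean_score": r.lda.control_mean_score,
                        "cp_mean_score": r.lda.cp_mean_score,
                        "degenerate": r.lda.degenerate,
                    }
                    for r in m.replicates
                ],
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def models_from_json(path) -> list[CpGSetModel]:
    with open(path) as fh:
        payload = json.load(fh)
    models = []
    for m in payload:
        site_ids = tuple(m["site_ids"])
        reps = [
            ReplicateEval(
                train_subject_ids=tuple(r["train_subject_ids"]),
                tp=r["tp"],
                fp=r["fp"],
                tn=r["tn"],
                fn=r["fn"],
                lda=LDAModel(
                    site_ids=site_ids,
                    weights=np.array(r["weights"], dtype=float),
                    control_mean_score=r["control_mean_score"],
                    cp_mean_score=r["cp_mean_score"],
                    degenerate=r["degenerate"],
                ),
            )
            for r in m["replicates"]
        ]
        models.append(
            CpGSetModel(
                site_ids=site_ids,
                replicates=reps,
                sensitivity=m["sensitivity"],
                specificity=m["specificity"],
                is_good=m["is_good"],
            )
        )
    return models
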