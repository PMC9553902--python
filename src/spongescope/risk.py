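"""Sponge-signature survival risk model.

Greedy forward gene selection maximising the *validation* Cox partial
log-likelihood over many random train/validation splits (rbsurv-style
repeated holdout): at each step, every remaining candidate is fitted together
with the already-selected genes on the training two-thirds of each split and
scored by the partial log-likelihood of the fitted coefficients on the
held-out third; the candidate with the highest mean validation log-likelihood
is accepted if it improves on the current model. The final model is a single
Cox refit on the full cohort; the risk score is the linear predictor
eta_i = sum_g beta_g * x_ig, dichotomised at its training-cohort median.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .survival import (
    CoxEngine,
    KMCurve,
    LogrankResult,
    SurvivalCohort,
    km_estimate,
    logrank_test,
)

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "RiskModel",
    "EvaluationResult",
    "select_genes",
    "fit_risk_model",
    "stratify",
    "evaluate",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Repeated-holdout forward-selection settings.

    ``n_iterations`` random train/validation splits (stratified on event
    status so every training set contains events) are drawn once and reused
    across steps and candidates; selection stops at ``max_genes`` or when the
    best candidate improves the mean validation log-likelihood by no more
    than ``improvement_tolerance``.
    """

    n_iterations: int = 1000
    train_fraction: float = 2.0 / 3.0
    max_genes: int = 4
    improvement_tolerance: float = 0.0
    rng_seed: int = 0
    ties: str = "breslow"
    resample_cap: int = 10

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.max_genes < 1:
            raise ValueError("max_genes must be >= 1")
        if self.improvement_tolerance < 0:
            raise ValueError("improvement_tolerance must be >= 0")


@dataclass
class SelectionResult:
    selected_genes: list[str]
    step_val_loglik: list[float]   # mean validation loglik after each accepted step
    baseline_val_loglik: float     # mean validation loglik of the empty model
    stop_reason: str               # max_genes | no_improvement | no_candidates


@dataclass
class RiskModel:
    """Selected genes, full-cohort Cox coefficients, and the median cutoff."""

    selected_genes: list[str]
    coefficients: dict[str, float]
    cutoff: float
    ties: str = "breslow"
    rng_seed: int | None = None

    def linear_predictor(self, cohort: SurvivalCohort) -> np.ndarray:
        missing = [g for g in self.selected_genes if g not in cohort.expression.columns]
        if missing:
            raise KeyError(f"cohort is missing model genes: {missing}")
        X = cohort.expression[self.selected_genes].to_numpy()
        beta = np.array([self.coefficients[g] for g in self.selected_genes])
        return X @ beta

    def to_json(self, path) -> None:
        payload = {
            "selected_genes": self.selected_genes,
            "coefficients": self.coefficients,
            "cutoff": self.cutoff,
            "ties": self.ties,
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            selected_genes=list(d["selected_genes"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            cutoff=float(d["cutoff"]),
            ties=d.get("ties", "breslow"),
            rng_seed=d.get("rng_seed"),
        )


@dataclass
class EvaluationResult:
    labels: np.ndarray
    km_low: KMCurve | None
    km_high: KMCurve | None
    logrank: LogrankResult | None
    degenerate: bool


def _stratified_splits(
    event: np.ndarray,
    n_iterations: int,
    train_fraction: float,
    rng: np.random.Generator,
    resample_cap: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random train/validation index splits, stratified on event status.

    Each split must leave at least one event on both sides; violating splits
    are redrawn up to ``resample_cap`` times each.
    """
    ev_idx = np.nonzero(event == 1)[0]
    cs_idx = np.nonzero(event == 0)[0]
    if len(ev_idx) < 2:
        raise ValueError("need at least two events to form train/validation splits")
    n_ev_train = min(max(1, round(train_fraction * len(ev_idx))), len(ev_idx) - 1)
    n_cs_train = round(train_fraction * len(cs_idx))
    splits = []
    for _ in range(n_iterations):
        for _try in range(resample_cap):
            ev_perm = rng.permutation(ev_idx)
            cs_perm = rng.permutation(cs_idx)
            train = np.sort(np.concatenate([ev_perm[:n_ev_train], cs_perm[:n_cs_train]]))
            valid = np.sort(np.concatenate([ev_perm[n_ev_train:], cs_perm[n_cs_train:]]))
            if event[train].sum() >= 1 and event[valid].sum() >= 1 and len(valid) >= 2:
                break
        else:
            raise RuntimeError("could not draw a valid train/validation split")
        splits.append((train, valid))
    return splits


def select_genes(
    cohort: SurvivalCohort,
    candidates: Sequence[str],
    config: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """Greedy forward selection by mean validation partial log-likelihood.

    Deterministic given ``config.rng_seed``. Returns the ordered selected
    genes, the mean validation log-likelihood after each accepted step, the
    empty-model baseline, and why selection stopped.
    """
    candidates = list(candidates)
    missing = [g for g in candidates if g not in cohort.expression.columns]
    if missing:
        raise KeyError(f"candidate genes not in cohort: {missing}")
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate genes")
    if not candidates:
        return SelectionResult([], [], float("nan"), "no_candidates")

    rng = np.random.default_rng(config.rng_seed)
    expr = cohort.expression[candidates].to_numpy()
    col_of = {g: j for j, g in enumerate(candidates)}
    splits = _stratified_splits(
        cohort.event, config.n_iterations, config.train_fraction, rng, config.resample_cap
    )

    # per-split engines and pre-sorted full candidate matrices
    prepared = []
    for train, valid in splits:
        eng_tr = CoxEngine(cohort.time[train], cohort.event[train], config.ties)
        eng_va = CoxEngine(cohort.time[valid], cohort.event[valid], config.ties)
        X_tr = expr[train][eng_tr.order]       # sorted once; columns sliced later
        X_va = expr[valid][eng_va.order]
        prepared.append((eng_tr, eng_va, X_tr, X_va))

    def mean_val_loglik(cols: list[int]) -> float:
        vals = []
        for eng_tr, eng_va, X_tr, X_va in prepared:
            fit = eng_tr.fit(X_tr[:, cols], presorted=True)
            beta = fit.coefficients
            if not np.all(np.isfinite(beta)):
                continue
            # loglik on pre-sorted validation covariates
            Xv = X_va[:, cols]
            eta = Xv @ beta
            vals.append(_sorted_loglik(eng_va, eta))
        return float(np.mean(vals)) if vals else -np.inf

    baseline = float(
        np.mean([_sorted_loglik(eng_va, np.zeros(eng_va.n)) for _, eng_va, _, _ in prepared])
    )

    selected: list[str] = []
    step_ll: list[float] = []
    current = baseline
    remaining = list(candidates)
    stop = "max_genes"
    while len(selected) < config.max_genes:
        if not remaining:
            stop = "no_candidates"
            break
        best_gene, best_ll = None, -np.inf
        sel_cols = [col_of[g] for g in selected]
        for g in remaining:
            ll = mean_val_loglik(sel_cols + [col_of[g]])
            if ll > best_ll:
                best_gene, best_ll = g, ll
        if best_gene is None or best_ll - current <= config.improvement_tolerance:
            stop = "no_improvement"
            break
        selected.append(best_gene)
        remaining.remove(best_gene)
        step_ll.append(best_ll)
        current = best_ll
    return SelectionResult(selected, step_ll, baseline, stop)


def _sorted_loglik(engine: CoxEngine, eta: np.ndarray) -> float:
    """Breslow/Efron partial loglik for a pre-sorted linear predictor."""
    return engine.loglik_presorted(eta)


def fit_risk_model(
    cohort: SurvivalCohort,
    selected_genes: Sequence[str],
    ties: str = "breslow",
    rng_seed: int | None = None,
) -> RiskModel:
    """Final Cox refit on the full cohort and median linear-predictor cutoff."""
    selected_genes = list(selected_genes)
    if not selected_genes:
        raise ValueError("selected_genes must be non-empty")
    missing = [g for g in selected_genes if g not in cohort.expression.columns]
    if missing:
        raise KeyError(f"cohort is missing genes: {missing}")
    X = cohort.expression[selected_genes].to_numpy()
    eng = CoxEngine(cohort.time, cohort.event, ties)
    fit = eng.fit(X)
    if not fit.converged:
        raise RuntimeError("full-cohort Cox fit did not converge")
    eta = X @ fit.coefficients
    return RiskModel(
        selected_genes=selected_genes,
        coefficients={g: float(b) for g, b in zip(selected_genes, fit.coefficients)},
        cutoff=float(np.median(eta)),
        ties=ties,
        rng_seed=rng_seed,
    )


def stratify(model: RiskModel, cohort: SurvivalCohort) -> np.ndarray:
    """Label samples 'high_risk' iff eta > cutoff (ties go to 'low_risk').

    The training-derived cutoff is applied unchanged to validation cohorts.
    """
    eta = model.linear_predictor(cohort)
    return np.where(eta > model.cutoff, "high_risk", "low_risk")


def evaluate(model: RiskModel, cohort: SurvivalCohort) -> EvaluationResult:
    """Stratify a cohort and compare risk-group survival (KM + log-rank).

    A degenerate stratification (one group empty) is reported as such; no
    p-value is fabricated.
    """
    labels = stratify(model, cohort)
    low = labels == "low_risk"
    high = labels == "high_risk"
    if not low.any() or not high.any():
        return EvaluationResult(labels, None, None, None, degenerate=True)
    km_low = km_estimate(cohort.time[low], cohort.event[low])
    km_high = km_estimate(cohort.time[high], cohort.event[high])
    lr = logrank_test(labels, cohort.time, cohort.event)
    return EvaluationResult(labels, km_low, km_high, lr, degenerate=False)
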