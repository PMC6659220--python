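"""Classification of posterior cheating probabilities and the scenario study.

Turns per-student posterior probabilities into cheater flags (fixed cut-off,
default 0.90, or an entropy-minimising classification-stump cut-off),
computes confusion-table metrics against known labels, and orchestrates the
replicate-based simulation study that calibrates the detector's sensitivity
and specificity per scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .model import _as_binary_array
from .sampler import ChainConfig, DeterministicGatedIRT, REDUCED_CHAIN
from .simulate import ScenarioConfig, simulate_exam

__all__ = [
    "DetectionMetrics",
    "StudyResult",
    "classify",
    "best_cutoff_entropy",
    "confusion_metrics",
    "run_simulation_study",
    "METRIC_NAMES",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "absolute_agreement",
    "apparent_prevalence",
    "cohens_kappa",
)


@dataclass(frozen=True)
class DetectionMetrics:
    """Confusion-table metrics of a cheater classification.

    All values are proportions (kappa in ``[-1, 1]``); undefined ratios
    (zero denominators) are NaN, never exceptions.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    absolute_agreement: float
    apparent_prevalence: float
    cohens_kappa: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass
class StudyResult:
    """Aggregated output of the replicate simulation study.

    Attributes
    ----------
    summary : DataFrame
        Rows = metrics (plus ``best_cutoff``), columns = scenarios; cells
        hold across-replicate means with SDs in the companion ``sd`` frame.
    sd : DataFrame
        Across-replicate standard deviations (NaN with < 2 replicates).
    replicates : DataFrame
        Long-format per-replicate metrics.
    best_cutoff : dict
        Scenario name -> entropy-optimal cut-off on the pooled
        (probability, truth) pairs of all replicates.
    best_cutoff_per_replicate : dict
        Scenario name -> array of per-replicate entropy-optimal cut-offs.
    excluded : dict
        Scenario name -> number of replicates dropped due to errors.
    """

    summary: pd.DataFrame
    sd: pd.DataFrame
    replicates: pd.DataFrame
    best_cutoff: dict = field(default_factory=dict)
    best_cutoff_per_replicate: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)


def classify(p_cheater: ArrayLike, cutoff: float) -> NDArray[np.int_]:
    """Flag students whose posterior cheating probability exceeds ``cutoff``.

    The comparison is strict (``>``): a student exactly at the cut-off is
    not flagged, the conservative choice towards honest students.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    p = np.asarray(p_cheater, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p > cutoff).astype(int)


def _binary_entropy(labels: NDArray) -> float:
    """Shannon entropy (bits) of a binary label vector; 0 for empty/pure."""
    n = labels.size
    if n == 0:
        return 0.0
    p = labels.mean()
    h = 0.0
    for q in (p, 1 - p):
        if q > 0:
            h -= q * np.log2(q)
    return h


def best_cutoff_entropy(p_cheater: ArrayLike, truth: ArrayLike) -> float:
    """Entropy-minimising single-split cut-off on the posterior probabilities.

    Candidate cut-offs are the midpoints between consecutive distinct sorted
    probability values (a classification stump: one split, as a single
    threshold is sought).  The returned candidate minimises the
    child-weighted sum of binary entropies of the truth labels; ties are
    broken towards the largest candidate, which favours specificity.
    """
    p = np.asarray(p_cheater, dtype=float)
    t = _as_binary_array(truth, "truth")
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("p_cheater and truth must be 1-D of equal length")
    if t.min() == t.max():
        raise ValueError("truth must contain both classes for an entropy split")
    order = np.argsort(p, kind="stable")
    ps, ts = p[order], t[order]
    distinct = np.unique(ps)
    if distinct.size < 2:
        raise ValueError("need at least two distinct probability values")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n = ps.size
    best_c, best_h = None, np.inf
    for c in candidates:
        left = ts[ps <= c]
        right = ts[ps > c]
        h = (left.size / n) * _binary_entropy(left) + (right.size / n) * _binary_entropy(right)
        # <= so that later (larger) candidates win ties
        if h <= best_h - 1e-12 or (abs(h - best_h) <= 1e-12):
            best_c, best_h = float(c), min(h, best_h)
    return best_c


def confusion_metrics(predicted: ArrayLike, truth: ArrayLike) -> DetectionMetrics:
    """Confusion-table metrics of predicted vs true cheater labels.

    SEN = TP/(TP+FN), SPE = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    agreement = (TP+TN)/M, apparent prevalence = (TP+FP)/M, and Cohen's
    kappa = (p_o - p_e)/(1 - p_e) with marginal-product expected agreement.
    """
    pred = _as_binary_array(predicted, "predicted")
    t = _as_binary_array(truth, "truth")
    if pred.shape != t.shape or pred.ndim != 1:
        raise ValueError("predicted and truth must be 1-D of equal length")
    m = t.size
    tp = int(((pred == 1) & (t == 1)).sum())
    tn = int(((pred == 0) & (t == 0)).sum())
    fp = int(((pred == 1) & (t == 0)).sum())
    fn = int(((pred == 0) & (t == 1)).sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    p_o = (tp + tn) / m
    p_yes = ((tp + fp) / m) * ((tp + fn) / m)
    p_no = ((tn + fn) / m) * ((tn + fp) / m)
    p_e = p_yes + p_no
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else float("nan")
    return DetectionMetrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        absolute_agreement=p_o,
        apparent_prevalence=(tp + fp) / m,
        cohens_kappa=kappa,
    )


def run_simulation_study(
    scenarios: Sequence[ScenarioConfig],
    chain: ChainConfig = REDUCED_CHAIN,
    cutoff: float = 0.9,
    theta_c_prior_variance: float = 2.0,
    progress: bool = False,
) -> StudyResult:
    """Replicate study: simulate, fit, classify, and aggregate per scenario.

    For every scenario and replicate: simulate an examination, fit the gated
    mixture by MCMC, flag students at ``cutoff``, and compute confusion
    metrics against the simulated truth.  The entropy-optimal cut-off is
    found both per replicate and on the pooled (probability, truth) pairs of
    all replicates of a scenario.  A replicate that raises is logged and
    excluded, with the exclusion count reported.
    """
    rows = []
    pooled_best: dict[str, float] = {}
    per_rep_best: dict[str, NDArray] = {}
    excluded: dict[str, int] = {}
    for scen in scenarios:
        pooled_p: list[NDArray] = []
        pooled_t: list[NDArray] = []
        rep_best: list[float] = []
        n_excluded = 0
        for r in range(scen.n_replicates):
            try:
                items, cohort, responses = simulate_exam(scen, r)
                chain_seed = int(
                    np.random.SeedSequence((scen.seed, r, 7919)).generate_state(1)[0]
                    % (2**31)
                )
                est = DeterministicGatedIRT(
                    n_iterations=chain.n_iterations,
                    burn_in=chain.burn_in,
                    thin=chain.thin,
                    proposal_scale=chain.proposal_scale,
                    theta_c_prior_variance=theta_c_prior_variance,
                    cutoff=cutoff,
                    compute_diagnostics=False,
                    random_state=chain_seed,
                )
                est.fit(responses, exposed=items.exposed)
                truth = cohort.is_cheater
                metrics = confusion_metrics(est.predict(), truth)
                pooled_p.append(est.p_cheater_)
                pooled_t.append(truth)
                if truth.min() != truth.max() and np.unique(est.p_cheater_).size >= 2:
                    rep_best.append(best_cutoff_entropy(est.p_cheater_, truth))
                rows.append(
                    {"scenario": scen.name, "replicate": r, **metrics.as_dict()}
                )
                if progress:
                    logger.info("scenario %s replicate %d done", scen.name, r)
            except Exception:  # pragma: no cover - defensive path
                logger.exception("scenario %s replicate %d failed; excluded", scen.name, r)
                n_excluded += 1
        excluded[scen.name] = n_excluded
        per_rep_best[scen.name] = np.asarray(rep_best)
        if pooled_p:
            p_all = np.concatenate(pooled_p)
            t_all = np.concatenate(pooled_t)
            if t_all.min() != t_all.max() and np.unique(p_all).size >= 2:
                pooled_best[scen.name] = best_cutoff_entropy(p_all, t_all)
            else:
                pooled_best[scen.name] = float("nan")
    replicates = pd.DataFrame(rows)
    means = replicates.groupby("scenario", sort=False)[list(METRIC_NAMES)].mean().T
    sds = replicates.groupby("scenario", sort=False)[list(METRIC_NAMES)].std(ddof=1).T
    summary = means.copy()
    summary.loc["best_cutoff"] = pd.Series(pooled_best)
    return StudyResult(
        summary=summary,
        sd=sds,
        replicates=replicates,
        best_cutoff=pooled_best,
        best_cutoff_per_replicate=per_rep_best,
        excluded=excluded,
    )
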