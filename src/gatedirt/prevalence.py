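"""Apparent-to-true prevalence conversion for an imperfect detector.

A detector with sensitivity SEN and specificity SPE applied to a population
with true prevalence TP flags an expected apparent prevalence

    AP = TP * SEN + (1 - TP) * (1 - SPE).

Inverting this relation gives the classical corrected (Rogan-Gladen-type)
estimate; a Bayesian variant places a Uniform(0, 1) prior on TP and uniform
priors on SEN and SPE over bounds taken from the calibration study, and
treats the flagged count as Binomial(n, AP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp, xlogy

__all__ = [
    "AccuracyPrior",
    "PrevalenceEstimate",
    "forward_ap",
    "rogan_gladen_tp",
    "bayesian_tp",
    "DEFAULT_PRIOR",
]


@dataclass(frozen=True)
class AccuracyPrior:
    """Uniform prior bounds on detector sensitivity and specificity."""

    sen_bounds: tuple[float, float]
    spe_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("sen", self.sen_bounds), ("spe", self.spe_bounds)):
            if not 0 <= lo <= hi <= 1:
                raise ValueError(f"{name}_bounds must satisfy 0 <= low <= high <= 1")


#: Default bounds: the minimum and maximum across-scenario mean sensitivity
#: (60.30-90.75%) and specificity (77.82-98.00%) of the calibration study at
#: the 0.90 cut-off.
DEFAULT_PRIOR = AccuracyPrior(sen_bounds=(0.603, 0.9075), spe_bounds=(0.7782, 0.98))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """True-prevalence estimate with posterior spread when Bayesian."""

    tp_mean: float
    tp_sd: float
    credible_interval: tuple[float, float]
    level: float
    method: str


def forward_ap(tp: float, sen: float, spe: float) -> float:
    """Expected apparent prevalence of an imperfect detector."""
    tp, sen, spe = float(tp), float(sen), float(spe)
    return tp * sen + (1.0 - tp) * (1.0 - spe)


def rogan_gladen_tp(ap: float, sen: float, spe: float) -> float:
    """Closed-form true prevalence ``(AP + SPE - 1) / (SEN + SPE - 1)``.

    Requires an informative detector (``SEN + SPE > 1``); the estimate is
    truncated to ``[0, 1]``.
    """
    ap, sen, spe = float(ap), float(sen), float(spe)
    if not 0 <= ap <= 1:
        raise ValueError("ap must be in [0, 1]")
    if sen + spe <= 1:
        raise ValueError("inversion undefined: need sen + spe > 1")
    tp = (ap + spe - 1.0) / (sen + spe - 1.0)
    return float(np.clip(tp, 0.0, 1.0))


def bayesian_tp(
    n_flagged: int,
    n_students: int,
    prior: AccuracyPrior = DEFAULT_PRIOR,
    grid: int = 400,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> PrevalenceEstimate:
    """Posterior of the true prevalence under uniform accuracy priors.

    Model: ``TP ~ U(0,1)``, ``SEN ~ U(sen_bounds)``, ``SPE ~ U(spe_bounds)``
    and ``n_flagged ~ Binomial(n_students, TP*SEN + (1-TP)*(1-SPE))``.  The
    posterior is computed on a deterministic tensor grid (``grid`` points
    per axis, cell midpoints) and marginalised to TP, avoiding Monte Carlo
    noise in this three-parameter problem; ``seed`` is accepted for
    interface uniformity but unused.  Degenerate (zero-width) bounds are
    point priors.

    Returns the posterior mean, SD and equal-tailed credible interval at
    ``level``.
    """
    if not 0 <= n_flagged <= n_students:
        raise ValueError("need 0 <= n_flagged <= n_students")
    if grid < 2:
        raise ValueError("grid must be >= 2")

    def axis(lo: float, hi: float) -> np.ndarray:
        if hi <= lo:
            return np.array([lo])
        edges = np.linspace(lo, hi, grid + 1)
        return (edges[:-1] + edges[1:]) / 2.0

    tp = axis(0.0, 1.0)
    sen = axis(*prior.sen_bounds)
    spe = axis(*prior.spe_bounds)

    # marginal posterior over TP: integrate the binomial likelihood over the
    # uniform (SEN, SPE) box, blockwise to bound memory
    log_post = np.full(tp.size, -np.inf)
    # binomial log-kernel k*log(ap) + (n-k)*log(1-ap); the constant binomial
    # coefficient cancels in the normalisation
    n_miss = n_students - n_flagged
    for s in sen:
        ap = tp[:, None] * s + (1.0 - tp[:, None]) * (1.0 - spe[None, :])  # (tp, spe)
        ap = np.clip(ap, 0.0, 1.0)
        ll = xlogy(n_flagged, ap) + xlogy(n_miss, 1.0 - ap)
        log_post = np.logaddexp(log_post, logsumexp(ll, axis=1))
    log_post -= log_post.max()
    w = np.exp(log_post)
    w /= w.sum()
    mean = float((w * tp).sum())
    sd = float(np.sqrt((w * (tp - mean) ** 2).sum()))
    cdf = np.cumsum(w)
    alpha = (1.0 - level) / 2.0
    lo = float(tp[np.searchsorted(cdf, alpha)])
    hi = float(tp[min(np.searchsorted(cdf, 1.0 - alpha), tp.size - 1)])
    return PrevalenceEstimate(
        tp_mean=mean,
        tp_sd=sd,
        credible_interval=(lo, hi),
        level=level,
        method="bayesian",
    )
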