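"""Classical test theory descriptives and 1-PL/2-PL marginal-ML fitting.

This is the data-description and model-validation layer: per-item difficulty
and biserial discrimination indices with the conventional category labels,
Cronbach's alpha, and logistic IRT models fitted by marginal maximum
likelihood with an EM algorithm (standard-normal ability integrated by
Gauss-Hermite quadrature), compared through AIC, BIC and the CHull scree
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .model import ResponseMatrix

__all__ = [
    "CTTSummary",
    "IrtFit",
    "MarginalMLIrt",
    "ctt_summary",
    "fit_irt",
    "chull_select",
    "compare_models",
]

# category edges on the proportion scale: [0, .30] difficult, (.30, .80]
# medium, (.80, 1] easy (printed as integer percent ranges 0-30 / 31-80 / 81-100)
_DIFFICULTY_EDGES = (0.30, 0.80)
# upper-inclusive edges at the printed cut points -0.19 / 0.19 / 0.29 / 0.39
_DISCRIMINATION_EDGES = (-0.19, 0.19, 0.29, 0.39)
_DISCRIMINATION_LABELS = ("negative", "weak", "sufficient", "good", "very_good")


@dataclass(frozen=True)
class CTTSummary:
    """Classical test theory item and examination descriptives."""

    difficulty: NDArray[np.float64]
    discrimination: NDArray[np.float64]
    cronbach_alpha: float
    difficulty_category: NDArray[np.str_]
    discrimination_category: NDArray[np.str_]
    item_id: NDArray[np.str_]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_id,
                "difficulty": self.difficulty,
                "difficulty_category": self.difficulty_category,
                "discrimination": self.discrimination,
                "discrimination_category": self.discrimination_category,
            }
        )


@dataclass(frozen=True)
class IrtFit:
    """Marginal-ML fit of a logistic IRT model."""

    model: str
    log_likelihood: float
    n_parameters: int
    aic: float
    bic: float
    difficulty: NDArray[np.float64]
    discrimination: NDArray[np.float64] | float
    converged: bool
    n_iter: int


def _difficulty_category(p: float) -> str:
    if p <= _DIFFICULTY_EDGES[0]:
        return "difficult"
    if p <= _DIFFICULTY_EDGES[1]:
        return "medium"
    return "easy"


def _discrimination_category(d: float) -> str:
    if np.isnan(d):
        return "undefined"
    for edge, label in zip(_DISCRIMINATION_EDGES, _DISCRIMINATION_LABELS):
        if d <= edge:
            return label
    return _DISCRIMINATION_LABELS[-1]


def _biserial(item: NDArray, rest: NDArray) -> float:
    """Biserial correlation of a binary item with its rest score.

    Point-biserial corrected to the latent-continuity scale:
    ``r_b = r_pb * sqrt(p(1-p)) / phi(Phi^{-1}(p))``.
    """
    p = item.mean()
    if p in (0.0, 1.0) or np.std(rest) == 0:
        return float("nan")
    r_pb = np.corrcoef(item, rest)[0, 1]
    y = stats.norm.pdf(stats.norm.ppf(p))
    return float(r_pb * np.sqrt(p * (1 - p)) / y)


def ctt_summary(responses) -> CTTSummary:
    """Item difficulty, biserial discrimination and Cronbach's alpha.

    Difficulty is the proportion of correct answers per item; discrimination
    is the biserial correlation between the item and the number of correct
    answers to the other items (the rest score).  Zero-variance items get
    NaN discrimination, reported rather than raised.
    """
    if isinstance(responses, ResponseMatrix):
        Y = responses.values.astype(float)
        item_id = responses.item_id
    else:
        Y = np.asarray(responses, dtype=float)
        item_id = np.array([f"item_{k + 1:03d}" for k in range(Y.shape[1])])
    m, k = Y.shape
    if m < 3 or k < 2:
        raise ValueError("need at least 3 students and 2 items")
    difficulty = Y.mean(axis=0)
    total = Y.sum(axis=1)
    discrimination = np.array(
        [_biserial(Y[:, i], total - Y[:, i]) for i in range(k)]
    )
    item_var = Y.var(axis=0, ddof=1)
    total_var = total.var(ddof=1)
    alpha = (
        k / (k - 1) * (1.0 - item_var.sum() / total_var) if total_var > 0 else float("nan")
    )
    return CTTSummary(
        difficulty=difficulty,
        discrimination=discrimination,
        cronbach_alpha=float(alpha),
        difficulty_category=np.array([_difficulty_category(p) for p in difficulty]),
        discrimination_category=np.array(
            [_discrimination_category(d) for d in discrimination]
        ),
        item_id=np.asarray(item_id, dtype=str),
    )


# ----------------------------------------------------------------------
# marginal maximum likelihood EM
# ----------------------------------------------------------------------


def _gh_nodes(n: int) -> tuple[NDArray, NDArray]:
    """Gauss-Hermite nodes/weights rescaled for a standard normal density."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


class MarginalMLIrt(BaseEstimator):
    """1-PL or 2-PL logistic IRT model fitted by marginal ML with EM.

    ``P(y=1 | x) = sigmoid(a_i (x - b_i))`` with a standard-normal latent
    ability integrated out by fixed Gauss-Hermite quadrature.  The 1-PL
    constrains the discrimination to a single common value ``a`` (estimated,
    so ``n_parameters = I + 1``); the 2-PL frees it per item
    (``n_parameters = 2I``).

    Parameters
    ----------
    model : {"1pl", "2pl"}
    n_quadrature : int
        Number of quadrature nodes for the ability integral.
    tol : float
        EM stopping tolerance on the marginal log-likelihood change.
    max_iter : int
        EM iteration cap; non-convergence is flagged, not raised.

    Attributes
    ----------
    difficulty_ : ndarray of shape (n_items,)
    discrimination_ : float (1-PL) or ndarray (2-PL)
    log_likelihood_, aic_, bic_ : float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        model: str = "1pl",
        n_quadrature: int = 61,
        tol: float = 1e-5,
        max_iter: int = 500,
    ):
        self.model = model
        self.n_quadrature = n_quadrature
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        if self.model not in ("1pl", "2pl"):
            raise ValueError("model must be '1pl' or '2pl'")
        Y = X.values if isinstance(X, ResponseMatrix) else np.asarray(X)
        if Y.ndim != 2 or not np.isin(Y, (0, 1)).all():
            raise ValueError("X must be a binary 2-D matrix")
        Y = Y.astype(float)
        m, n_items = Y.shape
        constant_cols = (Y.min(axis=0) == Y.max(axis=0))
        if constant_cols.any() and self.model == "2pl":
            # slope unbounded for an all-0/all-1 item; flagged, prior-free fit proceeds
            self.flagged_items_ = np.where(constant_cols)[0]
        else:
            self.flagged_items_ = np.array([], dtype=int)

        x, w = _gh_nodes(self.n_quadrature)
        logw = np.log(w)
        # slope-intercept parameterisation: logit P = a * x + c, b = -c / a
        p0 = np.clip(Y.mean(axis=0), 1e-3, 1 - 1e-3)
        c = np.log(p0 / (1 - p0))
        a = np.ones(n_items)

        ll_old = -np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            z = np.outer(a, x) + c[:, None]  # (I, K)
            logp = -np.logaddexp(0.0, -z)
            log1mp = -np.logaddexp(0.0, z)
            S = Y @ logp + (1.0 - Y) @ log1mp + logw  # (M, K)
            ll = float(logsumexp(S, axis=1).sum())
            W = np.exp(S - logsumexp(S, axis=1, keepdims=True))
            nk = W.sum(axis=0)  # (K,)
            rik = Y.T @ W  # (I, K)
            if self.model == "2pl":
                a, c = self._mstep_2pl(a, c, x, nk, rik)
            else:
                a, c = self._mstep_1pl(a, c, x, nk, rik)
            if abs(ll - ll_old) < self.tol:
                converged = True
                break
            ll_old = ll

        self.n_items_ = n_items
        self.n_students_ = m
        self.discrimination_ = a.copy() if self.model == "2pl" else float(a[0])
        self.difficulty_ = -c / a
        self.log_likelihood_ = ll
        k_params = 2 * n_items if self.model == "2pl" else n_items + 1
        self.n_parameters_ = k_params
        self.aic_ = -2.0 * ll + 2.0 * k_params
        self.bic_ = -2.0 * ll + k_params * np.log(m)
        self.converged_ = converged
        self.n_iter_ = it
        return self

    # expected complete-data objective is a weighted logistic regression per
    # item; both M-steps use damped Newton updates on its concave surface
    @staticmethod
    def _mstep_2pl(a, c, x, nk, rik, n_inner: int = 5):
        for _ in range(n_inner):
            p = expit(np.outer(a, x) + c[:, None])
            resid = rik - nk * p  # (I, K)
            wgt = nk * p * (1 - p)
            g_a = resid @ x
            g_c = resid.sum(axis=1)
            h_aa = wgt @ (x * x)
            h_ac = wgt @ x
            h_cc = wgt.sum(axis=1)
            det = h_aa * h_cc - h_ac**2
            det = np.where(det <= 1e-12, 1e-12, det)
            da = (h_cc * g_a - h_ac * g_c) / det
            dc = (h_aa * g_c - h_ac * g_a) / det
            a = np.clip(a + da, 0.02, 20.0)
            c = np.clip(c + dc, -30.0, 30.0)
        return a, c

    @staticmethod
    def _mstep_1pl(a, c, x, nk, rik, n_inner: int = 5):
        a0 = a[0]
        for _ in range(n_inner):
            # intercepts given common slope
            p = expit(a0 * x[None, :] + c[:, None])
            resid = rik - nk * p
            wgt = nk * p * (1 - p)
            c = np.clip(c + resid.sum(axis=1) / np.maximum(wgt.sum(axis=1), 1e-12), -30, 30)
            # common slope given intercepts
            p = expit(a0 * x[None, :] + c[:, None])
            g = ((rik - nk * p) @ x).sum()
            h = ((nk * p * (1 - p)) @ (x * x)).sum()
            a0 = float(np.clip(a0 + g / max(h, 1e-12), 0.02, 20.0))
        return np.full_like(a, a0), c


def fit_irt(responses, model: str = "1pl", **kwargs) -> IrtFit:
    """Fit a 1-PL or 2-PL model by marginal ML; thin wrapper over the estimator."""
    est = MarginalMLIrt(model=model, **kwargs).fit(responses)
    return IrtFit(
        model=model,
        log_likelihood=est.log_likelihood_,
        n_parameters=est.n_parameters_,
        aic=est.aic_,
        bic=est.bic_,
        difficulty=est.difficulty_,
        discrimination=est.discrimination_,
        converged=est.converged_,
        n_iter=est.n_iter_,
    )


def chull_select(
    fits: Sequence[tuple[float, float]],
) -> tuple[NDArray[np.float64], int]:
    """CHull scree ratios over (complexity, goodness-of-fit) pairs.

    Retains the models on the upper convex hull of fit against complexity
    and computes, for each interior hull model, the scree ratio

        st_i = [(f_i - f_{i-1}) / (c_i - c_{i-1})] / [(f_{i+1} - f_i) / (c_{i+1} - c_i)]

    i.e. the fit gain per unit complexity coming in, relative to going out.
    Boundary hull models have no defined ratio (NaN) when three or more
    models survive on the hull.  With exactly two hull models the elbow is
    degenerate: zero-fit-gain pseudo-endpoints are appended, giving ratio 0
    to the simpler model and inf to the one whose extra complexity buys
    fit, so the better-fitting model is selected.  Returns the per-model
    ratios (NaN for models off the hull) and the index of the selected
    model (highest ratio).
    """
    pts = [(float(ci), float(fi)) for ci, fi in fits]
    if len(pts) < 2:
        raise ValueError("chull_select needs at least 2 models")
    if len({c for c, _ in pts}) != len(pts):
        raise ValueError("model complexities must be distinct")
    order = np.argsort([c for c, _ in pts])
    ratios = np.full(len(pts), np.nan)

    # drop dominated models: a model must out-fit every simpler model
    kept: list[int] = []
    best_fit = -np.inf
    for idx in order:
        if pts[idx][1] > best_fit:
            kept.append(idx)
            best_fit = pts[idx][1]
    # upper convex hull (non-increasing slopes) over the kept models;
    # collinear interior points are retained so a flat scree reports ratio 1
    hull: list[int] = []
    for idx in kept:
        while len(hull) >= 2:
            (c1, f1), (c2, f2) = pts[hull[-2]], pts[hull[-1]]
            c3, f3 = pts[idx]
            if (f2 - f1) / (c2 - c1) < (f3 - f2) / (c3 - c2):
                hull.pop()
            else:
                break
        hull.append(idx)
    if len(hull) == 1:
        # every added complexity is wasted: the simplest model wins outright
        ratios[hull[0]] = np.inf
        return ratios, hull[0]

    if len(hull) == 2:
        # degenerate elbow: close the hull with zero-fit-gain pseudo-endpoints
        # (0/s = 0 incoming, s/0 = inf outgoing), selecting the model whose
        # extra complexity actually buys fit
        ratios[hull[0]] = 0.0
        ratios[hull[1]] = np.inf
    else:
        cs = [pts[j][0] for j in hull]
        fs = [pts[j][1] for j in hull]
        for pos in range(1, len(hull) - 1):
            s_in = (fs[pos] - fs[pos - 1]) / (cs[pos] - cs[pos - 1])
            s_out = (fs[pos + 1] - fs[pos]) / (cs[pos + 1] - cs[pos])
            ratios[hull[pos]] = s_in / s_out if s_out > 0 else np.inf
    selected = int(np.nanargmax(ratios))
    return ratios, selected


def compare_models(responses, **kwargs) -> pd.DataFrame:
    """Fit 1-PL and 2-PL and tabulate Log-Lik, AIC, BIC and CHull ratios.

    Returns a DataFrame indexed by model with the fit indices and a
    ``selected_by`` attribute in ``DataFrame.attrs`` naming the winner per
    criterion (lowest AIC/BIC, highest CHull ratio).
    """
    fits = {m: fit_irt(responses, model=m, **kwargs) for m in ("1pl", "2pl")}
    ratios, chull_idx = chull_select(
        [(fits[m].n_parameters, fits[m].log_likelihood) for m in ("1pl", "2pl")]
    )
    table = pd.DataFrame(
        {
            "log_lik": [fits[m].log_likelihood for m in ("1pl", "2pl")],
            "n_parameters": [fits[m].n_parameters for m in ("1pl", "2pl")],
            "aic": [fits[m].aic for m in ("1pl", "2pl")],
            "bic": [fits[m].bic for m in ("1pl", "2pl")],
            "chull": ratios,
        },
        index=["1pl", "2pl"],
    )
    table.attrs["selected_by"] = {
        "aic": table["aic"].idxmin(),
        "bic": table["bic"].idxmin(),
        "chull": table.index[chull_idx],
    }
    return table
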