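"""Core domain types and response-probability functions for the gated 1-PL mixture.

The model distinguishes each examinee's *true ability* ``theta_t`` (driving
responses to secure, first-use items) from a *cheating ability* ``theta_c``
that drives responses to exposed (reused, potentially compromised) items, but
only for examinees who actually hold pre-knowledge.  An examinee is a cheater
(``T = 1``) exactly when ``theta_t < theta_c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import expit

__all__ = [
    "ItemBank",
    "StudentCohort",
    "ResponseMatrix",
    "one_pl_prob",
    "gated_prob",
]


def _as_float_array(x: ArrayLike, name: str) -> NDArray[np.float64]:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _as_binary_array(x: ArrayLike, name: str) -> NDArray[np.int_]:
    arr = np.asarray(x)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(int)


def one_pl_prob(theta: ArrayLike, b: ArrayLike) -> NDArray[np.float64]:
    """One-parameter logistic probability of a correct response.

    ``P(y=1 | theta, b) = 1 / (1 + exp(-(theta - b)))`` with common
    discrimination fixed at 1: strictly increasing in ability ``theta`` and
    strictly decreasing in difficulty ``b``.

    Parameters
    ----------
    theta : float or array-like
        Latent ability on the logit scale.
    b : float or array-like
        Item difficulty on the same scale.  Broadcasts against ``theta``.

    Returns
    -------
    ndarray or float
        Probabilities strictly inside ``(0, 1)``.
    """
    theta = _as_float_array(theta, "theta")
    b = _as_float_array(b, "b")
    # clip into the open unit interval so extreme logits cannot underflow to
    # an exact 0 or 1
    p = np.clip(expit(theta - b), np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return p if p.ndim else float(p)


def gated_prob(
    theta_t: ArrayLike,
    theta_c: ArrayLike,
    is_cheater: ArrayLike,
    exposed: ArrayLike,
    b: ArrayLike,
) -> NDArray[np.float64]:
    """Correct-response probability under the gated mixture.

    Cheating ability influences the response only when the examinee is a
    cheater *and* the item is exposed; every other combination falls back to
    the plain 1-PL in the true ability:

    ====================  =====================
    ``(T, G)``            effective ability
    ====================  =====================
    ``(0, 0)``            ``theta_t``
    ``(0, 1)``            ``theta_t``
    ``(1, 0)``            ``theta_t``
    ``(1, 1)``            ``theta_c``
    ====================  =====================

    Equivalent to the single mixture expression
    ``P_t^(1-T) * [(1-G) P_t + G P_c]^T``.
    """
    t = _as_binary_array(is_cheater, "is_cheater")
    g = _as_binary_array(exposed, "exposed")
    p_t = one_pl_prob(theta_t, b)
    p_c = one_pl_prob(theta_c, b)
    use_cheat = (t * g).astype(bool)
    return np.where(use_cheat, p_c, p_t)


@dataclass(frozen=True)
class ItemBank:
    """Per-item difficulty and exposure status.

    Attributes
    ----------
    difficulty : ndarray of float
        Item difficulty ``b`` on the logit scale.
    exposed : ndarray of int
        Exposure status ``G``: 1 for a reused/compromised item, 0 for a
        secure first-use item.
    item_id : ndarray of str
        Opaque labels, defaulting to ``item_001`` ...
    """

    difficulty: NDArray[np.float64]
    exposed: NDArray[np.int_]
    item_id: NDArray[np.str_] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        diff = _as_float_array(self.difficulty, "difficulty")
        exp = _as_binary_array(self.exposed, "exposed")
        if diff.shape != exp.shape or diff.ndim != 1:
            raise ValueError("difficulty and exposed must be 1-D of equal length")
        ids = self.item_id
        if ids is None:
            ids = np.array([f"item_{i + 1:03d}" for i in range(diff.size)])
        else:
            ids = np.asarray(ids, dtype=str)
            if ids.shape != diff.shape:
                raise ValueError("item_id length mismatch")
        object.__setattr__(self, "difficulty", diff)
        object.__setattr__(self, "exposed", exp)
        object.__setattr__(self, "item_id", ids)

    @property
    def n_items(self) -> int:
        return self.difficulty.size

    @property
    def n_exposed(self) -> int:
        return int(self.exposed.sum())


@dataclass(frozen=True)
class StudentCohort:
    """Per-student latent abilities and cheater status.

    ``theta_cheat = theta_true + gain`` with ``gain >= 0``; a student is a
    cheater (``is_cheater = 1``) exactly when ``theta_true < theta_cheat``,
    i.e. when the gain is strictly positive.
    """

    theta_true: NDArray[np.float64]
    theta_cheat: NDArray[np.float64]
    gain: NDArray[np.float64]
    is_cheater: NDArray[np.int_]
    student_id: NDArray[np.str_] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        tt = _as_float_array(self.theta_true, "theta_true")
        tc = _as_float_array(self.theta_cheat, "theta_cheat")
        gn = _as_float_array(self.gain, "gain")
        ch = _as_binary_array(self.is_cheater, "is_cheater")
        if not (tt.shape == tc.shape == gn.shape == ch.shape) or tt.ndim != 1:
            raise ValueError("cohort fields must be 1-D of equal length")
        if np.any(gn < 0):
            raise ValueError("gain must be nonnegative")
        if not np.array_equal(ch, (tt < tc).astype(int)):
            raise ValueError("is_cheater must equal (theta_true < theta_cheat)")
        ids = self.student_id
        if ids is None:
            ids = np.array([f"student_{m + 1:03d}" for m in range(tt.size)])
        else:
            ids = np.asarray(ids, dtype=str)
            if ids.shape != tt.shape:
                raise ValueError("student_id length mismatch")
        object.__setattr__(self, "theta_true", tt)
        object.__setattr__(self, "theta_cheat", tc)
        object.__setattr__(self, "gain", gn)
        object.__setattr__(self, "is_cheater", ch)
        object.__setattr__(self, "student_id", ids)

    @property
    def n_students(self) -> int:
        return self.theta_true.size

    @property
    def n_cheaters(self) -> int:
        return int(self.is_cheater.sum())


@dataclass(frozen=True)
class ResponseMatrix:
    """Binary correctness matrix, students (rows) by items (columns)."""

    values: NDArray[np.int_]
    student_id: NDArray[np.str_] = field(default=None)  # type: ignore[assignment]
    item_id: NDArray[np.str_] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("values must be 2-D (students x items)")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("responses must be binary 0/1 with no missing entries")
        vals = vals.astype(np.int8)
        m, i = vals.shape
        sid = self.student_id
        iid = self.item_id
        sid = (
            np.array([f"student_{k + 1:03d}" for k in range(m)])
            if sid is None
            else np.asarray(sid, dtype=str)
        )
        iid = (
            np.array([f"item_{k + 1:03d}" for k in range(i)])
            if iid is None
            else np.asarray(iid, dtype=str)
        )
        if sid.size != m or iid.size != i:
            raise ValueError("label length mismatch")
        if len(set(sid)) != m or len(set(iid)) != i:
            raise ValueError("duplicate row or column labels")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "student_id", sid)
        object.__setattr__(self, "item_id", iid)

    @property
    def n_students(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]
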