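"""Least-squares fitting of observed ALD curves under the admixture models.

For a candidate coefficient vector C the predicted curve is
theta1 * (A @ C) + theta0 with A[i, l] = exp(-l * d_i); (theta0, theta1) are
profiled out by ordinary least squares, so the objective per candidate is the
residual sum of squares. Onset times are found by exhaustive scan over
n = 1..J for the one-parameter models (HI, GA, CGF1, CGF2) and by a greedy
shrinking-window search for the interval models (GA-I, CGF1-I, CGF2-I): start
from (E, S) = (1, J) and repeatedly move to whichever of (E+1, S) / (E, S-1)
lowers the objective, then polish the endpoint with an iterated local
neighborhood scan (see ``interval_search``).

``reference_fit`` provides the flexible exponential-mixture benchmark: a
nonnegative mixture over the full J-column basis plus a free offset, the
"de-noised" curve against which quasi-F compares the model fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import nnls

from .io import LDCurve
from .models import CoefficientVector, ModelSpec, window_coefficients

__all__ = ["DesignMatrix", "FitResult", "ReferenceFit", "design_matrix",
           "fit_theta", "scan_onset", "interval_search", "reference_fit",
           "fit_model", "DEFAULT_J"]

#: default upper bound on the admixture onset, in generations
DEFAULT_J = 500


@dataclass
class DesignMatrix:
    """Exponential-decay basis evaluated on a distance grid:
    A[i, l-1] = exp(-l * d_i), l = 1..J."""

    A: np.ndarray
    d: np.ndarray
    J: int


@dataclass
class FitResult:
    """One model's best fit to one curve."""

    spec: ModelSpec
    theta0: float
    theta1: float
    rss: float
    mse: float
    degenerate: bool = False

    @property
    def objective(self) -> float:
        return self.rss

    @property
    def nonphysical(self) -> bool:
        """theta1 < 0 cannot arise from admixture; flagged, not forbidden."""
        return self.theta1 < 0

    def to_dict(self) -> dict:
        return {"model": self.spec.model, "g_end": self.spec.g_end,
                "g_start": self.spec.g_start, "m1": self.spec.m1,
                "theta0": self.theta0, "theta1": self.theta1, "rss": self.rss,
                "mse": self.mse, "degenerate": self.degenerate,
                "nonphysical": self.nonphysical}


@dataclass
class ReferenceFit:
    """Nonnegative exponential-mixture fit with a free offset."""

    alpha: np.ndarray
    offset: float
    fitted: np.ndarray
    rss: float


def _as_values(z) -> np.ndarray:
    return z.z if isinstance(z, LDCurve) else np.asarray(z, dtype=float)


def design_matrix(d: np.ndarray, J: int = DEFAULT_J) -> DesignMatrix:
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    if J < 1:
        raise ValueError("J must be >= 1")
    A = np.exp(-np.outer(d, np.arange(1, J + 1)))
    return DesignMatrix(A, d, J)


def _ols(z: np.ndarray, u: np.ndarray) -> tuple[float, float, float, bool]:
    """OLS of z on [1, u]; returns (theta0, theta1, rss, degenerate)."""
    I = z.size
    mu, mz = u.mean(), z.mean()
    suu = float(u @ u - I * mu * mu)
    szz = float(z @ z - I * mz * mz)
    if np.ptp(u) < 1e-12 * max(1.0, float(np.abs(u).max())):
        return mz, 0.0, max(szz, 0.0), True
    suz = float(z @ u - I * mu * mz)
    theta1 = suz / suu
    theta0 = mz - theta1 * mu
    rss = max(szz - theta1 * suz, 0.0)
    return theta0, theta1, rss, False


def fit_theta(z, A: DesignMatrix, C: CoefficientVector | np.ndarray):
    """OLS estimate of (theta0, theta1) for a fixed coefficient vector.

    Returns (theta0, theta1, rss). A numerically constant A @ C is fitted by
    offset alone (theta1 = 0).
    """
    zv = _as_values(z)
    cv = C.C if isinstance(C, CoefficientVector) else np.asarray(C, dtype=float)
    if cv.size > A.J:
        raise ValueError("coefficient vector longer than design basis")
    u = A.A[:, :cv.size] @ cv
    theta0, theta1, rss, _ = _ols(zv, u)
    return theta0, theta1, rss


@lru_cache(maxsize=8)
def _cgf_shape_matrix(J: int, r_base: float) -> np.ndarray:
    """M[:, n-1] holds the CGF coefficient shape for onset n (ratio
    r = r_base**(1/n)), zero-padded to length J."""
    M = np.zeros((J, J))
    for n in range(1, J + 1):
        r = r_base ** (1.0 / n)
        M[:n, n - 1] = r ** (n - 1 - np.arange(n))
    return M


def _candidate_matrix(A: DesignMatrix, model: str, m1: float) -> np.ndarray:
    """U[:, n-1] = A @ C_model(n) for every onset candidate n = 1..J."""
    if model == "HI":
        return A.A
    if model == "GA":
        return np.cumsum(A.A, axis=1)
    if model == "CGF1":
        return A.A @ _cgf_shape_matrix(A.J, m1)
    if model == "CGF2":
        return A.A @ _cgf_shape_matrix(A.J, 1 - m1)
    raise ValueError(f"{model!r} is not a single-onset core model")


def scan_onset(z, A: DesignMatrix, model: str, m1: float,
               J: int | None = None) -> FitResult:
    """Exhaustive scan over onset n = 1..J for HI/GA/CGF1/CGF2.

    Ties in the objective are broken toward the smaller (more recent) n.
    """
    zv = _as_values(z)
    J = A.J if J is None else min(J, A.J)
    U = _candidate_matrix(A, model, m1)[:, :J]
    I = zv.size
    mu = U.mean(axis=0)
    mz = zv.mean()
    suu = np.einsum("ij,ij->j", U, U) - I * mu * mu
    suz = zv @ U - I * mu * mz
    szz = float(zv @ zv - I * mz * mz)
    ptp = U.max(axis=0) - U.min(axis=0)
    degen = ptp < 1e-12 * np.maximum(1.0, np.abs(U).max(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta1 = np.where(degen, 0.0, suz / np.where(suu == 0, 1.0, suu))
    rss = np.maximum(szz - theta1 * suz, 0.0)
    n = int(np.argmin(rss)) + 1
    t1 = float(theta1[n - 1])
    t0 = mz - t1 * float(mu[n - 1])
    g_end = n if model == "HI" else 1
    spec = ModelSpec(model, g_end, n, m1)
    return FitResult(spec, float(t0), t1, float(rss[n - 1]),
                     float(rss[n - 1]) / I, bool(degen[n - 1]))


#: Chebyshev radius of the local polish neighborhood in interval_search
_POLISH_RADIUS = 8


def interval_search(z, A: DesignMatrix, model: str, m1: float,
                    J: int | None = None) -> FitResult:
    """Window search for the interval models (GA-I, CGF1-I, CGF2-I).

    Phase 1 is the greedy shrink: start at (E, S) = (1, J); each step
    evaluates the two proposals (E+1, S) and (E, S-1) and moves to the
    better one if it improves the objective, preferring (E+1, S) on exact
    ties; it stops otherwise or when E == S. The two-proposal descent can
    stall on a window slightly wider than the optimum (both single-edge
    shrinks overshoot where a combined move would not), so phase 2 polishes:
    the full neighborhood |E' - E| <= R, |S' - S| <= R is scanned and the
    search jumps to its best strictly improving window, repeating until no
    neighbor improves (ties inside the neighborhood prefer larger E, then
    smaller S). On noiseless single-model curves the polished search attains
    the exhaustive global optimum (asserted against the exhaustive oracle in
    the tests).
    """
    if model not in ("GA-I", "CGF1-I", "CGF2-I"):
        raise ValueError(f"{model!r} is not an interval model")
    zv = _as_values(z)
    J = A.J if J is None else min(J, A.J)
    if J < 2:
        raise ValueError("interval search needs J >= 2")
    cache: dict[tuple[int, int], tuple] = {}

    def f(E: int, S: int):
        key = (E, S)
        if key not in cache:
            c = window_coefficients(model, E, S, m1)
            u = A.A[:, E - 1:S] @ c
            cache[key] = _ols(zv, u)
        return cache[key]

    E, S = 1, J
    cur = f(E, S)
    while E < S:
        prop1 = f(E + 1, S)
        prop2 = f(E, S - 1)
        if prop1[2] <= prop2[2]:
            best, move = prop1, (E + 1, S)
        else:
            best, move = prop2, (E, S - 1)
        if best[2] < cur[2]:
            E, S = move
            cur = best
        else:
            break
    R = _POLISH_RADIUS
    while True:
        move = None
        for e in range(max(1, E - R), min(J, E + R) + 1):
            for s in range(max(e, S - R), min(J, S + R) + 1):
                if (e, s) == (E, S):
                    continue
                cand = f(e, s)
                if cand[2] < cur[2] and (move is None
                                         or (cand[2], -e, s) < key):
                    move, key = (e, s, cand), (cand[2], -e, s)
        if move is None:
            break
        E, S, cur = move
    theta0, theta1, rss, degen = cur
    spec = ModelSpec(model, E, S, m1)
    return FitResult(spec, theta0, theta1, rss, rss / zv.size, degen)


def fit_model(z, A: DesignMatrix, model: str, m1: float,
              J: int | None = None) -> FitResult:
    """Dispatch to the onset scan or the interval search by model name."""
    if model in ("HI", "GA", "CGF1", "CGF2"):
        return scan_onset(z, A, model, m1, J)
    return interval_search(z, A, model, m1, J)


def reference_fit(z, A: DesignMatrix) -> ReferenceFit:
    """Flexible nonnegative exponential-mixture fit with a free offset.

    The offset is profiled out exactly: centering the curve and the basis
    columns and solving one NNLS on the centered system yields the joint
    minimizer over (alpha >= 0, offset).
    """
    zv = _as_values(z)
    col_means = A.A.mean(axis=0)
    Ac = A.A - col_means
    zc = zv - zv.mean()
    alpha, _ = nnls(Ac, zc, maxiter=max(30 * A.J, 1000))
    offset = float(np.mean(zv - A.A @ alpha))
    fitted = A.A @ alpha + offset
    rss = float(np.sum((zv - fitted) ** 2))
    return ReferenceFit(alpha, offset, fitted, rss)
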