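"""Admixture models: migration schedules and theoretical ALD coefficients.

A two-way admixture history is summarized by per-generation migrant fractions
(alpha1, alpha2) indexed by l = generations before present. The admixture
window runs from G_start (first contact, the founding generation) to G_end
(last gene flow), followed by isolation to the present. Supported models:

HI      one pulse: the population is founded l = n generations ago with
        fractions (m1, m2) and then isolated.
GA      gradual admixture over the window; the t-th window generation
        (t = 1 at G_start) receives total inflow 1/t split m1:m2, so every
        window generation contributes equally to final ancestry.
CGF1    source 1 is the recipient: each window generation (including the
        founding one, on a base of pure source 1) receives a constant
        fraction alpha = 1 - m1**(1/n) from source 2. CGF2 swaps the roles.
GA-I /  the same flows truncated at G_end > 1 with isolation afterwards; the
CGF-I   plain GA/CGF models are the G_end = 1 cases and HI is the
        one-generation window degeneracy of every continuous model.

ALD decays by a factor e^{-d} per generation of recombination, so the
expected curve is a mixture over the basis (e^{-d}, e^{-2d}, ..., e^{-Jd}):
a migrant cohort entering l generations ago undergoes l meioses and
contributes at basis index l. ``coefficient_vector`` builds the mixture
coefficients by running the ancestry-covariance recursion forward:
at each generation with total inflow a the coefficient ledger is diluted by
(1 - a) and shifted one basis index up (one round of recombination), and a
fresh injection

    K = (1 - a) * (m_prev - m)**2 + alpha1 * (1 - m)**2 + alpha2 * m**2

enters at the bottom, where m is the post-inflow mean source-1 ancestry.
The one-pulse anchor fixes the convention: HI(n) yields a single coefficient
at index n, i.e. a curve proportional to e^{-nd}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MODEL_NAMES", "INTERVAL_MODELS", "CLASSIC_MODELS", "ModelSpec",
           "MigrationSchedule", "CoefficientVector", "migration_schedule",
           "coefficient_vector", "window_coefficients", "model_curve",
           "model_class"]

CLASSIC_MODELS = ("HI", "GA", "CGF1", "CGF2")
INTERVAL_MODELS = ("GA-I", "CGF1-I", "CGF2-I")
MODEL_NAMES = CLASSIC_MODELS + INTERVAL_MODELS

_FAMILY = {"HI": "HI", "GA": "GA", "GA-I": "GA", "CGF1": "CGF1", "CGF1-I": "CGF1",
           "CGF2": "CGF2", "CGF2-I": "CGF2"}


def model_class(model: str) -> str:
    """Collapse a model name to its reported class (CGF1/CGF2 -> CGF etc.)."""
    if model in ("CGF1", "CGF2"):
        return "CGF"
    if model in ("CGF1-I", "CGF2-I"):
        return "CGF-I"
    return model


@dataclass(frozen=True)
class ModelSpec:
    """A named admixture model with its time window and final m1.

    ``g_end`` and ``g_start`` are generations before present (1 <= g_end <=
    g_start); HI requires g_end == g_start. Classic GA/CGF models flow to the
    present (g_end == 1).
    """

    model: str
    g_end: int
    g_start: int
    m1: float

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if not (1 <= self.g_end <= self.g_start):
            raise ValueError("need 1 <= g_end <= g_start")
        if self.model == "HI" and self.g_end != self.g_start:
            raise ValueError("HI is a single pulse: g_end must equal g_start")
        if self.model in ("GA", "CGF1", "CGF2") and self.g_end != 1:
            raise ValueError(f"{self.model} flows to the present: g_end must be 1")
        if not 0 < self.m1 < 1:
            raise ValueError("m1 must lie in (0, 1)")

    @property
    def duration(self) -> int:
        """Window length n = g_start - g_end + 1."""
        return self.g_start - self.g_end + 1

    def __str__(self) -> str:
        if self.model == "HI":
            return f"HI({self.g_start})"
        return f"{self.model}({self.g_end}-{self.g_start})"


@dataclass
class MigrationSchedule:
    """Per-generation migrant fractions, indexed by l generations before
    present (entry 0 is unused padding). alpha1[g_start] + alpha2[g_start] = 1
    (the founding generation consists entirely of migrants)."""

    alpha1: np.ndarray
    alpha2: np.ndarray
    spec: ModelSpec | None = None

    def __post_init__(self) -> None:
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        self.alpha2 = np.asarray(self.alpha2, dtype=float)
        tot = self.alpha1 + self.alpha2
        if np.any(self.alpha1 < 0) or np.any(self.alpha2 < 0) or np.any(tot > 1 + 1e-12):
            raise ValueError("migrant fractions must satisfy 0 <= a1 + a2 <= 1")

    @property
    def g_start(self) -> int:
        return len(self.alpha1) - 1

    def final_ancestry(self) -> float:
        """Present-day source-1 ancestry implied by the schedule."""
        m = 0.0
        for ell in range(self.g_start, 0, -1):
            a = self.alpha1[ell] + self.alpha2[ell]
            m = (1 - a) * m + self.alpha1[ell]
        return m


@dataclass
class CoefficientVector:
    """Theoretical ALD mixture coefficients in the e^{-l d} basis.

    ``C[i]`` multiplies e^{-(i+1) d}; the maximum entry is normalized to 1
    (the observed-curve scale is absorbed by the fitted theta1).
    """

    C: np.ndarray
    spec: ModelSpec

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if np.any(self.C < -1e-12):
            raise ValueError("coefficients must be nonnegative")

    @property
    def J(self) -> int:
        return self.C.size


def migration_schedule(spec: ModelSpec) -> MigrationSchedule:
    """Expand a model spec to per-generation migrant fractions.

    The resulting present-day source-1 ancestry equals m1 exactly (checked to
    1e-12).
    """
    S, E, m1 = spec.g_start, spec.g_end, spec.m1
    m2 = 1 - m1
    n = spec.duration
    a1 = np.zeros(S + 1)
    a2 = np.zeros(S + 1)
    fam = _FAMILY[spec.model]
    if fam == "HI":
        a1[S], a2[S] = m1, m2
    elif fam == "GA":
        for ell in range(E, S + 1):
            t = S - ell + 1
            a1[ell] = m1 / t
            a2[ell] = m2 / t
    elif fam in ("CGF1", "CGF2"):
        recip = m1 if fam == "CGF1" else m2
        alpha = 1 - recip ** (1.0 / n)
        donor_into_1 = fam == "CGF2"  # CGF2: source 2 recipient, inflow from source 1
        for ell in range(E, S + 1):
            if donor_into_1:
                a1[ell] = alpha
            else:
                a2[ell] = alpha
        # the founding generation is the recipient base plus the same inflow
        if donor_into_1:
            a2[S] = 1 - alpha
        else:
            a1[S] = 1 - alpha
    sched = MigrationSchedule(a1, a2, spec=spec)
    if abs(sched.final_ancestry() - m1) > 1e-12:
        raise AssertionError("schedule does not reproduce the requested m1")
    return sched


def coefficient_vector(spec: ModelSpec, J: int = 500) -> CoefficientVector:
    """Coefficient vector C_model of length J via the ancestry-LD recursion.

    Requires J >= g_start so the founding injection fits in the basis.
    """
    if spec.g_start > J:
        raise ValueError(f"g_start={spec.g_start} exceeds the basis size J={J}; raise J")
    sched = migration_schedule(spec)
    S = spec.g_start
    C = np.zeros(J + 1)  # index k multiplies e^{-k d}; k = 0 is the newest cohort
    a1, a2 = sched.alpha1[S], sched.alpha2[S]
    m = a1
    C[0] = a1 * (1 - a1)
    for ell in range(S - 1, -1, -1):
        a1 = sched.alpha1[ell] if ell >= 1 else 0.0
        a2 = sched.alpha2[ell] if ell >= 1 else 0.0
        a = a1 + a2
        C[1:] = (1 - a) * C[:-1]  # one round of recombination decay + dilution
        m_new = (1 - a) * m + a1
        C[0] = (1 - a) * (m - m_new) ** 2 + a1 * (1 - m_new) ** 2 + a2 * m_new ** 2
        m = m_new
    C = C[1:]
    peak = C.max()
    if peak > 0:
        C = C / peak
    C[np.abs(C) < 1e-300] = 0.0
    return CoefficientVector(C, spec)


def window_coefficients(model: str, E: int, S: int, m1: float) -> np.ndarray:
    """Closed-form max-normalized coefficients on the window [E, S].

    Returns the length-(S - E + 1) nonzero block of ``coefficient_vector``
    (entry i corresponds to basis index E + i):

    * HI: a single 1 (requires E == S),
    * GA family: uniform (every window generation contributes equally),
    * CGF1 family: geometric r**(S - l) with r = m1**(1/n) (peak at the
      founding generation), CGF2 with r = (1 - m1)**(1/n).

    These are exact consequences of the recursion in ``coefficient_vector``
    and are used in the fitting hot paths.
    """
    n = S - E + 1
    fam = _FAMILY[model]
    if fam == "HI":
        if E != S:
            raise ValueError("HI has a one-generation window")
        return np.ones(1)
    if fam == "GA":
        return np.ones(n)
    r = m1 ** (1.0 / n) if fam == "CGF1" else (1 - m1) ** (1.0 / n)
    ell = np.arange(E, S + 1)
    return r ** (S - ell)


def model_curve(coeff: CoefficientVector, d: np.ndarray, theta0: float,
                theta1: float) -> np.ndarray:
    """Evaluate theta1 * sum_l C[l] e^{-l d} + theta0 on a distance grid."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    ells = np.arange(1, coeff.J + 1)
    basis = np.exp(-np.outer(d, ells))
    return theta1 * (basis @ coeff.C) + theta0
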