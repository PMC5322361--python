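"""Best-fit-model selection from jackknife weighted-LD curves.

Each core model is fitted independently to the full-genome ALD curve and to
each of the N leave-one-chromosome-out curves (the time search is re-run per
curve). Per model M this yields log msE values L[M] (full) and L_drop[q, M]
(chromosome q left out), which are turned into Tukey jackknife pseudo-values

    pseudo[q, M] = N * L[M] - (N - 1) * L_drop[q, M]

treated as approximately independent replicates. Model pairs are compared by
a two-sided Wilcoxon signed-rank test on the paired pseudo-values (paired by
q), with Holm-Bonferroni family-wise adjustment. The best-fit set is built
around the model with the smallest median pseudo-value; if HI is not
significantly worse than that model, HI alone is reported (the simplest
model wins); otherwise every model not significantly worse than the best one
is reported, and the call is flagged undetermined when more than one model
survives.

Two full-curve diagnostics accompany the decision: msE (mean squared
residual; values above 1e-5 flag low-quality data) and quasi-F (the ratio of
the model fit's residual sum of squares to that of the flexible
exponential-mixture reference fit; values above 1.5 flag model rejection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .fitting import DEFAULT_J, design_matrix, fit_model, reference_fit
from .io import LDCurveSet

__all__ = ["MSE_THRESHOLD", "QUASI_F_THRESHOLD", "SelectionReport", "mse",
           "quasi_f", "pseudo_values", "pairwise_tests", "select_best",
           "summarize_intervals", "select_models"]

#: msE above this flags low-quality data
MSE_THRESHOLD = 1e-5
#: quasi-F above this flags rejection of the core model
QUASI_F_THRESHOLD = 1.5


@dataclass
class SelectionReport:
    """Outcome of the jackknife model-selection procedure."""

    models: list
    pseudo: np.ndarray              # N x n_models pseudo log(msE)
    medians: dict
    adj_p: dict                     # {frozenset({M1, M2}): adjusted p}
    best_set: list
    undetermined: bool
    time_summary: dict              # model -> (g_end, g_start) or extra flag
    diagnostics: dict               # model -> msE / quasi-F / flags
    fits: dict = field(default_factory=dict)   # model -> full-curve FitResult
    jackknife_fits: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "medians": self.medians,
            "adjusted_p": {" vs ".join(sorted(k)): v for k, v in self.adj_p.items()},
            "best_set": list(self.best_set),
            "undetermined": self.undetermined,
            "time_summary": self.time_summary,
            "diagnostics": self.diagnostics,
            "fits": {m: f.to_dict() for m, f in self.fits.items()},
        }


def mse(residuals: np.ndarray) -> float:
    """Mean squared residual of a fit; the data-quality diagnostic."""
    e = np.asarray(residuals, dtype=float)
    if e.size == 0:
        raise ValueError("empty residual vector")
    return float(np.mean(e ** 2))


def quasi_f(model_residuals: np.ndarray, reference_residuals: np.ndarray) -> float:
    """Residual-sum ratio of a core-model fit to the de-noised reference fit.

    F near 1 means the model fit does not deviate from the flexible fit;
    F > QUASI_F_THRESHOLD rejects the model. A zero-residual reference with a
    non-zero model residual gives +inf.
    """
    e = np.asarray(model_residuals, dtype=float)
    ep = np.asarray(reference_residuals, dtype=float)
    num = float(np.sum(e ** 2))
    den = float(np.sum(ep ** 2))
    if den == 0:
        return 1.0 if num == 0 else float("inf")
    return num / den


def pseudo_values(L_full: np.ndarray, L_drop: np.ndarray) -> np.ndarray:
    """Tukey jackknife pseudo-values N*L - (N-1)*L_{-q}.

    ``L_full`` has one log(msE) per model; ``L_drop`` is N x n_models.
    """
    L_full = np.asarray(L_full, dtype=float)
    L_drop = np.asarray(L_drop, dtype=float)
    N = L_drop.shape[0]
    if N < 2:
        raise ValueError("need at least 2 jackknife fits per model")
    return N * L_full[None, :] - (N - 1) * L_drop


def _log_mse(value: float) -> tuple[float, bool]:
    """log(msE), substituting log(machine epsilon) for an exact-zero msE."""
    if value <= 0:
        return float(np.log(np.finfo(float).eps)), True
    return float(np.log(value)), False


def pairwise_tests(pseudo: np.ndarray, models: list) -> dict:
    """Two-sided Wilcoxon signed-rank on every model pair of pseudo-values,
    paired by jackknife index, with Holm-Bonferroni adjustment.

    The exact null distribution is used when there are no ties or zero
    differences and N <= 25; zero differences are dropped. All differences
    zero gives p = 1 for that pair.
    """
    pairs = list(combinations(range(len(models)), 2))
    raw = []
    for i, j in pairs:
        diff = pseudo[:, i] - pseudo[:, j]
        if np.all(diff == 0):
            raw.append(1.0)
            continue
        nz = diff[diff != 0]
        method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
                             and nz.size == diff.size) else "approx"
        res = wilcoxon(diff, zero_method="wilcox", alternative="two-sided",
                       method=method)
        raw.append(float(res.pvalue))
    adj = multipletests(raw, method="holm")[1] if raw else []
    return {frozenset((models[i], models[j])): float(p)
            for (i, j), p in zip(pairs, adj)}


def select_best(medians: dict, adj_p: dict, alpha: float = 0.05) -> tuple[list, bool]:
    """Best-fit model set from the pseudo-value medians and adjusted p-values.

    The candidate best model has the smallest median. Model M is
    "significantly worse" than the best one when the adjusted p for the pair
    is below alpha AND M's median is larger (the test is two-sided, so the
    direction is checked separately). If HI is among the models and is not
    significantly worse than the best model, {HI} is returned (simplest
    model); otherwise the best model plus every model not significantly worse
    than it. More than one surviving model marks the call undetermined.
    """
    models = list(medians)
    best = min(models, key=lambda m: medians[m])

    def significantly_worse(m):
        if m == best:
            return False
        p = adj_p[frozenset((m, best))]
        return p < alpha and medians[m] > medians[best]

    if "HI" in models and not significantly_worse("HI"):
        return ["HI"], False
    best_set = [m for m in models if not significantly_worse(m)]
    # keep the input ordering, best model guaranteed present
    return best_set, len(best_set) > 1


def summarize_intervals(jack_fits: list, model: str) -> dict:
    """Summarize per-jackknife time estimates.

    HI: nearest integer to the mean point estimate. Continuous models: the
    [min, max] of the set of generations covered by more than half of the
    jackknife intervals; if no generation reaches majority coverage, the
    summary falls back to the first fit's interval and is flagged.
    """
    if not jack_fits:
        raise ValueError("need at least one jackknife fit")
    if model == "HI":
        n = int(np.floor(np.mean([f.spec.g_start for f in jack_fits]) + 0.5))
        return {"g_end": n, "g_start": n, "majority": True}
    lo = min(f.spec.g_end for f in jack_fits)
    hi = max(f.spec.g_start for f in jack_fits)
    gens = np.arange(lo, hi + 1)
    cover = np.zeros(gens.size)
    for f in jack_fits:
        cover += (gens >= f.spec.g_end) & (gens <= f.spec.g_start)
    majority = gens[cover > len(jack_fits) / 2]
    if majority.size == 0:
        return {"g_end": int(jack_fits[0].spec.g_end),
                "g_start": int(jack_fits[0].spec.g_start), "majority": False}
    return {"g_end": int(majority.min()), "g_start": int(majority.max()),
            "majority": True}


def select_models(curves: LDCurveSet, models: list, J: int = DEFAULT_J,
                  alpha: float = 0.05, with_reference: bool = True) -> SelectionReport:
    """Run the full selection procedure on a jackknife ALD curve set."""
    models = list(models)
    if len(models) < 2:
        raise ValueError("model selection needs at least 2 core models")
    A = design_matrix(curves.full.d, J)
    full_fits = {m: fit_model(curves.full, A, m, curves.m1) for m in models}
    jack_fits = {m: [fit_model(c, A, m, curves.m1) for c in curves.jackknives]
                 for m in models}

    L_full = np.empty(len(models))
    L_drop = np.empty((curves.n_jackknives, len(models)))
    zero_flagged = False
    for k, m in enumerate(models):
        L_full[k], flag = _log_mse(full_fits[m].mse)
        zero_flagged |= flag
        for q, f in enumerate(jack_fits[m]):
            L_drop[q, k], flag = _log_mse(f.mse)
            zero_flagged |= flag

    pseudo = pseudo_values(L_full, L_drop)
    medians = {m: float(np.median(pseudo[:, k])) for k, m in enumerate(models)}
    adj_p = pairwise_tests(pseudo, models)
    best_set, undetermined = select_best(medians, adj_p, alpha)

    ref = reference_fit(curves.full, A) if with_reference else None
    diagnostics = {}
    for m in models:
        fit = full_fits[m]
        diag = {"mse": fit.mse, "low_quality": fit.mse > MSE_THRESHOLD,
                "nonphysical": fit.nonphysical}
        if ref is not None:
            F = fit.rss / ref.rss if ref.rss > 0 else (1.0 if fit.rss == 0 else float("inf"))
            diag["quasi_f"] = F
            diag["rejected"] = F > QUASI_F_THRESHOLD
        diagnostics[m] = diag
    if zero_flagged:
        diagnostics["_zero_mse_substituted"] = True

    time_summary = {m: summarize_intervals(jack_fits[m], m) for m in models}
    return SelectionReport(models, pseudo, medians, adj_p, best_set,
                           undetermined, time_summary, diagnostics,
                           fits=full_fits, jackknife_fits=jack_fits)
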