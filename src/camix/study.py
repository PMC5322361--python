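"""Desk-scale model-determination study: simulate, date, select, tabulate.

Reproduces the simulation-study design used to benchmark the selection
machinery: forward-simulate admixed populations under ten histories (HI,
GA, CGF1 with onsets 50/100; GA-I and CGF-I windows 30-100 and 70-100; final
m1 = 0.3; 10 chromosomes of 0.3 Morgan), paint synthetic source/admixed SNP
panels, build jackknife ALD curve sets, and run model selection under both
core-model sets (classic HI/GA/CGF1/CGF2 and interval HI/GA-I/CGF1-I/
CGF2-I). Outcomes are tabulated as correct / undetermined / wrong, with
CGF1+CGF2 collapsed to one CGF class (and likewise for CGF-I), and GA/CGF
truths matched by GA-I/CGF-I when only the interval models are offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LDCurveSet
from .models import ModelSpec, migration_schedule, model_class
from .selection import select_models
from .simulate import SimConfig, SourcePanelModel, simulate_panels
from .weighted_ld import BinSpec, curve_set

__all__ = ["SCENARIOS", "CORE_CLASSIC", "CORE_INTERVAL", "StudySettings",
           "replicate_curve_set", "classify_outcome", "model_determination_study",
           "study_targets"]

CORE_CLASSIC = ("HI", "GA", "CGF1", "CGF2")
CORE_INTERVAL = ("HI", "GA-I", "CGF1-I", "CGF2-I")

#: the ten simulated admixture histories (m1 = 0.3 throughout)
SCENARIOS = (
    ModelSpec("HI", 50, 50, 0.3),
    ModelSpec("HI", 100, 100, 0.3),
    ModelSpec("GA", 1, 50, 0.3),
    ModelSpec("GA", 1, 100, 0.3),
    ModelSpec("CGF1", 1, 50, 0.3),
    ModelSpec("CGF1", 1, 100, 0.3),
    ModelSpec("GA-I", 30, 100, 0.3),
    ModelSpec("GA-I", 70, 100, 0.3),
    ModelSpec("CGF1-I", 30, 100, 0.3),
    ModelSpec("CGF1-I", 70, 100, 0.3),
)

_CLASSIC_TRUTHS = tuple(s for s in SCENARIOS if s.model in ("HI", "GA", "CGF1"))
_INTERVAL_TRUTHS = tuple(s for s in SCENARIOS if s.model in ("GA-I", "CGF1-I"))


@dataclass(frozen=True)
class StudySettings:
    """Desk-scale study conditions (see docs/methods.md).

    Population size, chromosome layout and final admixture proportion follow
    the original simulation design; the synthetic SNP panels (1000 sites per
    chromosome at divergence 0.15) stand in for the dense real source
    haplotypes used there and carry far less information, which limits how
    well the continuous models can be told apart (see methods, Limitations).
    """

    pop_size: int = 5000
    chrom_lengths: tuple = tuple([0.3] * 10)
    n_sample: int = 1000
    n_source: int = 500
    n_sites: int = 1000
    divergence: float = 0.15
    bin_width: float = 0.001
    J: int = 200


def _child_seeds(seed: int, *keys: int) -> tuple[int, int]:
    state = np.random.SeedSequence([int(seed), *map(int, keys)]).generate_state(2)
    return int(state[0] & 0x7FFFFFFF), int(state[1] & 0x7FFFFFFF)


def replicate_curve_set(spec: ModelSpec, seed: int,
                        settings: StudySettings | None = None) -> LDCurveSet:
    """Simulate one admixed population under ``spec`` and return its
    jackknife ALD curve set."""
    st = settings or StudySettings()
    sim_seed, paint_seed = _child_seeds(seed, 1)
    cfg = SimConfig(migration_schedule(spec), pop_size=st.pop_size,
                    chrom_lengths=st.chrom_lengths, seed=sim_seed,
                    n_sample=st.n_sample)
    pm = SourcePanelModel(n_sites=st.n_sites, divergence=st.divergence,
                          n_source=st.n_source)
    admixed, s1, s2 = simulate_panels(cfg, pm, paint_seed=paint_seed)
    bins = BinSpec(bin_width=st.bin_width)
    return curve_set(admixed, s1, s2, m1=spec.m1, bins=bins)


def classify_outcome(best_set, truth: ModelSpec, offered) -> str:
    """Correct / undetermined / wrong for one selection call.

    Classes collapse CGF1/CGF2 (and CGF1-I/CGF2-I). When the truth's exact
    class is not offered, GA is matched by GA-I and CGF by CGF-I; a truth
    with no matching offered class (e.g. GA-I truth under classic cores) is
    always wrong. "Correct" needs the best set to name exactly the matching
    class; a multi-class best set containing it is "undetermined".
    """
    offered_classes = {model_class(m) for m in offered}
    target = model_class(truth.model)
    if target not in offered_classes:
        target = {"GA": "GA-I", "CGF": "CGF-I"}.get(target)
    classes = {model_class(m) for m in best_set}
    if target is None or target not in classes:
        return "wrong"
    if classes == {target}:
        return "correct"
    return "undetermined"


def model_determination_study(reps: int = 10, seed: int = 0,
                              settings: StudySettings | None = None,
                              progress: bool = False) -> dict:
    """Run the full study: ``reps`` replicates per scenario, both core sets.

    Returns a dict with per-replicate ``records`` and a ``rates`` table of
    correct/undetermined/wrong percentages per (truth-group, core-set) row.
    """
    st = settings or StudySettings()
    records = []
    for si, spec in enumerate(SCENARIOS):
        for rep in range(reps):
            rep_seed, _ = _child_seeds(seed, 100 + si, rep)
            curves = replicate_curve_set(spec, rep_seed, st)
            for core_name, core in (("classic", CORE_CLASSIC),
                                    ("interval", CORE_INTERVAL)):
                report = select_models(curves, core, J=st.J, with_reference=False)
                records.append({
                    "scenario": str(spec), "truth": spec.model, "rep": rep,
                    "core_set": core_name, "best_set": list(report.best_set),
                    "outcome": classify_outcome(report.best_set, spec, core),
                })
            if progress:  # pragma: no cover
                print(f"{spec} rep {rep + 1}/{reps} done", flush=True)

    def row(truths, core_name):
        truth_names = {s.model for s in truths}
        rs = [r for r in records
              if r["truth"] in truth_names and r["core_set"] == core_name]
        n = len(rs)
        counts = {k: sum(r["outcome"] == k for r in rs)
                  for k in ("correct", "undetermined", "wrong")}
        rates = {k: 100.0 * v / n for k, v in counts.items()}
        return {"n": n, "counts": counts, "rates": rates}

    rates = {
        "classic_truths_classic_cores": row(_CLASSIC_TRUTHS, "classic"),
        "interval_truths_classic_cores": row(_INTERVAL_TRUTHS, "classic"),
        "classic_truths_interval_cores": row(_CLASSIC_TRUTHS, "interval"),
        "interval_truths_interval_cores": row(_INTERVAL_TRUTHS, "interval"),
    }
    return {"records": records, "rates": rates, "reps": reps,
            "settings": st.__dict__ | {"seed": seed}}


def study_targets(study: dict) -> dict:
    """Headline percentages of the study in reporting form."""
    r = study["rates"]
    return {
        "t1": {"value": r["classic_truths_classic_cores"]["rates"]["correct"],
               "n": r["classic_truths_classic_cores"]["n"]},
        "t2": {"value": r["interval_truths_classic_cores"]["rates"]["wrong"],
               "n": r["interval_truths_classic_cores"]["n"]},
        "t3": {"value": r["classic_truths_interval_cores"]["rates"]["correct"],
               "n": r["classic_truths_interval_cores"]["n"]},
        "t4": {"value": r["interval_truths_interval_cores"]["rates"]["wrong"],
               "n": r["interval_truths_interval_cores"]["n"]},
    }
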