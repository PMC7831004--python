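"""Combination-index synergy analysis of treatment growth curves.

Fractional inhibition of each arm is measured against the control arm at a
fixed endpoint, and synergy of a triple combination is quantified with two
combination indices:

* linear interaction (response additivity):
  ``CI = (E_A + E_B + E_C) / E_ABC``
* Bliss independence, three-agent form subtracting only the triple product:
  ``CI = ((E_A + E_B + E_C) - E_A*E_B*E_C) / E_ABC``

The canonical Bliss expectation ``1 - (1-E_A)(1-E_B)(1-E_C)`` is offered as
a side-by-side variant (``bliss_canonical``); for small effects the two
Bliss forms differ because the three-agent form omits the pairwise product
terms. CI < 1 indicates synergy, CI = 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ADDITIVITY_TOL = 0.05


class EffectError(ValueError):
    pass


@dataclass
class Effect:
    arm: str
    value: float
    se: float
    endpoint_h: float
    n_replicates: int
    growth_promotion: bool  # negative inhibition: treated grows faster


@dataclass
class EffectSet:
    """Single-agent and combination fractional inhibitions at one endpoint."""

    E_A: float
    E_B: float
    E_C: float
    E_ABC: float
    endpoint_h: float = float("nan")
    n_replicates: int = 0
    se_A: float = float("nan")
    se_B: float = float("nan")
    se_C: float = float("nan")
    se_ABC: float = float("nan")

    @property
    def singles(self) -> tuple[float, float, float]:
        return (self.E_A, self.E_B, self.E_C)


@dataclass
class CombinationIndex:
    model: str  # linear | bliss_paper | bliss_canonical
    ci: float
    interpretation: str  # synergy | additivity | antagonism
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def _interpret(ci: float, tol: float = ADDITIVITY_TOL) -> str:
    if abs(ci - 1.0) <= tol:
        return "additivity"
    return "synergy" if ci < 1.0 else "antagonism"


def _endpoint_values(
    curves: pd.DataFrame, arm: str, endpoint_h: float
) -> np.ndarray:
    """Replicate signals of ``arm`` at the recorded time nearest endpoint_h."""
    sub = curves[curves["arm"] == arm]
    if sub.empty:
        raise EffectError(f"arm {arm!r} not present in the curve set")
    times = np.sort(sub["time_h"].unique())
    snap = times[np.argmin(np.abs(times - endpoint_h))]
    vals = sub.loc[sub["time_h"] == snap, "signal"].to_numpy(dtype=float)
    return vals


def compute_effect(
    curves: pd.DataFrame, arm: str, endpoint_h: float = 120.0
) -> Effect:
    """Fractional inhibition ``E = 1 - mean(arm) / mean(control)`` at endpoint.

    The endpoint snaps to the nearest recorded time (imaging intervals are
    irregular). The standard error is obtained by the delta method for a
    ratio of independent replicate means.
    """
    treated = _endpoint_values(curves, arm, endpoint_h)
    control = _endpoint_values(curves, "control", endpoint_h)
    mc = control.mean()
    if mc == 0:
        raise EffectError("control mean signal is 0; effect undefined")
    ma = treated.mean()
    e = 1.0 - ma / mc
    na, nc = treated.size, control.size
    va = treated.var(ddof=1) / na if na > 1 else 0.0
    vc = control.var(ddof=1) / nc if nc > 1 else 0.0
    se = math.sqrt(va / mc**2 + (ma**2 / mc**4) * vc)
    times = np.sort(curves.loc[curves["arm"] == arm, "time_h"].unique())
    snap = float(times[np.argmin(np.abs(times - endpoint_h))])
    return Effect(arm, e, se, snap, min(na, nc), growth_promotion=e < 0)


def estimate_effects(
    curves: pd.DataFrame,
    *,
    endpoint_h: float = 120.0,
    arms: tuple[str, str, str, str] = ("A", "B", "C", "ABC"),
) -> EffectSet:
    """EffectSet for the three single arms and the combination arm."""
    effs = [compute_effect(curves, a, endpoint_h) for a in arms]
    return EffectSet(
        E_A=effs[0].value,
        E_B=effs[1].value,
        E_C=effs[2].value,
        E_ABC=effs[3].value,
        endpoint_h=effs[0].endpoint_h,
        n_replicates=effs[0].n_replicates,
        se_A=effs[0].se,
        se_B=effs[1].se,
        se_C=effs[2].se,
        se_ABC=effs[3].se,
    )


def linear_ci(effects: EffectSet) -> CombinationIndex:
    """Response-additivity CI = (E_A + E_B + E_C) / E_ABC."""
    if effects.E_ABC == 0:
        raise ZeroDivisionError(
            "E_ABC is 0: the combination shows no effect, the linear CI "
            "is undefined"
        )
    ci = (effects.E_A + effects.E_B + effects.E_C) / effects.E_ABC
    return CombinationIndex("linear", ci, _interpret(ci))


def bliss_ci(effects: EffectSet, variant: str = "paper") -> CombinationIndex:
    """Bliss-independence CI.

    ``variant="paper"``: ((E_A + E_B + E_C) - E_A*E_B*E_C) / E_ABC
    ``variant="canonical"``: (1 - (1-E_A)(1-E_B)(1-E_C)) / E_ABC
    """
    if effects.E_ABC == 0:
        raise ZeroDivisionError(
            "E_ABC is 0: the combination shows no effect, the Bliss CI "
            "is undefined"
        )
    a, b, c = effects.singles
    if variant == "paper":
        expected = (a + b + c) - a * b * c
        model = "bliss_paper"
    elif variant == "canonical":
        expected = 1.0 - (1.0 - a) * (1.0 - b) * (1.0 - c)
        model = "bliss_canonical"
    else:
        raise ValueError(f"unknown Bliss variant {variant!r}")
    ci = expected / effects.E_ABC
    return CombinationIndex(model, ci, _interpret(ci))


def bootstrap_ci(
    curves: pd.DataFrame,
    model: str = "linear",
    *,
    endpoint_h: float = 120.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> CombinationIndex:
    """Point CI with a percentile bootstrap interval over replicates."""
    point = _ci_from_curves(curves, model, endpoint_h)
    rng = np.random.default_rng(seed)
    arms = {a: _endpoint_values(curves, a, endpoint_h) for a in
            ("control", "A", "B", "C", "ABC")}
    vals = []
    for _ in range(n_boot):
        res = {a: rng.choice(v, size=v.size, replace=True)
               for a, v in arms.items()}
        mc = res["control"].mean()
        if mc == 0:
            continue
        es = EffectSet(
            *(1.0 - res[a].mean() / mc for a in ("A", "B", "C", "ABC"))
        )
        if es.E_ABC == 0:
            continue
        if model == "linear":
            vals.append(linear_ci(es).ci)
        else:
            vals.append(bliss_ci(es, model.removeprefix("bliss_")).ci)
    lo, hi = np.percentile(vals, [2.5, 97.5]) if vals else (np.nan, np.nan)
    return CombinationIndex(point.model, point.ci, point.interpretation,
                            float(lo), float(hi))


def _ci_from_curves(curves, model, endpoint_h) -> CombinationIndex:
    es = estimate_effects(curves, endpoint_h=endpoint_h)
    if model == "linear":
        return linear_ci(es)
    if model in ("bliss_paper", "bliss_canonical"):
        return bliss_ci(es, model.removeprefix("bliss_"))
    raise ValueError(f"unknown CI model {model!r}")


def endpoint_comparison(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with Tukey HSD post-hoc over endpoint replicate values.

    Returns the omnibus F and p plus a tidy table of Tukey-adjusted pairwise
    p-values; results do not depend on the ordering of ``groups``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = sorted(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two replicates")

    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:  # all values identical: no signal, no variance
        pairs = [
            {"group1": labels[i], "group2": labels[j], "p_adj": 1.0}
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        return {"anova_F": 0.0, "anova_p": 1.0, "tukey": pd.DataFrame(pairs)}

    f_stat, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    pairs = [
        {
            "group1": labels[i],
            "group2": labels[j],
            "p_adj": float(tk.pvalue[i, j]),
        }
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    return {
        "anova_F": float(f_stat),
        "anova_p": float(p),
        "tukey": pd.DataFrame(pairs),
    }
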