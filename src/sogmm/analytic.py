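"""Closed-form oracle for composite-score growth-parameter bias under ignored
measurement noninvariance.

Averaging the six items at occasion t gives the composite trajectory of class c

    E[c_t | class c] = nu-bar_c + lam-bar_c * (kappa_Ic + t * kappa_Sc),

a straight line with intercept a_c = nu-bar_c + lam-bar_c * kappa_Ic and slope
b_c = lam-bar_c * kappa_Sc. A one-class composite growth model fitted to the
pooled population recovers the mixing-weighted average line, so the expected
bias of the growth-factor means against the latent truth (0, 1) is

    bias_I = sum_c pi_c a_c,      bias_S = sum_c pi_c b_c - 1.

Item intercept noninvariance of size d on 2 of 6 items shifts a_c by 2d/6 and
moves only the intercept mean; loading noninvariance of size d scales lam-bar
by -2d/6 and moves only the slope mean — the bias is linear in the DIF size.
For populations with a true factor-mean difference, the same algebra predicts
the bias of the between-class differences recovered by a two-class fit; there
it is an approximation (mixture fitting reweights observations), accurate when
the classes are well separated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import KAPPA_SHIFT, Condition, build_population
from .model import LatentClass, MixturePopulation


@dataclass
class CompositeTrajectory:
    a: float  # composite intercept = nu-bar + lam-bar * kappa_I
    b: float  # composite slope = lam-bar * kappa_S


def composite_trajectory(cls: LatentClass) -> CompositeTrajectory:
    lam_bar = float(cls.meas.lam.mean())
    nu_bar = float(cls.meas.nu.mean())
    return CompositeTrajectory(
        a=nu_bar + lam_bar * cls.growth.kappa_I,
        b=lam_bar * cls.growth.kappa_S,
    )


def predicted_one_class_bias(pop: MixturePopulation) -> tuple[float, float]:
    """Expected (intercept, slope) factor-mean bias of a one-class composite
    growth model against the latent truth (0, 1), for populations whose classes
    share the growth means."""
    a = sum(c.pi * composite_trajectory(c).a for c in pop.classes)
    b = sum(c.pi * composite_trajectory(c).b for c in pop.classes)
    return float(a - 0.0), float(b - 1.0)


def predicted_difference_bias(pop: MixturePopulation) -> tuple[float, float]:
    """Expected relative bias of the between-class (intercept, slope) mean
    differences recovered by a two-class composite fit, against the generated
    differences (1.4, 0.4)."""
    t1 = composite_trajectory(pop.classes[0])
    t2 = composite_trajectory(pop.classes[1])
    di, ds = KAPPA_SHIFT
    return float(((t2.a - t1.a) - di) / di), float(((t2.b - t1.b) - ds) / ds)


def prediction_table(conditions: list[Condition]) -> pd.DataFrame:
    """Analytic predictions for a set of conditions, for side-by-side comparison
    with the simulated bias tables."""
    rows = []
    for cond in conditions:
        pop = build_population(cond)
        row = {"condition_id": cond.condition_id, "mean_diff": cond.mean_diff}
        if cond.mean_diff == "none":
            bi, bs = predicted_one_class_bias(pop)
            row.update(pred_bias_kappa_I=bi, pred_bias_kappa_S=bs)
        else:
            ri, rs = predicted_difference_bias(pop)
            row.update(pred_rel_bias_kappa_I_diff=ri, pred_rel_bias_kappa_S_diff=rs)
        rows.append(row)
    return pd.DataFrame(rows)
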