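"""Information criteria and class enumeration.

Four criteria (natural logs throughout):

    AIC   = -2 logL + 2 k
    BIC   = -2 logL + log(n) k
    saBIC = -2 logL + log((n + 2) / 24) k
    HBIC  = -2 logL + (k0 + C - 1) log(n) + sum_c log(n pi_c) k'_c

HBIC penalizes class-specific parameters with the class's effective sample size
n*pi_c instead of n, so HBIC = BIC at C = 1 and HBIC < BIC for C > 1 whenever
all classes are non-empty. Model selection minimizes a criterion over candidate
class counts and then applies the minimum-class-proportion rule: each class of
the chosen fit holding less than 5% of the observations is discounted from the
effective class count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import FitResult

CRITERIA = ("aic", "bic", "sabic", "hbic")
DEFAULT_MIN_PROP = 0.05


@dataclass
class ICValues:
    aic: float
    bic: float
    sabic: float
    hbic: float

    def __getitem__(self, criterion: str) -> float:
        return getattr(self, criterion)


def information_criteria(fit: FitResult, n: int) -> ICValues:
    if n < 1:
        raise ValueError("n must be >= 1")
    m2ll = -2.0 * fit.loglik
    k, k0, kc = fit.counts.k, fit.counts.k0, fit.counts.kc
    C = len(kc)
    aic = m2ll + 2.0 * k
    bic = m2ll + math.log(n) * k
    sabic = m2ll + math.log((n + 2) / 24.0) * k
    pis = np.asarray(fit.class_proportions, dtype=float)
    if np.any(pis <= 0):
        hbic = math.nan  # effective sample size of an empty class is undefined
    else:
        hbic = m2ll + (k0 + C - 1) * math.log(n) + float(
            sum(math.log(n * pi) * kci for pi, kci in zip(pis, kc))
        )
    return ICValues(aic=aic, bic=bic, sabic=sabic, hbic=hbic)


@dataclass
class SelectionResult:
    chosen_C_by: dict[str, int]
    effective_C_by: dict[str, int]
    candidate_ics: pd.DataFrame
    n_converged: int = 0
    dropped: tuple[int, ...] = ()
    condition_id: str = ""
    replication: int = 0


def select_model(
    fits: dict[int, FitResult],
    n: int,
    criteria=CRITERIA,
    min_prop: float = DEFAULT_MIN_PROP,
) -> SelectionResult:
    """Choose the class count minimizing each criterion over the converged fits
    (ties toward smaller C), then discount classes below ``min_prop``."""
    rows = []
    usable = {}
    dropped = []
    for C in sorted(fits):
        fit = fits[C]
        if not fit.converged or not np.isfinite(fit.loglik):
            dropped.append(C)
            continue
        ics = information_criteria(fit, n)
        usable[C] = (fit, ics)
        rows.append(
            {"C": C, "loglik": fit.loglik, "k": fit.counts.k,
             **{crit: ics[crit] for crit in CRITERIA}}
        )
    if not usable:
        raise ValueError("no converged fit to select from")
    table = pd.DataFrame(rows)

    chosen, effective = {}, {}
    for crit in criteria:
        best_C, best_val = None, math.inf
        for C, (fit, ics) in usable.items():
            val = ics[crit]
            if math.isnan(val):
                continue
            if val < best_val - 1e-12:  # strict improvement; ties keep smaller C
                best_C, best_val = C, val
        if best_C is None:
            continue
        chosen[crit] = best_C
        fit = usable[best_C][0]
        small = int(np.sum(np.asarray(fit.class_proportions) < min_prop))
        effective[crit] = max(best_C - small, 1)
    return SelectionResult(
        chosen_C_by=chosen,
        effective_C_by=effective,
        candidate_ics=table,
        n_converged=len(usable),
        dropped=tuple(dropped),
    )


def enumeration_rates(records: pd.DataFrame, class_counts=(1, 2, 3)) -> pd.DataFrame:
    """Per (condition x criterion) proportions of replications landing on each
    effective class count. ``records`` is tidy with columns condition_id,
    replication, criterion, effective_C. Rows sum to 1 over the class counts."""
    need = {"condition_id", "criterion", "effective_C"}
    if not need.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(need)}")
    out = []
    for (cond, crit), grp in records.groupby(["condition_id", "criterion"], sort=True):
        total = len(grp)
        row = {"condition_id": cond, "criterion": crit, "n_replications": total}
        for C in class_counts:
            row[f"rate_{C}"] = float((grp["effective_C"] == C).sum() / total)
        out.append(row)
    return pd.DataFrame(out)
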