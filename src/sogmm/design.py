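"""Simulation design: the 64-cell condition grid and replication data generation.

The generating model is a two-class second-order growth mixture model with four
occasions and six items per occasion. Crossed factors:

* location of noninvariance: item factor loadings vs item intercepts,
* degree of noninvariance: small (0.20 loading / 0.30 intercept) vs large
  (0.40 / 0.60), applied to items 2 and 3,
* growth-factor mean difference between classes: none vs large (+1.4, +0.4 for
  class 2, Mahalanobis separation 2.0),
* total sample size: 100, 200, 400, 1000,
* mixing: balanced 50/50 vs unbalanced 80/20 (the larger share goes to the
  class with the higher factor means and/or measurement parameters).

The reference class has growth-factor means (0, 1), variances (0.5, 0.1) with
covariance 0.089, occasion disturbance variances 0.3, loadings
(1.00, 0.80, 0.95, 1.05, 0.95, 1.25) (mean 1, range 0.80-1.25), intercepts
(0.00, -0.15, 0.25, 0.10, -0.10, -0.06) (range -0.15-0.25) and item residual
variances 0.36, giving item reliabilities from 0.587 to 0.906.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    GROWTH_LOADINGS,
    N_INDICATORS,
    N_ITEMS,
    N_OCCASIONS,
    GrowthParams,
    LatentClass,
    MeasurementParams,
    MixturePopulation,
    population_from_dict,
    population_to_dict,
)

# Reference-class generating parameters (temporal invariance: shared over occasions).
LAMBDA_REF = np.array([1.00, 0.80, 0.95, 1.05, 0.95, 1.25])
NU_REF = np.array([0.00, -0.15, 0.25, 0.10, -0.10, -0.06])
THETA_REF = np.full(N_ITEMS, 0.36)
PSI_REF = np.full(N_OCCASIONS, 0.3)
PHI_REF = np.array([[0.5, 0.089], [0.089, 0.1]])
KAPPA_REF = np.array([0.0, 1.0])
KAPPA_SHIFT = np.array([1.4, 0.4])

#: 0-based indices of the two conventionally noninvariant items.
DIF_ITEMS = (1, 2)
DIF_SIZES = {"loading": {"small": 0.20, "large": 0.40}, "intercept": {"small": 0.30, "large": 0.60}}

DIF_LOCATIONS = ("loading", "intercept")
DEGREES = ("small", "large")
MEAN_DIFFS = ("none", "large")
SAMPLE_SIZES = (100, 200, 400, 1000)
MIXINGS = ("balanced", "unbalanced")


@dataclass(frozen=True)
class Condition:
    dif_location: str
    dif_size: str
    mean_diff: str
    n_total: int
    mixing: str

    def __post_init__(self):
        assert self.dif_location in DIF_LOCATIONS
        assert self.dif_size in DEGREES
        assert self.mean_diff in MEAN_DIFFS
        assert self.n_total in SAMPLE_SIZES
        assert self.mixing in MIXINGS

    @property
    def condition_id(self) -> str:
        return (
            f"{self.dif_location}-{self.dif_size}-md{self.mean_diff}"
            f"-n{self.n_total}-{self.mixing}"
        )

    @property
    def true_n_classes_composite(self) -> int:
        """Correct class count for the composite-score GMM: growth heterogeneity
        exists only under a factor-mean difference."""
        return 2 if self.mean_diff == "large" else 1

    @property
    def true_n_classes_sogmm(self) -> int:
        """The SOGMM can represent measurement heterogeneity, so two classes are
        always correct."""
        return 2


def build_condition_grid() -> list[Condition]:
    """All 2 x 2 x 2 x 4 x 2 = 64 simulation conditions in deterministic order."""
    return [
        Condition(loc, size, md, n, mix)
        for loc, size, md, n, mix in product(DIF_LOCATIONS, DEGREES, MEAN_DIFFS, SAMPLE_SIZES, MIXINGS)
    ]


def grid_to_frame(grid=None) -> pd.DataFrame:
    grid = build_condition_grid() if grid is None else grid
    return pd.DataFrame(
        [
            {
                "condition_id": c.condition_id,
                "dif_location": c.dif_location,
                "dif_size": c.dif_size,
                "mean_diff": c.mean_diff,
                "n_total": c.n_total,
                "mixing": c.mixing,
            }
            for c in grid
        ]
    )


def build_population(cond: Condition) -> MixturePopulation:
    """Two-class generating population for one condition.

    Class 1 is the reference class (kappa = (0, 1)). Under a factor-mean
    difference, class 2 has kappa = (1.4, 1.4) and noninvariance is positively
    paired with growth status: the higher class carries the higher loadings
    (class 1's loadings on items 2-3 are reduced) or the higher intercepts
    (class 2's intercepts are raised). Without a factor-mean difference,
    class 2 carries the reduced loadings or the raised intercepts. Unbalanced
    mixing gives 0.8 to the class with higher factor means and/or measurement
    parameters.
    """
    delta = DIF_SIZES[cond.dif_location][cond.dif_size]

    lam = [LAMBDA_REF.copy(), LAMBDA_REF.copy()]
    nu = [NU_REF.copy(), NU_REF.copy()]
    if cond.dif_location == "loading":
        # the class with LOWER growth status carries the reduced loadings
        low = 1 if cond.mean_diff == "none" else 0
        lam[low][list(DIF_ITEMS)] -= delta
        high = 1 - low if cond.mean_diff == "none" else 1
    else:
        # the class with HIGHER growth status carries the raised intercepts
        nu[1][list(DIF_ITEMS)] += delta
        high = 1

    kappa2 = KAPPA_REF + KAPPA_SHIFT if cond.mean_diff == "large" else KAPPA_REF.copy()
    if cond.mean_diff == "large":
        high = 1

    if cond.mixing == "balanced":
        pis = [0.5, 0.5]
    else:
        pis = [0.2, 0.2]
        pis[high] = 0.8

    classes = []
    for c, (kap, pi) in enumerate(zip((KAPPA_REF.copy(), kappa2), pis)):
        classes.append(
            LatentClass(
                pi=pi,
                growth=GrowthParams(kap, PHI_REF.copy(), PSI_REF.copy()),
                meas=MeasurementParams(lam[c], nu[c], THETA_REF.copy()),
            )
        )
    return MixturePopulation(classes, label=cond.condition_id)


# ---------------------------------------------------------------------------
# Data generation


@dataclass
class Dataset:
    items: np.ndarray  # (n, 24)
    composites: np.ndarray  # (n, 4)
    true_class: np.ndarray  # (n,) 0-based labels
    seed: int
    condition_id: str = ""
    replication: int = 0

    @property
    def n(self) -> int:
        return self.items.shape[0]


def condition_seed(root_seed: int, condition_id: str, replication: int) -> int:
    """Deterministic per-replication seed derived from a root seed (< 2**31)."""
    h = zlib.crc32(f"{condition_id}|{replication}".encode())
    return int((root_seed * 2654435761 + h) % (2**31 - 1))


def generate_dataset(
    pop: MixturePopulation, n: int, seed: int, replication: int = 0
) -> Dataset:
    """Draw n observations from the mixture by simulating the latent structure:
    class label from pi, growth factors from N(kappa, Phi), occasion disturbances
    from N(0, Psi), item errors from N(0, Theta), assembled through the
    measurement model. Reproducible under (seed, replication)."""
    if n < pop.n_classes:
        raise ValueError("n must be at least the number of classes")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(replication)]))
    labels = rng.choice(pop.n_classes, size=n, p=pop.mixing)
    items = np.empty((n, N_INDICATORS))
    for c, cls in enumerate(pop.classes):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        m = idx.size
        xi = rng.multivariate_normal(cls.growth.kappa, cls.growth.phi, size=m)
        zeta = rng.normal(0.0, np.sqrt(cls.growth.psi), size=(m, N_OCCASIONS))
        eta = xi @ GROWTH_LOADINGS.T + zeta  # (m, 4)
        eps = rng.normal(
            0.0, np.sqrt(np.tile(cls.meas.theta, N_OCCASIONS)), size=(m, N_INDICATORS)
        )
        y = np.tile(cls.meas.nu, N_OCCASIONS) + np.repeat(eta, N_ITEMS, axis=1) * np.tile(
            cls.meas.lam, N_OCCASIONS
        ) + eps
        items[idx] = y
    ds = Dataset(
        items=items,
        composites=np.empty((n, N_OCCASIONS)),
        true_class=labels,
        seed=int(seed),
        condition_id=pop.label,
        replication=int(replication),
    )
    return to_composites(ds)


def to_composites(ds: Dataset) -> Dataset:
    """Fill the per-occasion unweighted item means; items are retained."""
    ds.composites = ds.items.reshape(ds.n, N_OCCASIONS, N_ITEMS).mean(axis=2)
    return ds


# ---------------------------------------------------------------------------
# CSV I/O (wide layout: id, class, y_1_1..y_4_6, c_1..c_4)

ITEM_COLS = [f"y_{t + 1}_{j + 1}" for t in range(N_OCCASIONS) for j in range(N_ITEMS)]
COMP_COLS = [f"c_{t + 1}" for t in range(N_OCCASIONS)]


def dataset_to_frame(ds: Dataset) -> pd.DataFrame:
    df = pd.DataFrame(ds.items, columns=ITEM_COLS)
    for t, col in enumerate(COMP_COLS):
        df[col] = ds.composites[:, t]
    df.insert(0, "class", ds.true_class + 1)
    df.insert(0, "id", np.arange(1, ds.n + 1))
    return df


def write_dataset(ds: Dataset, path, pop: MixturePopulation | None = None) -> None:
    path = Path(path)
    dataset_to_frame(ds).to_csv(path, index=False)
    meta = {
        "condition_id": ds.condition_id,
        "replication": ds.replication,
        "seed": ds.seed,
        "item_order": "occasion-major",
    }
    if pop is not None:
        meta["population"] = population_to_dict(pop)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_dataset(path) -> Dataset:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    ds = Dataset(
        items=df[ITEM_COLS].to_numpy(),
        composites=df[COMP_COLS].to_numpy(),
        true_class=df["class"].to_numpy() - 1,
        seed=int(meta.get("seed", -1)),
        condition_id=str(meta.get("condition_id", "")),
        replication=int(meta.get("replication", 0)),
    )
    return ds


def read_dataset_population(path) -> MixturePopulation | None:
    side = Path(path).with_suffix(".json")
    if not side.exists():
        return None
    meta = json.loads(side.read_text())
    if "population" not in meta:
        return None
    return population_from_dict(meta["population"])
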