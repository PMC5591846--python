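"""Parameter containers and exact model-implied moments for growth mixture models.

Two model families are covered by the same containers:

* the first-order (composite-score) growth mixture model, where the observed
  variables are the four per-occasion composites and the within-class model is
  a linear latent growth curve, and
* the second-order growth mixture model (SOGMM), where each occasion's outcome
  is a common factor measured by six continuous items and the growth curve sits
  on top of those factors.

Conventions fixed throughout the package: four occasions with linear slope
loadings (0, 1, 2, 3); six items per occasion; item order is occasion-major
(occasion 1 items 1-6, ..., occasion 4 items 19-24); measurement parameters are
invariant over time within class (strict temporal invariance), so a class is
described by a single 6-vector of loadings, intercepts, and residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

N_OCCASIONS = 4
N_ITEMS = 6
N_INDICATORS = N_OCCASIONS * N_ITEMS

#: Growth-curve design matrix Gamma: intercept loadings all 1, slope loadings 0..3.
GROWTH_LOADINGS = np.column_stack(
    [np.ones(N_OCCASIONS), np.arange(N_OCCASIONS, dtype=float)]
)


class ModelError(ValueError):
    """Raised for structurally invalid parameter sets (non-PSD, negative variances)."""


def _as_vector(x, n, name):
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.shape != (n,):
        raise ModelError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr


@dataclass
class GrowthParams:
    """Second-order (growth) part of one latent class.

    kappa : (2,) means of the intercept and slope factors.
    phi   : (2, 2) covariance of the growth factors (must be symmetric PSD).
    psi   : (4,) occasion-specific disturbance variances of the first-order factors.
    """

    kappa: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        self.kappa = _as_vector(self.kappa, 2, "kappa")
        self.phi = np.asarray(self.phi, dtype=float).reshape(2, 2)
        self.psi = _as_vector(self.psi, N_OCCASIONS, "psi")
        if not np.allclose(self.phi, self.phi.T, atol=1e-10):
            raise ModelError("phi must be symmetric")
        if np.min(np.linalg.eigvalsh(self.phi)) < -1e-10:
            raise ModelError("phi must be positive semi-definite")
        if np.any(self.psi < -1e-12):
            raise ModelError("psi must be non-negative")

    @property
    def kappa_I(self) -> float:
        return float(self.kappa[0])

    @property
    def kappa_S(self) -> float:
        return float(self.kappa[1])

    @property
    def growth_loadings(self) -> np.ndarray:
        return GROWTH_LOADINGS.copy()

    def factor_means(self) -> np.ndarray:
        """Implied means of the four first-order factors, Gamma @ kappa."""
        return GROWTH_LOADINGS @ self.kappa

    def factor_cov(self) -> np.ndarray:
        """Implied covariance of the four first-order factors, Gamma Phi Gamma' + Psi."""
        return GROWTH_LOADINGS @ self.phi @ GROWTH_LOADINGS.T + np.diag(self.psi)


@dataclass
class MeasurementParams:
    """First-order measurement model of one class, shared across the four occasions."""

    lam: np.ndarray
    nu: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.lam = _as_vector(self.lam, N_ITEMS, "lam")
        self.nu = _as_vector(self.nu, N_ITEMS, "nu")
        self.theta = _as_vector(self.theta, N_ITEMS, "theta")
        if np.any(self.theta < -1e-12):
            raise ModelError("theta must be non-negative")

    @staticmethod
    def identity() -> "MeasurementParams":
        """Degenerate measurement model (lam=1, nu=0, theta=0) used by the
        composite-score family, where the composites are modeled directly."""
        return MeasurementParams(np.ones(N_ITEMS), np.zeros(N_ITEMS), np.zeros(N_ITEMS))


@dataclass
class LatentClass:
    pi: float
    growth: GrowthParams
    meas: MeasurementParams

    def __post_init__(self):
        if not (0.0 < self.pi <= 1.0):
            raise ModelError(f"pi must lie in (0, 1], got {self.pi}")


@dataclass
class MixturePopulation:
    """Ordered set of latent classes; class 1 is the reference class."""

    classes: list[LatentClass]
    label: str = ""

    def __post_init__(self):
        total = sum(c.pi for c in self.classes)
        if abs(total - 1.0) > 1e-8:
            raise ModelError(f"mixing proportions must sum to 1, got {total}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def mixing(self) -> np.ndarray:
        return np.array([c.pi for c in self.classes])

    def permuted(self, order) -> "MixturePopulation":
        return MixturePopulation([self.classes[i] for i in order], label=self.label)


@dataclass
class ParamCount:
    """Free-parameter bookkeeping: k = k0 + (C-1) + sum(kc)."""

    k: int
    k0: int
    kc: tuple[int, ...]

    def __post_init__(self):
        self.kc = tuple(int(x) for x in self.kc)
        if self.k != self.k0 + (len(self.kc) - 1) + sum(self.kc):
            raise ModelError("parameter-count identity k = k0 + (C-1) + sum(kc) violated")


# ---------------------------------------------------------------------------
# Implied moments


def expanded_loading_matrix(lam: np.ndarray) -> np.ndarray:
    """Block-diagonal 24 x 4 loading matrix: one 6-vector column per occasion."""
    lam = _as_vector(lam, N_ITEMS, "lam")
    big = np.zeros((N_INDICATORS, N_OCCASIONS))
    for t in range(N_OCCASIONS):
        big[t * N_ITEMS : (t + 1) * N_ITEMS, t] = lam
    return big


def implied_item_moments(cls: LatentClass) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean (24,) and covariance (24, 24) of the item vector.

    mu    = nu + Lambda Gamma kappa
    Sigma = Lambda (Gamma Phi Gamma' + Psi) Lambda' + Theta
    with Lambda the block-diagonal expansion of the 6 item loadings.
    """
    g, m = cls.growth, cls.meas
    big_lam = expanded_loading_matrix(m.lam)
    mu = np.tile(m.nu, N_OCCASIONS) + big_lam @ g.factor_means()
    sigma = big_lam @ g.factor_cov() @ big_lam.T + np.diag(np.tile(m.theta, N_OCCASIONS))
    return mu, sigma


def implied_composite_moments(cls: LatentClass) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean (4,) and covariance (4, 4) of the per-occasion
    unweighted item-mean composites.

    Composite at occasion t is nu-bar + lam-bar * eta_t + eps-bar, so
    mean_t  = nu-bar + lam-bar * (kappa_I + t kappa_S)
    cov     = lam-bar^2 * (Gamma Phi Gamma' + Psi) + diag(theta-bar / 6)
    where theta-bar/6 is the variance of the mean of the 6 item errors.
    """
    g, m = cls.growth, cls.meas
    lam_bar = m.lam.mean()
    nu_bar = m.nu.mean()
    mu = nu_bar + lam_bar * g.factor_means()
    # mean of 6 independent errors: variance sum(theta)/36 = theta-bar/6
    err = m.theta.sum() / N_ITEMS**2
    sigma = lam_bar**2 * g.factor_cov() + np.diag(np.full(N_OCCASIONS, err))
    return mu, sigma


def class_moments(cls: LatentClass, family: str) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch on observation family: 'composite' (4-dim) or 'item' (24-dim)."""
    if family == "composite":
        return implied_composite_moments(cls)
    if family == "item":
        return implied_item_moments(cls)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Mixture log-likelihood


def _mvn_logpdf(data: np.ndarray, mu: np.ndarray, sigma: np.ndarray, what: str) -> np.ndarray:
    p = mu.shape[0]
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ModelError(f"singular covariance for {what}") from exc
    z = solve_triangular(chol, (data - mu).T, lower=True)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (p * np.log(2.0 * np.pi) + logdet + np.einsum("ij,ij->j", z, z))


def mixture_loglik(data: np.ndarray, pop: MixturePopulation, family: str) -> float:
    """Observed-data log-likelihood sum_i log sum_c pi_c N(y_i; mu_c, Sigma_c),
    accumulated with log-sum-exp for numerical stability."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    parts = np.empty((data.shape[0], pop.n_classes))
    for c, cls in enumerate(pop.classes):
        mu, sigma = class_moments(cls, family)
        if data.shape[1] != mu.shape[0]:
            raise ValueError(
                f"data has {data.shape[1]} columns but family {family!r} implies {mu.shape[0]}"
            )
        parts[:, c] = np.log(cls.pi) + _mvn_logpdf(data, mu, sigma, f"class {c + 1}")
    return float(logsumexp(parts, axis=1).sum())


# ---------------------------------------------------------------------------
# Scalar summaries


def class_separation_md(kappa_diff, phi) -> float:
    """Mahalanobis distance sqrt(d' Phi^-1 d) between class factor means."""
    d = _as_vector(kappa_diff, 2, "kappa_diff")
    phi = np.asarray(phi, dtype=float).reshape(2, 2)
    try:
        sol = np.linalg.solve(phi, d)
    except np.linalg.LinAlgError as exc:
        raise ModelError("phi is singular") from exc
    return float(np.sqrt(d @ sol))


def item_reliability(lam_j: float, occasion_t: int, growth: GrowthParams, theta_j: float) -> float:
    """Proportion of item variance explained by the first-order factor at occasion t:
    lam^2 V_t / (lam^2 V_t + theta), V_t = phi_I + t^2 phi_S + 2 t phi_IS + psi_t."""
    if occasion_t not in range(N_OCCASIONS):
        raise ValueError(f"occasion_t must be in 0..{N_OCCASIONS - 1}")
    if theta_j < 0:
        raise ModelError("theta must be non-negative")
    v_t = growth.factor_cov()[occasion_t, occasion_t]
    if v_t < 0:
        raise ModelError("negative factor variance")
    common = lam_j**2 * v_t
    return float(common / (common + theta_j)) if common + theta_j > 0 else 0.0


# ---------------------------------------------------------------------------
# Flat serialization of parameter sets (config round-trip)


def population_to_dict(pop: MixturePopulation) -> dict:
    out = {"label": pop.label, "classes": []}
    for cls in pop.classes:
        out["classes"].append(
            {
                "pi": float(cls.pi),
                "kappa": cls.growth.kappa.tolist(),
                "phi": cls.growth.phi.tolist(),
                "psi": cls.growth.psi.tolist(),
                "lambda": cls.meas.lam.tolist(),
                "nu": cls.meas.nu.tolist(),
                "theta": cls.meas.theta.tolist(),
            }
        )
    return out


def population_from_dict(d: dict) -> MixturePopulation:
    classes = [
        LatentClass(
            pi=c["pi"],
            growth=GrowthParams(np.array(c["kappa"]), np.array(c["phi"]), np.array(c["psi"])),
            meas=MeasurementParams(np.array(c["lambda"]), np.array(c["nu"]), np.array(c["theta"])),
        )
        for c in d["classes"]
    ]
    return MixturePopulation(classes, label=d.get("label", ""))
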