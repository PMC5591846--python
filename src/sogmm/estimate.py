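"""Maximum-likelihood estimation of composite-score GMMs and second-order GMMs.

Both families are finite mixtures of structured multivariate normals and are
fitted by an expectation-conditional-maximization (ECM) algorithm. The E-step
computes posterior class responsibilities together with the conditional moments
of the latent variables (growth factors, and for the SOGMM the occasion
disturbances) given the data and class; the M-step then has closed-form
conditional-maximization updates for every parameter block:

* mixing proportions,
* class-specific growth-factor means,
* pooled (or class-specific) growth-factor covariance and occasion disturbance
  variances,
* class-specific non-marker loadings and intercepts (a weighted 2x2 regression
  per item and class), and
* pooled item residual variances.

Each CM step maximizes the expected complete-data log-likelihood over its block,
so the observed-data log-likelihood is non-decreasing across iterations — the
usual EM monotonicity guarantee, which the test suite asserts per iteration.

Identification of the SOGMM: item 1 is the marker (loading 1, intercept 0,
invariant over classes and time), so the fitted latent metric coincides with
the generating metric and bias can be read off without rescaling. By default
the within-class covariance structure (growth covariance, disturbance and
residual variances) is pooled across classes; only means, non-marker loadings
and intercepts are class-specific. ``ModelSpec.pooled_covariance=False`` frees
the full covariance structure per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular

from .design import Dataset
from .model import (
    GROWTH_LOADINGS,
    N_INDICATORS,
    N_ITEMS,
    N_OCCASIONS,
    GrowthParams,
    LatentClass,
    MeasurementParams,
    MixturePopulation,
    ParamCount,
    population_to_dict,
)

FAMILIES = ("composite_gmm", "sogmm")
VARIANCE_FLOOR = 1e-4
# relative change in loglik; 1e-8 keeps the absolute gap well below IC margins
# even at the 24-indicator likelihood magnitudes (|logL| ~ 3e4 at n = 1000)
DEFAULT_TOL = 1e-8
# Aitken-projected remaining loglik gain below which the run is declared
# converged; cuts off the slow geometric crawl of weakly separated mixtures
DEFAULT_GAP_TOL = 1e-4
DEFAULT_MAX_ITER = 2000
DEFAULT_STARTS = {"composite_gmm": 20, "sogmm": 10}

# eta_t = xi_I + t * xi_S + zeta_t  ->  H maps (xi, zeta) to eta
_H = np.hstack([GROWTH_LOADINGS, np.eye(N_OCCASIONS)])  # (4, 6)


@dataclass(frozen=True)
class ModelSpec:
    family: str
    n_classes: int
    pooled_covariance: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")

    @property
    def obs_family(self) -> str:
        return "composite" if self.family == "composite_gmm" else "item"

    @property
    def n_obs_columns(self) -> int:
        return N_OCCASIONS if self.family == "composite_gmm" else N_INDICATORS

    def describe_constraints(self) -> dict:
        if self.family == "composite_gmm":
            class_specific = ["kappa_I", "kappa_S"]
            pooled = ["phi (3)", "psi (4 occasion residual variances)"]
            fixed = ["growth loadings Gamma = [1, t]"]
        else:
            class_specific = ["kappa_I", "kappa_S", "lambda[2..6]", "nu[2..6]"]
            pooled = ["phi (3)", "psi (4)", "theta (6)"]
            fixed = ["marker item 1: lambda=1, nu=0", "temporal invariance", "Gamma = [1, t]"]
        if not self.pooled_covariance:
            class_specific, pooled = class_specific + pooled, []
        return {"class_specific": class_specific, "pooled": pooled, "fixed": fixed}


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: MixturePopulation
    loglik: float
    counts: ParamCount
    responsibilities: np.ndarray
    class_proportions: np.ndarray
    converged: bool
    n_starts_used: int = 1
    best_start_seed: int = 0
    loglik_path: list[float] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "family": self.spec.family,
            "n_classes": self.spec.n_classes,
            "pooled_covariance": self.spec.pooled_covariance,
            "loglik": self.loglik,
            "counts": {"k": self.counts.k, "k0": self.counts.k0, "kc": list(self.counts.kc)},
            "class_proportions": self.class_proportions.tolist(),
            "converged": bool(self.converged),
            "n_starts_used": self.n_starts_used,
            "best_start_seed": self.best_start_seed,
            "estimates": population_to_dict(self.estimates),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def count_free_parameters(spec: ModelSpec) -> ParamCount:
    """Free parameters: k = k0 + (C - 1) + sum_c kc.

    Composite GMM (pooled): k0 = 3 (Phi) + 4 (occasion residual variances),
    kc = 2 per class (growth means). SOGMM (pooled): k0 = 3 (Phi) + 4 (Psi) +
    6 (Theta), kc = 2 + 5 + 5 (growth means, non-marker loadings, intercepts).
    """
    C = spec.n_classes
    if spec.family == "composite_gmm":
        k0, kc = 7, 2
    else:
        k0, kc = 13, 12
    if not spec.pooled_covariance:
        kc += k0
        k0 = 0
    return ParamCount(k=k0 + (C - 1) + C * kc, k0=k0, kc=(kc,) * C)


def _extract(data, spec: ModelSpec) -> np.ndarray:
    if isinstance(data, Dataset):
        arr = data.composites if spec.family == "composite_gmm" else data.items
    else:
        arr = np.asarray(data, dtype=float)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != spec.n_obs_columns:
        raise ValueError(
            f"{spec.family} expects {spec.n_obs_columns} columns, got {arr.shape[1]}"
        )
    return arr


# ---------------------------------------------------------------------------
# Internal parameter representation
#
# The EM inner loop works on plain per-class dicts (pi, kappa, phi, psi, lam,
# nu, theta) and converts to the validated public containers only at the
# boundary; container validation per iteration would dominate the runtime of
# the small-n fits.


def _pop_to_params(pop: MixturePopulation) -> list[dict]:
    out = []
    for cls in pop.classes:
        out.append(
            {
                "pi": float(cls.pi),
                "kappa": cls.growth.kappa.copy(),
                "phi": cls.growth.phi.copy(),
                "psi": cls.growth.psi.copy(),
                "lam": cls.meas.lam.copy(),
                "nu": cls.meas.nu.copy(),
                "theta": cls.meas.theta.copy(),
            }
        )
    return out


def _params_to_pop(params: list[dict]) -> MixturePopulation:
    classes = [
        LatentClass(
            pi=p["pi"],
            growth=GrowthParams(p["kappa"], p["phi"], p["psi"]),
            meas=MeasurementParams(p["lam"], p["nu"], p["theta"]),
        )
        for p in params
    ]
    total = sum(p["pi"] for p in params)
    for cls in classes:
        cls.pi /= total
    return MixturePopulation(classes)


# ---------------------------------------------------------------------------
# E-step machinery

_LOG2PI = np.log(2.0 * np.pi)


class _ClassWorkspace:
    """Per-class observation moments and latent conditional moments."""

    def __init__(self, p: dict, spec: ModelSpec):
        self.p = p
        if spec.family == "composite_gmm":
            # y = Gamma xi + e, e ~ N(0, diag(psi))
            self.B = GROWTH_LOADINGS
            self.mu_y = GROWTH_LOADINGS @ p["kappa"]
            self.prior_mean = p["kappa"]
            self.prior_cov = p["phi"]
            resid = p["psi"]
        else:
            # y = nu + Lambda (H u) + eps, u = (xi, zeta)
            lam = p["lam"]
            self.B = (np.repeat(lam[None, :], N_OCCASIONS, axis=0)[:, :, None]
                      * _H[:, None, :]).reshape(N_INDICATORS, 6)
            self.prior_mean = np.concatenate([p["kappa"], np.zeros(N_OCCASIONS)])
            self.prior_cov = np.block(
                [
                    [p["phi"], np.zeros((2, N_OCCASIONS))],
                    [np.zeros((N_OCCASIONS, 2)), np.diag(p["psi"])],
                ]
            )
            self.mu_y = np.tile(p["nu"], N_OCCASIONS) + self.B @ self.prior_mean
            resid = np.tile(p["theta"], N_OCCASIONS)
        self.sigma_y = self.B @ self.prior_cov @ self.B.T + np.diag(resid)

    def prepare(self, Y: np.ndarray):
        d = self.mu_y.shape[0]
        chol = np.linalg.cholesky(self.sigma_y)  # raises LinAlgError if singular
        dev = (Y - self.mu_y).T  # (d, n)
        w = solve_triangular(chol, dev, lower=True, check_finite=False)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        self.logpdf = -0.5 * (d * _LOG2PI + logdet + np.einsum("ij,ij->j", w, w))
        z = solve_triangular(chol.T, w, lower=False, check_finite=False)  # Sigma^-1 dev
        K = self.prior_cov @ self.B.T  # (q, d)
        self.Eu = self.prior_mean + (K @ z).T  # (n, q)
        KS = solve_triangular(chol, K.T, lower=True, check_finite=False)
        self.Vu = self.prior_cov - KS.T @ KS  # (q, q)


def _estep(Y: np.ndarray, params: list[dict], spec: ModelSpec):
    works = []
    logp = np.empty((Y.shape[0], len(params)))
    for c, p in enumerate(params):
        w = _ClassWorkspace(p, spec)
        w.prepare(Y)
        works.append(w)
        logp[:, c] = np.log(max(p["pi"], 1e-300)) + w.logpdf
    m = logp.max(axis=1)
    norm = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
    resp = np.exp(logp - norm[:, None])
    return float(norm.sum()), resp, works


# ---------------------------------------------------------------------------
# M-step (closed-form conditional maximizations)


def _symmetrize_psd(a: np.ndarray, floor: float) -> np.ndarray:
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    return (v * np.maximum(w, floor)) @ v.T


def _mstep(Y: np.ndarray, resp: np.ndarray, works, spec: ModelSpec) -> list[dict]:
    n, C = resp.shape
    n_c = resp.sum(axis=0)
    pis = np.maximum(n_c / n, 1e-12)
    pis = pis / pis.sum()

    per_class: list[dict] = []
    Y3 = Y.reshape(n, N_OCCASIONS, -1) if spec.family == "sogmm" else None

    for c in range(C):
        w, r, nc = works[c], resp[:, c], n_c[c]
        old = w.p
        if nc < 1e-8:
            # empty component: freeze its parameters; contributes nothing to pools
            frozen = dict(old)
            frozen.update(
                phi_sum=np.zeros((2, 2)), psi_sum=np.zeros(N_OCCASIONS),
                theta_sum=np.zeros(N_ITEMS), frozen=True,
            )
            per_class.append(frozen)
            continue

        Exi = w.Eu[:, :2]
        kappa = (r @ Exi) / nc
        dev = Exi - kappa
        phi_sum = (r[:, None] * dev).T @ dev + nc * w.Vu[:2, :2]

        if spec.family == "composite_gmm":
            fitted = Exi @ GROWTH_LOADINGS.T  # (n, 4)
            gvg = np.einsum("ti,ij,tj->t", GROWTH_LOADINGS, w.Vu, GROWTH_LOADINGS)
            psi_sum = r @ (Y - fitted) ** 2 + nc * gvg
            per_class.append(
                dict(kappa=kappa, phi_sum=phi_sum, psi_sum=psi_sum,
                     theta_sum=np.zeros(N_ITEMS), lam=old["lam"], nu=old["nu"],
                     frozen=False)
            )
        else:
            Ezeta = w.Eu[:, 2:]
            psi_sum = r @ (Ezeta**2) + nc * np.diag(w.Vu[2:, 2:])
            Eeta = w.Eu @ _H.T  # (n, 4)
            veta = np.einsum("ti,ij,tj->t", _H, w.Vu, _H)  # (4,)
            s1 = r @ Eeta.sum(axis=1)
            s2 = r @ (Eeta**2).sum(axis=1) + nc * veta.sum()
            b1 = np.einsum("n,ntj->j", r, Y3)
            b2 = np.einsum("n,ntj,nt->j", r, Y3, Eeta)
            A = np.array([[N_OCCASIONS * nc, s1], [s1, s2]])
            sol = np.linalg.solve(A, np.vstack([b1, b2]))  # (2, 6)
            nu = sol[0].copy()
            lam = sol[1].copy()
            nu[0], lam[0] = 0.0, 1.0  # marker identification
            res = Y3 - nu[None, None, :] - lam[None, None, :] * Eeta[:, :, None]
            theta_sum = np.einsum("n,ntj->j", r, res**2) + nc * (lam**2) * veta.sum()
            per_class.append(
                dict(kappa=kappa, phi_sum=phi_sum, psi_sum=psi_sum,
                     theta_sum=theta_sum, lam=lam, nu=nu, frozen=False)
            )

    # assemble, pooling covariance blocks if requested
    if spec.pooled_covariance:
        pooled_phi = _symmetrize_psd(sum(p["phi_sum"] for p in per_class) / n, VARIANCE_FLOOR)
        pooled_psi = np.maximum(sum(p["psi_sum"] for p in per_class) / n, VARIANCE_FLOOR)
        pooled_theta = (
            np.maximum(sum(p["theta_sum"] for p in per_class) / (N_OCCASIONS * n),
                       VARIANCE_FLOOR)
            if spec.family == "sogmm"
            else np.zeros(N_ITEMS)
        )
    out = []
    for c in range(C):
        p = per_class[c]
        if p["frozen"]:
            newp = dict(works[c].p)
        elif spec.pooled_covariance:
            theta = pooled_theta if spec.family == "sogmm" else np.zeros(N_ITEMS)
            newp = dict(kappa=p["kappa"], phi=pooled_phi, psi=pooled_psi,
                        lam=p["lam"], nu=p["nu"], theta=theta)
        else:
            nc = n_c[c]
            newp = dict(
                kappa=p["kappa"],
                phi=_symmetrize_psd(p["phi_sum"] / nc, VARIANCE_FLOOR),
                psi=np.maximum(p["psi_sum"] / nc, VARIANCE_FLOOR),
                lam=p["lam"], nu=p["nu"],
                theta=(np.maximum(p["theta_sum"] / (N_OCCASIONS * nc), VARIANCE_FLOOR)
                       if spec.family == "sogmm" else np.zeros(N_ITEMS)),
            )
        newp["pi"] = float(pis[c])
        out.append(newp)
    return out


# ---------------------------------------------------------------------------
# EM driver, starts, public fitting API

# at the iteration cap, a run whose final loglik increment is below this is
# within information-criterion noise of its limit and treated as converged
PRACTICAL_CAP_INCREMENT = 1e-3


def _run_em_params(
    Y: np.ndarray,
    spec: ModelSpec,
    params: list[dict],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    gap_tol: float = DEFAULT_GAP_TOL,
):
    path: list[float] = []
    prev = -np.inf
    converged = False
    resp = None
    for it in range(max_iter):
        try:
            ll, resp, works = _estep(Y, params, spec)
        except np.linalg.LinAlgError:
            return params, prev, path, False, resp
        path.append(ll)
        if np.isfinite(prev):
            d1 = ll - prev
            if abs(d1) / (abs(prev) + 1.0) < tol:
                converged = True
                break
            # Aitken projection, trusted only in a stable geometric regime:
            # the last few increment ratios must agree and lie below 1
            # (a transient saddle plateau shows fluctuating ratios instead).
            if gap_tol > 0 and it >= 8:
                d = np.diff(path[-5:])
                if np.all(d > 0):
                    ratios = d[1:] / d[:-1]
                    if np.all(ratios < 0.999) and np.ptp(ratios) < 0.03:
                        a = ratios[-1]
                        if d1 * a / (1.0 - a) < gap_tol:
                            converged = True
                            break
        prev = ll
        params = _mstep(Y, resp, works, spec)
    if resp is None:
        return params, -np.inf, path, False, None
    try:
        ll, resp, _ = _estep(Y, params, spec)
        path.append(ll)
    except np.linalg.LinAlgError:
        return params, prev, path, False, resp
    if not converged and len(path) >= 2 and path[-1] - path[-2] < PRACTICAL_CAP_INCREMENT:
        converged = True
    return params, ll, path, converged, resp


def run_em(
    Y: np.ndarray,
    spec: ModelSpec,
    init: MixturePopulation,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    gap_tol: float = DEFAULT_GAP_TOL,
):
    """Run ECM from one start. Returns (pop, loglik, path, converged, resp).

    Stopping rules, whichever fires first: relative per-iteration loglik
    change below ``tol``, or Aitken-accelerated projection of the remaining
    loglik gain below ``gap_tol`` (EM converges geometrically, so the limit
    is l_inf ~ l_k + (l_{k+1} - l_k) * a / (1 - a) with rate a estimated from
    successive increments once they decay stably)."""
    params, ll, path, converged, resp = _run_em_params(
        Y, spec, _pop_to_params(init), tol=tol, max_iter=max_iter, gap_tol=gap_tol
    )
    return _params_to_pop(params), ll, path, converged, resp


def _single_class_init(Y: np.ndarray, spec: ModelSpec) -> MixturePopulation:
    """Crude moment-based start for the one-class model."""
    if spec.family == "composite_gmm":
        kappa, *_ = np.linalg.lstsq(GROWTH_LOADINGS, Y.mean(axis=0), rcond=None)
        growth = GrowthParams(kappa, np.array([[0.3, 0.0], [0.0, 0.1]]), np.full(4, 0.3))
        meas = MeasurementParams.identity()
    else:
        comp = Y.reshape(len(Y), N_OCCASIONS, N_ITEMS).mean(axis=2)
        kappa, *_ = np.linalg.lstsq(GROWTH_LOADINGS, comp.mean(axis=0), rcond=None)
        item_dev = (Y.reshape(len(Y), N_OCCASIONS, N_ITEMS) - comp[:, :, None]).mean(axis=(0, 1))
        nu = item_dev
        nu = nu - nu[0]  # marker nu = 0
        growth = GrowthParams(kappa, np.array([[0.3, 0.0], [0.0, 0.1]]), np.full(4, 0.3))
        meas = MeasurementParams(np.ones(N_ITEMS), nu, np.full(N_ITEMS, 0.3))
    return MixturePopulation([LatentClass(1.0, growth, meas)])


def fit_single_class(Y: np.ndarray, spec: ModelSpec, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER):
    base_spec = ModelSpec(spec.family, 1, spec.pooled_covariance)
    init = _single_class_init(Y, base_spec)
    return run_em(Y, base_spec, init, tol=tol, max_iter=max_iter)


def _jitter_class(cls: LatentClass, shift: np.ndarray, rng, spec: ModelSpec, meas_scale=0.0):
    growth = GrowthParams(cls.growth.kappa + shift, cls.growth.phi.copy(), cls.growth.psi.copy())
    lam, nu = cls.meas.lam.copy(), cls.meas.nu.copy()
    if spec.family == "sogmm" and meas_scale > 0:
        lam[1:] += rng.normal(0.0, meas_scale, N_ITEMS - 1)
        nu[1:] += rng.normal(0.0, meas_scale, N_ITEMS - 1)
    return LatentClass(1.0, growth, MeasurementParams(lam, nu, cls.meas.theta.copy()))


def initialize_starts(
    data, spec: ModelSpec, n_starts: int, seed: int
) -> list[MixturePopulation]:
    """Multi-start strategy: start 1 splits the single-class ML solution by
    shifting the growth means by deterministic +/- one-SD offsets; the remaining
    starts add random growth-mean (and, for the SOGMM, measurement) jitter.
    Deterministic under ``seed``."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    Y = _extract(data, spec)
    base_pop, *_ = fit_single_class(Y, spec)
    base = base_pop.classes[0]
    C = spec.n_classes
    if C == 1:
        return [base_pop] * n_starts

    sd = np.sqrt(np.maximum(np.diag(base.growth.phi), 1e-3))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), C]))
    starts = []
    # deterministic symmetric split
    offsets = np.linspace(-1.0, 1.0, C)
    classes = [_jitter_class(base, off * sd, rng, spec) for off in offsets]
    for cls in classes:
        cls.pi = 1.0 / C
    starts.append(MixturePopulation(classes))
    # random starts cycle through jitter scales so both nearby splits and
    # distant basins are reachable; mixing weights start equal (perturbing
    # them seeds degenerate tiny-class optima that the emulated procedure
    # does not produce)
    scales = (0.5, 1.0, 2.0)
    for s in range(n_starts - 1):
        scale = scales[s % len(scales)]
        classes = [
            _jitter_class(base, rng.normal(0.0, scale, 2) * sd, rng, spec, meas_scale=0.1)
            for _ in range(C)
        ]
        for cls in classes:
            cls.pi = 1.0 / C
        starts.append(MixturePopulation(classes))
    return starts


def fit_mixture(
    data,
    spec: ModelSpec,
    n_starts: int | None = None,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    gap_tol: float = DEFAULT_GAP_TOL,
) -> FitResult:
    """Fit by EM from multiple starts; returns the best start by final
    log-likelihood (ties broken toward the lower start index). With four or
    more starts the search is two-stage: every start runs a short burn-in,
    then only the top quarter (at least two) run to full convergence. If no
    start converges, the best non-converged solution is returned flagged,
    never an exception."""
    Y = _extract(data, spec)
    if n_starts is None:
        n_starts = DEFAULT_STARTS[spec.family]
    starts = [_pop_to_params(s) for s in initialize_starts(Y, spec, n_starts, seed)]

    if spec.n_classes > 1 and n_starts >= 4:
        burn = []
        for idx, params in enumerate(starts):
            params, ll, _, _, resp = _run_em_params(
                Y, spec, params, tol=tol, max_iter=100, gap_tol=gap_tol
            )
            if resp is not None:
                burn.append((ll, idx, params))
        burn.sort(key=lambda t: (-t[0], t[1]))
        keep = max(2, n_starts // 4)
        starts = [(idx, params) for _, idx, params in burn[:keep]]
    else:
        starts = list(enumerate(starts))

    best = None

    def better(cand, cur):
        """Prefer converged runs; among equals, higher loglik; ties (<1e-8)
        keep the earlier start index."""
        if cur is None:
            return True
        if cand[0] != cur[0]:
            return cand[0]
        return cand[1] > cur[1] + 1e-8

    for idx, params in starts:
        params, ll, path, conv, resp = _run_em_params(
            Y, spec, params, tol=tol, max_iter=max_iter, gap_tol=gap_tol
        )
        if resp is None:
            continue
        cand = (conv, ll, idx, params, path, resp)
        if better(cand, best):
            best = cand
        if spec.n_classes == 1:
            break  # single-class likelihood is unimodal under this structure
    if best is None:
        pop = _params_to_pop(starts[0][1])
        return FitResult(
            spec, pop, -np.inf, count_free_parameters(spec),
            np.full((Y.shape[0], spec.n_classes), np.nan), np.full(spec.n_classes, np.nan),
            converged=False, n_starts_used=n_starts, best_start_seed=seed,
        )
    conv, ll, _idx, params, path, resp = best
    return FitResult(
        spec=spec,
        estimates=_params_to_pop(params),
        loglik=ll,
        counts=count_free_parameters(spec),
        responsibilities=resp,
        class_proportions=resp.mean(axis=0),
        converged=conv,
        n_starts_used=n_starts,
        best_start_seed=int(seed),
        loglik_path=path,
    )
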