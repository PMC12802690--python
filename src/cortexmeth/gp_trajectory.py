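"""Gaussian-process trajectory classification of methylation sites.

Each site's (mean-centred) methylation is modelled against developmental age
in pcw under three nested zero-mean GP models, all sharing a bias and an
i.i.d. noise term:

    constant   K = s_b^2 J + s_n^2 I
    linear     K = s_b^2 J + s_v^2 x x' + s_n^2 I
    nonlinear  K = s_b^2 J + s_f^2 Matern52(|x - x'| / l) + s_n^2 I

with Matern52(r; l) = (1 + sqrt(5) r / l + 5 r^2 / (3 l^2)) exp(-sqrt(5) r / l).
Hyperparameters maximise the exact log marginal likelihood

    L = -1/2 y' K^-1 y - 1/2 log|K| - n/2 log 2 pi

via multi-restart L-BFGS on log-hyperparameters with analytic gradients.
A site's class is the kernel with the greatest optimised L (ties broken
toward the simpler model).  Nonlinear calls are refined by requiring a log
likelihood ratio of at least 2 against *both* simpler models and a
timescale (lengthscale, pcw) of at least 10; the period of one full
oscillation is 2 pi sqrt(3/5) times the timescale, i.e. a timescale of 1
oscillates about every 5 pcw.

Ages are used in raw pcw units (no x standardisation) so the fitted
lengthscale is directly the timescale that the period conversion assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

SQRT5 = np.sqrt(5.0)
PERIOD_FACTOR = 2.0 * np.pi * np.sqrt(3.0 / 5.0)

VAR_BOUNDS = (1e-8, 10.0)  # proportion^2 scale
# the linear-slope variance multiplies x x' (entries ~ age^2, up to ~500), so
# its floor must sit ~3 orders lower to make the constant model recoverable
SLOPE_VAR_BOUNDS = (1e-12, 10.0)  # proportion^2 / pcw^2
ELL_BOUNDS = (0.5, 200.0)  # pcw
JITTERS = (0.0, 1e-10, 1e-8, 1e-6)
TIE_TOL = 1e-6

KERNEL_KINDS = ("constant", "linear", "matern52")
_PARAM_NAMES = {
    "constant": ("sigma_b2", "sigma_n2"),
    "linear": ("sigma_b2", "sigma_v2", "sigma_n2"),
    "matern52": ("sigma_b2", "sigma_f2", "ell", "sigma_n2"),
}


@dataclass
class KernelSpec:
    kind: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        for name in _PARAM_NAMES[self.kind]:
            if name not in self.params or self.params[name] <= 0:
                raise ValueError(f"{self.kind} kernel needs positive {name!r}")

    def theta(self) -> np.ndarray:
        return np.log([self.params[n] for n in _PARAM_NAMES[self.kind]])

    @classmethod
    def from_theta(cls, kind: str, theta: np.ndarray) -> "KernelSpec":
        return cls(kind, dict(zip(_PARAM_NAMES[kind], np.exp(theta))))


@dataclass
class GPFit:
    kernel: KernelSpec
    log_marginal_likelihood: float
    n_used: int
    converged: bool
    restarts_used: int


@dataclass
class GPClassification:
    site_id: str
    L_const: float
    L_lin: float
    L_nl: float
    klass: str
    llr_vs_const: float
    llr_vs_lin: float
    timescale: float
    period: float
    high_confidence: bool = field(default=False)


# ---------------------------------------------------------------------------
# Kernel matrices and marginal likelihood
# ---------------------------------------------------------------------------

def _kernel_parts(kind: str, x: np.ndarray, values: np.ndarray):
    """Kernel matrix and its derivatives w.r.t. each log-hyperparameter."""
    n = x.size
    J = np.ones((n, n))
    eye = np.eye(n)
    if kind == "constant":
        s_b2, s_n2 = values
        K = s_b2 * J + s_n2 * eye
        return K, (s_b2 * J, s_n2 * eye)
    if kind == "linear":
        s_b2, s_v2, s_n2 = values
        XX = np.outer(x, x)
        K = s_b2 * J + s_v2 * XX + s_n2 * eye
        return K, (s_b2 * J, s_v2 * XX, s_n2 * eye)
    s_b2, s_f2, ell, s_n2 = values
    r = np.abs(x[:, None] - x[None, :])
    u = SQRT5 * r / ell
    e = np.exp(-u)
    m52 = s_f2 * (1.0 + u + u**2 / 3.0) * e
    dK_dlogell = s_f2 * (u**2 / 3.0) * (1.0 + u) * e
    K = s_b2 * J + m52 + s_n2 * eye
    return K, (s_b2 * J, m52, dK_dlogell, s_n2 * eye)


def kernel_matrix(x: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Full covariance (signal + bias + noise) of the model at ``x``."""
    values = [kernel.params[n] for n in _PARAM_NAMES[kernel.kind]]
    K, _ = _kernel_parts(kernel.kind, np.asarray(x, float), values)
    return K


def _chol_with_jitter(K: np.ndarray):
    for jit in JITTERS:
        try:
            return np.linalg.cholesky(K + jit * np.eye(K.shape[0])), jit
        except np.linalg.LinAlgError:
            continue
    return None, None


def gp_marginal_loglik(x: np.ndarray, y: np.ndarray, kernel: KernelSpec) -> float:
    """Exact log marginal likelihood of centred ``y`` under ``kernel``.

    Computed via Cholesky with a jitter ladder (1e-10 .. 1e-6); returns -inf
    if the covariance is not positive definite after the maximum jitter.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    K = kernel_matrix(x, kernel)
    L, _ = _chol_with_jitter(K)
    if L is None:
        return -np.inf
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
    n = y.size
    return float(-0.5 * y @ alpha - np.log(np.diag(L)).sum() - 0.5 * n * np.log(2 * np.pi))


def _neg_loglik_and_grad(theta: np.ndarray, kind: str, x: np.ndarray, y: np.ndarray):
    K, dKs = _kernel_parts(kind, x, np.exp(theta))
    L, _ = _chol_with_jitter(K)
    if L is None:
        return 1e12, np.zeros_like(theta)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
    n = y.size
    nll = 0.5 * y @ alpha + np.log(np.diag(L)).sum() + 0.5 * n * np.log(2 * np.pi)
    Kinv = np.linalg.solve(L.T, np.linalg.solve(L, np.eye(n)))
    A = np.outer(alpha, alpha) - Kinv
    grad = np.array([-0.5 * np.sum(A * dK) for dK in dKs])
    return float(nll), grad


# ---------------------------------------------------------------------------
# Hyperparameter optimisation
# ---------------------------------------------------------------------------

def _param_bounds(name: str) -> tuple[float, float]:
    if name == "ell":
        return ELL_BOUNDS
    if name == "sigma_v2":
        return SLOPE_VAR_BOUNDS
    return VAR_BOUNDS


def _bounds(kind: str) -> list[tuple[float, float]]:
    return [tuple(np.log(_param_bounds(n))) for n in _PARAM_NAMES[kind]]


def _default_init(kind: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    v = max(float(np.var(y)), 1e-6)
    span = max(float(x.max() - x.min()), 1.0)
    init = {"sigma_b2": v, "sigma_v2": v / max(span**2, 1.0), "sigma_f2": v,
            "ell": span / 3.0, "sigma_n2": v / 2.0}
    return np.log(np.array([np.clip(init[n], *_param_bounds(n))
                            for n in _PARAM_NAMES[kind]]))


def fit_gp(
    x: np.ndarray,
    y: np.ndarray,
    kind: str,
    n_restarts: int = 5,
    seed: int | np.random.Generator = 0,
    extra_inits: list[np.ndarray] | None = None,
) -> GPFit:
    """Maximise the marginal likelihood over log-hyperparameters.

    ``n_restarts`` runs of bounded L-BFGS start from a moment-based
    initialisation plus seeded log-uniform draws within the bounds;
    ``extra_inits`` lets a caller warm-start from a simpler model's optimum
    (used to keep nested likelihood ratios non-negative).  The best restart
    wins; if every restart fails, ``converged`` is False and L is -inf.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if y.size < 5:
        raise ValueError("need >= 5 observations")
    y = y - y.mean()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bounds = _bounds(kind)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    inits = [_default_init(kind, x, y)]
    for _ in range(max(n_restarts - 1, 0)):
        inits.append(rng.uniform(lo, hi))
    inits.extend(extra_inits or [])

    best_fun, best_theta = np.inf, None
    used = 0
    for theta0 in inits:
        theta0 = np.clip(theta0, lo, hi)
        res = minimize(
            _neg_loglik_and_grad,
            theta0,
            args=(kind, x, y),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
        used += 1
        # L-BFGS-B can terminate on a worse iterate than its start; keep the
        # start too so warm starts never lose likelihood
        f0, _ = _neg_loglik_and_grad(theta0, kind, x, y)
        for fun, theta in ((float(res.fun), res.x), (float(f0), theta0)):
            if np.isfinite(fun) and fun < best_fun:
                best_fun, best_theta = fun, np.array(theta)
    if best_theta is None:
        return GPFit(KernelSpec.from_theta(kind, inits[0]), -np.inf, y.size, False, used)
    spec = KernelSpec.from_theta(kind, best_theta)
    return GPFit(spec, -best_fun, y.size, True, used)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_site(
    x: np.ndarray,
    y: np.ndarray,
    site_id: str = "",
    n_restarts: int = 5,
    seed: int | np.random.Generator = 0,
    llr_min: float = 2.0,
    timescale_min: float = 10.0,
) -> GPClassification:
    """Fit all three kernels and classify by the optimised marginal likelihood.

    The linear and Matern fits are additionally warm-started from the
    constant optimum (signal variance at its lower bound) so the nested
    likelihood ratios are non-negative up to optimiser tolerance.

    Between constant and linear the class is the argmax (ties, delta L <
    1e-6, go to the simpler model).  The nonlinear class additionally
    requires an LLR of at least ``llr_min`` against *both* simpler models:
    type-II maximum likelihood over the Matern's two extra hyperparameters
    gains O(1) likelihood units on pure-noise sites by construction, so a
    bare argmax would systematically overcall nonlinearity; the margin is
    the same LLR threshold used for high-confidence refinement.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    fit_c = fit_gp(x, y, "constant", n_restarts, rng)
    warm_b = np.log(max(fit_c.kernel.params["sigma_b2"], VAR_BOUNDS[0]))
    warm_n = np.log(max(fit_c.kernel.params["sigma_n2"], VAR_BOUNDS[0]))
    tiny = np.log(VAR_BOUNDS[0])
    span = max(float(x.max() - x.min()), 1.0)
    lin_warm = [np.array([warm_b, np.log(SLOPE_VAR_BOUNDS[0]), warm_n])]
    nl_warm = [
        np.array([warm_b, tiny, np.log(np.clip(span / 3.0, *ELL_BOUNDS)), warm_n]),
        np.array([warm_b, tiny, np.log(ELL_BOUNDS[1]), warm_n]),
    ]
    fit_l = fit_gp(x, y, "linear", n_restarts, rng, extra_inits=lin_warm)
    fit_m = fit_gp(x, y, "matern52", n_restarts, rng, extra_inits=nl_warm)

    L_c, L_l, L_m = (f.log_marginal_likelihood for f in (fit_c, fit_l, fit_m))
    klass = "constant"
    if L_l > L_c + TIE_TOL:
        klass = "linear"
    if L_m - L_c >= llr_min and L_m - L_l >= llr_min:
        klass = "nonlinear"

    ell = fit_m.kernel.params["ell"]
    cls = GPClassification(
        site_id=site_id,
        L_const=L_c,
        L_lin=L_l,
        L_nl=L_m,
        klass=klass,
        llr_vs_const=L_m - L_c,
        llr_vs_lin=L_m - L_l,
        timescale=ell,
        period=timescale_to_period(ell),
    )
    cls.high_confidence = (
        klass == "nonlinear"
        and min(cls.llr_vs_const, cls.llr_vs_lin) >= llr_min
        and ell >= timescale_min
    )
    return cls


def classify_sites(
    beta, ages: np.ndarray, n_restarts: int = 5, seed: int = 0,
    llr_min: float = 2.0, timescale_min: float = 10.0,
) -> pd.DataFrame:
    """Classify every site of a BetaMatrix; returns the classification table."""
    ages = np.asarray(ages, float)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(beta.n_sites)
    rows = []
    for i, sid in enumerate(beta.site_ids):
        cls = classify_site(
            ages, beta.values[i], site_id=sid, n_restarts=n_restarts,
            seed=np.random.default_rng(children[i]),
            llr_min=llr_min, timescale_min=timescale_min,
        )
        rows.append(
            {
                "site_id": sid, "class": cls.klass,
                "L_const": cls.L_const, "L_lin": cls.L_lin, "L_nl": cls.L_nl,
                "llr_const": cls.llr_vs_const, "llr_lin": cls.llr_vs_lin,
                "timescale": cls.timescale, "period": cls.period,
                "high_confidence": cls.high_confidence,
            }
        )
    return pd.DataFrame(rows)


def refine_nonlinear(
    classifications: pd.DataFrame, llr_min: float = 2.0, timescale_min: float = 10.0
) -> pd.DataFrame:
    """High-confidence nonlinear sites: class nonlinear, both LLRs >= ``llr_min``
    and timescale >= ``timescale_min`` (inclusive bounds)."""
    keep = (
        (classifications["class"] == "nonlinear")
        & (classifications[["llr_const", "llr_lin"]].min(axis=1) >= llr_min)
        & (classifications["timescale"] >= timescale_min)
    )
    return classifications[keep].reset_index(drop=True)


def timescale_to_period(ell: float) -> float:
    """Period (pcw) of one complete oscillation for a Matern 5/2 timescale.

    period = 2 pi sqrt(3/5) * ell, so a timescale of 1 oscillates roughly
    every 5 pcw.
    """
    return PERIOD_FACTOR * ell
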