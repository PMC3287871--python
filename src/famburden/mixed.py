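"""Linear mixed-model association tests for collapsed rare-variant burdens.

The model is ``Y = X b + Q v + Z u + e`` with Y the quantitative trait, X the
binary collapsed-gene indicator, Q optional principal-component covariates,
u a polygenic random effect with ``Var(u) = sigma2_g * K`` for a relatedness
matrix K (the additive relationship matrix 2*phi, or a marker IBS matrix; Z
is the identity) and e i.i.d. residual noise.  Six configurations are
supported:

========  ==================================  =====================
method    fixed effects                        random-effect K
========  ==================================  =====================
REG       intercept, X                         none (OLS)
PC        intercept, X, top PCs                none (OLS)
KIN       intercept, X                         2*phi from pedigree
PC-KIN    intercept, X, top PCs                2*phi from pedigree
IBS       intercept, X                         marker IBS
PC-IBS    intercept, X, top PCs                marker IBS
========  ==================================  =====================

Variance components are estimated by REML, profiled to the single variance
ratio ``delta = sigma2_e / sigma2_g`` through one spectral decomposition of
K (shared across genes and replicates), with a log10(delta) grid search
followed by bounded Brent refinement.  The burden effect is then tested with
a GLS Wald t-statistic on ``n - p`` degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .collapse import CollapsedDesign
from .genotype import CovariateMatrix
from .pedigree import RelatednessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "ModelSpec",
    "VarianceComponents",
    "AssociationResult",
    "KinshipEigen",
    "spectral_decomposition",
    "build_fixed_design",
    "reml_fit",
    "gls_wald_test",
    "ols_test",
    "run_method",
    "run_all",
    "results_to_frame",
]

METHODS = ("REG", "PC", "KIN", "PC-KIN", "IBS", "PC-IBS")

_METHOD_COV = {
    "REG": "none",
    "PC": "none",
    "KIN": "relationship_2phi",
    "PC-KIN": "relationship_2phi",
    "IBS": "ibs",
    "PC-IBS": "ibs",
}

DELTA_LOG10_BOUNDS = (-10.0, 10.0)
DELTA_GRID_POINTS = 101
PSD_TOL = 1e-8
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """One of the six model configurations."""

    method: str
    n_pcs: int = -1  # -1 -> default for the method (10 for PC-*, 0 otherwise)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.n_pcs == -1:
            object.__setattr__(self, "n_pcs", 10 if self.uses_pcs else 0)
        if self.uses_pcs and self.n_pcs <= 0:
            raise ValueError(f"{self.method} requires n_pcs > 0")
        if not self.uses_pcs and self.n_pcs != 0:
            raise ValueError(f"{self.method} does not take principal components")

    @property
    def uses_pcs(self) -> bool:
        return self.method in ("PC", "PC-KIN", "PC-IBS")

    @property
    def covariance_kind(self) -> str:
        return _METHOD_COV[self.method]

    @property
    def is_mixed(self) -> bool:
        return self.covariance_kind != "none"


@dataclass
class VarianceComponents:
    """REML estimates of the polygenic and residual variances."""

    sigma2_g: float
    sigma2_e: float
    delta: float  # sigma2_e / sigma2_g
    reml_loglik: float
    boundary: bool = False  # optimum at an end of the delta search interval


@dataclass
class AssociationResult:
    gene: str
    method: str
    beta: float = float("nan")
    se: float = float("nan")
    statistic: float = float("nan")
    df: float = float("nan")
    p_value: float = float("nan")
    carrier_count: int = 0
    status: str = "ok"  # ok | untestable | fit_failure
    sigma2_g: float = float("nan")
    sigma2_e: float = float("nan")


@dataclass
class KinshipEigen:
    """Cached spectral decomposition of a relatedness matrix.

    Eigenvalues below zero but above ``-PSD_TOL`` are clipped to zero; a
    smaller eigenvalue raises, since the matrix is then not a covariance.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    kind: str
    subject_order: list[str] = field(default_factory=list)


def spectral_decomposition(k: RelatednessMatrix) -> KinshipEigen:
    vals, vecs = np.linalg.eigh(k.values)
    if vals[0] < -PSD_TOL * max(1.0, float(vals[-1])):
        raise ValueError(
            f"relatedness matrix ({k.kind}) is not positive semidefinite: "
            f"smallest eigenvalue {vals[0]:.3e}"
        )
    vals = np.clip(vals, 0.0, None)
    return KinshipEigen(vals, vecs, k.kind, list(k.subject_order))


def build_fixed_design(
    x: CollapsedDesign, q: CovariateMatrix | None = None
) -> tuple[np.ndarray, str]:
    """Fixed-effect design [intercept, X, Q columns] with a rank check.

    Returns ``(F, status)`` where status is ``"ok"`` or ``"untestable"``
    (constant indicator, or X collinear with the other columns).  Rank
    deficiency among the Q columns drops the offending columns with a
    warning; the tested column X is always column 1.
    """
    n = len(x.indicator)
    cols = [np.ones(n), x.indicator.astype(float)]
    if q is not None:
        if q.subject_order != x.subject_order:
            raise ValueError("covariate subject order does not match design")
        for j in range(q.n_components):
            cols.append(q.values[:, j])
    F = np.column_stack(cols)
    if not x.testable:
        return F, "untestable"
    # drop Q columns that are collinear with what precedes them
    if F.shape[1] > 2:
        keep = [0, 1]
        for j in range(2, F.shape[1]):
            trial = F[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                logger.warning("dropping rank-deficient covariate column %d", j - 1)
        F = F[:, keep]
    if np.linalg.matrix_rank(F) < F.shape[1]:
        return F, "untestable"
    # X collinear with intercept+Q once other columns are in?
    rest = np.delete(F, 1, axis=1)
    if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(F):
        return F, "untestable"
    return F, "ok"


def _profile_loglik_grid(
    lam: np.ndarray, Fstar: np.ndarray, ystar: np.ndarray, deltas: np.ndarray
) -> np.ndarray:
    """Profiled restricted log-likelihood at each delta (vectorised).

    For H = K + delta*I with K = U diag(lam) U', the REML log-likelihood
    profiled over sigma2_g is
    ``-0.5 * [(n-p)(log 2pi + 1 + log(R/(n-p))) + log|H| + log|F'H^-1 F|]``
    with R the weighted residual sum of squares of the GLS fit.
    """
    n, p = Fstar.shape
    M = np.concatenate([Fstar, ystar[:, None]], axis=1)
    W = 1.0 / (lam[None, :] + deltas[:, None])  # (d, n)
    G = np.einsum("dn,ni,nj->dij", W, M, M)
    A = G[:, :p, :p]
    b = G[:, :p, p]
    yy = G[:, p, p]
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    R = np.maximum(yy - np.einsum("di,di->d", b, beta), 1e-300)
    sign, logdetA = np.linalg.slogdet(A)
    logdetH = np.log(lam[None, :] + deltas[:, None]).sum(axis=1)
    nmp = n - p
    return -0.5 * (nmp * (_LOG_2PI + 1.0 + np.log(R / nmp)) + logdetH + logdetA)


def reml_fit(
    y: np.ndarray,
    fixed: np.ndarray,
    k: RelatednessMatrix | None = None,
    eig: KinshipEigen | None = None,
) -> VarianceComponents:
    """REML variance components for Var(y) = sigma2_g*K + sigma2_e*I.

    Either ``k`` or its precomputed spectral decomposition ``eig`` must be
    given.  The restricted likelihood is profiled to the ratio
    ``delta = sigma2_e / sigma2_g``; the optimum is located on a log10(delta)
    grid over [-10, 10] (0.2 spacing) and refined by bounded Brent search in
    each bracket around a grid local maximum.  A solution at a grid end is
    returned with ``boundary=True``.
    """
    if eig is None:
        if k is None:
            raise ValueError("either k or eig must be provided")
        eig = spectral_decomposition(k)
    y = np.asarray(y, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    n, p = fixed.shape
    if n <= p:
        raise ValueError(f"n={n} must exceed the {p} fixed-effect columns")
    U = eig.eigenvectors
    lam = eig.eigenvalues
    ystar = U.T @ y
    Fstar = U.T @ fixed

    lo, hi = DELTA_LOG10_BOUNDS
    grid = np.linspace(lo, hi, DELTA_GRID_POINTS)
    ll = _profile_loglik_grid(lam, Fstar, ystar, 10.0**grid)

    def neg_ll(log10d: float) -> float:
        return -float(
            _profile_loglik_grid(lam, Fstar, ystar, np.array([10.0**log10d]))[0]
        )

    # candidates: every grid local maximum (ends included), Brent-refined
    best_logd = grid[int(np.argmax(ll))]
    best_ll = float(np.max(ll))
    is_locmax = np.r_[ll[0] >= ll[1], (ll[1:-1] >= ll[:-2]) & (ll[1:-1] >= ll[2:]),
                      ll[-1] >= ll[-2]]
    for i in np.flatnonzero(is_locmax):
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        if a == b:
            continue
        res = minimize_scalar(
            neg_ll, bounds=(a, b), method="bounded",
            options={"xatol": 1e-6},
        )
        if -res.fun > best_ll:
            best_ll = float(-res.fun)
            best_logd = float(res.x)

    delta = 10.0**best_logd
    # back out the variance components at the optimum
    w = 1.0 / (lam + delta)
    A = (Fstar * w[:, None]).T @ Fstar
    bvec = (Fstar * w[:, None]).T @ ystar
    beta = np.linalg.solve(A, bvec)
    R = float(ystar @ (w * ystar) - bvec @ beta)
    sigma2_g = max(R / (n - p), 0.0)
    sigma2_e = delta * sigma2_g
    boundary = bool(best_logd <= lo + 1e-9 or best_logd >= hi - 1e-9)
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        delta=delta,
        reml_loglik=best_ll,
        boundary=boundary,
    )


def gls_wald_test(
    y: np.ndarray,
    fixed: np.ndarray,
    vc: VarianceComponents,
    k: RelatednessMatrix | None = None,
    test_column: int = 1,
    eig: KinshipEigen | None = None,
    gene: str = "",
    method: str = "",
    carrier_count: int = 0,
) -> AssociationResult:
    """GLS Wald t-test of one fixed-effect column under V = s2g*K + s2e*I.

    ``beta_hat = (F'V^-1 F)^-1 F'V^-1 y``; the statistic ``beta/se`` is
    referred to a t distribution on ``n - p`` degrees of freedom.
    """
    if eig is None:
        if k is None:
            raise ValueError("either k or eig must be provided")
        eig = spectral_decomposition(k)
    y = np.asarray(y, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    n, p = fixed.shape
    ystar = eig.eigenvectors.T @ y
    Fstar = eig.eigenvectors.T @ fixed
    w = 1.0 / (eig.eigenvalues + vc.delta)  # V = sigma2_g * (K + delta I)
    A = (Fstar * w[:, None]).T @ Fstar
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return AssociationResult(
            gene=gene, method=method, carrier_count=carrier_count,
            status="fit_failure", sigma2_g=vc.sigma2_g, sigma2_e=vc.sigma2_e,
        )
    beta = Ainv @ ((Fstar * w[:, None]).T @ ystar)
    # Var(beta_hat) = sigma2_g * A^-1
    se = float(np.sqrt(vc.sigma2_g * Ainv[test_column, test_column]))
    if not np.isfinite(se) or se == 0.0:
        return AssociationResult(
            gene=gene, method=method, carrier_count=carrier_count,
            status="fit_failure", sigma2_g=vc.sigma2_g, sigma2_e=vc.sigma2_e,
        )
    df = float(n - p)
    tstat = float(beta[test_column]) / se
    pval = float(2.0 * stats.t.sf(abs(tstat), df))
    return AssociationResult(
        gene=gene, method=method, beta=float(beta[test_column]), se=se,
        statistic=tstat, df=df, p_value=max(pval, np.finfo(float).tiny),
        carrier_count=carrier_count, status="ok",
        sigma2_g=vc.sigma2_g, sigma2_e=vc.sigma2_e,
    )


def ols_test(
    y: np.ndarray,
    fixed: np.ndarray,
    test_column: int = 1,
    gene: str = "",
    method: str = "",
    carrier_count: int = 0,
) -> AssociationResult:
    """Ordinary least-squares t-test of one fixed-effect column."""
    y = np.asarray(y, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    n, p = fixed.shape
    A = fixed.T @ fixed
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return AssociationResult(
            gene=gene, method=method, carrier_count=carrier_count,
            status="fit_failure",
        )
    beta = Ainv @ (fixed.T @ y)
    resid = y - fixed @ beta
    df = float(n - p)
    s2 = float(resid @ resid) / df
    se = float(np.sqrt(s2 * Ainv[test_column, test_column]))
    if not np.isfinite(se) or se == 0.0:
        return AssociationResult(
            gene=gene, method=method, carrier_count=carrier_count,
            status="fit_failure",
        )
    tstat = float(beta[test_column]) / se
    pval = float(2.0 * stats.t.sf(abs(tstat), df))
    return AssociationResult(
        gene=gene, method=method, beta=float(beta[test_column]), se=se,
        statistic=tstat, df=df, p_value=max(pval, np.finfo(float).tiny),
        carrier_count=carrier_count, status="ok",
        sigma2_g=0.0, sigma2_e=s2,
    )


def run_method(
    spec: ModelSpec,
    x: CollapsedDesign,
    y: np.ndarray,
    q: CovariateMatrix | None,
    relmats: dict[str, RelatednessMatrix],
    eigen_cache: dict[str, KinshipEigen] | None = None,
) -> AssociationResult:
    """Fit one model configuration for one gene and test the burden effect.

    ``relmats`` maps covariance kinds (``relationship_2phi``, ``ibs``) to
    matrices; ``eigen_cache`` optionally holds their spectral decompositions
    (it is filled on demand so repeated calls share the eigendecomposition).
    """
    if spec.uses_pcs:
        if q is None:
            raise ValueError(f"method {spec.method} requires principal components")
        if q.n_components < spec.n_pcs:
            raise ValueError(
                f"method {spec.method} needs {spec.n_pcs} PCs, "
                f"covariates provide {q.n_components}"
            )
        q_used: CovariateMatrix | None = CovariateMatrix(
            q.values[:, : spec.n_pcs], q.subject_order,
            q.eigenvalues[: spec.n_pcs], q.variance_captured,
        )
    else:
        q_used = None

    eig = None
    if spec.is_mixed:
        kind = spec.covariance_kind
        if kind not in relmats:
            raise ValueError(
                f"method {spec.method} requires a {kind!r} relatedness matrix"
            )
        if relmats[kind].subject_order != x.subject_order:
            raise ValueError("relatedness matrix subject order does not match design")
        if eigen_cache is not None and kind in eigen_cache:
            eig = eigen_cache[kind]
        else:
            eig = spectral_decomposition(relmats[kind])
            if eigen_cache is not None:
                eigen_cache[kind] = eig

    F, status = build_fixed_design(x, q_used)
    if status != "ok":
        return AssociationResult(
            gene=x.gene, method=spec.method,
            carrier_count=x.carrier_count, status="untestable",
        )
    if not spec.is_mixed:
        return ols_test(
            y, F, test_column=1, gene=x.gene, method=spec.method,
            carrier_count=x.carrier_count,
        )
    try:
        vc = reml_fit(y, F, eig=eig)
    except np.linalg.LinAlgError:
        return AssociationResult(
            gene=x.gene, method=spec.method,
            carrier_count=x.carrier_count, status="fit_failure",
        )
    return gls_wald_test(
        y, F, vc, eig=eig, test_column=1, gene=x.gene, method=spec.method,
        carrier_count=x.carrier_count,
    )


def run_all(
    specs: list[ModelSpec],
    designs: list[CollapsedDesign],
    y: np.ndarray,
    q: CovariateMatrix | None = None,
    relmats: dict[str, RelatednessMatrix] | None = None,
    eigen_cache: dict[str, KinshipEigen] | None = None,
) -> list[AssociationResult]:
    """Scan every gene under every model configuration.

    Individual gene failures are recorded in the result status and never
    abort the scan; spectral decompositions are shared across genes through
    ``eigen_cache`` (created here if not supplied).
    """
    relmats = relmats or {}
    if eigen_cache is None:
        eigen_cache = {}
    results: list[AssociationResult] = []
    for gi, x in enumerate(designs):
        if gi and gi % 50 == 0:
            logger.info("run_all: %d/%d genes done", gi, len(designs))
        for spec in specs:
            try:
                res = run_method(spec, x, y, q, relmats, eigen_cache)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("gene %s method %s failed: %s", x.gene, spec.method, exc)
                res = AssociationResult(
                    gene=x.gene, method=spec.method,
                    carrier_count=x.carrier_count, status="fit_failure",
                )
            results.append(res)
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Association results as a tidy DataFrame (one row per gene x method)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "method": [r.method for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "carrier_count": [r.carrier_count for r in results],
            "status": [r.status for r in results],
            "sigma2_g": [r.sigma2_g for r in results],
            "sigma2_e": [r.sigma2_e for r in results],
        }
    )
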