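"""Restricted maximum likelihood for genomic variance components (GREML).

The model is y = X beta + sum_i g_i + e with g_i ~ N(0, sigma_i^2 A_i) for
each relationship matrix A_i and e ~ N(0, sigma_e^2 I).  The restricted
log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    V = sum_i sigma_i^2 A_i + sigma_e^2 I,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

is maximized with one EM step from the starting values followed by
average-information (AI) Newton steps, the GCTA scheme.  Components driven
negative under the constrained fit are held at a small positive floor.

Two fitting paths share the same iteration engine:

* a dense path for arbitrary component lists (V factored at O(n^3) per
  iteration), and
* a rotated low-rank path for the two-component regional model, where the
  genome-wide GRM is eigendecomposed once and the regional component has
  rank at most the window size, so each iteration is O(n m_w).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg as sla
from scipy.stats import chi2

from .genotype_io import MISSING, GenotypeMatrix
from .grm import RelatednessMatrix


class REMLError(RuntimeError):
    pass


@dataclasses.dataclass
class VarianceComponentModel:
    """Phenotype, fixed-effect design, and 1-2 relationship matrices.

    Sample order must be identical across y, X and every GRM.
    """

    y: np.ndarray
    X: np.ndarray
    grms: list[RelatednessMatrix]
    component_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y length")
        for a in self.grms:
            if a.n != n:
                raise ValueError("GRM dimension must match y length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise REMLError("fixed-effect design X is rank deficient")
        if self.component_names is None:
            self.component_names = [f"grm{i + 1}" for i in range(len(self.grms))]


@dataclasses.dataclass
class REMLResult:
    sigma2: np.ndarray            # genetic components in model order, residual last
    sigma2_cov: np.ndarray        # inverse average information
    pve: np.ndarray               # per genetic component
    pve_se: np.ndarray
    loglik_reml: float
    n_iter: int
    converged: bool
    component_names: list[str]
    wald_p: np.ndarray            # one-sided normal p per genetic component
    lrt_p: float | None = None    # filled by fit_with_lrt
    n: int = 0

    def summary_rows(self):
        rows = []
        for i, name in enumerate(self.component_names):
            rows.append({
                "component": name,
                "sigma2": self.sigma2[i],
                "se": float(np.sqrt(max(self.sigma2_cov[i, i], 0.0))),
                "pve": self.pve[i],
                "pve_se": self.pve_se[i],
                "logL": self.loglik_reml,
                "lrt_p": self.lrt_p,
                "n": self.n,
            })
        rows.append({
            "component": "residual",
            "sigma2": self.sigma2[-1],
            "se": float(np.sqrt(max(self.sigma2_cov[-1, -1], 0.0))),
            "pve": np.nan, "pve_se": np.nan,
            "logL": self.loglik_reml, "lrt_p": None, "n": self.n,
        })
        return rows


# ---------------------------------------------------------------------------
# iteration engine, shared by the dense and low-rank paths


def _ai_reml(ops, theta0, n, var_y, constrain, tol, max_iter):
    """Maximize l_R via one EM step then AI-Newton steps with step-halving."""
    floor = 1e-6 * var_y
    theta = np.maximum(np.asarray(theta0, dtype=float), floor)
    ll, score, ai, ypapy, trpa = ops(theta)
    n_iter = 0
    converged = False
    for it in range(1, max_iter + 1):
        n_iter = it
        if it == 1:
            # EM update: stable from arbitrary starts
            theta_new = theta + theta**2 / n * (ypapy - trpa)
            if constrain:
                theta_new = np.maximum(theta_new, floor)
        else:
            free = np.ones(theta.size, dtype=bool)
            if constrain:
                free = ~((theta <= floor * (1 + 1e-9)) & (score < 0))
                if not free.any():
                    converged = True
                    break
            delta = np.zeros_like(theta)
            try:
                delta[free] = np.linalg.solve(ai[np.ix_(free, free)], score[free])
            except np.linalg.LinAlgError as exc:
                raise REMLError(
                    "average-information matrix is singular "
                    "(components aliased?)"
                ) from exc
            theta_new = theta + delta
            if constrain:
                theta_new = np.maximum(theta_new, floor)
        # step halving towards the current point until the likelihood
        # improves (keeps accepted iterations monotone after the EM step)
        for _ in range(30):
            try:
                out = ops(theta_new)
            except np.linalg.LinAlgError:
                out = None
            if out is not None and out[0] >= ll - 1e-10:
                break
            theta_new = (theta + theta_new) / 2.0
            if constrain:
                theta_new = np.maximum(theta_new, floor)
        else:
            out = ops(theta_new)
        ll_new, score, ai, ypapy, trpa = out
        delta_ll = abs(ll_new - ll)
        theta, ll = theta_new, ll_new
        if it >= 2 and delta_ll < tol * max(1.0, abs(ll_new)):
            converged = True
            break
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
    return theta, ll, cov, n_iter, converged


# ---------------------------------------------------------------------------
# dense path


def _dense_ops(y, X, mats):
    """Return ops(theta) evaluating l_R and its AI quantities at O(n^3)."""
    n = y.shape[0]

    def ops(theta):
        V = theta[-1] * np.eye(n)
        for t, A in zip(theta[:-1], mats):
            V += t * A
        cf = sla.cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vinv = sla.cho_solve(cf, np.eye(n), check_finite=False)
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        cf_x = sla.cho_factor(XtVinvX, lower=True, check_finite=False)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cf_x[0])))
        P = Vinv - VinvX @ sla.cho_solve(cf_x, VinvX.T, check_finite=False)
        Py = P @ y
        yPy = float(y @ Py)
        ll = -0.5 * (logdet_v + logdet_x + yPy)

        k = len(mats) + 1
        U = np.empty((n, k))
        trpa = np.empty(k)
        for i, A in enumerate(mats):
            U[:, i] = A @ Py
            trpa[i] = float(np.sum(P * A))
        U[:, -1] = Py
        trpa[-1] = float(np.trace(P))
        ypapy = Py @ U
        PU = P @ U
        ai = 0.5 * (U.T @ PU)
        score = -0.5 * (trpa - ypapy)
        return ll, score, ai, ypapy, trpa

    return ops


def fit_reml(
    model: VarianceComponentModel,
    constrain: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> REMLResult:
    """AI-REML fit of the variance-component model.

    Starting values put var(y)/(k+1) on every component.  With ``constrain``
    (the default) components are kept at or above a floor of 1e-6 var(y);
    unconstrained mode is available for boundary diagnostics.
    """
    y, X = model.y, model.X
    n, c = y.shape[0], X.shape[1]
    k = len(model.grms)
    if n <= c + k:
        raise REMLError("more parameters than samples")
    mats = [a.values for a in model.grms]
    for name, A in zip(model.component_names, mats):
        if np.allclose(A, np.eye(n), atol=1e-10):
            raise REMLError(
                f"component {name!r} is the identity matrix: "
                "indistinguishable from the residual (singular model)"
            )
    var_y = float(np.var(y))
    if var_y <= 0:
        raise REMLError("phenotype has zero variance")
    theta0 = np.full(k + 1, var_y / (k + 1))
    try:
        theta, ll, cov, n_iter, converged = _ai_reml(
            _dense_ops(y, X, mats), theta0, n, var_y, constrain, tol, max_iter
        )
    except np.linalg.LinAlgError as exc:
        raise REMLError("V is numerically singular") from exc
    return _package_result(theta, ll, cov, n_iter, converged,
                           model.component_names, n)


def _package_result(theta, ll, cov, n_iter, converged, names, n):
    k = theta.size - 1
    pve = np.empty(k)
    pve_se = np.empty(k)
    wald = np.empty(k)
    for i in range(k):
        pve[i], pve_se[i] = _pve_delta(theta, cov, i)
        se_i = np.sqrt(max(cov[i, i], 0.0))
        z = theta[i] / se_i if se_i > 0 else np.inf
        wald[i] = float(chi2.sf(z * z, 1) / 2.0)
    return REMLResult(
        sigma2=theta, sigma2_cov=cov, pve=pve, pve_se=pve_se,
        loglik_reml=ll, n_iter=n_iter, converged=converged,
        component_names=list(names), wald_p=wald, n=n,
    )


def _pve_delta(sigma2, cov, component):
    total = float(sigma2.sum())
    if total <= 0:
        raise REMLError("total variance is zero")
    pve = sigma2[component] / total
    grad = np.full(sigma2.size, -sigma2[component] / total**2)
    grad[component] = (total - sigma2[component]) / total**2
    var = float(grad @ cov @ grad)
    return float(pve), float(np.sqrt(max(var, 0.0)))


def pve_with_se(result: REMLResult, component: int = 0):
    """Proportion of variance explained by one component, with delta-method SE."""
    return _pve_delta(result.sigma2, result.sigma2_cov, component)


def lrt_pvalue(loglik_full: float, loglik_reduced: float) -> float:
    """Boundary likelihood-ratio p: one variance component tested at zero.

    The null distribution is the 1/2:1/2 mixture of a point mass at zero and
    chi-square with 1 df, so p = 0.5 Pr(chi2_1 > LRT) and p = 0.5 at LRT = 0.
    """
    if loglik_full < loglik_reduced - 1e-6:
        raise ValueError("full-model likelihood below reduced-model likelihood")
    stat = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    return float(0.5 * chi2.sf(stat, 1))


def drop_component(model: VarianceComponentModel, index: int = 0) -> VarianceComponentModel:
    grms = [a for i, a in enumerate(model.grms) if i != index]
    names = [nm for i, nm in enumerate(model.component_names) if i != index]
    return VarianceComponentModel(model.y, model.X, grms, names)


def fit_null_variance(y, X, tol: float = 1e-10):
    """Closed-form REML for the no-GRM model (residual variance only)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, c = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - c)
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * ((n - c) * np.log(sigma2) + logdet_xx + (n - c))
    return sigma2, ll


def fit_with_lrt(
    model: VarianceComponentModel,
    tested_component: int = 0,
    constrain: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> REMLResult:
    """Fit the model and attach the mixture-LRT p for one genetic component."""
    full = fit_reml(model, constrain=constrain, tol=tol, max_iter=max_iter)
    if len(model.grms) == 1:
        _, ll_red = fit_null_variance(model.y, model.X)
    else:
        reduced = fit_reml(drop_component(model, tested_component),
                           constrain=constrain, tol=tol, max_iter=max_iter)
        ll_red = reduced.loglik_reml
    # a boundary fit can land a hair below the reduced model numerically
    full.lrt_p = lrt_pvalue(max(full.loglik_reml, ll_red), ll_red)
    return full


def add_snp_covariates(
    model: VarianceComponentModel, g: GenotypeMatrix, snp_ids
) -> VarianceComponentModel:
    """Append SNP dosage columns to the fixed effects (Table-2-style adjustment).

    Missing dosages are mean-imputed for the fixed effect only.
    """
    ids = list(g.sample_ids)
    cols = []
    for sid in snp_ids:
        j = g.snp_index(sid)  # raises KeyError for unknown ids
        col = g.dosages[:, j].astype(float)
        miss = g.dosages[:, j] == MISSING
        if miss.all():
            raise ValueError(f"SNP {sid} has no observed genotypes")
        col[miss] = col[~miss].mean()
        cols.append(col[:, None])
    X_new = np.hstack([model.X] + cols)
    if np.linalg.matrix_rank(X_new) < X_new.shape[1]:
        raise REMLError("added SNP covariates make X rank deficient")
    del ids
    return VarianceComponentModel(model.y, X_new, model.grms,
                                  list(model.component_names))


# ---------------------------------------------------------------------------
# rotated low-rank path for the regional two-component model


class GenomeRotation:
    """Eigenbasis of the genome-wide GRM, shared across window fits.

    Rotating by U' makes the genome component diagonal, and a window
    component Z_w Z_w' keeps rank m_w, so each window's two-component REML
    costs O(n m_w) per iteration instead of O(n^3).
    """

    def __init__(self, genome_grm: RelatednessMatrix):
        evals, evecs = np.linalg.eigh(genome_grm.values)
        self.s = evals
        self.U = evecs
        self.sample_ids = list(genome_grm.sample_ids)

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.U.T @ M


def _lowrank_ops(y_rot, X_rot, s, Z_rot):
    """ops(theta) for V = t_w Z Z' + t_g diag(s) + t_e I in the rotated basis.

    theta order: (window, genome, residual).  Uses the Woodbury identity
    with the m x m capacitance matrix; all traces reduce to O(n m) sums.
    """
    n, m = Z_rot.shape
    c = X_rot.shape[1]
    YX = np.column_stack([y_rot, X_rot])  # solve for y and X together

    def ops(theta):
        t_w, t_g, t_e = theta
        d = t_g * s + t_e
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("non-positive diagonal")
        dinv = 1.0 / d
        logdet_v = float(np.sum(np.log(d)))
        if m:
            W = Z_rot * dinv[:, None]
            G = Z_rot.T @ W
            cap = np.eye(m) + t_w * G
            cf = sla.cho_factor(cap, lower=True, check_finite=False)
            logdet_v += 2.0 * np.sum(np.log(np.diag(cf[0])))
            B = sla.cho_solve(cf, np.eye(m), check_finite=False)
            WB = W @ B

            def vinv(M):
                return dinv[:, None] * M - t_w * (WB @ (W.T @ M))

            diag_vinv = dinv - t_w * np.einsum("ij,ij->i", WB, W)
        else:
            G = np.zeros((0, 0))
            B = G
            WB = np.zeros((n, 0))

            def vinv(M):
                return dinv[:, None] * M

            diag_vinv = dinv

        VinvYX = vinv(YX)
        Vinvy, VinvX = VinvYX[:, 0], VinvYX[:, 1:]
        XtVinvX = X_rot.T @ VinvX
        cf_x = sla.cho_factor(XtVinvX, lower=True, check_finite=False)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cf_x[0])))

        Py = Vinvy - VinvX @ sla.cho_solve(cf_x, VinvX.T @ y_rot, check_finite=False)
        yPy = float(y_rot @ Py)
        ll = -0.5 * (logdet_v + logdet_x + yPy)

        # tr(V^-1 A_i) and the fixed-effect corrections tr((X'VinvX)^-1 X'Vinv A Vinv X)
        tr_v = np.empty(3)
        corr = np.empty(3)
        if m:
            BG = B @ G
            tr_v[0] = float(np.trace(G)) - t_w * float(np.sum(G * BG.T))
            T = Z_rot.T @ VinvX  # m x c
            M0 = T.T @ T
        else:
            tr_v[0] = 0.0
            M0 = np.zeros((c, c))
        tr_v[1] = float(np.sum(s * diag_vinv))
        tr_v[2] = float(np.sum(diag_vinv))
        M1 = (VinvX * s[:, None]).T @ VinvX
        M2 = VinvX.T @ VinvX
        for i, M in enumerate((M0, M1, M2)):
            corr[i] = float(np.trace(sla.cho_solve(cf_x, M, check_finite=False)))
        trpa = tr_v - corr

        U = np.empty((n, 3))
        U[:, 0] = Z_rot @ (Z_rot.T @ Py) if m else 0.0
        U[:, 1] = s * Py
        U[:, 2] = Py
        ypapy = Py @ U
        PU = vinv(U) - VinvX @ sla.cho_solve(cf_x, VinvX.T @ U, check_finite=False)
        ai = 0.5 * (U.T @ PU)
        score = -0.5 * (trpa - ypapy)
        return ll, score, ai, ypapy, trpa

    return ops


def _rotated_residual_variance(y_rot, X_rot) -> float:
    """Variance of y around the fixed effects, computed in the rotated basis.

    An orthogonal rotation preserves norms but not the sample mean, so
    np.var(y_rot) would absorb the (large) mean of the unrotated phenotype;
    the OLS residual variance is rotation-invariant and on the right scale
    for starting values and the constraint floor.
    """
    beta, *_ = np.linalg.lstsq(X_rot, y_rot, rcond=None)
    r = y_rot - X_rot @ beta
    return float(r @ r) / y_rot.shape[0]


def fit_two_component_rotated(
    rot: GenomeRotation,
    y_rot: np.ndarray,
    X_rot: np.ndarray,
    Z_rot: np.ndarray,
    constrain: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    component_names=("regional", "genome"),
) -> REMLResult:
    """Two-component (window + genome) REML in the genome eigenbasis.

    ``Z_rot`` is U' Z_w with Z_w the standardized window dosages scaled by
    1/sqrt(m_w), so Z_w Z_w' is the window GRM.  Component order in the
    result: regional, genome, residual.
    """
    n = y_rot.shape[0]
    var_y = _rotated_residual_variance(y_rot, X_rot)
    theta0 = np.full(3, var_y / 3.0)
    theta, ll, cov, n_iter, converged = _ai_reml(
        _lowrank_ops(y_rot, X_rot, rot.s, Z_rot), theta0, n, var_y,
        constrain, tol, max_iter,
    )
    return _package_result(theta, ll, cov, n_iter, converged,
                           list(component_names), n)


def fit_genome_rotated(
    rot: GenomeRotation,
    y_rot: np.ndarray,
    X_rot: np.ndarray,
    constrain: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> REMLResult:
    """Single genome-component REML in the eigenbasis (diagonal V)."""
    n = y_rot.shape[0]
    var_y = _rotated_residual_variance(y_rot, X_rot)
    theta0 = np.full(2, var_y / 2.0)
    Z_empty = np.zeros((n, 0))

    def ops(theta):
        full = _lowrank_ops(y_rot, X_rot, rot.s, Z_empty)(
            np.array([0.0, theta[0], theta[1]])
        )
        ll, score, ai, ypapy, trpa = full
        return ll, score[1:], ai[1:, 1:], ypapy[1:], trpa[1:]

    theta, ll, cov, n_iter, converged = _ai_reml(
        ops, theta0, n, var_y, constrain, tol, max_iter
    )
    return _package_result(theta, ll, cov, n_iter, converged, ["genome"], n)
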