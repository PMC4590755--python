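"""Per-predictor association tests: OLS and relatedness-aware mixed models.

The mixed model fits the variance structure once under the null
(phenotype ~ covariates with a GRM random effect) and then tests each
predictor by generalized least squares under the fitted covariance — the
usual GWAS economy.  Binary outcomes are analyzed on the 0/1 scale with the
same linear mixed model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg as sla
from scipy.stats import t as t_dist

from .genotype_io import MISSING, GenotypeMatrix
from .grm import RelatednessMatrix
from .reml import VarianceComponentModel, fit_reml


@dataclasses.dataclass
class AssocResult:
    predictor_id: str
    beta: float
    se: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.beta)


def _prepare_predictor(x) -> np.ndarray:
    """Mean-impute missing values (NaN or the int sentinel) in a predictor."""
    x = np.asarray(x, dtype=float).copy()
    miss = ~np.isfinite(x) | (x == float(MISSING))
    if miss.any() and not miss.all():
        x[miss] = x[~miss].mean()
    return x


def linear_assoc(y, x, covariates=None, predictor_id="x") -> AssocResult:
    """OLS of y on the predictor plus covariates; Wald t-test.

    Missing dosages are mean-imputed.  A constant predictor yields an
    undefined (NaN) beta rather than an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = _prepare_predictor(x)
    n = y.shape[0]
    C = (np.ones((n, 1)) if covariates is None
         else np.atleast_2d(np.asarray(covariates, dtype=float)))
    if x.std() == 0:
        return AssocResult(predictor_id, np.nan, np.nan, np.nan, n)
    X = np.column_stack([C, x])
    if n <= X.shape[1]:
        raise ValueError("more parameters than observations")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[-1, -1]))
    tval = beta[-1] / se
    p = float(2.0 * t_dist.sf(abs(tval), dof))
    return AssocResult(predictor_id, float(beta[-1]), se, p, n)


class MixedModelNull:
    """Null variance-structure fit, reusable across predictors."""

    def __init__(self, y, covariates, grm: RelatednessMatrix,
                 constrain: bool = True):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.shape[0]
        self.C = (np.ones((n, 1)) if covariates is None
                  else np.atleast_2d(np.asarray(covariates, dtype=float)))
        if np.allclose(grm.values, np.eye(n), atol=1e-8):
            # genetic and residual variances are aliased: V is proportional
            # to I and GLS collapses to OLS, so skip the REML fit
            self.null_fit = None
            V = np.eye(n)
        else:
            model = VarianceComponentModel(self.y, self.C, [grm], ["genome"])
            self.null_fit = fit_reml(model, constrain=constrain)
            sg, se_ = self.null_fit.sigma2
            V = sg * grm.values + se_ * np.eye(n)
        self._identity = self.null_fit is None
        self._cho = sla.cho_factor(V, lower=True, check_finite=False)

    def test(self, x, predictor_id="x") -> AssocResult:
        x = _prepare_predictor(x)
        n = x.shape[0]
        if x.std() == 0:
            return AssocResult(predictor_id, np.nan, np.nan, np.nan, n)
        X = np.column_stack([self.C, x])
        VinvX = sla.cho_solve(self._cho, X, check_finite=False)
        XtVinvX = X.T @ VinvX
        rhs = VinvX.T @ self.y
        cov = np.linalg.inv(XtVinvX)
        beta = cov @ rhs
        if self._identity:
            # V was taken as I up to scale; estimate the scale from residuals
            resid = self.y - X @ beta
            cov = cov * (float(resid @ resid) / (n - X.shape[1]))
        se = float(np.sqrt(cov[-1, -1]))
        dof = n - X.shape[1]
        tval = beta[-1] / se
        p = float(2.0 * t_dist.sf(abs(tval), dof))
        return AssocResult(predictor_id, float(beta[-1]), se, p, n)


def mlm_assoc(y, x, covariates, grm: RelatednessMatrix,
              predictor_id="x", null_fit: MixedModelNull | None = None) -> AssocResult:
    """Mixed-model association of one predictor under a GRM random effect.

    With ``grm`` equal to the identity this reduces numerically to
    ``linear_assoc`` (the GLS rotation is a rescaling).  Pass a prefit
    ``MixedModelNull`` to amortize the variance-component estimation over
    many predictors.
    """
    if null_fit is None:
        null_fit = MixedModelNull(y, covariates, grm)
    return null_fit.test(x, predictor_id)


def ld_r2(g: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of dosages over jointly observed samples.

    Invariant to allele flipping on either SNP; NaN (undefined) when either
    SNP is monomorphic in the shared samples.
    """
    ja, jb = g.snp_index(snp_a), g.snp_index(snp_b)
    a = g.dosages[:, ja]
    b = g.dosages[:, jb]
    obs = (a != MISSING) & (b != MISSING)
    if obs.sum() < 2:
        raise ValueError("need at least two jointly observed samples")
    af, bf = a[obs].astype(float), b[obs].astype(float)
    if af.std() == 0 or bf.std() == 0:
        return np.nan
    r = np.corrcoef(af, bf)[0, 1]
    return float(r * r)
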