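"""Ridge-regression BLUP of marker effects (RRBLUP).

Model: y = 1*mu + Z u + e with u ~ N(0, sigma2_m I), e ~ N(0, sigma2_e I)
and Z the column-centred predictor doses.  Effects are the ridge solution
u = (Z'Z + lambda I)^-1 Z' (y - mean(y)) with lambda = sigma2_e / sigma2_m
estimated by REML.  The REML profile likelihood is evaluated through the
eigendecomposition of whichever Gram matrix (ZZ' or Z'Z) is smaller, with
the zero-eigenvalue bulk handled in closed form, so both genome-wide
panels (many predictors) and causal-variant panels (few predictors) are
cheap.  Predictors are centred by training-population column means and
candidates are centred by those same means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import minimize_scalar

_LOG_LAMBDA_RANGE = (-8.0, 8.0)


@dataclass
class MarkerEffectsModel:
    """Fitted shrunken marker effects plus the centring needed to apply them."""

    intercept: float
    effects: np.ndarray
    lam: float
    col_means: np.ndarray

    @property
    def n_predictors(self) -> int:
        return self.effects.size


def _reml_lambda(zc: np.ndarray, yc: np.ndarray) -> float:
    """REML estimate of lambda = sigma2_e / sigma2_m via eigendecomposition.

    ``zc`` is column-centred, ``yc`` mean-centred; the fixed effect is the
    grand mean only, leaving n-1 degrees of freedom.
    """
    n, m = zc.shape
    df = n - 1
    if df < 2:
        raise ValueError("training population too small for REML")
    if n <= m:
        k = zc @ zc.T
        vals, vecs = linalg.eigh(k - k.mean(0, keepdims=True)
                                 - k.mean(1, keepdims=True) + k.mean())
        order = np.argsort(vals)[::-1][:df]
        xi = np.clip(vals[order], 0.0, None)
        eta2 = (vecs[:, order].T @ yc) ** 2
        eta0 = 0.0
        n_zero = 0
    else:
        g = zc.T @ zc
        vals, vecs = linalg.eigh(g)
        pos = vals > max(1e-10, vals.max() * 1e-12) if vals.size else vals > 0
        xi = vals[pos]
        u = zc @ (vecs[:, pos] / np.sqrt(xi)[None, :])
        eta = u.T @ yc
        eta2 = eta**2
        eta0 = float(yc @ yc - eta2.sum())
        n_zero = df - xi.size

    def crit(log_lam: float) -> float:
        lam = 10.0**log_lam
        ss = float(np.sum(eta2 / (xi + lam)))
        logdet = float(np.sum(np.log(xi + lam)))
        if n_zero > 0:
            ss += max(eta0, 0.0) / lam
            logdet += n_zero * np.log(lam)
        return df * np.log(max(ss, 1e-300)) + logdet

    res = minimize_scalar(crit, bounds=_LOG_LAMBDA_RANGE, method="bounded",
                          options={"xatol": 1e-4})
    if not res.success or not np.isfinite(res.fun):
        raise RuntimeError("REML optimisation failed")
    return float(10.0**res.x)


def fit_rrblup(doses: np.ndarray, phenotypes: np.ndarray, lam: float | None = None,
               fallback_h2: float = 0.5) -> MarkerEffectsModel:
    """Fit shrunken marker effects on a training population.

    ``doses`` is (n, m) allele-1 counts at the predictor loci, ``phenotypes``
    length n.  ``lam`` fixes the shrinkage directly; otherwise it is
    estimated by REML, falling back to m (1 - h2) / h2 at ``fallback_h2``
    if the optimiser fails.  Monomorphic predictors have zero centred
    column and therefore zero estimated effect.
    """
    z = np.asarray(doses, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    if z.ndim != 2 or z.shape[0] != y.size:
        raise ValueError("doses must be (n, m) matching phenotypes")
    n, m = z.shape
    if n < 2:
        raise ValueError("training population must have at least 2 individuals")
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance; cannot fit marker effects")
    col_means = z.mean(axis=0)
    zc = z - col_means[None, :]
    mu = float(y.mean())
    yc = y - mu
    if lam is None:
        try:
            lam = _reml_lambda(zc, yc)
        except RuntimeError:
            lam = m * (1.0 - fallback_h2) / fallback_h2
    if lam <= 0:
        raise ValueError("shrinkage lambda must be positive")
    if m <= n:
        a = zc.T @ zc + lam * np.eye(m)
        rhs = zc.T @ yc
    else:  # dual form: u = Z'(ZZ' + lam I)^-1 yc
        a = zc @ zc.T + lam * np.eye(n)
        rhs = yc
    try:
        c, low = linalg.cho_factor(a, check_finite=False)
        sol = linalg.cho_solve((c, low), rhs, check_finite=False)
    except linalg.LinAlgError as err:
        raise ValueError(
            f"singular ridge system (condition {np.linalg.cond(a):.2e})") from err
    effects = sol if m <= n else zc.T @ sol
    return MarkerEffectsModel(mu, effects, float(lam), col_means)


def predict_ebv(model: MarkerEffectsModel, doses: np.ndarray) -> np.ndarray:
    """Estimated breeding values: intercept + centred doses @ effects."""
    z = np.asarray(doses, dtype=float)
    if z.ndim != 2 or z.shape[1] != model.n_predictors:
        raise ValueError(
            f"predictor mismatch: model has {model.n_predictors} predictors, "
            f"candidates have {z.shape[-1]}")
    return model.intercept + (z - model.col_means[None, :]) @ model.effects


def prediction_accuracy(ebv: np.ndarray, true_g: np.ndarray) -> float:
    """Pearson correlation of predictions with true genetic values.

    Returns NaN (missing, not zero) when either vector has no variance.
    """
    ebv = np.asarray(ebv, dtype=float)
    true_g = np.asarray(true_g, dtype=float)
    if ebv.size != true_g.size or ebv.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.var(ebv) == 0 or np.var(true_g) == 0:
        return float("nan")
    return float(np.corrcoef(ebv, true_g)[0, 1])
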