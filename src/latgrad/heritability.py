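"""Polygenic variance-components heritability on pedigree kinship.

The model is the classical twin/family decomposition

    y ~ N(X beta, sigma_g^2 * K + sigma_e^2 * I)

with K the expected relatedness matrix (2*Phi): 1 on the diagonal and for MZ
co-twins, 0.5 for DZ co-twins and full siblings, 0 across families.
Narrow-sense heritability is h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

Estimation eigendecomposes K once; after rotating y and X into the
eigenbasis the covariance is diagonal, so every likelihood evaluation is
O(n * p) and the 1-D profile likelihood in h^2 can be maximized cheaply.
The h^2 = 0 null lies on the boundary of the parameter space, so the
likelihood-ratio statistic is referred to the 50:50 chi2_0 : chi2_1 mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import Pedigree

__all__ = [
    "KinshipMatrix",
    "KinshipEigen",
    "HeritabilityFit",
    "kinship_matrix",
    "eigendecompose",
    "fit_polygenic",
    "lrt_h2",
    "heritability_table",
]


class HeritabilityError(ValueError):
    pass


@dataclass
class KinshipMatrix:
    """Expected relatedness (2*Phi) with the subject order it is indexed by."""

    values: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise HeritabilityError("kinship matrix must be square")
        if not np.allclose(v, v.T):
            raise HeritabilityError("kinship matrix must be symmetric")


@dataclass
class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix (reusable across traits)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    subject_ids: np.ndarray


@dataclass
class HeritabilityFit:
    h2: float
    se: float
    loglik: float
    null_loglik: float
    p_value: float
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    method: str
    se_available: bool


def kinship_matrix(pedigree: Pedigree) -> KinshipMatrix:
    """Build 2*Phi from a validated pedigree.

    Members of the same family are full siblings (0.5) unless they are the two
    members of an MZ twin pair (1.0). Subjects of different families are
    unrelated.
    """
    t = pedigree.table
    n = len(t)
    K = np.zeros((n, n))
    np.fill_diagonal(K, 1.0)
    fam = t["family_id"].to_numpy(dtype=object)
    pair = t["twin_pair_id"].to_numpy(dtype=object)
    rel = t["relation"].to_numpy(dtype=object)
    for i in range(n):
        for j in range(i + 1, n):
            if fam[i] != fam[j]:
                continue
            if (
                rel[i] == "MZ_twin"
                and rel[j] == "MZ_twin"
                and pd.notna(pair[i])
                and pair[i] == pair[j]
            ):
                K[i, j] = K[j, i] = 1.0
            else:
                K[i, j] = K[j, i] = 0.5
    return KinshipMatrix(K, t["subject_id"].to_numpy(dtype=object))


def eigendecompose(kin: KinshipMatrix) -> KinshipEigen:
    lam, U = np.linalg.eigh(kin.values)
    return KinshipEigen(lam, U, kin.subject_ids)


def _profile_nll(h2: float, yt: np.ndarray, Xt: np.ndarray, lam: np.ndarray, reml: bool):
    """Negative log-likelihood profiled over beta and the total variance."""
    n, p = Xt.shape
    w = h2 * lam + (1.0 - h2)
    sw = np.sqrt(w)
    Xw = Xt / sw[:, None]
    yw = yt / sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if reml:
        df = n - p
        sigma2 = rss / df
        _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * (
            df * np.log(2.0 * np.pi * sigma2)
            + np.sum(np.log(w))
            + logdet_xx
            + df
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + np.sum(np.log(w)) + n)
    return -ll, beta, sigma2


def lrt_h2(loglik: float, null_loglik: float) -> float:
    """Boundary likelihood-ratio p-value for h^2 > 0.

    T = 2 * (loglik - null_loglik); the null distribution is the 50:50
    mixture of a point mass at zero and chi-square with 1 df.
    """
    T = 2.0 * (loglik - null_loglik)
    if T < -1e-8:
        raise HeritabilityError(
            f"alternative log-likelihood below the null (T = {T:.3g}); optimization failed"
        )
    T = max(T, 0.0)
    if T == 0.0:
        return 1.0
    return float(0.5 * stats.chi2.sf(T, df=1))


def fit_polygenic(
    y: np.ndarray,
    X: np.ndarray | None,
    kinship: KinshipMatrix | KinshipEigen,
    method: str = "ML",
) -> HeritabilityFit:
    """Maximum-likelihood variance-components fit of a quantitative trait.

    Parameters
    ----------
    y : per-subject trait values, in kinship subject order.
    X : covariate design matrix (an intercept is appended if no constant
        column is present); ``None`` for intercept-only.
    kinship : a :class:`KinshipMatrix`, or a precomputed
        :class:`KinshipEigen` when fitting many traits on one pedigree.
    method : "ML" (default; supports the boundary LRT) or "REML".
    """
    if method not in ("ML", "REML"):
        raise HeritabilityError(f"unknown method {method!r}")
    reml = method == "REML"
    eig = kinship if isinstance(kinship, KinshipEigen) else eigendecompose(kinship)
    lam, U = eig.eigenvalues, eig.eigenvectors
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n != lam.shape[0]:
        raise HeritabilityError("trait length does not match the kinship matrix")
    if np.ptp(lam) < 1e-8:
        raise HeritabilityError(
            "kinship matrix is proportional to the identity: genetic and "
            "environmental variances are not identifiable"
        )
    if X is None:
        X = np.ones((n, 1))
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            raise HeritabilityError("covariate design does not match the trait length")
        col_sd = X.std(axis=0)
        if not np.any(col_sd == 0):
            X = np.column_stack([np.ones(n), X])
    if n <= X.shape[1]:
        raise HeritabilityError("more model columns than subjects")

    yt = U.T @ y
    Xt = U.T @ X

    def nll(h2: float) -> float:
        return _profile_nll(h2, yt, Xt, lam, reml)[0]

    hi = 1.0 - 1e-9
    res = optimize.minimize_scalar(nll, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-9})
    candidates = [(nll(0.0), 0.0), (res.fun, float(res.x)), (nll(hi), hi)]
    best_nll, h2_hat = min(candidates, key=lambda c: c[0])
    _, beta, sigma2 = _profile_nll(h2_hat, yt, Xt, lam, reml)
    loglik = -best_nll
    null_loglik = -nll(0.0)
    p_value = lrt_h2(loglik, null_loglik) if not reml else float("nan")

    se, se_available = _h2_standard_error(h2_hat, yt, Xt, lam, reml)
    return HeritabilityFit(
        h2=h2_hat,
        se=se,
        loglik=loglik,
        null_loglik=null_loglik,
        p_value=p_value,
        sigma2_g=h2_hat * sigma2,
        sigma2_e=(1.0 - h2_hat) * sigma2,
        beta=beta,
        method=method,
        se_available=se_available,
    )


def _h2_standard_error(h2_hat, yt, Xt, lam, reml):
    """Delta-method SE of h^2 from a finite-difference observed information
    in (sigma_g^2, sigma_e^2). Unavailable exactly at the boundary."""
    if h2_hat < 1e-6 or h2_hat > 1.0 - 1e-6:
        return float("nan"), False
    _, _, sigma2 = _profile_nll(h2_hat, yt, Xt, lam, reml)
    sg, se_ = h2_hat * sigma2, (1.0 - h2_hat) * sigma2
    n, p = Xt.shape

    def nll_var(theta):
        vg, ve = theta
        if vg <= 0 or ve <= 0:
            return np.inf
        w = vg * lam + ve
        sw = np.sqrt(w)
        Xw = Xt / sw[:, None]
        yw = yt / sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        ll = -0.5 * (n * np.log(2.0 * np.pi) + np.sum(np.log(w)) + rss)
        if reml:
            _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
            ll += 0.5 * p * np.log(2.0 * np.pi) - 0.5 * logdet_xx
        return -ll

    theta = np.array([sg, se_])
    h = np.maximum(1e-5 * np.abs(theta), 1e-8)
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = (
                nll_var(theta + ei + ej)
                - nll_var(theta + ei - ej)
                - nll_var(theta - ei + ej)
                + nll_var(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return float("nan"), False
    s = sg + se_
    grad = np.array([se_ / s**2, -sg / s**2])
    var = float(grad @ cov @ grad)
    if not np.isfinite(var) or var <= 0:
        return float("nan"), False
    return float(np.sqrt(var)), True


def heritability_table(
    traits: pd.DataFrame,
    X: np.ndarray | None,
    kinship: KinshipMatrix | KinshipEigen,
    n_tests: int = 7,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every trait column on one pedigree and tabulate h^2, SE, p and the
    Bonferroni significance flag (default n = 7 network-level tests)."""
    eig = kinship if isinstance(kinship, KinshipEigen) else eigendecompose(kinship)
    rows = []
    for name in traits.columns:
        fit = fit_polygenic(traits[name].to_numpy(dtype=float), X, eig)
        rows.append(
            {
                "trait": name,
                "h2": fit.h2,
                "se": fit.se,
                "p_value": fit.p_value,
                "significant_bonferroni": bool(fit.p_value <= alpha / n_tests),
            }
        )
    return pd.DataFrame(rows)
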