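"""Mediation and first-stage moderated mediation with percentile bootstrap.

All paths are estimated by ordinary least squares on the same sample, so the
single-mediator decomposition c = c' + a*b holds exactly for the point
estimates.  Bootstrap confidence intervals are percentile intervals over
row resamples; resamples in which the exposure is constant are redrawn (and
counted), since no path model is estimable on them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import AnnualPanel

__all__ = [
    "OLSFit",
    "MediationResult",
    "ModeratedMediationResult",
    "fit_ols",
    "mediate",
    "moderated_mediation",
    "simple_slopes",
]

logger = logging.getLogger(__name__)

SMALL_SAMPLE_N = 20


class RankDeficiencyError(ValueError):
    pass


@dataclass
class OLSFit:
    """Classical OLS fit: exact least-squares coefficients, homoskedastic
    standard errors, t statistics and two-sided p values."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    cov_params: np.ndarray
    df_resid: int
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "std_errors": self.std_errors.tolist(),
            "t_values": self.t_values.tolist(),
            "p_values": self.p_values.tolist(),
            "r_squared": self.r_squared,
            "df_resid": self.df_resid,
            "n_obs": self.n_obs,
        }


def fit_ols(response: np.ndarray, design: np.ndarray) -> OLSFit:
    """Least squares of ``response`` on ``design`` (which must include an
    intercept column if one is wanted).

    Rank-deficient designs are a hard error naming the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(int(piv[j]) for j in range(rank, p))
        raise RankDeficiencyError(f"design is rank deficient; collinear columns: {bad}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df_resid = n - p
    sigma2 = resid @ resid / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * xtx_inv
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pvals = 2 * stats.t.sf(np.abs(t), df_resid)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    return OLSFit(
        coefficients=coef,
        std_errors=se,
        t_values=t,
        p_values=pvals,
        r_squared=float(r2),
        cov_params=cov,
        df_resid=df_resid,
        n_obs=n,
    )


@dataclass
class MediationResult:
    a: float  # X -> M
    b: float  # M -> Y | X
    c: float  # total X -> Y
    c_prime: float  # direct X -> Y | M
    indirect: float  # a * b
    fit_total: OLSFit  # Y ~ X
    fit_m: OLSFit  # M ~ X
    fit_y: OLSFit  # Y ~ X + M
    n_boot: int
    seed: int
    indirect_ci: tuple[float, float]
    indirect_boot: np.ndarray = field(repr=False)
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "c_prime": self.c_prime,
            "indirect": self.indirect,
            "indirect_ci": list(self.indirect_ci),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
            "fit_total": self.fit_total.to_dict(),
            "fit_m": self.fit_m.to_dict(),
            "fit_y": self.fit_y.to_dict(),
        }


@dataclass
class ModeratedMediationResult:
    a1: float  # X -> M at centered W = 0
    a2: float  # W -> M
    a3: float  # interaction X*W -> M
    b: float  # M -> Y | X
    c_prime: float  # direct X -> Y | M
    a3_se: float
    a3_t: float
    a3_p: float
    w_mean: float
    w_sd: float
    conditional_levels: np.ndarray  # centered w values probed
    conditional_a: np.ndarray  # a1 + a3 * w
    conditional_indirect: np.ndarray  # (a1 + a3 * w) * b
    index_modmed: float  # a3 * b
    index_ci: tuple[float, float]
    fit_m: OLSFit  # M ~ X + Wc + X*Wc
    fit_y: OLSFit  # Y ~ X + M
    n_boot: int
    seed: int
    index_boot: np.ndarray = field(repr=False)
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {
            "a1": self.a1,
            "a2": self.a2,
            "a3": self.a3,
            "b": self.b,
            "c_prime": self.c_prime,
            "a3_se": self.a3_se,
            "a3_t": self.a3_t,
            "a3_p": self.a3_p,
            "w_mean": self.w_mean,
            "w_sd": self.w_sd,
            "conditional_levels": self.conditional_levels.tolist(),
            "conditional_a": self.conditional_a.tolist(),
            "conditional_indirect": self.conditional_indirect.tolist(),
            "index_modmed": self.index_modmed,
            "index_ci": list(self.index_ci),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
            "fit_m": self.fit_m.to_dict(),
            "fit_y": self.fit_y.to_dict(),
        }


def _extract(panel, name: str) -> np.ndarray:
    if isinstance(panel, AnnualPanel):
        return panel.column(name)
    if isinstance(panel, pd.DataFrame):
        return panel[name].to_numpy(dtype=float)
    raise TypeError("panel must be an AnnualPanel or DataFrame")


def _complete_rows(*cols: np.ndarray) -> list[np.ndarray]:
    keep = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        keep &= ~np.isnan(c)
    return [c[keep] for c in cols]


_MAX_COND = 1e12


def _bootstrap_products(
    rng: np.random.Generator,
    x: np.ndarray,
    n_boot: int,
    make_designs,
    m_coef_index: int,
    y_coef_index: int,
) -> tuple[np.ndarray, int]:
    """Percentile-bootstrap draws of a (first-stage coef) x (second-stage
    coef) product.

    ``make_designs(idx)`` returns stacked designs/responses
    ``(d_m, resp_m, d_y, resp_y)`` for the row-index matrix ``idx``.
    Degenerate resamples — constant exposure or (near-)singular normal
    equations — are redrawn and counted.
    """
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    n_redrawn = 0
    for _ in range(1000):
        xb = x[idx]
        bad = np.all(xb == xb[:, :1], axis=1)
        if not bad.any():
            d_m, resp_m, d_y, resp_y = make_designs(idx)
            gram_m = np.einsum("bni,bnj->bij", d_m, d_m)
            gram_y = np.einsum("bni,bnj->bij", d_y, d_y)
            with np.errstate(all="ignore"):
                bad = (np.linalg.cond(gram_m) > _MAX_COND) | (
                    np.linalg.cond(gram_y) > _MAX_COND
                )
            if not bad.any():
                rhs_m = np.einsum("bni,bn->bi", d_m, resp_m)[..., None]
                rhs_y = np.einsum("bni,bn->bi", d_y, resp_y)[..., None]
                coef_m = np.linalg.solve(gram_m, rhs_m)[..., 0]
                coef_y = np.linalg.solve(gram_y, rhs_y)[..., 0]
                if n_redrawn:
                    logger.info("redrew %d degenerate bootstrap resamples", n_redrawn)
                return coef_m[:, m_coef_index] * coef_y[:, y_coef_index], n_redrawn
        n_bad = int(bad.sum())
        n_redrawn += n_bad
        idx[bad] = rng.integers(0, n, size=(n_bad, n))
    raise RuntimeError("could not draw non-degenerate bootstrap resamples")


def _check_n(n: int) -> None:
    if n < 4:
        raise ValueError(f"need at least 4 complete rows, got {n}")
    if n < SMALL_SAMPLE_N:
        warnings.warn(
            f"only {n} observations; path-model inference is fragile at this size",
            stacklevel=3,
        )


def mediate(
    panel,
    x: str = "policy",
    m: str = "med",
    y: str = "sas",
    n_boot: int = 5000,
    seed: int | None = None,
    ci: float = 0.95,
) -> MediationResult:
    """Single-mediator mediation: Y ~ X (total), M ~ X, Y ~ X + M.

    ``indirect = a * b``; its confidence interval is a seeded percentile
    bootstrap over row resamples.
    """
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    xv, mv, yv = _complete_rows(_extract(panel, x), _extract(panel, m), _extract(panel, y))
    n = len(xv)
    _check_n(n)
    ones = np.ones(n)
    fit_total = fit_ols(yv, np.column_stack([ones, xv]))
    fit_m = fit_ols(mv, np.column_stack([ones, xv]))
    fit_y = fit_ols(yv, np.column_stack([ones, xv, mv]))
    a = float(fit_m.coefficients[1])
    b = float(fit_y.coefficients[2])
    c = float(fit_total.coefficients[1])
    c_prime = float(fit_y.coefficients[1])

    rng = np.random.default_rng(seed)

    def make_designs(idx):
        xb, mb, yb = xv[idx], mv[idx], yv[idx]
        ones_b = np.ones_like(xb)
        return np.stack([ones_b, xb], axis=2), mb, np.stack([ones_b, xb, mb], axis=2), yb

    indirect_boot, n_redrawn = _bootstrap_products(
        rng, xv, n_boot, make_designs, m_coef_index=1, y_coef_index=2
    )
    tail = 100 * (1 - ci) / 2
    lo, hi = np.percentile(indirect_boot, [tail, 100 - tail])
    return MediationResult(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=a * b,
        fit_total=fit_total,
        fit_m=fit_m,
        fit_y=fit_y,
        n_boot=n_boot,
        seed=seed,
        indirect_ci=(float(lo), float(hi)),
        indirect_boot=indirect_boot,
        n_redrawn=n_redrawn,
    )


def moderated_mediation(
    panel,
    x: str = "policy",
    m: str = "med",
    y: str = "sas",
    w: str = "support_ratio",
    n_boot: int = 5000,
    seed: int | None = None,
    ci: float = 0.95,
    center_w: bool = True,
) -> ModeratedMediationResult:
    """First-stage moderated mediation: M ~ X + Wc + X*Wc; Y ~ X + M.

    The moderator is mean-centered before the product term is formed (set
    ``center_w=False`` for raw-scale coding).  Conditional indirect effects
    (a1 + a3*w)*b are reported at w = mean-SD, mean, mean+SD; the index of
    moderated mediation is a3*b with a percentile bootstrap CI.
    """
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    xv, mv, yv, wv = _complete_rows(
        _extract(panel, x), _extract(panel, m), _extract(panel, y), _extract(panel, w)
    )
    n = len(xv)
    _check_n(n)
    if np.var(wv) == 0:
        raise ValueError("moderator has zero variance")
    w_mean = float(wv.mean())
    w_sd = float(wv.std(ddof=1))
    wc = wv - w_mean if center_w else wv
    ones = np.ones(n)
    fit_m = fit_ols(mv, np.column_stack([ones, xv, wc, xv * wc]))
    fit_y = fit_ols(yv, np.column_stack([ones, xv, mv]))
    a1, a2, a3 = (float(fit_m.coefficients[k]) for k in (1, 2, 3))
    b = float(fit_y.coefficients[2])
    c_prime = float(fit_y.coefficients[1])
    levels = np.array([-w_sd, 0.0, w_sd]) if center_w else np.array(
        [w_mean - w_sd, w_mean, w_mean + w_sd]
    )
    cond_a = a1 + a3 * levels
    cond_ind = cond_a * b

    rng = np.random.default_rng(seed)

    def make_designs(idx):
        xb, mb, yb, wb = xv[idx], mv[idx], yv[idx], wc[idx]
        ones_b = np.ones_like(xb)
        return (
            np.stack([ones_b, xb, wb, xb * wb], axis=2),
            mb,
            np.stack([ones_b, xb, mb], axis=2),
            yb,
        )

    index_boot, n_redrawn = _bootstrap_products(
        rng, xv, n_boot, make_designs, m_coef_index=3, y_coef_index=2
    )
    tail = 100 * (1 - ci) / 2
    lo, hi = np.percentile(index_boot, [tail, 100 - tail])
    return ModeratedMediationResult(
        a1=a1,
        a2=a2,
        a3=a3,
        b=b,
        c_prime=c_prime,
        a3_se=float(fit_m.std_errors[3]),
        a3_t=float(fit_m.t_values[3]),
        a3_p=float(fit_m.p_values[3]),
        w_mean=w_mean,
        w_sd=w_sd,
        conditional_levels=levels,
        conditional_a=cond_a,
        conditional_indirect=cond_ind,
        index_modmed=a3 * b,
        index_ci=(float(lo), float(hi)),
        fit_m=fit_m,
        fit_y=fit_y,
        n_boot=n_boot,
        seed=seed,
        index_boot=index_boot,
        n_redrawn=n_redrawn,
    )


def simple_slopes(
    first_stage_fit: OLSFit,
    w_levels,
    x_index: int = 1,
    xw_index: int = 3,
) -> pd.DataFrame:
    """Conditional effect of X on M at each moderator level.

    effect(w) = a1 + a3*w with SE from the coefficient covariance:
    sqrt(var(a1) + w^2 var(a3) + 2 w cov(a1, a3)).
    """
    a1 = first_stage_fit.coefficients[x_index]
    a3 = first_stage_fit.coefficients[xw_index]
    cov = first_stage_fit.cov_params
    rows = []
    for w in np.asarray(w_levels, dtype=float):
        effect = a1 + a3 * w
        var = cov[x_index, x_index] + w**2 * cov[xw_index, xw_index] + 2 * w * cov[x_index, xw_index]
        se = float(np.sqrt(var))
        t = effect / se if se > 0 else float("nan")
        p = 2 * stats.t.sf(abs(t), first_stage_fit.df_resid)
        rows.append({"w": float(w), "effect": float(effect), "se": se, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
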