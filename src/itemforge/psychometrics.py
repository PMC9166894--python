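"""Psychometric evaluation of Likert-scale item pools.

Covers the ordinal evaluation chain for scales of rating items answered on
K categories (default K = 5):

* per-item descriptives from category frequency tables (mean, sample SD,
  skewness, excess kurtosis),
* polychoric correlations via the two-step estimator (marginal thresholds
  by inverse-normal of cumulative proportions, then the correlation of the
  underlying bivariate normal by profile maximum likelihood),
* a single-factor model fit to the polychoric matrix by minimum residuals
  (unweighted least squares), giving standardized loadings lambda_j and
  residual variances theta_j = 1 - lambda_j^2,
* McDonald's omega-total, (sum lambda)^2 / ((sum lambda)^2 + sum theta),
  with a respondent-resampling percentile bootstrap CI and a two-sample
  bootstrap comparison,
* Cohen's kappa with its asymptotic 95% CI for two-rater agreement,
* parallel analysis for factor retention.

Moment conventions for the descriptives: SD uses divisor N-1; skewness is
m3 / s^3 and excess kurtosis m4 / s^4 - 3, where m3, m4 are central moments
with divisor N and s is the sample SD.

The bivariate-normal CDF inside the polychoric likelihood is evaluated by
Gauss-Legendre quadrature on dPhi2/drho = phi2 (the bivariate density),
vectorized over all contingency-table cells, which keeps bootstrap
pipelines of thousands of polychoric fits tractable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "LikertMatrix",
    "FrequencyTable",
    "FactorModel",
    "OmegaEstimate",
    "KappaEstimate",
    "likert_descriptives",
    "bivariate_normal_cdf",
    "polychoric",
    "polychoric_matrix",
    "fit_one_factor",
    "omega_total",
    "bootstrap_omega",
    "compare_omegas",
    "cohens_kappa",
    "parallel_analysis",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class LikertMatrix:
    """Respondents x items integer responses in 1..K plus item metadata."""

    values: np.ndarray  # (N, J) int
    item_names: list[str] = field(default_factory=list)
    constructs: list[str] = field(default_factory=list)
    keying: list[str] = field(default_factory=list)  # '+' or '-' per item
    n_categories: int = 5
    n_listwise_dropped: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("response matrix must be respondents x items")
        complete = ~np.isnan(vals).any(axis=1)
        self.n_listwise_dropped = int((~complete).sum())
        vals = vals[complete]
        if vals.size == 0:
            raise ValueError("no complete response rows")
        if vals.min() < 1 or vals.max() > self.n_categories:
            raise ValueError(
                f"responses must lie in 1..{self.n_categories}"
            )
        self.values = vals.astype(int)
        J = self.values.shape[1]
        if not self.item_names:
            self.item_names = [f"item{j + 1}" for j in range(J)]
        if not self.constructs:
            self.constructs = [""] * J
        if not self.keying:
            self.keying = ["+"] * J

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def reverse_scored(self) -> "LikertMatrix":
        """Apply keying: items marked '-' become K + 1 - x; raw data kept."""
        vals = self.values.copy()
        for j, key in enumerate(self.keying):
            if key == "-":
                vals[:, j] = self.n_categories + 1 - vals[:, j]
        return LikertMatrix(
            values=vals,
            item_names=list(self.item_names),
            constructs=list(self.constructs),
            keying=["+"] * self.n_items,
            n_categories=self.n_categories,
        )


@dataclass(frozen=True)
class FrequencyTable:
    """Category counts 1..K for one item."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts) or sum(self.counts) == 0:
            raise ValueError("counts must be nonnegative with positive total")

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass
class FactorModel:
    """Standardized one-factor solution."""

    loadings: np.ndarray  # lambda_j
    residuals: np.ndarray  # theta_j = 1 - lambda_j^2
    converged: bool
    heywood: bool
    smoothed: bool = False


@dataclass
class OmegaEstimate:
    omega: float
    ci_low: float
    ci_high: float
    k_boot: int
    n_nonconverged: int
    seed: int


@dataclass
class KappaEstimate:
    kappa: float
    ci_low: float
    ci_high: float
    observed_agreement: float
    expected_agreement: float


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


def likert_descriptives(freqs: FrequencyTable | Sequence[int]) -> dict:
    """Mean, sample SD, skewness and excess kurtosis from category counts.

    Zero-variance items report sd 0 with skewness/kurtosis flagged
    undefined (NaN).
    """
    ft = freqs if isinstance(freqs, FrequencyTable) else FrequencyTable(tuple(freqs))
    counts = np.asarray(ft.counts, dtype=float)
    n = counts.sum()
    cats = np.arange(1, counts.size + 1, dtype=float)
    mean = float((cats * counts).sum() / n)
    dev = cats - mean
    m2 = float((counts * dev**2).sum() / n)
    if n < 2 or m2 == 0:
        return {"mean": mean, "sd": 0.0, "skewness": float("nan"),
                "kurtosis": float("nan"), "n": int(n)}
    sd = float(np.sqrt((counts * dev**2).sum() / (n - 1)))
    m3 = float((counts * dev**3).sum() / n)
    m4 = float((counts * dev**4).sum() / n)
    return {
        "mean": mean,
        "sd": sd,
        "skewness": m3 / sd**3,
        "kurtosis": m4 / sd**4 - 3.0,
        "n": int(n),
    }


# ---------------------------------------------------------------------------
# Polychoric correlation
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)
_CLIP = 8.0  # |z| beyond this is numerically 0/1 under the normal CDF


def bivariate_normal_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses Phi2(h, k; rho) = Phi(h) Phi(k) + integral_0^rho phi2(h, k; r) dr
    with fixed Gauss-Legendre nodes; vectorized over h, k of any shape.
    """
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    base = norm.cdf(h) * norm.cdf(k)
    if rho == 0.0:
        return base
    r = 0.5 * rho * (_GL_NODES + 1.0)  # nodes mapped onto [0, rho]
    w = 0.5 * rho * _GL_WEIGHTS
    r = r.reshape((-1,) + (1,) * h.ndim)
    w = w.reshape((-1,) + (1,) * h.ndim)
    one_m_r2 = 1.0 - r * r
    dens = np.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * one_m_r2)) / (
        2.0 * np.pi * np.sqrt(one_m_r2)
    )
    return base + (w * dens).sum(axis=0)


def _thresholds(x: np.ndarray, n_categories: int) -> np.ndarray:
    counts = np.bincount(x, minlength=n_categories + 1)[1:]
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return norm.ppf(np.clip(cum, 1e-10, 1 - 1e-10))


def _cell_probs(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the contingency cells given thresholds."""
    af = np.concatenate(([-np.inf], a, [np.inf]))
    bf = np.concatenate(([-np.inf], b, [np.inf]))
    grid = bivariate_normal_cdf(af[:, None], bf[None, :], rho)
    return np.diff(np.diff(grid, axis=0), axis=1)


def polychoric(
    x: Sequence[int],
    y: Sequence[int],
    n_categories: int = 5,
) -> tuple[float, np.ndarray, np.ndarray, bool]:
    """Two-step polychoric correlation of two ordinal vectors.

    Returns (rho_hat, thresholds_x, thresholds_y, boundary_flag).  Raises if
    either vector shows fewer than two observed categories.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("each vector needs at least two observed categories")
    a = _thresholds(x, n_categories)
    b = _thresholds(y, n_categories)
    table = np.zeros((n_categories, n_categories))
    np.add.at(table, (x - 1, y - 1), 1.0)

    nz = table > 0

    def negll(rho: float) -> float:
        probs = np.clip(_cell_probs(a, b, rho), 1e-12, None)
        return -float((table[nz] * np.log(probs[nz])).sum())

    res = optimize.minimize_scalar(
        negll, bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-4},
    )
    rho = float(res.x)
    boundary = abs(rho) >= 0.998
    return rho, a, b, boundary


def polychoric_matrix(values: np.ndarray, n_categories: int = 5) -> np.ndarray:
    """J x J polychoric correlation matrix of a response matrix."""
    J = values.shape[1]
    R = np.eye(J)
    for i in range(J):
        for j in range(i + 1, J):
            rho, *_ = polychoric(values[:, i], values[:, j], n_categories)
            R[i, j] = R[j, i] = rho
    return R


# ---------------------------------------------------------------------------
# One-factor model and omega
# ---------------------------------------------------------------------------


def _smooth_corr(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 1e-6, None)
    S = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def fit_one_factor(R: np.ndarray, max_iter: int = 500) -> FactorModel:
    """Minimum-residual (ULS) one-factor solution on a correlation matrix.

    Minimizes the sum of squared off-diagonal residuals of R - lambda
    lambda^T, with loadings box-bounded to [-1, 1] so residual variances
    stay nonnegative (otherwise near-null matrices admit unbounded
    single-item spikes and omega degenerates).  Loadings follow a
    majority-positive sign convention; a solution pinned at the boundary
    sets the Heywood flag.
    """
    R = np.asarray(R, dtype=float)
    J = R.shape[0]
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if J < 3:
        raise ValueError("a one-factor model needs at least 3 items")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("R must have a unit diagonal")
    smoothed = False
    if np.linalg.eigvalsh(R).min() < -1e-8:
        R = _smooth_corr(R)
        smoothed = True

    offdiag = ~np.eye(J, dtype=bool)

    def objective(lam: np.ndarray):
        resid = (R - np.outer(lam, lam))[offdiag]
        fit = R - np.outer(lam, lam)
        grad = -4.0 * (np.where(offdiag, fit, 0.0) @ lam)
        return float((resid**2).sum()), grad

    vals, vecs = np.linalg.eigh(R)
    lam0 = np.clip(np.sqrt(max(vals[-1], 1e-6)) * vecs[:, -1], -1.0, 1.0)
    res = optimize.minimize(
        objective, lam0, jac=True, method="L-BFGS-B",
        bounds=[(-1.0, 1.0)] * J,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    lam = res.x
    # degenerate matrices (e.g. identity) admit single-spike minimizers with
    # the same off-diagonal fit as the null solution; prefer the smaller norm
    if objective(lam)[0] >= objective(np.zeros(J))[0] - 1e-12:
        lam = np.zeros(J)
    if (lam < 0).sum() > J / 2:
        lam = -lam
    heywood = bool(np.any(np.abs(lam) > 1.0 - 1e-6))
    return FactorModel(
        loadings=lam,
        residuals=1.0 - lam**2,
        converged=bool(res.success),
        heywood=heywood,
        smoothed=smoothed,
    )


def omega_total(model: FactorModel) -> float:
    """McDonald's omega-total, (sum lambda)^2 / ((sum lambda)^2 + sum theta)."""
    s = float(model.loadings.sum())
    theta = float(model.residuals.sum())
    if s == 0 and theta == 0:
        return 0.0
    return s * s / (s * s + theta)


def _omega_from_values(values: np.ndarray, n_categories: int) -> float | None:
    """One polychoric -> one-factor -> omega evaluation; None if it fails."""
    try:
        R = polychoric_matrix(values, n_categories)
        model = fit_one_factor(R)
    except (ValueError, np.linalg.LinAlgError):
        return None
    if not model.converged:
        return None
    return omega_total(model)


def bootstrap_omega(
    data: LikertMatrix, k_boot: int = 1000, seed: int = 0
) -> OmegaEstimate:
    """Omega with a respondent-resampling percentile 95% CI.

    Each replicate resamples rows with replacement and reruns the full
    polychoric -> one-factor -> omega chain; replicates whose model fails
    to converge (or whose resample degenerates) are omitted and counted.
    """
    if data.n_respondents < 30:
        raise ValueError("bootstrap needs at least 30 respondents")
    if k_boot < 100:
        raise ValueError("k_boot must be >= 100")
    values = data.reverse_scored().values
    point = _omega_from_values(values, data.n_categories)
    if point is None:
        raise RuntimeError("omega undefined on the full sample")
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    draws: list[float] = []
    failed = 0
    for _ in range(k_boot):
        idx = rng.integers(0, n, n)
        w = _omega_from_values(values[idx], data.n_categories)
        if w is None:
            failed += 1
        else:
            draws.append(w)
    if failed > k_boot / 2:
        raise RuntimeError(
            f"{failed}/{k_boot} bootstrap replicates failed to converge"
        )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return OmegaEstimate(
        omega=point, ci_low=float(lo), ci_high=float(hi),
        k_boot=k_boot, n_nonconverged=failed, seed=seed,
    )


def compare_omegas(
    data_a: LikertMatrix,
    data_b: LikertMatrix,
    k_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Two-sample bootstrap comparison of omega coefficients.

    Each iteration resamples both samples independently and records the
    omega difference; the two-sided p-value is twice the smaller tail
    proportion of differences crossing zero.  Returns (p, differences).
    """
    va = data_a.reverse_scored().values
    vb = data_b.reverse_scored().values
    rng = np.random.default_rng(seed)
    diffs: list[float] = []
    failed = 0
    for _ in range(k_boot):
        ia = rng.integers(0, va.shape[0], va.shape[0])
        ib = rng.integers(0, vb.shape[0], vb.shape[0])
        wa = _omega_from_values(va[ia], data_a.n_categories)
        wb = _omega_from_values(vb[ib], data_b.n_categories)
        if wa is None or wb is None:
            failed += 1
            continue
        diffs.append(wa - wb)
    if failed > k_boot / 2:
        raise RuntimeError(
            f"{failed}/{k_boot} bootstrap iterations failed to converge"
        )
    d = np.asarray(diffs)
    p = 2.0 * min(float((d <= 0).mean()), float((d >= 0).mean()))
    return min(p, 1.0), d


# ---------------------------------------------------------------------------
# Rater agreement
# ---------------------------------------------------------------------------


def cohens_kappa(table: np.ndarray) -> KappaEstimate:
    """Chance-corrected two-rater agreement from an R x R count table.

    kappa = (p_o - p_e) / (1 - p_e) with the Fleiss-Cohen-Everitt
    asymptotic standard error for the 95% CI.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("agreement table must be square")
    n = T.sum()
    if n < 1:
        raise ValueError("agreement table must contain at least one rating")
    P = T / n
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    p_o = float(np.trace(P))
    p_e = float((p_row * p_col).sum())
    if p_e >= 1.0:
        raise ValueError("degenerate marginals: expected agreement is 1")
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss, Cohen & Everitt (1969) large-sample variance
    diag = np.diag(P)
    term1 = float(
        (diag * ((1 - p_e) - (p_row + p_col) * (1 - p_o)) ** 2).sum()
    )
    off = ~np.eye(T.shape[0], dtype=bool)
    sums = p_col[None, :] + p_row[:, None]  # p_.j + p_i. for cell (i, j)
    term2 = float(((1 - p_o) ** 2 * (P * sums**2))[off].sum())
    term3 = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (term1 + term2 - term3) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(0.975)
    return KappaEstimate(
        kappa=float(kappa),
        ci_low=float(kappa - z * se),
        ci_high=float(kappa + z * se),
        observed_agreement=p_o,
        expected_agreement=p_e,
    )


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------


def parallel_analysis(
    data: LikertMatrix,
    n_sims: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Factor retention by comparison with random-data eigenvalues.

    Retains the leading factors whose observed correlation-matrix
    eigenvalues exceed the chosen quantile of eigenvalues from ``n_sims``
    standard-normal datasets of the same N x J; stops at the first factor
    that fails.
    """
    if n_sims < 20:
        raise ValueError("n_sims must be >= 20")
    values = data.values
    N, J = values.shape
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(values, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, J))
    for s in range(n_sims):
        X = rng.standard_normal((N, J))
        sims[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    ref = np.quantile(sims, quantile, axis=0)
    retained = 0
    for lam_obs, lam_ref in zip(obs, ref):
        if lam_obs > lam_ref:
            retained += 1
        else:
            break
    return retained
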