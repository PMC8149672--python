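"""Window-level association testing: score tests, burden, SKAT, ACAT.

Each candidate window receives a single importance p-value built from an
ensemble of covariate-adjusted score tests:

* single-variant score tests (with a saddlepoint-approximated tail for
  unbalanced binary traits);
* burden tests — score test on a weighted dosage sum, powered against
  same-direction effects;
* dispersion (SKAT) tests — a quadratic-form statistic whose null law is
  a mixture of chi-squares, powered against mixed-direction effects;
* an unweighted burden of ultra-rare variants (MAC < 5);
* optional annotation-weighted burden/SKAT variants for rare variants.

The component p-values are combined with the Cauchy combination (ACAT),
which is calibrated under arbitrary dependence among components.  The same
entry point scores original and knockoff dosage matrices, so original and
control features travel through an identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import math

from scipy import optimize, special, stats

_SQRT2 = math.sqrt(2.0)

from .panel import COMMON, LOW_FREQUENCY, RARE, ULTRA_RARE, GenotypePanel, Window

__all__ = [
    "NullModel",
    "fit_null_model",
    "beta_maf_weights",
    "single_variant_score_test",
    "saddlepoint_pvalue",
    "burden_test",
    "skat_test",
    "ultra_rare_burden",
    "cauchy_combine",
    "window_pvalue",
    "ScoreCache",
]

P_FLOOR = 1e-300
SPA_Z_SWITCH = 2.0  # |z| below which the normal tail is kept


@dataclass
class NullModel:
    """Phenotype ~ covariates fit exposing score-test ingredients.

    ``resid`` is ``Y - mu``; ``weights`` is the GLM variance function at
    the fitted mean (ones for gaussian); ``dispersion`` is the residual
    variance for gaussian traits and 1 for binomial.
    """

    family: str
    X: np.ndarray
    mu: np.ndarray
    resid: np.ndarray
    weights: np.ndarray
    dispersion: float
    _XtVX_inv: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def adjust(self, G: np.ndarray) -> np.ndarray:
        """Residualize columns of G against covariates in the V metric."""
        VX = self.X * self.weights[:, None]
        return G - self.X @ (self._XtVX_inv @ (VX.T @ G))


def fit_null_model(Y, X=None, family: str = "gaussian") -> NullModel:
    """Fit the covariate-only null model by maximum likelihood.

    X is augmented with an intercept column.  Gaussian fits are ordinary
    least squares; binomial fits use iteratively reweighted least squares
    and raise on non-convergence (e.g. separation).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if np.ptp(Y) == 0:
        raise ValueError("constant phenotype")
    X = (
        np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
        if X is not None and np.asarray(X).size
        else np.ones((n, 1))
    )
    if family == "gaussian":
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        mu = X @ beta
        resid = Y - mu
        dof = max(n - X.shape[1], 1)
        disp = float(resid @ resid / dof)
        w = np.ones(n)
    elif family == "binomial":
        if not set(np.unique(Y)) <= {0.0, 1.0}:
            raise ValueError("binomial phenotype must be 0/1")
        beta = np.zeros(X.shape[1])
        for _ in range(100):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1 - mu)
            if w.min() < 1e-12:
                w = np.maximum(w, 1e-12)
            z = eta + (Y - mu) / w
            WX = X * w[:, None]
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
            if np.max(np.abs(beta_new - beta)) < 1e-10:
                beta = beta_new
                break
            beta = beta_new
        else:
            raise RuntimeError(
                "binomial null model did not converge "
                "(possible separation or degenerate covariates)"
            )
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        resid = Y - mu
        disp = 1.0
    else:
        raise ValueError(f"unknown family {family!r}")
    XtVX = X.T @ (X * w[:, None])
    return NullModel(family, X, mu, resid, w, disp, np.linalg.inv(XtVX))


def _norm_sf2(z: float) -> float:
    """Two-sided normal tail 2*P(Z > |z|), floored."""
    return max(math.erfc(abs(z) / _SQRT2), P_FLOOR)


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta-density MAF weights (default shape (1, 25)), upweighting rare alleles."""
    x = np.asarray(maf, dtype=float)
    return x ** (a - 1) * (1 - x) ** (b - 1) / special.beta(a, b)


# ---------------------------------------------------------------------------
# score tests


def _score_and_variance(null: NullModel, G: np.ndarray):
    """Score vector U = G'(Y-mu) and its covariance, covariate-adjusted."""
    Ga = null.adjust(G)
    U = Ga.T @ null.resid
    V = (Ga * null.weights[:, None]).T @ Ga * null.dispersion
    return U, V, Ga


def single_variant_score_test(
    null: NullModel, g: np.ndarray, use_spa: bool = False
) -> float:
    """Two-sided score test of one dosage vector against the phenotype."""
    g = np.asarray(g, dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("zero-variance genotype vector")
    U, V, ga = _score_and_variance(null, g[:, None])
    u, v = float(U[0]), float(V[0, 0])
    raw_v = float((g - g.mean()) @ (g - g.mean()))
    if v <= 1e-12 * max(raw_v, 1.0):
        return 1.0  # genotype numerically in the covariate span
    z = u / np.sqrt(v)
    if use_spa and null.family == "binomial" and abs(z) >= SPA_Z_SWITCH:
        return saddlepoint_pvalue(u, ga[:, 0], null)
    return _norm_sf2(z)


def _cgf(t, g, mu):
    """Cumulant generating function of sum_i g_i (Y_i - mu_i), binomial."""
    x = np.clip(g * t, -700, 700)
    big = x > 30  # log(1 - mu + mu e^x) rewritten to avoid overflow
    val = np.empty_like(x)
    val[~big] = np.log1p(mu[~big] * np.expm1(x[~big]))
    val[big] = np.log(mu[big]) + x[big] + np.log1p(
        (1 - mu[big]) * np.exp(-x[big]) / mu[big]
    )
    return float(np.sum(val) - t * np.sum(g * mu))


def _cgf_d1(t, g, mu):
    ex = np.exp(np.clip(g * t, -700, 700))
    return float(np.sum(g * mu * ex / (1 - mu + mu * ex)) - np.sum(g * mu))


def _cgf_d2(t, g, mu):
    ex = np.exp(np.clip(g * t, -700, 700))
    pi = mu * ex / (1 - mu + mu * ex)
    return float(np.sum(g * g * pi * (1 - pi)))


def _spa_tail(s, g, mu):
    """P(S >= s) by the Lugannani-Rice formula; None if root-finding fails."""
    try:
        zeta = optimize.brentq(
            lambda t: _cgf_d1(t, g, mu) - s, -500, 500, xtol=1e-12
        )
    except ValueError:
        return None
    if abs(zeta) < 1e-8:
        return 0.5
    k, k2 = _cgf(zeta, g, mu), _cgf_d2(zeta, g, mu)
    if k2 <= 0:
        return None
    w = np.sign(zeta) * np.sqrt(max(2 * (zeta * s - k), 0.0))
    v = zeta * np.sqrt(k2)
    if w == 0:
        return 0.5
    return float(stats.norm.sf(w + np.log(v / w) / w))


def saddlepoint_pvalue(score: float, g_adj: np.ndarray, null: NullModel) -> float:
    """Two-sided saddlepoint p-value for a binomial score statistic.

    The tail of the score statistic S = sum_i g_i (Y_i - mu_i) is computed
    from its exact cumulant generating function, which remains accurate in
    the extreme case-control imbalance regime where the normal tail fails.
    Falls back to the normal approximation if root-finding fails.
    """
    if null.family != "binomial":
        raise ValueError("saddlepoint tail is defined for binomial traits")
    s = abs(float(score))
    if s == 0:
        return 1.0
    hi = _spa_tail(s, g_adj, null.mu)
    lo = _spa_tail(s, -g_adj, null.mu)  # P(S <= -s) = P(-S >= s)
    if hi is None or lo is None:
        v = _cgf_d2(0.0, g_adj, null.mu)
        return _norm_sf2(s / math.sqrt(v))
    return float(min(max(hi + lo, P_FLOOR), 1.0))


def burden_test(
    null: NullModel, G: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Score test on the weighted dosage sum across a window's variants."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.ndim == 1:
        G = G[:, None]
    w = np.ones(G.shape[1]) if weights is None else np.asarray(weights, float)
    b = G @ w
    if np.ptp(b) == 0:
        raise ValueError("burden vector is constant (all-zero weights?)")
    return single_variant_score_test(null, b)


def _mixture_chi2_sf(q: float, lam: np.ndarray) -> float:
    """P(sum lam_i chi2_1 > q) for positive mixture weights lam.

    A single weight is handled exactly as a scaled 1-df chi-square.
    Otherwise the tail is computed by saddlepoint inversion of the
    mixture's cumulant generating function (Lugannani-Rice), which is
    essentially exact in the tail region that matters for screening, with
    Liu's moment-matching chi-square approximation as a fallback near the
    mean or on numerical failure.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.size == 1:
        return max(math.erfc(math.sqrt(q / lam[0] / 2.0)), P_FLOOR)
    mean = float(lam.sum())
    if q <= 0:
        return 1.0
    if abs(q - mean) < 1e-8 * mean:
        return _liu_sf(q, lam)
    zeta = _solve_saddle(q, lam)
    if zeta is None or abs(zeta) < 1e-12:
        return _liu_sf(q, lam)
    K = -0.5 * float(np.sum(np.log1p(-2 * lam * zeta)))
    K2 = 2.0 * float(np.sum(lam ** 2 / (1 - 2 * lam * zeta) ** 2))
    w = math.copysign(math.sqrt(max(2 * (zeta * q - K), 0.0)), zeta)
    v = zeta * math.sqrt(K2)
    if w == 0 or K2 <= 0:
        return _liu_sf(q, lam)
    p = 0.5 * math.erfc((w + math.log(v / w) / w) / _SQRT2)
    if not np.isfinite(p):
        return _liu_sf(q, lam)
    return float(min(max(p, P_FLOOR), 1.0))


def _solve_saddle(q: float, lam: np.ndarray):
    """Root of K'(z) = q by safeguarded Newton; K' is increasing in z."""
    upper = 1.0 / (2 * lam.max())
    lo, hi = -1e10, upper * (1 - 1e-10)
    z = 0.0 if q > lam.sum() else -1.0  # start left of the pole
    for _ in range(100):
        d = 1.0 - 2.0 * lam * z
        f = float(np.sum(lam / d)) - q
        if abs(f) < 1e-11 * max(q, 1.0):
            return z
        if f > 0:
            hi = z
        else:
            lo = z
        fp = 2.0 * float(np.sum(lam ** 2 / d ** 2))
        z_new = z - f / fp
        if not (lo < z_new < hi):
            z_new = 0.5 * (lo + hi) if np.isfinite(lo) else z - 1.0
        z = z_new
    return None


def _liu_sf(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matched chi-square tail approximation."""
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1 / (s1 - np.sqrt(s1 ** 2 - s2))
        d = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * d
    else:
        d = 0.0
        df = 1 / s2
        a = np.sqrt(df)
    t_star = (q - c1) / np.sqrt(2 * c2)
    x = t_star * np.sqrt(2 * df + 4 * d) + df + d
    return float(min(max(stats.ncx2.sf(x, df, d), P_FLOOR), 1.0))


def skat_test(
    null: NullModel, G: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Dispersion (SKAT) test: Q = r' G W^2 G' r against a chi-square mixture.

    The mixture weights are the nonzero eigenvalues of the weighted,
    covariate-projected genotype cross-product; eigenvalues below
    1e-10 x max are dropped.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    w = np.ones(G.shape[1]) if weights is None else np.asarray(weights, float)
    Z = G * w[None, :]
    U = Z.T @ null.resid
    q_obs = float(U @ U)
    Za = null.adjust(Z)
    A = (Za * null.weights[:, None]).T @ Za * null.dispersion
    lam = np.linalg.eigvalsh(A)
    lam = lam[lam > max(1e-10 * lam.max(), 0.0)] if lam.size and lam.max() > 0 else lam[:0]
    if lam.size == 0:
        raise ValueError("degenerate SKAT kernel: all eigenvalues ~ 0")
    return _mixture_chi2_sf(q_obs, lam)


def ultra_rare_burden(null: NullModel, G_ultra: np.ndarray) -> float:
    """Unweighted burden (carrier count) score test over MAC<5 variants."""
    return burden_test(null, G_ultra, None)


def cauchy_combine(pvalues, weights=None) -> float:
    """ACAT combination of p-values via the Cauchy transform.

    T = sum_j w_j tan((0.5 - p_j) pi) / sum_j w_j; the combined p-value is
    0.5 - arctan(T)/pi.  Tiny p-values use the asymptote tan((0.5-p) pi)
    ~ 1/(p pi); p-values at 1 are nudged to 1 - 1e-15.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    w = np.ones(p.size) if weights is None else np.asarray(weights, float)
    p = np.clip(p, P_FLOOR, 1 - 1e-15)
    tiny = p < 1e-15
    terms = np.empty_like(p)
    terms[tiny] = 1.0 / (p[tiny] * np.pi)
    terms[~tiny] = np.tan((0.5 - p[~tiny]) * np.pi)
    T = float(np.sum(w * terms) / np.sum(w))
    if T > 1e15:
        return max(1.0 / (T * np.pi), P_FLOOR)
    return float(min(max(0.5 - np.arctan(T) / np.pi, P_FLOOR), 1.0))


# ---------------------------------------------------------------------------
# the per-window ensemble


class ScoreCache:
    """Shared per-dosage-matrix precomputations for window testing.

    Adjusted genotypes, per-variant scores and variances are computed once
    per matrix (original panel or one knockoff copy); window-level burden
    and SKAT statistics then only need small k x k cross-products.  Using
    one cache per matrix also guarantees that originals and knockoffs run
    through the identical code path.
    """

    def __init__(self, null: NullModel, dosages: np.ndarray):
        self.null = null
        G = np.asarray(dosages, dtype=float)
        self.Ga = null.adjust(G)
        self.wGa = self.Ga * null.weights[:, None]
        self.U = self.Ga.T @ null.resid
        self.var = np.einsum("ij,ij->j", self.wGa, self.Ga) * null.dispersion
        Gc = G - G.mean(axis=0)
        raw = np.einsum("ij,ij->j", Gc, Gc)
        # mark variants that are constant or numerically inside the
        # covariate span as untestable
        self.testable = self.var > 1e-12 * np.maximum(raw, 1.0)
        self._sv: dict = {}

    def crossprod(self, members: np.ndarray) -> np.ndarray:
        """Covariate-adjusted score covariance of a variant subset."""
        return (
            self.wGa[:, members].T @ self.Ga[:, members] * self.null.dispersion
        )

    def sv_pvalue(self, j: int, use_spa: bool = False) -> float:
        key = (int(j), bool(use_spa))
        if key not in self._sv:
            if not self.testable[j]:
                raise ValueError("zero adjusted variance for variant")
            v = self.var[j]
            z = self.U[j] / np.sqrt(v)
            if use_spa and self.null.family == "binomial" and abs(z) >= SPA_Z_SWITCH:
                p = saddlepoint_pvalue(self.U[j], self.Ga[:, j], self.null)
            else:
                p = _norm_sf2(z)
            self._sv[key] = float(p)
        return self._sv[key]


def _burden_p(U: np.ndarray, A: np.ndarray, w: np.ndarray) -> float:
    u = float(w @ U)
    v = float(w @ A @ w)
    if v <= 0:
        raise ValueError("burden vector carries no adjusted variance")
    return _norm_sf2(u / math.sqrt(v))


def _skat_p(U: np.ndarray, A: np.ndarray, w: np.ndarray) -> float:
    q_obs = float(np.sum((w * U) ** 2))
    lam = np.linalg.eigvalsh(A * np.outer(w, w))
    if lam.size == 0 or lam.max() <= 0:
        raise ValueError("degenerate SKAT kernel: all eigenvalues ~ 0")
    lam = lam[lam > 1e-10 * lam.max()]
    return _mixture_chi2_sf(q_obs, lam)


def window_pvalue(
    null: NullModel,
    dosages: np.ndarray,
    window: Window,
    categories: np.ndarray,
    maf: np.ndarray,
    annotations: np.ndarray | None = None,
    use_spa: bool = True,
    cache: ScoreCache | None = None,
) -> float:
    """Ensemble importance p-value for one window.

    ``dosages`` may be the original panel's matrix or a knockoff copy;
    variant categories and MAFs always come from the original panel so the
    original window and its knockoff counterparts contain matched variant
    sets.  ``annotations``, if given, is a (p x n_scores) array of opaque
    functional scores.

    1 bp windows reduce to the single-variant score test.  Multi-bp
    windows combine burden + SKAT on common/low-frequency variants, burden
    + SKAT on rare variants (Beta(1,25) MAF weights, optionally rescaled
    by each annotation score), the ultra-rare burden, and per-variant
    score tests, via the Cauchy combination.  Components with no
    qualifying variants are omitted rather than entered as p = 1.
    """
    if cache is None:
        cache = ScoreCache(null, dosages)
    members = np.asarray(window.members, dtype=int)
    cats = categories[members]
    nonconst = cache.testable[members]

    if window.size_class == 1:
        if not nonconst[0]:
            raise ValueError("constant dosage in 1 bp window")
        return cache.sv_pvalue(members[0], use_spa=use_spa)

    keep = members[nonconst]
    if keep.size == 0:
        raise ValueError("window has no testable component")
    A = cache.crossprod(keep)
    U = cache.U[keep]
    kcats = categories[keep]
    w_beta = beta_maf_weights(maf[keep])

    cl_mask = np.isin(kcats, [COMMON, LOW_FREQUENCY])
    rare_mask = kcats == RARE
    ultra_mask = kcats == ULTRA_RARE

    pvals: list[float] = []
    for mask in (cl_mask, rare_mask):
        if mask.any():
            ix = np.flatnonzero(mask)
            Am = A[np.ix_(ix, ix)]
            pvals.append(_burden_p(U[ix], Am, w_beta[ix]))
            pvals.append(_skat_p(U[ix], Am, w_beta[ix]))
    if annotations is not None and rare_mask.any():
        ann = np.asarray(annotations, dtype=float)
        if ann.ndim == 1:
            ann = ann[:, None]
        ix = np.flatnonzero(rare_mask)
        Am = A[np.ix_(ix, ix)]
        for s in range(ann.shape[1]):
            a = ann[keep, s]
            lo, hi = np.nanmin(a), np.nanmax(a)
            scaled = (a - lo) / (hi - lo) if hi > lo else np.ones_like(a)
            w_ann = w_beta * scaled
            if np.any(w_ann[ix] > 0):
                pvals.append(_burden_p(U[ix], Am, w_ann[ix]))
                pvals.append(_skat_p(U[ix], Am, w_ann[ix]))
    if ultra_mask.any():
        ix = np.flatnonzero(ultra_mask)
        pvals.append(_burden_p(U[ix], A[np.ix_(ix, ix)], np.ones(ix.size)))
    for j in keep:
        pvals.append(cache.sv_pvalue(j, use_spa=False))
    if not pvals:
        raise ValueError("window has no testable component")
    return cauchy_combine(pvals)
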