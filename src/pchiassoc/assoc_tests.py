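"""Global multilocus association tests built on score statistics.

All tests reduce a score vector ``U`` with estimated null covariance ``V``
to a scalar via the eigendecomposition ``V = xi diag(lambda) xi^T``:

* principal chi-squared: ``sum_{k<=s} (U xi_k)^2 / lambda_k`` over the top
  ``s`` components explaining a target fraction (default 85%) of the total
  eigenvalue mass; asymptotically chi-squared with ``s`` degrees of freedom.
  On the additive prospective score this is the classical principal
  component regression score test (PChiP); on the empirical-Bayes
  codominant score it is PChiB.
* Hotelling T^2: the same sum over every retained component.
* SSUP: the sum of squared scores ``U U^T``, distributed as the eigenvalue-
  weighted chi-squared mixture ``sum lambda_k chi2_1``.
* GOLD: the oracle 1-df score test on the causal SNP alone.
* Min2: the minimum of the PChiP and PChiB asymptotic p-values, calibrated
  by case-control label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .dataset import GenotypeDataset
from .scores import (
    CODING_ADDITIVE,
    CODING_EB,
    ScoreStat,
    _eb_centers,
    codominant_code,
    eb_covariance,
    gold_score,
)

__all__ = [
    "EigenTest",
    "TestResult",
    "select_components",
    "principal_chisq",
    "hotelling_t2",
    "ssup",
    "gold_test",
    "min2",
    "MultiTest",
]

#: eigenvalues below this fraction of the largest are treated as null space
EIGENVALUE_FLOOR = 1e-8


@dataclass
class EigenTest:
    """An eigen-truncated chi-squared test of a score statistic."""

    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # orthonormal columns, matching order
    s: int
    statistic: float
    df: int
    p_value: float


@dataclass
class TestResult:
    method: str
    statistic: float
    df: int | None
    p_value: float
    diagnostics: dict = field(default_factory=dict)


def _eigh_desc(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, vec = np.linalg.eigh(v)
    order = np.argsort(lam)[::-1]
    return lam[order], vec[:, order]


def select_components(eigenvalues: np.ndarray, threshold: float = 0.85) -> int:
    """Smallest s whose top-s eigenvalue share reaches ``threshold``.

    Eigenvalues below ``EIGENVALUE_FLOOR`` times the largest are dropped
    from both the numerator and the denominator, so duplicated or
    monomorphic columns do not inflate the apparent variability.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if lam.size == 0 or lam[0] <= 0:
        raise ValueError("degenerate input: no positive eigenvalues")
    if lam.min() < -EIGENVALUE_FLOOR * lam[0] * 100:
        raise ValueError("covariance has a substantially negative eigenvalue")
    kept = lam[lam >= EIGENVALUE_FLOOR * lam[0]]
    frac = np.cumsum(kept) / kept.sum()
    return int(np.argmax(frac >= threshold - 1e-12)) + 1


def _retained(lam: np.ndarray) -> np.ndarray:
    return lam >= EIGENVALUE_FLOOR * lam[0]


def principal_chisq(score: ScoreStat, threshold: float = 0.85) -> EigenTest:
    """Principal chi-squared test: top-s eigencomponents of ``(U xi)^2 / lambda``.

    With ``threshold = 1.0`` every retained component enters and the
    statistic equals Hotelling's T^2 on the retained subspace.
    """
    lam, vec = _eigh_desc(score.v)
    s = select_components(lam, threshold)
    proj = score.u @ vec[:, :s]
    statistic = float(np.sum(proj**2 / lam[:s]))
    p = float(stats.chi2.sf(statistic, df=s))
    return EigenTest(lam, vec, s, statistic, s, p)


def hotelling_t2(score: ScoreStat) -> TestResult:
    """Hotelling T^2 = U V^+ U^T over the retained eigen-subspace."""
    et = principal_chisq(score, threshold=1.0)
    return TestResult(
        "T2", et.statistic, et.df, et.p_value, {"retained_rank": et.s}
    )


def _liu_pvalue(t: float, lam: np.ndarray) -> float:
    """Moment-matching (skewness-corrected noncentral chi-squared) tail
    probability of the mixture ``sum lam_k chi2_1`` at ``t``."""
    c1, c2, c3, c4 = (np.sum(lam**r) for r in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        df = 1.0 / s2
        a = np.sqrt(df)
        delta = 0.0
    mu_x = df + delta
    sigma_x = np.sqrt(2.0) * np.sqrt(df + 2 * delta)
    tstar = (t - c1) / np.sqrt(2 * c2)
    x = tstar * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def _imhof_pvalue(t: float, lam: np.ndarray) -> float:
    """Exact tail probability of ``sum lam_k chi2_1`` by numerical inversion
    of the characteristic function (Imhof's integral).

    The oscillatory tail (frequency t/2, slowly varying envelope) is
    integrated separately with quadrature weighted by sin/cos so the
    integral converges even for a single eigenvalue, where the envelope
    decays only like u^(-3/2).
    """
    lam = np.asarray(lam, dtype=float)

    def phi(u: float) -> float:
        return 0.5 * np.sum(np.arctan(lam * u))

    def envelope(u: float) -> float:
        return 1.0 / (u * np.prod((1 + (lam * u) ** 2) ** 0.25))

    def body(u: float) -> float:
        return np.sin(phi(u) - 0.5 * t * u) * envelope(u)

    cut = 30.0 / lam.min()
    head, _ = integrate.quad(body, 0, cut, limit=500)
    if t > 0:
        # sin(phi - tu/2) = sin(phi) cos(tu/2) - cos(phi) sin(tu/2)
        i_cos, _ = integrate.quad(
            lambda u: np.sin(phi(u)) * envelope(u), cut, np.inf,
            weight="cos", wvar=0.5 * t, limit=500,
        )
        i_sin, _ = integrate.quad(
            lambda u: np.cos(phi(u)) * envelope(u), cut, np.inf,
            weight="sin", wvar=0.5 * t, limit=500,
        )
        tail = i_cos - i_sin
    else:
        tail, _ = integrate.quad(body, cut, np.inf, limit=500)
    return float(min(max(0.5 + (head + tail) / np.pi, 0.0), 1.0))


def ssup(score: ScoreStat, method: str = "liu") -> TestResult:
    """Sum-of-squared-scores test ``SSUP = U U^T`` on the prospective score.

    The null law is the eigenvalue-weighted mixture ``sum lam_k chi2_1``;
    the tail is evaluated by moment matching (``method='liu'``, default) or
    by exact characteristic-function inversion (``method='imhof'``).
    """
    if score.coding != CODING_ADDITIVE:
        raise ValueError("ssup is defined on the additive prospective score")
    statistic = float(score.u @ score.u)
    lam, _ = _eigh_desc(score.v)
    lam = lam[_retained(lam)]
    if method == "liu":
        p = _liu_pvalue(statistic, lam)
    elif method == "imhof":
        p = _imhof_pvalue(statistic, lam)
    else:
        raise ValueError(f"unknown ssup method {method!r}")
    return TestResult("SSUP", statistic, None, p, {"n_eigenvalues": lam.size})


def gold_test(
    data: GenotypeDataset, causal: int | str, coding: str = "additive"
) -> TestResult:
    """Oracle 1-df chi-squared score test on the causal column only.

    ``coding`` enters the causal SNP under its true genetic model
    (additive / dominant / recessive), as the oracle knows it.
    """
    sc = gold_score(data, causal, coding=coding)
    statistic = float(sc.u[0] ** 2 / sc.v[0, 0])
    return TestResult(
        "GOLD", statistic, 1, float(stats.chi2.sf(statistic, 1)), {"coding": coding}
    )


class MultiTest:
    """Shared machinery for the test battery on one dataset.

    Computes both score systems (additive prospective and empirical-Bayes
    codominant) with their eigendecompositions once, exposes the asymptotic
    tests, and runs the Min2 label permutation on precomputed projections.
    All pooled quantities (allele frequencies, shrinkage weights, both
    covariances, eigenvectors, component counts) are label-invariant, so a
    permutation only changes which rows enter the case sums.
    """

    def __init__(self, data: GenotypeDataset, threshold: float = 0.85):
        self.data = data
        self.threshold = threshold
        y = data.phenotype.astype(float)
        self.ybar = y.mean()
        yc = y - self.ybar

        # additive prospective system
        g = data.genotypes.astype(float)
        gc = g - g.mean(axis=0)
        self._u_p = gc.T @ yc
        v_p = self.ybar * (1 - self.ybar) * (gc.T @ gc)
        lam_p, vec_p = _eigh_desc(v_p)
        self.s_p = select_components(lam_p, threshold)
        self._lam_p = lam_p
        # n x s projection: row i maps a label vector to the standardized
        # component scores (U xi_k) / sqrt(lambda_k)
        self._proj_p = gc @ vec_p[:, : self.s_p] / np.sqrt(lam_p[: self.s_p])

        # empirical-Bayes codominant system
        x = codominant_code(data).astype(float)
        centers, _ = _eb_centers(data, None)
        self._xc_b = x - centers
        v_b = eb_covariance(data)
        lam_b, vec_b = _eigh_desc(v_b)
        lam_b = np.clip(lam_b, 0.0, None)
        self.s_b = select_components(lam_b, threshold)
        self._lam_b = lam_b
        self._rank_b = int(_retained(lam_b).sum())
        self._proj_b = self._xc_b @ vec_b[:, : self._rank_b] / np.sqrt(lam_b[: self._rank_b])

        self._y = y
        self._yc = yc

    # --- asymptotic tests -------------------------------------------------
    def pchip(self) -> TestResult:
        stat = float(np.sum((self._yc @ self._proj_p) ** 2))
        return TestResult(
            "PChiP", stat, self.s_p, float(stats.chi2.sf(stat, self.s_p)), {"s": self.s_p}
        )

    def pchib(self) -> TestResult:
        z = self._y @ self._proj_b[:, : self.s_b]
        stat = float(np.sum(z**2))
        return TestResult(
            "PChiB", stat, self.s_b, float(stats.chi2.sf(stat, self.s_b)), {"s": self.s_b}
        )

    def t2(self) -> TestResult:
        z = self._y @ self._proj_b
        stat = float(np.sum(z**2))
        return TestResult(
            "T2", stat, self._rank_b, float(stats.chi2.sf(stat, self._rank_b)),
            {"retained_rank": self._rank_b},
        )

    def ssup(self, method: str = "liu") -> TestResult:
        stat = float(self._u_p @ self._u_p)
        lam = self._lam_p[_retained(self._lam_p)]
        p = _liu_pvalue(stat, lam) if method == "liu" else _imhof_pvalue(stat, lam)
        return TestResult("SSUP", stat, None, p, {"n_eigenvalues": lam.size})

    # --- Min2 -------------------------------------------------------------
    def min2(self, n_perm: int = 200, rng: np.random.Generator | None = None) -> TestResult:
        """Min of the PChiP and PChiB p-values, permutation-calibrated.

        Each permutation shuffles the case-control labels and recomputes
        both asymptotic p-values on the fixed pooled projections; the
        reported p-value is the add-one estimator
        ``(1 + #{perm minp <= observed minp}) / (n_perm + 1)``.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if rng is None:
            rng = np.random.default_rng()
        p_obs_p = self.pchip().p_value
        p_obs_b = self.pchib().p_value
        observed = min(p_obs_p, p_obs_b)

        labels = rng.permuted(np.tile(self._y, (n_perm, 1)), axis=1)
        z_p = (labels - self.ybar) @ self._proj_p
        z_b = labels @ self._proj_b[:, : self.s_b]
        pp = stats.chi2.sf(np.sum(z_p**2, axis=1), self.s_p)
        pb = stats.chi2.sf(np.sum(z_b**2, axis=1), self.s_b)
        perm_min = np.minimum(pp, pb)
        p = (1 + int(np.sum(perm_min <= observed))) / (n_perm + 1)
        return TestResult(
            "Min2",
            observed,
            None,
            p,
            {
                "n_perm": n_perm,
                "p_pchip": p_obs_p,
                "p_pchib": p_obs_b,
                "s_pchip": self.s_p,
                "s_pchib": self.s_b,
            },
        )


def min2(
    data: GenotypeDataset,
    threshold: float = 0.85,
    n_perm: int = 200,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Permutation-calibrated minimum of the PChiP and PChiB p-values."""
    return MultiTest(data, threshold).min2(n_perm=n_perm, rng=rng)
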