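"""Dependence-corrected Fisher combination of per-source p-values and q-values.

Fisher's statistic X = sum_i -2 ln p_i follows chi^2 with 2k degrees of
freedom only when the k tests are independent.  The per-source association
scores here share both the phenotype-similarity response and correlated
genomic measurements, so X is instead approximated by a scaled chi-squared
r * chi^2_v whose scale and degrees of freedom are matched to the first two
moments of X:

    r_hat = (1 / 4k) * sum_ij cov(V_i, V_j),    v_hat = 2k / r_hat,

with cov(V_i, V_i) = 4 and the cross covariances obtained from a quartic
polynomial in a bias-corrected ("shrunk") correlation of the
probit-transformed scores Z_i = Phi^{-1}(1 - p_i).  With all correlations
zero the correction reduces exactly to plain Fisher.  Combined p-values
over a candidate list are converted to Storey q-values controlling the
positive false discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .scoring import P_CEIL, P_FLOOR

# covariance polynomial coefficients for cov(V_i, V_j) in the shrunk
# correlation; the n-dependent quartic term vanishes for large samples
A1 = 3.263119
A2 = 0.709866
A3 = 0.026589
A4_NUM = -0.709866  # a4 = A4_NUM / n


def clip_p(p):
    """Clip p-values into [1e-300, 1 - 1e-16] before logs/probits."""
    return np.clip(np.asarray(p, dtype=float), P_FLOOR, P_CEIL)


def fisher_statistic(pvals) -> float:
    """X = sum of -2 ln p_i over the supplied p-values."""
    p = clip_p(pvals)
    if p.size == 0:
        raise InputError("empty p-value vector")
    return float(-2.0 * np.log(p).sum())


def shrink_correlation(rho_hat: float, n_corr: int) -> float:
    """Bias-corrected correlation rho * (1 + (1 - rho^2) / (2 (n - 1)))."""
    if n_corr < 2:
        raise InputError("correlation shrinkage needs n >= 2")
    rho_hat = float(rho_hat)
    if abs(rho_hat) > 1 + 1e-12:
        raise InputError("|rho| must be <= 1")
    rho_hat = float(np.clip(rho_hat, -1.0, 1.0))
    out = rho_hat * (1.0 + (1.0 - rho_hat**2) / (2.0 * (n_corr - 1)))
    return float(np.clip(out, -1.0, 1.0))


def cov_vi_vj(rho_tilde: float, n_corr: int) -> float:
    """Covariance of V_i = -2 ln p_i terms as a quartic in the shrunk correlation."""
    r = float(rho_tilde)
    if abs(r) > 1 + 1e-12:
        raise InputError("|rho_tilde| must be <= 1")
    a4 = A4_NUM / n_corr
    return A1 * r + A2 * r**2 + A3 * r**3 + a4 * r**4


@dataclass
class SourceCorrelation:
    """Estimated correlation structure of probit scores across sources."""

    labels: tuple[str, ...]
    rho_hat: np.ndarray
    n_corr: int

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.rho_hat = np.asarray(self.rho_hat, dtype=float)
        k = len(self.labels)
        if self.rho_hat.shape != (k, k):
            raise InputError("correlation matrix shape mismatch")
        if not np.allclose(self.rho_hat, self.rho_hat.T, atol=1e-10):
            raise InputError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.rho_hat), 1.0):
            raise InputError("correlation matrix must have unit diagonal")
        if np.abs(self.rho_hat).max() > 1 + 1e-12:
            raise InputError("correlations must lie in [-1, 1]")
        if self.n_corr < 2:
            raise InputError("n_corr must be >= 2")

    @classmethod
    def independent(cls, labels, n_corr: int = 10**9) -> "SourceCorrelation":
        k = len(labels)
        return cls(labels=tuple(labels), rho_hat=np.eye(k), n_corr=n_corr)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def scaled_chi2_params(corr: SourceCorrelation, available) -> tuple[float, float]:
    """Moment-matched (r_hat, v_hat) for the available subset of sources.

    The double sum over the k x k covariance block uses cov(V_i, V_i) = 4 on
    the diagonal; a non-positive r_hat (pathological negative covariances)
    falls back to independence with a warning.
    """
    avail = list(available)
    if not avail:
        raise InputError("no available sources")
    idx = [corr.index(s) for s in avail]
    k = len(idx)
    total = 4.0 * k
    for a in range(k):
        for b in range(a + 1, k):
            rho_t = shrink_correlation(corr.rho_hat[idx[a], idx[b]], corr.n_corr)
            total += 2.0 * cov_vi_vj(rho_t, corr.n_corr)
    r_hat = total / (4.0 * k)
    if r_hat <= 0.0:
        warnings.warn("non-positive r_hat estimate; falling back to independence",
                      stacklevel=2)
        r_hat = 1.0
    return float(r_hat), float(2.0 * k / r_hat)


def combine(pvals: dict, corr: SourceCorrelation) -> tuple[float, float, float, float]:
    """Combine available per-source p-values into one.

    ``pvals`` maps source name -> p-value, with ``None``/NaN marking a
    missing source; missing sources are dropped and k reduced accordingly.
    Returns ``(X_stat, r_hat, v_hat, combined_p)`` with
    ``combined_p = P(chi^2_{v_hat} >= X / r_hat)``, never exactly 0.
    """
    avail = {s: p for s, p in pvals.items()
             if p is not None and np.isfinite(p)}
    if not avail:
        raise InputError("all sources missing")
    x = fisher_statistic(list(avail.values()))
    r_hat, v_hat = scaled_chi2_params(corr, avail.keys())
    p = float(stats.chi2.sf(x / r_hat, df=v_hat))
    return x, r_hat, v_hat, float(np.clip(p, P_FLOOR, 1.0))


def estimate_source_correlation(score_table: pd.DataFrame,
                                min_overlap: int = 30) -> SourceCorrelation:
    """Correlation of probit-transformed scores across source columns.

    ``score_table`` holds calibrated p-values (rows = disease-gene pairs,
    columns = sources; NaN = source missing for that pair).  Scores are
    probit-transformed as Z = Phi^{-1}(1 - p) and correlated pairwise-
    complete; pairs with fewer than ``min_overlap`` complete observations
    fall back to 0 (independence) with a warning.  ``n_corr`` is the
    minimum pairwise-complete count among retained pairs.
    """
    if score_table.shape[1] < 1:
        raise InputError("score table needs at least one source column")
    Z = pd.DataFrame(stats.norm.isf(clip_p(score_table.to_numpy())),
                     columns=score_table.columns)
    Z = Z.mask(score_table.isna().to_numpy())
    labels = tuple(str(c) for c in score_table.columns)
    k = len(labels)
    rho = np.eye(k)
    notna = Z.notna().to_numpy().astype(float)
    counts = notna.T @ notna
    n_corr = None
    corr_full = Z.corr(min_periods=min_overlap).to_numpy()
    for a in range(k):
        for b in range(a + 1, k):
            c = counts[a, b]
            if c < min_overlap or not np.isfinite(corr_full[a, b]):
                warnings.warn(
                    f"insufficient overlap ({int(c)}) between sources "
                    f"{labels[a]!r} and {labels[b]!r}; assuming independence",
                    stacklevel=2,
                )
                rho[a, b] = rho[b, a] = 0.0
            else:
                rho[a, b] = rho[b, a] = float(np.clip(corr_full[a, b], -1.0, 1.0))
                n_corr = c if n_corr is None else min(n_corr, c)
    if n_corr is None:  # single source or no usable pair
        n_corr = max(int(counts.max()), 2)
    return SourceCorrelation(labels=labels, rho_hat=rho, n_corr=int(n_corr))


def qvalues(pvals, lambda_: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values controlling the positive false discovery rate.

    pi0 is estimated at a single fixed lambda (default 0.5) as
    ``#{p > lambda} / ((1 - lambda) m)`` clipped into (0, 1]; with
    ``pi0=1`` the result equals Benjamini-Hochberg adjusted p-values.
    Order-preserving: p_a <= p_b implies q_a <= q_b.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if p.min() < 0 or p.max() > 1:
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = np.sum(p > lambda_) / ((1.0 - lambda_) * m)
        pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    elif not (0.0 < pi0 <= 1.0):
        raise InputError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, P_FLOOR, 1.0)
    return q
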