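"""Per-source association scoring between a query disease and a candidate gene.

For one genomic data source with final gene similarities ``phi``, the
strength of association between a query disease ``d`` and a candidate gene
``g`` is assessed by regressing phenotype similarity on genotype similarity
across the reference diseases:

    Y_i = alpha + beta * x_i + eps_i,    x_i = sum_{k in I_i} phi(g, k),

where ``I_i`` is the set of genes annotated to reference disease ``i`` and
``Y_i`` the phenotype similarity between ``d`` and disease ``i``.  The
candidate is treated as if it were the only gene associated with the query,
so no prior knowledge about the query's genetics is required.  A one-sided
t-test of H0: beta = 0 against H1: beta > 0 (t with n-2 degrees of freedom)
yields a raw p-value, which is then calibrated against an empirical null
distribution of raw p-values over non-associated disease-gene pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationUnavailableError, DegeneratePredictorError, InputError
from .similarity import SimilarityMatrix

# p-values are clipped to this range before any log/probit transform
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16

#: disease id -> set of associated gene ids
AssociationMap = dict


@dataclass(frozen=True)
class SourceScore:
    """Association score of one candidate gene under one data source."""

    gene: str
    source: str
    beta_hat: float
    t_stat: float
    raw_p: float
    calibrated_p: float
    n_used: int


def clean_associations(assoc: AssociationMap, diseases=None, genes=None) -> tuple[AssociationMap, int]:
    """Drop unresolvable ids and empty gene sets; return (map, n_dropped)."""
    out: AssociationMap = {}
    dropped = 0
    diseases = None if diseases is None else set(diseases)
    genes = None if genes is None else set(genes)
    for d, gs in assoc.items():
        if diseases is not None and d not in diseases:
            dropped += len(gs)
            continue
        kept = set(gs) if genes is None else set(gs) & genes
        dropped += len(gs) - len(kept)
        if kept:
            out[d] = kept
    return out, dropped


def _annotated_references(assoc: AssociationMap, phenotype: SimilarityMatrix,
                          query_disease: str) -> list[str]:
    """Reference diseases: all annotated diseases in the phenotype matrix
    other than the query (its own annotations are never used)."""
    return [d for d in phenotype.labels if d != query_disease and assoc.get(d)]


def genotype_vector(query_gene: str, reference_diseases, assoc: AssociationMap,
                    phi: SimilarityMatrix) -> np.ndarray:
    """x_i = sum of phi(query_gene, k) over genes k annotated to disease i.

    Genes absent from the source matrix and entries flagged missing are
    skipped (they contribute nothing rather than a fabricated 0 - the two
    coincide numerically, but missing entries are not evidence).
    """
    gi = phi.index(query_gene)
    row = phi.values[gi]
    mask = None if phi.missing is None else phi.missing[gi]
    x = np.zeros(len(reference_diseases))
    for j, d in enumerate(reference_diseases):
        genes = assoc.get(d)
        if not genes:
            raise InputError(f"reference disease {d!r} has no annotated genes")
        s = 0.0
        for k in genes:
            if k not in phi:
                continue
            ki = phi.index(k)
            if mask is not None and mask[ki]:
                continue
            s += row[ki]
        x[j] = s
    return x


def genotype_matrix(query_genes, reference_diseases, assoc: AssociationMap,
                    phi: SimilarityMatrix) -> np.ndarray:
    """Vectorized :func:`genotype_vector`: shape (n_diseases, n_genes).

    Column j holds the genotype-similarity vector of ``query_genes[j]``.
    """
    gene_idx = np.array([phi.index(g) for g in query_genes])
    n_d = len(reference_diseases)
    A = np.zeros((n_d, phi.n))  # disease x gene indicator of annotations
    for i, d in enumerate(reference_diseases):
        genes = assoc.get(d)
        if not genes:
            raise InputError(f"reference disease {d!r} has no annotated genes")
        for k in genes:
            if k in phi:
                A[i, phi.index(k)] = 1.0
    V = phi.values if phi.missing is None else np.where(phi.missing, 0.0, phi.values)
    return A @ V[:, gene_idx]


def pair_genotype_similarity(D, E, phi: SimilarityMatrix) -> float:
    """x_de = sum over g in D, h in E of phi(g, h) (cross pairs, g=h allowed)."""
    gi = [phi.index(g) for g in D if g in phi]
    hi = [phi.index(h) for h in E if h in phi]
    if not gi or not hi:
        raise InputError("no resolvable genes in one of the sets")
    block = phi.values[np.ix_(gi, hi)]
    if phi.missing is not None:
        m = phi.missing[np.ix_(gi, hi)]
        if m.all():
            raise InputError("all cross pairs missing")
        block = np.where(m, 0.0, block)
    return float(block.sum())


def slope_test(x, y) -> tuple[float, float, float]:
    """Closed-form OLS slope with one-sided t-test of H1: beta > 0.

    Returns ``(beta_hat, t_stat, raw_p)`` with
    ``raw_p = P(T_{n-2} >= t)``.  The residual variance estimate is
    ``S^2 = RSS / (n - 2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise InputError("slope test needs n >= 3")
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0.0:
        raise DegeneratePredictorError("predictor has zero variance")
    yc = y - y.mean()
    sxy = float(np.dot(xc, yc))
    beta = sxy / sxx
    rss = float(np.dot(yc, yc)) - beta * sxy
    s2 = max(rss, 0.0) / (n - 2)
    if s2 == 0.0:
        # perfect fit: p underflows to the smallest representable positive
        t = np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0)
    else:
        t = beta / np.sqrt(s2 / sxx)
    p = float(stats.t.sf(t, df=n - 2))
    return float(beta), float(t), float(np.clip(p, P_FLOOR, P_CEIL))


def slope_test_batch(X: np.ndarray, y: np.ndarray):
    """One-sided slope test for every column of ``X`` against the same ``y``.

    Returns ``(beta, t, p)`` arrays; columns with zero predictor variance
    get NaN in all three.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise InputError("slope test needs n >= 3")
    Xc = X - X.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.maximum(float(np.dot(yc, yc)) - beta * sxy, 0.0)
        s2 = rss / (n - 2)
        t = beta / np.sqrt(s2 / sxx)
    t = np.where((s2 == 0.0) & (sxx > 0), np.sign(beta) * np.inf, t)
    p = stats.t.sf(t, df=n - 2)
    bad = sxx == 0.0
    beta[bad] = np.nan
    t[bad] = np.nan
    p = np.clip(p, P_FLOOR, P_CEIL)
    p[bad] = np.nan
    return beta, t, p


def calibrate_p(raw_p, null_raw_ps) -> float | np.ndarray:
    """Empirical p-value of ``raw_p`` within a null sample of raw p-values.

    Add-one smoothed rank: ``(#{null <= p} + 1) / (M + 1)``, strictly
    positive and monotone in ``raw_p``.  Accepts scalars or arrays.
    """
    null = np.sort(np.asarray(null_raw_ps, dtype=float))
    if null.size == 0:
        raise CalibrationUnavailableError("empty null sample")
    if null.min() < 0 or null.max() > 1:
        raise InputError("null p-values must lie in [0, 1]")
    r = np.searchsorted(null, raw_p, side="right")
    out = (r + 1) / (null.size + 1)
    return float(out) if np.isscalar(raw_p) else np.asarray(out)


def sample_null_pairs(assoc: AssociationMap, phenotype: SimilarityMatrix,
                      genes, m_pairs: int, seed: int,
                      enumerate_all: bool = False) -> list[tuple[str, str]]:
    """Uniformly sample non-associated (disease, gene) pairs, seeded.

    Diseases are the annotated diseases of the phenotype matrix (they need
    a reference set); genes come from ``genes``.  Annotated pairs are
    excluded.  With ``enumerate_all`` the full eligible cross product is
    returned.
    """
    diseases = [d for d in phenotype.labels if assoc.get(d)]
    genes = list(genes)
    if not diseases or not genes:
        raise InputError("no eligible diseases or genes for the null sample")
    eligible = [(d, g) for d in diseases for g in genes if g not in assoc.get(d, ())]
    if enumerate_all:
        return eligible
    if m_pairs < 1:
        raise InputError("m_pairs must be >= 1")
    if len(eligible) <= m_pairs:
        if len(eligible) < m_pairs:
            warnings.warn(
                f"only {len(eligible)} eligible null pairs (< {m_pairs}); using all",
                stacklevel=2,
            )
        return eligible
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=m_pairs, replace=False)
    return [eligible[i] for i in idx]


def build_null_sample(assoc: AssociationMap, phenotype: SimilarityMatrix,
                      phi: SimilarityMatrix, m_pairs: int = 10_000,
                      seed: int = 0, enumerate_all: bool = False) -> np.ndarray:
    """Raw p-values of the slope test over sampled non-associated pairs.

    Uses exactly the query protocol of :func:`score_gene` for each sampled
    (disease, gene) pair; pairs whose gene is absent from the source or
    whose test is degenerate are dropped.
    """
    pairs = sample_null_pairs(assoc, phenotype, [g for g in phi.labels],
                              m_pairs, seed, enumerate_all)
    by_disease: dict[str, list[str]] = {}
    for d, g in pairs:
        by_disease.setdefault(d, []).append(g)
    out = []
    for d, gs in by_disease.items():
        refs = _annotated_references(assoc, phenotype, d)
        if len(refs) < 3:
            continue
        y = np.array([phenotype.loc(d, r) for r in refs])
        X = genotype_matrix(gs, refs, assoc, phi)
        _, _, p = slope_test_batch(X, y)
        out.append(p[~np.isnan(p)])
    if not out:
        raise InputError("no valid null p-values could be computed")
    return np.concatenate(out)


def score_genes(query_disease: str, genes, phenotype: SimilarityMatrix,
                phi: SimilarityMatrix, assoc: AssociationMap,
                null_sample=None) -> list[SourceScore | None]:
    """Score many candidate genes against one query under one source.

    Returns one :class:`SourceScore` per gene, or ``None`` where the gene is
    absent from the source matrix (a missing-source signal for the fusion
    step) or the test is degenerate.
    """
    if query_disease not in phenotype:
        raise InputError(f"query disease {query_disease!r} not in phenotype matrix")
    refs = _annotated_references(assoc, phenotype, query_disease)
    if len(refs) < 3:
        raise InputError("need at least 3 annotated reference diseases")
    y = np.array([phenotype.loc(query_disease, r) for r in refs])
    present = [g for g in genes if g in phi]
    results: dict[str, SourceScore] = {}
    if present:
        X = genotype_matrix(present, refs, assoc, phi)
        beta, t, p = slope_test_batch(X, y)
        if null_sample is not None and len(null_sample) > 0:
            null_sorted = np.sort(np.asarray(null_sample, dtype=float))
            cal = np.where(np.isnan(p), np.nan,
                           calibrate_p(np.nan_to_num(p, nan=1.0), null_sorted))
        else:
            cal = p  # calibration unavailable: raw p passed through
        for j, g in enumerate(present):
            if np.isnan(p[j]):
                continue
            results[g] = SourceScore(
                gene=g, source=phi.source, beta_hat=float(beta[j]),
                t_stat=float(t[j]), raw_p=float(p[j]),
                calibrated_p=float(cal[j]), n_used=len(refs),
            )
    return [results.get(g) for g in genes]


def score_gene(query_disease: str, gene: str, phenotype: SimilarityMatrix,
               phi: SimilarityMatrix, assoc: AssociationMap,
               null_sample=None) -> SourceScore | None:
    """Score one candidate gene; ``None`` signals a missing source."""
    return score_genes(query_disease, [gene], phenotype, phi, assoc, null_sample)[0]
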