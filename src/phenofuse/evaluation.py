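"""Validation harness: leave-one-out benchmarking, ranking metrics,
binned phenotype-genotype correlation, and enrichment testing.

Each leave-one-out run hides one annotated disease-gene association, ranks
the hidden (test) gene against a set of control genes - either the nearest
neighbours on its chromosome (emulating a linkage interval) or a random
draw from the genome - and records the test gene's rank.  Rank ratios
(rank / list size) are summarized as the mean rank ratio (MRR; lower is
better, 50% for a random ranker) and as the area under a rank-ROC curve
obtained by sweeping a rank-ratio threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .scoring import AssociationMap, pair_genotype_similarity
from .similarity import SimilarityMatrix


# ---------------------------------------------------------------------------
# control sets


def linkage_controls(test_gene: str, locations: pd.DataFrame, m: int = 99,
                     exclude=()) -> list[str]:
    """The m genes nearest the test gene on the same chromosome.

    ``locations`` is indexed by gene id with columns ``chrom`` and ``pos``.
    Distance is |pos - test pos|; ties are broken by smaller coordinate,
    then lexicographic gene id.  If the chromosome holds fewer than m
    eligible genes, all of them are returned.
    """
    if test_gene not in locations.index:
        raise InputError(f"no location for test gene {test_gene!r}")
    chrom = locations.at[test_gene, "chrom"]
    pos = int(locations.at[test_gene, "pos"])
    excl = set(exclude) | {test_gene}
    same = locations[(locations["chrom"] == chrom) & (~locations.index.isin(excl))]
    ranked = sorted(
        ((abs(int(p) - pos), int(p), str(g)) for g, p in same["pos"].items()),
    )
    return [g for _, _, g in ranked[:m]]


def random_controls(test_gene: str, genome, m: int = 99, seed: int = 0,
                    exclude=()) -> list[str]:
    """Uniform sample of m control genes from the genome, seeded.

    Never contains the test gene or anything in ``exclude``.
    """
    excl = set(exclude) | {test_gene}
    pool = sorted(g for g in genome if g not in excl)
    if len(pool) < m:
        raise InputError(f"genome too small for {m} controls")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=m, replace=False)
    return [pool[i] for i in idx]


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


@dataclass(frozen=True)
class ValidationRun:
    query_disease: str
    test_gene: str
    n_ranked: int  # test + control genes actually ranked
    rank: int      # 1-based rank of the test gene

    @property
    def rank_ratio(self) -> float:
        return self.rank / self.n_ranked


@dataclass
class ValidationSummary:
    runs: list[ValidationRun]
    n_excluded: int = 0
    top_ks: tuple[int, ...] = (1, 5, 10, 20)
    mrr: float = field(init=False)
    auc: float = field(init=False)
    top_k_counts: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.runs:
            raise InputError("no validation runs")
        self.mrr = mean_rank_ratio(self.runs)
        _, self.auc = rank_roc_auc(self.runs)
        self.top_k_counts = {k: sum(1 for r in self.runs if r.rank <= k)
                             for k in self.top_ks}

    def to_dict(self) -> dict:
        return {
            "n_runs": len(self.runs),
            "n_excluded": self.n_excluded,
            "MRR": self.mrr,
            "AUC": self.auc,
            "top_k": {str(k): v for k, v in self.top_k_counts.items()},
        }


def mean_rank_ratio(runs) -> float:
    """Arithmetic mean of rank ratios; 0.505 expected for a random ranker
    over lists of 100."""
    runs = list(runs)
    if not runs:
        raise InputError("no runs")
    return float(np.mean([r.rank_ratio for r in runs]))


def rank_roc_auc(runs):
    """Rank-ROC curve and its AUC.

    Sensitivity at threshold theta is the fraction of test genes with rank
    ratio <= theta; specificity is the fraction of control genes with rank
    ratio > theta.  Control rank ratios are every rank in a run except the
    test gene's.  The threshold sweeps all observed rank ratios plus the
    endpoints 0 and 1; the curve is integrated by the trapezoid rule.
    """
    runs = list(runs)
    if not runs:
        raise InputError("no runs")
    test_rr = np.array([r.rank_ratio for r in runs])
    ctrl = []
    for r in runs:
        ranks = np.delete(np.arange(1, r.n_ranked + 1), r.rank - 1)
        ctrl.append(ranks / r.n_ranked)
    ctrl_rr = np.concatenate(ctrl)
    thresholds = np.unique(np.concatenate([[0.0, 1.0], test_rr, ctrl_rr]))
    sens = np.array([(test_rr <= t).mean() for t in thresholds])
    spec = np.array([(ctrl_rr > t).mean() for t in thresholds])
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    curve = pd.DataFrame({"threshold": thresholds[order],
                          "fpr": fpr[order], "sensitivity": sens[order]})
    auc = float(np.trapezoid(curve["sensitivity"], curve["fpr"]))
    return curve, auc


def expected_random_topk(n_runs: int, list_size: int, k: int) -> float:
    """Expected number of test genes in the top k under random ranking."""
    if not (1 <= k <= list_size):
        raise InputError("need 1 <= k <= list_size")
    return n_runs * k / list_size


def loocv(assoc: AssociationMap, prioritizer, control_mode: str = "random",
          locations: pd.DataFrame | None = None, genome=None, m: int = 99,
          seed: int = 0, top_ks=(1, 5, 10, 20)) -> ValidationSummary:
    """Leave-one-out cross-validation over every annotated association.

    ``prioritizer`` must expose ``prioritize(query_disease, candidates)``
    returning a DataFrame indexed by gene with a ``rank`` column (the
    scoring protocol itself never uses the query's own annotations, so
    hiding the test association is inherent).  Controls exclude the test
    gene and every gene annotated to the query disease.  Runs whose test
    gene is scoreable under no source are excluded and counted.
    """
    if control_mode not in ("random", "linkage"):
        raise InputError(f"unknown control mode {control_mode!r}")
    if control_mode == "linkage" and locations is None:
        raise InputError("linkage controls need gene locations")
    if control_mode == "random" and genome is None:
        raise InputError("random controls need a genome gene list")
    pairs = sorted((d, g) for d, gs in assoc.items() for g in gs)
    rng = np.random.default_rng(seed)
    runs: list[ValidationRun] = []
    excluded = 0
    for d, g in pairs:
        annotated = assoc.get(d, set())
        try:
            if control_mode == "linkage":
                controls = linkage_controls(g, locations, m=m, exclude=annotated)
            else:
                controls = random_controls(
                    g, genome, m=m, seed=int(rng.integers(2**31)), exclude=annotated)
            ranking = prioritizer.prioritize(d, [g] + controls)
        except (InputError, KeyError):
            excluded += 1
            continue
        if g not in ranking.index:
            excluded += 1
            continue
        runs.append(ValidationRun(query_disease=d, test_gene=g,
                                  n_ranked=len(ranking),
                                  rank=int(ranking.at[g, "rank"])))
    if not runs:
        raise InputError("every validation run was excluded")
    return ValidationSummary(runs=runs, n_excluded=excluded, top_ks=tuple(top_ks))


# ---------------------------------------------------------------------------
# binned phenotype-genotype correlation


@dataclass
class BinnedCorrelation:
    bin_edges: np.ndarray
    mean_phenotype: np.ndarray   # NaN for empty bins
    mean_genotype: np.ndarray
    counts: np.ndarray
    pearson_r: float
    r_pvalue: float


def bin_correlation(phenotype: SimilarityMatrix, assoc: AssociationMap,
                    phi: SimilarityMatrix, bins: int = 10) -> BinnedCorrelation:
    """Correlation of binned phenotype vs genotype similarity.

    Every unordered pair of annotated diseases contributes one phenotype
    similarity (binned into equal-width bins on [0, 1], last bin closed)
    and one genotype similarity (sum of gene similarities over the cross
    product of the two diseases' gene sets).  Pearson's r is computed over
    the per-bin means of the two quantities; empty bins are dropped with a
    warning via NaN means.
    """
    diseases = [d for d in phenotype.labels if assoc.get(d)]
    if len(diseases) < 2:
        raise InputError("need at least 2 annotated diseases")
    n_d = len(diseases)
    # genotype similarity for all pairs at once: X = A Phi A^T over indicator A
    A = np.zeros((n_d, phi.n))
    for i, d in enumerate(diseases):
        for g in assoc[d]:
            if g in phi:
                A[i, phi.index(g)] = 1.0
    V = phi.values if phi.missing is None else np.where(phi.missing, 0.0, phi.values)
    G = A @ V @ A.T
    pidx = [phenotype.index(d) for d in diseases]
    P = phenotype.values[np.ix_(pidx, pidx)]
    iu = np.triu_indices(n_d, k=1)
    pheno = P[iu]
    geno = G[iu]
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(pheno, edges[1:-1], right=False), 0, bins - 1)
    counts = np.bincount(which, minlength=bins)
    mean_p = np.full(bins, np.nan)
    mean_g = np.full(bins, np.nan)
    for b in range(bins):
        sel = which == b
        if sel.any():
            mean_p[b] = pheno[sel].mean()
            mean_g[b] = geno[sel].mean()
    ok = ~np.isnan(mean_p)
    if ok.sum() < 3:
        raise InputError("fewer than 3 non-empty bins")
    r, pval = stats.pearsonr(mean_p[ok], mean_g[ok])
    return BinnedCorrelation(bin_edges=edges, mean_phenotype=mean_p,
                             mean_genotype=mean_g, counts=counts,
                             pearson_r=float(r), r_pvalue=float(pval))


# ---------------------------------------------------------------------------
# enrichment


def hypergeom_enrichment(N: int, K: int, n: int, x: int) -> float:
    """One-sided Fisher's exact test: P(X >= x) for X ~ Hypergeom(N, K, n).

    N candidates of which K are functional; n drawn (e.g. the top-n ranked
    genes) of which x are functional.
    """
    if not (0 <= x <= min(n, K) and 0 < n <= N and 0 <= K <= N):
        raise InputError(f"inconsistent counts N={N}, K={K}, n={n}, x={x}")
    return float(stats.hypergeom.sf(x - 1, N, K, n))
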