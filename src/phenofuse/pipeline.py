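"""End-to-end prioritization: scoring -> calibration -> fusion -> q-values.

The :class:`Prioritizer` wires the per-source regression scores, the
empirical null calibration, the cross-source correlation estimate and the
dependence-corrected combination into a single object that ranks a list of
candidate genes for a query disease.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .fusion import (
    SourceCorrelation,
    combine,
    estimate_source_correlation,
    fisher_statistic,
    qvalues,
    scaled_chi2_params,
)
from .scoring import (
    AssociationMap,
    _annotated_references,
    calibrate_p,
    genotype_matrix,
    sample_null_pairs,
    slope_test_batch,
)
from .similarity import SimilarityMatrix


class Prioritizer:
    """Rank candidate genes for a query disease across genomic sources.

    On construction, a seeded grid of non-associated (disease, gene) pairs
    is scored under every source to provide (a) the per-source null
    distributions used for empirical p-value calibration and (b) a
    consistent background sample for estimating the cross-source
    correlation of probit scores.  The same grid serves both purposes so
    the dependence correction and the calibration refer to one background.

    Parameters
    ----------
    phenotype
        Disease-disease phenotype similarity matrix.
    sources
        Mapping source name -> transformed gene similarity matrix.
    assoc
        Disease id -> set of associated gene ids.
    null_size
        Number of non-associated pairs in the calibration grid.
    seed
        Seed for sampling the grid.
    lambda_
        Storey pi0 tuning parameter for q-values.
    """

    def __init__(self, phenotype: SimilarityMatrix, sources: dict[str, SimilarityMatrix],
                 assoc: AssociationMap, *, null_size: int = 2000, seed: int = 0,
                 lambda_: float = 0.5, min_overlap: int = 30,
                 corr: SourceCorrelation | None = None):
        if not sources:
            raise InputError("need at least one gene similarity source")
        self.phenotype = phenotype
        self.sources = dict(sources)
        self.assoc = {d: set(g) for d, g in assoc.items() if g}
        self.lambda_ = lambda_
        self.seed = seed
        self._fit_null_grid(null_size, seed, min_overlap, corr)
        self._params_cache: dict[frozenset, tuple[float, float]] = {}

    # -- background grid -------------------------------------------------

    def _fit_null_grid(self, null_size, seed, min_overlap, corr) -> None:
        all_genes = sorted(set().union(*(set(m.labels) for m in self.sources.values())))
        pairs = sample_null_pairs(self.assoc, self.phenotype, all_genes,
                                  null_size, seed)
        raw = pd.DataFrame(np.nan, index=range(len(pairs)),
                           columns=list(self.sources))
        pair_index = {p: i for i, p in enumerate(pairs)}
        by_disease: dict[str, list[str]] = {}
        for d, g in pairs:
            by_disease.setdefault(d, []).append(g)
        for name, phi in self.sources.items():
            for d, gs in by_disease.items():
                present = [g for g in gs if g in phi]
                if not present:
                    continue
                refs = _annotated_references(self.assoc, self.phenotype, d)
                if len(refs) < 3:
                    continue
                y = np.array([self.phenotype.loc(d, r) for r in refs])
                X = genotype_matrix(present, refs, self.assoc, phi)
                _, _, p = slope_test_batch(X, y)
                rows = [pair_index[(d, g)] for g in present]
                raw.loc[rows, name] = p
        self.null_raw: dict[str, np.ndarray] = {}
        cal = raw.copy()
        for name in self.sources:
            col = raw[name].to_numpy()
            vals = np.sort(col[~np.isnan(col)])
            if vals.size == 0:
                raise InputError(f"no null p-values for source {name!r}")
            self.null_raw[name] = vals
            mask = ~np.isnan(col)
            cal.loc[mask, name] = calibrate_p(col[mask], vals)
        self.null_calibrated = cal
        self.correlation = corr if corr is not None else estimate_source_correlation(
            cal, min_overlap=min_overlap)

    def _chi2_params(self, available: frozenset) -> tuple[float, float]:
        if available not in self._params_cache:
            self._params_cache[available] = scaled_chi2_params(
                self.correlation, sorted(available))
        return self._params_cache[available]

    # -- scoring ---------------------------------------------------------

    def score_table(self, query_disease: str, candidate_genes) -> pd.DataFrame:
        """Calibrated p-value per (candidate gene, source); NaN = missing."""
        genes = list(dict.fromkeys(candidate_genes))
        if query_disease not in self.phenotype:
            raise InputError(f"query disease {query_disease!r} not in phenotype matrix")
        refs = _annotated_references(self.assoc, self.phenotype, query_disease)
        if len(refs) < 3:
            raise InputError("need at least 3 annotated reference diseases")
        y = np.array([self.phenotype.loc(query_disease, r) for r in refs])
        out = pd.DataFrame(np.nan, index=genes, columns=list(self.sources))
        for name, phi in self.sources.items():
            present = [g for g in genes if g in phi]
            if not present:
                continue
            X = genotype_matrix(present, refs, self.assoc, phi)
            _, _, p = slope_test_batch(X, y)
            ok = ~np.isnan(p)
            cal = np.full(len(present), np.nan)
            cal[ok] = calibrate_p(p[ok], self.null_raw[name])
            out.loc[present, name] = cal
        return out

    def prioritize(self, query_disease: str, candidate_genes) -> pd.DataFrame:
        """Full ranking of candidate genes for one query disease.

        Returns a DataFrame indexed by gene with columns
        ``k_used, X, r_hat, v_hat, p, q, rank``; genes scoreable under no
        source are excluded.  Ties are broken deterministically by
        (q, p, gene id).
        """
        table = self.score_table(query_disease, candidate_genes)
        rows = []
        for gene, row in table.iterrows():
            avail = {s: row[s] for s in table.columns if np.isfinite(row[s])}
            if not avail:
                continue
            x, r_hat, v_hat = self._combine_stats(avail)
            p = float(np.clip(stats.chi2.sf(x / r_hat, df=v_hat), 1e-300, 1.0))
            rows.append((gene, len(avail), x, r_hat, v_hat, p))
        if not rows:
            raise InputError("no candidate gene scoreable under any source")
        df = pd.DataFrame(rows, columns=["gene", "k_used", "X", "r_hat", "v_hat", "p"])
        df["q"] = qvalues(df["p"].to_numpy(), lambda_=self.lambda_)
        df = df.sort_values(["q", "p", "gene"], kind="stable").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df.set_index("gene")

    def _combine_stats(self, avail: dict) -> tuple[float, float, float]:
        x = fisher_statistic(list(avail.values()))
        r_hat, v_hat = self._chi2_params(frozenset(avail))
        return x, r_hat, v_hat

    def combine_row(self, pvals: dict) -> tuple[float, float, float, float]:
        """Dependence-corrected combination using the fitted correlation."""
        return combine(pvals, self.correlation)
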