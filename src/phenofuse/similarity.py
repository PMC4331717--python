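"""Construction of pairwise similarity matrices from profiles and networks.

Every genomic data source is reduced to the same currency: a labeled,
symmetric matrix of pairwise similarity scores in [0, 1].  Profile-based
sources (expression vectors, annotation/information-content vectors, binary
membership vectors, binding-site counts) use cosine similarity or the
absolute Pearson correlation; network-based sources (sequence-similarity and
protein-interaction graphs) use a shortest-path distance rescaled to [0, 1].
Raw scores ``w`` are then sharpened by the exponential transform

    phi = exp(-((1 - w) / sigma)**2),

where ``sigma`` defaults to the standard deviation of the raw scores over
all distinct pairs.  The transform keeps a perfect raw score at 1 while
pushing the bulk of weak scores towards 0, which suppresses background noise
in the raw measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    DegenerateDispersionError,
    InputError,
    UndefinedSimilarityError,
)

SYMMETRY_RTOL = 1e-10


@dataclass
class SimilarityMatrix:
    """Labeled symmetric matrix of pairwise similarity scores in [0, 1].

    Parameters
    ----------
    labels
        Ordered entity identifiers (genes or diseases).
    values
        Square float array, ``values[i, j]`` = similarity of ``labels[i]``
        and ``labels[j]``.
    kind
        ``"raw"`` for untransformed scores ``w`` or ``"transformed"`` for
        final scores ``phi``.
    source
        Name of the data source the matrix was derived from.
    missing
        Optional boolean mask marking entries whose similarity is undefined
        (zero-norm profile, disconnected network pair).  Missing entries are
        excluded from sigma estimation and from genotype-similarity sums.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "raw"
    source: str = ""
    missing: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InputError("similarity matrix must be square")
        if len(self.labels) != self.values.shape[0]:
            raise InputError("label count does not match matrix dimension")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("duplicate labels in similarity matrix")
        if self.kind not in ("raw", "transformed"):
            raise InputError(f"unknown matrix kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, rtol=SYMMETRY_RTOL, atol=1e-12):
            raise InputError("similarity matrix is not symmetric within tolerance")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise InputError("similarity entries must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise InputError("missing mask shape mismatch")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"label {label!r} not in similarity matrix") from None

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels) -> "SimilarityMatrix":
        idx = np.array([self.index(l) for l in labels])
        return SimilarityMatrix(
            labels=tuple(labels),
            values=self.values[np.ix_(idx, idx)].copy(),
            kind=self.kind,
            source=self.source,
            missing=None if self.missing is None else self.missing[np.ix_(idx, idx)].copy(),
        )


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative profile vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("profile vectors differ in length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def abs_pearson(a, b) -> float:
    """Absolute Pearson correlation of two profile vectors (length >= 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("profile vectors differ in length")
    if a.size < 3:
        raise InputError("absolute Pearson similarity needs vectors of length >= 3")
    ac = a - a.mean()
    bc = b - b.mean()
    va = np.dot(ac, ac)
    vb = np.dot(bc, bc)
    if va == 0.0 or vb == 0.0:
        raise UndefinedSimilarityError("Pearson similarity undefined for zero-variance vector")
    return float(np.clip(abs(np.dot(ac, bc) / np.sqrt(va * vb)), 0.0, 1.0))


MEASURES = ("cosine", "abs_pearson")


def build_similarity_matrix(profiles: pd.DataFrame, measure: str = "cosine",
                            source: str = "") -> SimilarityMatrix:
    """Pairwise raw similarity matrix from a table of profile vectors.

    ``profiles`` holds one row per entity (index = entity id, columns =
    shared dimension labels).  Entities whose similarity is undefined under
    the chosen measure (zero norm for cosine, zero variance for Pearson)
    get their row/column flagged in the missing mask rather than a
    fabricated 0.
    """
    if measure not in MEASURES:
        raise InputError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if len(profiles) < 2:
        raise InputError("need at least two profiles")
    X = profiles.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise InputError("profile values must be finite")
    labels = tuple(str(i) for i in profiles.index)

    if measure == "cosine":
        norms = np.linalg.norm(X, axis=1)
        bad = norms == 0.0
        safe = np.where(bad, 1.0, norms)
        U = X / safe[:, None]
        M = U @ U.T
    else:
        if X.shape[1] < 3:
            raise InputError("absolute Pearson similarity needs vectors of length >= 3")
        Xc = X - X.mean(axis=1, keepdims=True)
        ss = np.einsum("ij,ij->i", Xc, Xc)
        bad = ss == 0.0
        safe = np.where(bad, 1.0, np.sqrt(ss))
        U = Xc / safe[:, None]
        M = np.abs(U @ U.T)

    M = np.clip((M + M.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(M, np.where(bad, 0.0, 1.0))
    missing = None
    if bad.any():
        missing = np.zeros_like(M, dtype=bool)
        missing[bad, :] = True
        missing[:, bad] = True
    return SimilarityMatrix(labels=labels, values=M, kind="raw", source=source,
                            missing=missing)


def sequence_network_from_evalues(pairs, threshold: float = 1e-4) -> nx.Graph:
    """Build an undirected similarity network from pairwise alignment e-values.

    An edge connects two entities iff their e-value is strictly below
    ``threshold`` (default 1e-4).  Self-pairs are ignored.
    """
    g = nx.Graph()
    for a, b, ev in pairs:
        ev = float(ev)
        if ev < 0:
            raise InputError(f"negative e-value {ev} for pair ({a}, {b})")
        a, b = str(a), str(b)
        g.add_node(a)
        g.add_node(b)
        if a != b and ev < threshold:
            g.add_edge(a, b)
    return g


def network_raw_similarity(net: nx.Graph, source: str = "") -> SimilarityMatrix:
    """Raw similarity from shortest-path distances: ``w = 1 - d / d_max``.

    ``d_max`` is the largest finite shortest-path distance in the network;
    disconnected pairs get w = 0 and are flagged in the missing mask.  The
    diagonal is 1 (distance 0).
    """
    if net.number_of_nodes() == 0:
        raise InputError("empty network")
    labels = tuple(sorted(str(n) for n in net.nodes))
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(net):
        i = idx[str(src)]
        for dst, d in lengths.items():
            dist[i, idx[str(dst)]] = d
    finite = dist[np.isfinite(dist)]
    dmax = finite.max()
    if dmax == 0.0:
        # isolated nodes only: every defined distance is a self-distance
        w = np.zeros((n, n))
        np.fill_diagonal(w, 1.0)
    else:
        with np.errstate(invalid="ignore"):
            w = 1.0 - dist / dmax
        w[~np.isfinite(dist)] = 0.0
    missing = ~np.isfinite(dist)
    return SimilarityMatrix(labels=labels, values=np.clip(w, 0.0, 1.0), kind="raw",
                            source=source, missing=missing if missing.any() else None)


def default_sigma(raw: SimilarityMatrix) -> float:
    """Population standard deviation of off-diagonal upper-triangle raw scores.

    Self-pairs are excluded (they are not pairs); missing entries are
    excluded as carrying no information.
    """
    iu = np.triu_indices(raw.n, k=1)
    vals = raw.values[iu]
    if raw.missing is not None:
        vals = vals[~raw.missing[iu]]
    if vals.size == 0:
        raise DegenerateDispersionError("no defined off-diagonal raw scores")
    return float(np.std(vals))  # population (divide by N)


def exp_transform(raw: SimilarityMatrix, sigma: float | None = None) -> SimilarityMatrix:
    """Apply ``phi = exp(-((1 - w) / sigma)**2)`` entrywise.

    Strictly increasing in ``w`` with phi(1) = 1.  When ``sigma`` is not
    given it is estimated from the matrix itself via :func:`default_sigma`.
    """
    if raw.kind != "raw":
        raise InputError("exp_transform expects a raw similarity matrix")
    if sigma is None:
        sigma = default_sigma(raw)
    sigma = float(sigma)
    if sigma <= 0.0:
        raise DegenerateDispersionError(f"sigma must be positive, got {sigma}")
    phi = np.exp(-(((1.0 - raw.values) / sigma) ** 2))
    return SimilarityMatrix(labels=raw.labels, values=phi, kind="transformed",
                            source=raw.source,
                            missing=None if raw.missing is None else raw.missing.copy())
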