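"""Synthetic disease/gene worlds with planted associations.

The generator emulates the guilt-by-association structure the method
exploits: genes fall into functional modules, each disease is driven by one
module and annotated with a few of its genes, and both the phenotype
similarity between two diseases and the gene similarity under every genomic
source are elevated when the module is shared.  A latent noise component
shared across sources induces a tunable cross-source correlation so the
dependence correction has something to correct.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` children (``modules``, ``phenotype``,
``source-<i>``, ``shared-noise``, ``locations``), so each piece of the
world can be regenerated independently and worlds are byte-identical for a
fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InputError
from .scoring import build_null_sample
from .similarity import SimilarityMatrix, exp_transform


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated world.

    Parameters
    ----------
    n_diseases, n_genes, n_modules
        Universe sizes; genes are split into contiguous modules and each
        disease is assigned one module round-robin.
    genes_per_disease
        Number of module genes annotated to each disease.  The default
        equals the module size, so every disease is annotated with its
        whole causal gene family and every non-annotated disease-gene
        pair is a genuine null.
    effect_b
        Phenotype-similarity boost for disease pairs sharing a module
        (the planted effect size).
    noise_sd
        Gaussian noise on phenotype similarities.
    pheno_baseline
        Baseline phenotype similarity of unrelated disease pairs.
    source_reliabilities
        Per-source multiplier on the within-module gene similarity boost;
        0 makes the source pure noise.
    cross_source_rho
        Fraction of the gene-similarity noise variance shared between
        sources (induces correlated per-source p-values).
    sim_baseline, sim_boost, sim_noise_sd
        Raw gene-similarity baseline, within-module boost, and noise scale.
    n_chromosomes
        Synthetic chromosomes over which gene locations are scattered.
    """

    n_diseases: int = 100
    n_genes: int = 200
    n_modules: int = 50
    genes_per_disease: int = 4
    effect_b: float = 0.3
    noise_sd: float = 0.05
    pheno_baseline: float = 0.2
    source_reliabilities: tuple[float, ...] = (1.0, 1.0, 1.0)
    cross_source_rho: float = 0.2
    sim_baseline: float = 0.1
    sim_boost: float = 0.6
    sim_noise_sd: float = 0.05
    n_chromosomes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_diseases, self.n_genes, self.n_modules) < 1:
            raise InputError("all sizes must be >= 1")
        if self.n_modules > self.n_genes:
            raise InputError("more modules than genes")
        if self.genes_per_disease > self.n_genes // self.n_modules:
            raise InputError("genes_per_disease exceeds module size")
        if not (0.0 <= self.cross_source_rho < 1.0):
            raise InputError("cross_source_rho must be in [0, 1)")
        if any(not (0.0 <= r <= 1.0) for r in self.source_reliabilities):
            raise InputError("source reliabilities must be in [0, 1]")
        if self.effect_b < 0 or self.noise_sd <= 0:
            raise InputError("effect_b must be >= 0 and noise_sd > 0")


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    assoc: dict                      # disease -> set of gene ids (planted truth)
    phenotype: SimilarityMatrix
    sources: dict                    # source name -> transformed SimilarityMatrix
    locations: pd.DataFrame          # index gene, columns chrom/pos
    gene_modules: dict = field(default_factory=dict)
    disease_modules: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return sorted(set().union(*(set(m.labels) for m in self.sources.values())))


def _symmetric_noise(rng, n, sd) -> np.ndarray:
    z = rng.normal(0.0, sd, size=(n, n))
    z = np.triu(z, k=1)
    return z + z.T


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate a fully seeded synthetic world under the given conditions."""
    c = config
    root = np.random.SeedSequence(c.seed)
    ss_modules, ss_pheno, ss_shared, ss_loc, ss_sources = root.spawn(5)

    genes = [f"G{i:04d}" for i in range(c.n_genes)]
    diseases = [f"D{i:04d}" for i in range(c.n_diseases)]
    module_of_gene = {g: i * c.n_modules // c.n_genes for i, g in enumerate(genes)}
    module_genes: dict[int, list[str]] = {}
    for g, m in module_of_gene.items():
        module_genes.setdefault(m, []).append(g)
    module_of_disease = {d: i % c.n_modules for i, d in enumerate(diseases)}

    rng_mod = np.random.default_rng(ss_modules)
    assoc: dict[str, set[str]] = {}
    for d in diseases:
        pool = module_genes[module_of_disease[d]]
        pick = rng_mod.choice(len(pool), size=c.genes_per_disease, replace=False)
        assoc[d] = {pool[i] for i in pick}

    # phenotype similarity: baseline + effect for shared-module pairs + noise
    dm = np.array([module_of_disease[d] for d in diseases])
    same_mod_d = (dm[:, None] == dm[None, :]).astype(float)
    rng_ph = np.random.default_rng(ss_pheno)
    P = c.pheno_baseline + c.effect_b * same_mod_d
    P += _symmetric_noise(rng_ph, c.n_diseases, c.noise_sd)
    np.fill_diagonal(P, 1.0)
    phenotype = SimilarityMatrix(labels=tuple(diseases), values=np.clip(P, 0.0, 1.0),
                                 kind="raw", source="phenotype")

    # gene similarities: per-source boost + shared latent noise + own noise
    gm = np.array([module_of_gene[g] for g in genes])
    same_mod_g = (gm[:, None] == gm[None, :]).astype(float)
    rng_shared = np.random.default_rng(ss_shared)
    shared = _symmetric_noise(rng_shared, c.n_genes, 1.0)
    src_children = ss_sources.spawn(len(c.source_reliabilities))
    sources: dict[str, SimilarityMatrix] = {}
    for i, rel in enumerate(c.source_reliabilities):
        name = f"src{i}"
        rng_s = np.random.default_rng(src_children[i])
        own = _symmetric_noise(rng_s, c.n_genes, 1.0)
        noise = c.sim_noise_sd * (np.sqrt(c.cross_source_rho) * shared
                                  + np.sqrt(1.0 - c.cross_source_rho) * own)
        W = c.sim_baseline + c.sim_boost * rel * same_mod_g + noise
        np.fill_diagonal(W, 1.0)
        raw = SimilarityMatrix(labels=tuple(genes), values=np.clip(W, 0.0, 1.0),
                               kind="raw", source=name)
        sources[name] = exp_transform(raw)

    rng_loc = np.random.default_rng(ss_loc)
    locations = pd.DataFrame({
        "chrom": [f"chr{int(x) + 1}" for x in rng_loc.integers(0, c.n_chromosomes,
                                                               size=c.n_genes)],
        "pos": rng_loc.integers(0, 100_000_000, size=c.n_genes),
    }, index=pd.Index(genes, name="gene"))

    return SyntheticWorld(config=c, assoc=assoc, phenotype=phenotype,
                          sources=sources, locations=locations,
                          gene_modules=module_of_gene,
                          disease_modules=module_of_disease)


def null_pvalue_grid(world: SyntheticWorld, n_pairs: int, seed: int,
                     source: str | None = None) -> np.ndarray:
    """Raw slope-test p-values over sampled non-associated pairs of a world.

    Convenience wrapper around the calibration null-sample builder, run
    against the planted truth; ``source`` defaults to the world's first.
    """
    if n_pairs < 1:
        raise InputError("n_pairs must be >= 1")
    name = source if source is not None else next(iter(world.sources))
    return build_null_sample(world.assoc, world.phenotype, world.sources[name],
                             m_pairs=n_pairs, seed=seed)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["source_reliabilities"] = list(d["source_reliabilities"])
    return d
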