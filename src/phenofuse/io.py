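"""Readers and writers for the on-disk TSV/JSON formats.

Similarity matrices travel as TSV with a label header row and column and
are round-trip lossless at 17 significant digits; associations as
two-column TSV (disease, gene); gene locations as BED-like three-column TSV
(chromosome, position, gene id); profile vectors as TSV with the entity id
in the first column.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .similarity import SimilarityMatrix


def read_similarity_tsv(path, kind: str = "raw", source: str = "") -> SimilarityMatrix:
    """Read a labeled symmetric similarity matrix; validates on load."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if row_labels != col_labels:
        raise InputError(f"{path}: row and column labels disagree")
    try:
        return SimilarityMatrix(labels=tuple(row_labels),
                                values=df.to_numpy(dtype=float),
                                kind=kind, source=source or Path(path).stem)
    except InputError as e:
        raise InputError(f"{path}: {e}") from e


def write_similarity_tsv(matrix: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_association_tsv(path) -> dict:
    """Two-column TSV (disease id, gene id); duplicates collapsed."""
    assoc: dict[str, set[str]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            assoc.setdefault(parts[0].strip(), set()).add(parts[1].strip())
            n_rows += 1
    if n_rows == 0:
        raise InputError(f"{path}: empty association table")
    return assoc


def write_association_tsv(assoc: dict, path) -> None:
    with open(path, "w") as fh:
        for d in sorted(assoc):
            for g in sorted(assoc[d]):
                fh.write(f"{d}\t{g}\n")


def read_locations_tsv(path) -> pd.DataFrame:
    """BED-like TSV: chromosome, position, gene id; indexed by gene."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: expected 3 tab-separated columns")
            try:
                pos = int(parts[1])
            except ValueError:
                raise InputError(f"{path}:{lineno}: position must be an integer") from None
            if pos < 0:
                raise InputError(f"{path}:{lineno}: position must be >= 0")
            rows.append((parts[0].strip(), pos, parts[2].strip()))
    if not rows:
        raise InputError(f"{path}: empty locations table")
    df = pd.DataFrame(rows, columns=["chrom", "pos", "gene"]).set_index("gene")
    if df.index.duplicated().any():
        raise InputError(f"{path}: duplicate gene records")
    return df


def write_locations_tsv(locations: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for gene, row in locations.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{gene}\n")


def read_profiles_tsv(path) -> pd.DataFrame:
    """Profile vectors: first column entity id, named dimension columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise InputError(f"{path}: no dimension columns")
    if df.index.duplicated().any():
        raise InputError(f"{path}: duplicate entity ids")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise InputError(f"{path}: non-finite profile values")
    return df.astype(float)


def read_network_tsv(path, threshold: float = 1e-4):
    """Edge-list TSV: 2 columns (unweighted) or 3 (id, id, e-value)."""
    from .similarity import sequence_network_from_evalues

    pairs = []
    unweighted = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                unweighted.append((parts[0].strip(), parts[1].strip()))
            elif len(parts) >= 3:
                try:
                    ev = float(parts[2])
                except ValueError:
                    raise InputError(f"{path}:{lineno}: e-value must be numeric") from None
                pairs.append((parts[0].strip(), parts[1].strip(), ev))
            else:
                raise InputError(f"{path}:{lineno}: expected 2 or 3 columns")
    if pairs and unweighted:
        raise InputError(f"{path}: mixed 2- and 3-column rows")
    if unweighted:
        import networkx as nx

        g = nx.Graph()
        for a, b in unweighted:
            g.add_node(a)
            g.add_node(b)
            if a != b:
                g.add_edge(a, b)
        return g
    return sequence_network_from_evalues(pairs, threshold=threshold)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_world(world, outdir) -> None:
    """Write a synthetic world to a directory with a JSON config manifest."""
    from .synthetic import config_to_dict

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_similarity_tsv(world.phenotype, out / "phenotype.tsv")
    for name, mat in world.sources.items():
        write_similarity_tsv(mat, out / f"source_{name}.tsv")
    write_association_tsv(world.assoc, out / "associations.tsv")
    write_locations_tsv(world.locations, out / "locations.tsv")
    write_json({"config": config_to_dict(world.config),
                "sources": sorted(world.sources)}, out / "manifest.json")


def read_world(indir):
    """Load a directory written by :func:`write_world`."""
    from .synthetic import SyntheticConfig, SyntheticWorld

    ind = Path(indir)
    with open(ind / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = manifest["config"]
    cfg["source_reliabilities"] = tuple(cfg["source_reliabilities"])
    config = SyntheticConfig(**cfg)
    phenotype = read_similarity_tsv(ind / "phenotype.tsv", kind="raw",
                                    source="phenotype")
    sources = {name: read_similarity_tsv(ind / f"source_{name}.tsv",
                                         kind="transformed", source=name)
               for name in manifest["sources"]}
    assoc = read_association_tsv(ind / "associations.tsv")
    locations = read_locations_tsv(ind / "locations.tsv")
    return SyntheticWorld(config=config, assoc=assoc, phenotype=phenotype,
                          sources=sources, locations=locations)
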