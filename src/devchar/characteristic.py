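"""Characteristic-gene discovery by principal-component loading magnitudes.

The samples of a column-standardized expression matrix are treated as points
in gene space.  PCA of that sample cloud yields, for each component, a unit
loading vector over genes; the magnitude of a gene's loading measures its
contribution to sample variation along the component.  The characteristic
set of a dataset is the union, over the leading components, of the genes in
the top fraction of loading magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import DataError, ExpressionMatrix


@dataclass
class PCAResult:
    """Gene loadings, per-sample scores and explained-variance fractions."""

    loadings: pd.DataFrame            # genes x components, columns PC1..PCk, unit norm
    scores: pd.DataFrame              # samples x components
    explained_variance_ratio: np.ndarray
    centered: bool = True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca_gene_loadings(mat: ExpressionMatrix, n_components: int = 3,
                      center_genes: bool = True) -> PCAResult:
    """PCA of samples in gene space; returns per-gene loading coefficients.

    The matrix should already be column-standardized.  Each gene's values are
    centered across samples (so components describe variation of the sample
    cloud about its centroid) unless ``center_genes=False`` is requested for
    sensitivity analysis.  Components are computed by singular value
    decomposition; each loading vector has unit Euclidean norm and an
    orientation fixed so its largest-magnitude entry is positive.
    """
    x = mat.values.astype(float)
    n, m = x.shape
    max_rank = min(n, m) - (1 if center_genes else 0)
    if not (1 <= n_components <= max_rank):
        raise DataError(f"n_components must lie in [1, {max_rank}] for a {n}x{m} matrix")
    if center_genes:
        x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float(np.sum(s ** 2))
    rank = int(np.sum(s > s[0] * max(n, m) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        raise DataError(f"n_components={n_components} exceeds matrix rank {rank}")
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|entry| gene loading is positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    u *= flip
    vt *= flip[:, None]
    evr = s ** 2 / total_var if total_var > 0 else np.zeros_like(s)
    comps = [f"PC{k}" for k in range(1, n_components + 1)]
    loadings = pd.DataFrame(u, index=mat.data.index, columns=comps)
    scores = pd.DataFrame((s[:, None] * vt).T, index=mat.data.columns, columns=comps)
    return PCAResult(loadings, scores, evr, centered=center_genes)


def rank_loadings(pca: PCAResult) -> pd.DataFrame:
    """Long-format loading table with per-component magnitude ranks.

    Rank 1 is the largest |loading| within its component; ties are broken by
    gene id so ranks are a deterministic permutation of 1..N.
    """
    genes = pca.loadings.index.to_numpy()
    rows = []
    for k, comp in enumerate(pca.loadings.columns, start=1):
        load = pca.loadings[comp].to_numpy()
        order = np.lexsort((genes.astype(str), -np.abs(load)))
        rank = np.empty(len(genes), int)
        rank[order] = np.arange(1, len(genes) + 1)
        rows.append(pd.DataFrame({
            "gene_id": genes, "pc": k, "loading": load, "rank": rank,
        }))
    return pd.concat(rows, ignore_index=True)


@dataclass
class CharacteristicGeneSet:
    """Union over components of the top-ranking genes by loading magnitude."""

    gene_ids: set
    per_pc_members: dict          # pc index -> set of gene ids
    top_fraction: float

    def __post_init__(self) -> None:
        union = set().union(*self.per_pc_members.values()) if self.per_pc_members else set()
        if union != self.gene_ids:
            raise DataError("gene_ids must equal the union of per-PC members")


def characteristic_gene_set(loading_table: pd.DataFrame, top_fraction: float = 0.05,
                            pcs: tuple = (1, 2, 3)) -> CharacteristicGeneSet:
    """Genes in the top ``top_fraction`` of |loading| rank on any requested component.

    The per-component set size is round(top_fraction * N), half-up.
    """
    if not (0 < top_fraction < 1):
        raise DataError("top_fraction must lie in (0, 1)")
    per_pc = {}
    for k in pcs:
        sub = loading_table[loading_table["pc"] == k]
        if sub.empty:
            raise DataError(f"no loadings for component {k}")
        n = len(sub)
        n_top = int(np.floor(top_fraction * n + 0.5))
        per_pc[k] = set(sub.loc[sub["rank"] <= n_top, "gene_id"])
    union = set().union(*per_pc.values())
    return CharacteristicGeneSet(union, per_pc, top_fraction)


def write_loading_table(loading_table: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        loading_table[["gene_id", "pc", "loading", "rank"]].to_csv(
            fh, sep="\t", index=False, lineterminator="\n")


def write_gene_list(genes, path, header_lines=()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for g in sorted(map(str, genes)):
            fh.write(g + "\n")


def read_gene_list(path) -> list:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
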