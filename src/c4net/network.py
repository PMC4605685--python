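"""Per-species unsigned weighted co-expression networks and module detection.

The pipeline follows the weighted-network recipe: Pearson correlation of
log-transformed expression profiles along the leaf gradient, soft
thresholding a_ij = |r_ij|^beta with a species-specific power chosen for
approximate scale-free topology, topological overlap as the clustering
similarity, average-linkage clustering with branch cutting, and iterative
merging of modules whose eigengenes correlate at >= 0.9.  Modules are
named by color in decreasing size order; "grey" collects unassigned genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._treecut import cut_tree_modules, relabel_by_size
from .io import ExpressionMatrix, ValidationError

GREY = "grey"

# color vocabulary in assignment order (decreasing module size)
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "skyblue3", "plum", "orangered", "mediumpurple",
)


def color_name(rank: int) -> str:
    if rank < len(MODULE_COLORS):
        return MODULE_COLORS[rank]
    return f"module{rank + 1}"


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal, in [-1, 1]


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, in [0, 1]
    beta: int


@dataclass
class ModulePartition:
    """Gene -> module-color assignment with optional per-module eigengenes."""

    species_code: str
    labels: pd.Series  # gene_id -> color ("grey" = unassigned)
    eigengenes: pd.DataFrame | None = None  # module x section
    section_labels: list[str] = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        sizes = self.labels[self.labels != GREY].value_counts()
        return sorted(sizes.index, key=lambda m: (-sizes[m], m))

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def qualified(self, module: str) -> str:
        """Report name, e.g. 'M.turquoise'."""
        return f"{self.species_code}.{module}"


def build_correlation(
    mat: ExpressionMatrix, transform: str = "log2p1"
) -> CorrelationMatrix:
    """Pearson correlations of gene profiles across sections.

    `transform` is "log2p1" (log2(RPKM+1), the default variance
    stabilization) or "none".
    """
    if transform not in ("none", "log2p1"):
        raise ValueError(f"unknown transform {transform!r}")
    x = mat.values.to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = mat.values.index[np.where(sd == 0)[0][0]]
        raise ValidationError(f"zero-variance gene {bad!r}; exclude before correlation")
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(mat.gene_ids, r)


def soft_threshold(cor: CorrelationMatrix, beta: int) -> AdjacencyMatrix:
    """Unsigned adjacency a_ij = |r_ij|^beta with zero diagonal."""
    if beta < 1 or int(beta) != beta:
        raise ValueError(f"beta must be a positive integer, got {beta}")
    a = np.abs(cor.values) ** beta
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(cor.gene_ids, a, int(beta))


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-frequency regression.

    Positive-slope fits are reported as negative R^2 (the scale-free
    criterion requires frequency to fall with connectivity).
    """
    k = adj.sum(axis=1)
    k = k[k > 0]
    if len(k) < 10:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return 0.0
    x = np.log10(mids[keep])
    y = np.log10(counts[keep] / counts.sum())
    slope, _ = np.polyfit(x, y, 1)
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    return float(-np.sign(slope) * r2)


def select_soft_power(
    cor: CorrelationMatrix,
    candidate_betas: list[int] | None = None,
    target_r2: float = 0.8,
) -> int:
    """Smallest power reaching the scale-free fit target, else the best fit."""
    if candidate_betas is None:
        candidate_betas = list(range(1, 21))
    if not candidate_betas:
        raise ValueError("candidate_betas must be non-empty")
    if len(cor.gene_ids) < 30:
        raise ValidationError("scale-free fit needs >= 30 genes")
    fits = {}
    for beta in candidate_betas:
        fits[beta] = scale_free_fit(soft_threshold(cor, beta).values)
        if fits[beta] >= target_r2:
            return beta
    best = max(fits, key=lambda b: fits[b])
    warnings.warn(
        f"no candidate power reached R^2 >= {target_r2}; "
        f"using beta={best} (R^2={fits[best]:.3f})",
        stacklevel=2,
    )
    return best


def compute_tom(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Topological overlap: shared weighted neighbourhood similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with k_i the weighted connectivity and unit diagonal.
    """
    a = adj.values if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_dissimilarity(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    return 1.0 - compute_tom(adj)


def detect_modules(
    dissim: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    cut_height: float = 0.90,
    split_gap: float = 0.25,
    species_code: str = "",
) -> ModulePartition:
    """Average-linkage clustering with branch cutting; colors by size.

    Genes in no branch of at least `min_module_size` are labelled "grey".
    """
    n = len(gene_ids)
    if n < min_module_size:
        warnings.warn(
            f"{n} genes < min module size {min_module_size}; all grey", stacklevel=2
        )
        labels = pd.Series(GREY, index=pd.Index(gene_ids, name="gene_id"))
        return ModulePartition(species_code, labels)
    order = np.argsort(np.asarray(gene_ids, dtype=object))
    raw = cut_tree_modules(
        np.asarray(dissim, float),
        cut_height=cut_height,
        min_size=min_module_size,
        split_gap=split_gap,
        order=order,
    )
    raw = relabel_by_size(raw)
    labels = pd.Series(
        [color_name(c) if c >= 0 else GREY for c in raw],
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ModulePartition(species_code, labels)


def module_eigengene(mat: ExpressionMatrix, member_genes: list[str]) -> np.ndarray:
    """First principal component over sections of the standardized member profiles.

    Unit-norm, oriented so its mean correlation with member profiles is >= 0
    (largest-loading element made positive on an exact tie).
    """
    if len(member_genes) < 2:
        raise ValidationError("eigengene needs >= 2 member genes")
    x = np.log2(mat.values.loc[list(member_genes)].to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance member(s) excluded", stacklevel=2
        )
        x = x[sd > 0]
        if x.shape[0] == 0:
            raise ValidationError("all member genes have zero variance")
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    # PC1 over sections = leading right singular vector of the gene x section z
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_cor = np.mean([np.corrcoef(eig, row)[0, 1] for row in z])
    if mean_cor < 0:
        eig = -eig
    elif mean_cor == 0 and eig[np.argmax(np.abs(eig))] < 0:
        eig = -eig
    return eig / np.linalg.norm(eig)


def attach_eigengenes(part: ModulePartition, mat: ExpressionMatrix) -> ModulePartition:
    eigs = {
        m: module_eigengene(mat, part.members(m)) for m in part.modules
    }
    df = pd.DataFrame(eigs, index=mat.section_labels).T
    df.index.name = "module"
    return ModulePartition(part.species_code, part.labels, df, mat.section_labels)


def merge_modules(
    part: ModulePartition, mat: ExpressionMatrix, merge_cor: float = 0.9
) -> ModulePartition:
    """Iteratively merge the most-correlated eigengene pair while r >= merge_cor.

    Ties on correlation prefer the pair with larger combined size, then
    lexicographic labels.  Colors are re-assigned by size afterwards; "grey"
    is never merged.
    """
    if part.eigengenes is None:
        part = attach_eigengenes(part, mat)
    members: dict[str, list[str]] = {m: part.members(m) for m in part.modules}
    eigs: dict[str, np.ndarray] = {
        m: part.eigengenes.loc[m].to_numpy() for m in part.modules
    }
    while len(members) > 1:
        best = None
        mods = sorted(members)
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                r = float(np.corrcoef(eigs[a], eigs[b])[0, 1])
                size = len(members[a]) + len(members[b])
                # ties on r prefer larger combined size, then lexicographic
                if best is None or (round(r, 12), size) > (best[0], best[1]):
                    best = (round(r, 12), size, a, b, r)
        _, _, a, b, r = best
        if r < merge_cor:
            break
        members[a] = members[a] + members[b]
        del members[b], eigs[b]
        eigs[a] = module_eigengene(mat, members[a])
    # re-label by size
    order = sorted(members, key=lambda m: (-len(members[m]), m))
    labels = pd.Series(GREY, index=part.labels.index)
    new_eigs = {}
    for rank, old in enumerate(order):
        color = color_name(rank)
        labels.loc[members[old]] = color
        new_eigs[color] = eigs[old]
    df = pd.DataFrame(new_eigs, index=part.section_labels or mat.section_labels).T
    df.index.name = "module"
    return ModulePartition(part.species_code, labels, df, list(df.columns))


def build_species_network(
    mat: ExpressionMatrix,
    beta: int | None = None,
    transform: str = "log2p1",
    min_module_size: int = 30,
    merge_cor: float = 0.9,
    cut_height: float = 0.90,
    split_gap: float = 0.25,
) -> tuple[ModulePartition, int]:
    """Full per-species module detection; returns partition and power used."""
    cor = build_correlation(mat, transform=transform)
    if beta is None:
        beta = select_soft_power(cor)
    adj = soft_threshold(cor, beta)
    dissim = tom_dissimilarity(adj)
    part = detect_modules(
        dissim,
        mat.gene_ids,
        min_module_size=min_module_size,
        cut_height=cut_height,
        split_gap=split_gap,
        species_code=mat.species_code,
    )
    part = attach_eigengenes(part, mat)
    part = merge_modules(part, mat, merge_cor=merge_cor)
    return part, beta
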