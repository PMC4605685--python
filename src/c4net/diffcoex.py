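"""Sign-separated differential co-expression between a C4 species and rice.

Gene pairs are compared through their signed squared correlations in the
two species; the change adjacency

    c_ij = ( | sign(rA_ij) rA_ij^2  -  sign(rB_ij) rB_ij^2 | / 2 )^(beta/2)

is turned into a topological-overlap dissimilarity and clustered with the
same branch-cutting engine as the single-species networks.  Because a
module detected this way can mix genes that gain and genes that lose
correlation, each module is split by the sign of every gene's mean
correlation change against its module mates, and each half is kept only if
it still reaches the minimum size.  Retained modules must additionally show
|rA - rB| > 0.7 in strictly more than 10% of their gene pairs; modules of
fewer than 30 genes are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._treecut import cut_tree_modules, relabel_by_size
from .network import CorrelationMatrix, color_name, tom_dissimilarity

HIGHER_IN_C4 = "higher_in_C4"
LOWER_IN_C4 = "lower_in_C4"


@dataclass
class DiffModulePartition:
    """Differential co-expression modules for one C4-vs-rice comparison."""

    c4_code: str
    c3_code: str
    modules: dict[str, list[str]] = field(default_factory=dict)  # label -> ids
    direction: dict[str, str] = field(default_factory=dict)
    qualifying_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def comparison(self) -> str:
        return f"{self.c4_code}{self.c3_code}"

    def module_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for label, ids in self.modules.items():
            for g in ids:
                out[g] = label
        return out


def _check_aligned(cor_a: CorrelationMatrix, cor_b: CorrelationMatrix) -> None:
    if list(cor_a.gene_ids) != list(cor_b.gene_ids):
        raise ValueError("correlation matrices must share one ordered gene set")


def change_adjacency(
    cor_a: CorrelationMatrix, cor_b: CorrelationMatrix, beta: int = 6
) -> np.ndarray:
    """Adjacency of correlation changes between the two species."""
    _check_aligned(cor_a, cor_b)
    ra, rb = cor_a.values, cor_b.values
    c = (np.abs(np.sign(ra) * ra**2 - np.sign(rb) * rb**2) / 2.0) ** (beta / 2.0)
    np.fill_diagonal(c, 0.0)
    return c


def diff_dissimilarity(
    cor_a: CorrelationMatrix, cor_b: CorrelationMatrix, beta: int = 6
) -> np.ndarray:
    """1 - TOM of the change adjacency; pairs with equal signed squared
    correlations in both species sit at dissimilarity ~1."""
    return tom_dissimilarity(change_adjacency(cor_a, cor_b, beta))


def module_direction(
    genes: list[str], cor_a: CorrelationMatrix, cor_b: CorrelationMatrix
) -> str:
    """Label a module by the mean within-module correlation change (A = C4)."""
    _check_aligned(cor_a, cor_b)
    if len(genes) < 2:
        raise ValueError("direction needs >= 2 genes")
    pos = [cor_a.gene_ids.index(g) for g in genes]
    idx = np.ix_(pos, pos)
    delta = cor_a.values[idx] - cor_b.values[idx]
    iu = np.triu_indices(len(pos), k=1)
    mean_delta = float(delta[iu].mean())
    if mean_delta == 0:
        warnings.warn("tie in mean correlation change; labelled higher_in_C4",
                      stacklevel=2)
        return HIGHER_IN_C4
    return HIGHER_IN_C4 if mean_delta > 0 else LOWER_IN_C4


def detect_diff_modules(
    dissim: np.ndarray,
    cor_a: CorrelationMatrix,
    cor_b: CorrelationMatrix,
    min_size: int = 30,
    cut_height: float = 0.99,
    split_gap: float = 0.25,
    c4_code: str = "A",
    c3_code: str = "B",
) -> DiffModulePartition:
    """Cluster the change dissimilarity, then sign-separate each module.

    Within each detected module genes are split into two groups by the sign
    of their mean correlation change against the other members; each group
    is kept as its own module if it reaches `min_size`.
    """
    _check_aligned(cor_a, cor_b)
    gene_ids = list(cor_a.gene_ids)
    order = np.argsort(np.asarray(gene_ids, dtype=object))
    raw = cut_tree_modules(
        np.asarray(dissim, float),
        cut_height=cut_height,
        min_size=min_size,
        split_gap=split_gap,
        order=order,
    )
    raw = relabel_by_size(raw)
    delta = cor_a.values - cor_b.values
    groups: list[list[str]] = []
    for cid in np.unique(raw[raw >= 0]):
        pos = np.where(raw == cid)[0]
        # mean signed correlation change of each gene vs its module mates
        sub = delta[np.ix_(pos, pos)]
        np.fill_diagonal(sub, 0.0)
        mean_change = sub.sum(axis=1) / (len(pos) - 1)
        for sign_sel in (mean_change >= 0, mean_change < 0):
            sel = pos[sign_sel]
            if len(sel) >= min_size:
                groups.append([gene_ids[i] for i in sel])
    groups.sort(key=lambda g: (-len(g), g[0]))
    part = DiffModulePartition(c4_code, c3_code)
    for rank, genes in enumerate(groups):
        label = color_name(rank)
        part.modules[label] = genes
        part.direction[label] = module_direction(genes, cor_a, cor_b)
    return part


def qualifying_pair_fraction(
    genes: list[str], cor_a: CorrelationMatrix, cor_b: CorrelationMatrix,
    delta: float = 0.7,
) -> float:
    """Fraction of within-module gene pairs with |rA - rB| > delta."""
    pos = [cor_a.gene_ids.index(g) for g in genes]
    idx = np.ix_(pos, pos)
    d = np.abs(cor_a.values[idx] - cor_b.values[idx])
    iu = np.triu_indices(len(pos), k=1)
    return float((d[iu] > delta).mean())


def filter_diff_modules(
    part: DiffModulePartition,
    cor_a: CorrelationMatrix,
    cor_b: CorrelationMatrix,
    delta: float = 0.7,
    frac_cut: float = 0.10,
    min_size: int = 30,
) -> DiffModulePartition:
    """Retain modules of >= `min_size` genes whose qualifying-pair fraction
    (|rA - rB| > `delta`) strictly exceeds `frac_cut`."""
    out = DiffModulePartition(part.c4_code, part.c3_code)
    kept = []
    for label, genes in part.modules.items():
        if len(genes) < min_size:
            continue
        frac = qualifying_pair_fraction(genes, cor_a, cor_b, delta)
        if frac > frac_cut:
            kept.append((genes, frac))
    kept.sort(key=lambda t: (-len(t[0]), t[0][0]))
    for rank, (genes, frac) in enumerate(kept):
        label = color_name(rank)
        out.modules[label] = genes
        out.direction[label] = module_direction(genes, cor_a, cor_b)
        out.qualifying_fraction[label] = frac
    return out


def run_diffcoex(
    cor_c4: CorrelationMatrix,
    cor_rice: CorrelationMatrix,
    beta: int = 6,
    delta: float = 0.7,
    frac_cut: float = 0.10,
    min_size: int = 30,
    cut_height: float = 0.99,
    c4_code: str = "A",
    c3_code: str = "R",
) -> DiffModulePartition:
    """Full detect-separate-filter chain for one C4-vs-rice comparison."""
    dissim = diff_dissimilarity(cor_c4, cor_rice, beta)
    part = detect_diff_modules(
        dissim, cor_c4, cor_rice, min_size=min_size, cut_height=cut_height,
        c4_code=c4_code, c3_code=c3_code,
    )
    return filter_diff_modules(
        part, cor_c4, cor_rice, delta=delta, frac_cut=frac_cut, min_size=min_size
    )
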