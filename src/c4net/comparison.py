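"""Cross-species module overlap tests and functional-bin enrichment.

Module overlap between two species is tested on the universe of orthologue
groups present (and expressed) in both species, with a one-sided
hypergeometric upper tail — the over-representation form of Fisher's exact
test.  Functional enrichment per (module, bin) uses the same tail with
Benjamini-Hochberg correction across all pairs of one species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap, OrthologueMap, ValidationError
from .network import GREY, ModulePartition


@dataclass
class OverlapResult:
    module_a: str
    module_b: str
    overlap: int
    n_a: int
    n_b: int
    universe: int
    p_value: float

    @property
    def neglog10_p(self) -> float:
        return float(-np.log10(self.p_value))


@dataclass
class EnrichmentResult:
    module: str
    bin_label: str
    in_module: int
    module_size: int
    bin_size: int
    universe: int
    p_value: float
    q_value: float = np.nan

    @property
    def neglog10_q(self) -> float:
        return float(-np.log10(self.q_value))


def hypergeom_upper_tail(k, N: int, n_a: int, n_b: int):
    """P(X >= k) for X ~ Hypergeom(N, n_a, n_b); `k` may be an array."""
    out = hypergeom.sf(np.asarray(k) - 1, N, n_a, n_b)
    return float(out) if np.ndim(k) == 0 else out


def fisher_overlap(
    part_a: ModulePartition,
    part_b: ModulePartition,
    orth: OrthologueMap,
    include_grey: bool = False,
) -> list[OverlapResult]:
    """Overlap significance for every module pair of two species.

    The universe is restricted to orthologue groups whose members survived
    filtering in both species (i.e. appear in both partitions).
    """
    map_a = orth.present(part_a.species_code)
    map_b = orth.present(part_b.species_code)
    shared = map_a.index.intersection(map_b.index)
    shared = [
        og
        for og in shared
        if map_a[og] in part_a.labels.index and map_b[og] in part_b.labels.index
    ]
    if not shared:
        raise ValidationError("empty overlap universe: no shared orthologue groups")
    lab_a = part_a.labels[[map_a[og] for og in shared]].to_numpy()
    lab_b = part_b.labels[[map_b[og] for og in shared]].to_numpy()
    if not include_grey:
        keep = (lab_a != GREY) & (lab_b != GREY)
        lab_a, lab_b = lab_a[keep], lab_b[keep]
    N = len(lab_a)
    if N == 0:
        raise ValidationError("empty overlap universe after removing grey genes")
    results = []
    counts = pd.crosstab(pd.Series(lab_a), pd.Series(lab_b))
    size_a = pd.Series(lab_a).value_counts()
    size_b = pd.Series(lab_b).value_counts()
    for ma in counts.index:
        for mb in counts.columns:
            k = int(counts.loc[ma, mb])
            results.append(
                OverlapResult(
                    part_a.qualified(ma),
                    part_b.qualified(mb),
                    k,
                    int(size_a[ma]),
                    int(size_b[mb]),
                    N,
                    hypergeom_upper_tail(k, N, int(size_a[ma]), int(size_b[mb])),
                )
            )
    return results


def bin_enrichment(
    part: ModulePartition, ann: AnnotationMap, fdr_method: str = "fdr_bh"
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every functional bin in every module.

    The universe is the species' post-filter gene set (the partition index);
    q-values are Benjamini-Hochberg across all (module, bin) pairs.
    """
    universe = set(part.labels.index)
    annotated = {g for g in universe if g in ann.bins}
    if not annotated:
        raise ValidationError("no annotated gene in the enrichment universe")
    N = len(universe)
    results: list[EnrichmentResult] = []
    bins = sorted(ann.vocabulary())
    bin_genes = {b: ann.genes_in_bin(b) & universe for b in bins}
    for module in part.modules:
        mem = set(part.members(module))
        for b in bins:
            bg = bin_genes[b]
            if not bg:
                continue
            k = len(mem & bg)
            results.append(
                EnrichmentResult(
                    module, b, k, len(mem), len(bg), N,
                    hypergeom_upper_tail(k, N, len(mem), len(bg)),
                )
            )
    if results:
        _, qvals, _, _ = multipletests(
            [r.p_value for r in results], method=fdr_method
        )
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    return results


def flag_ps_modules(
    enrich: list[EnrichmentResult], ps_bins: list[str], q_cut: float = 0.05
) -> set[str]:
    """Modules significantly enriched for any photosynthesis-related bin."""
    ps = set(ps_bins)
    return {r.module for r in enrich if r.bin_label in ps and r.q_value <= q_cut}


def overlap_table(results: list[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "moduleA": r.module_a,
                "moduleB": r.module_b,
                "k": r.overlap,
                "nA": r.n_a,
                "nB": r.n_b,
                "N": r.universe,
                "p": r.p_value,
                "neglog10p": r.neglog10_p,
            }
            for r in results
        ]
    )


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module,
                "bin": r.bin_label,
                "in_module": r.in_module,
                "module_size": r.module_size,
                "bin_size": r.bin_size,
                "N": r.universe,
                "p": r.p_value,
                "q": r.q_value,
                "neglog10q": r.neglog10_q,
            }
            for r in results
        ]
    )
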