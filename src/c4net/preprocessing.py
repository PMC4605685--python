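"""Low-expression filtering and outlier-section detection.

A gene is kept when its RPKM exceeds 1 in strictly more than 10% of
sections, so for 15, 13, 11 or 10 sections alike a gene must clear the
threshold in at least 2 sections.  Outlier sections — typically the
youngest basal section, whose sink-tissue expression profile is unlike
the rest of the gradient — are flagged by their correlation to the other
sections and removed before network construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError


def filter_low_expression(
    mat: ExpressionMatrix, rpkm_cut: float = 1.0, frac: float = 0.10
) -> ExpressionMatrix:
    """Keep genes with RPKM > `rpkm_cut` in strictly more than `frac` of sections."""
    if not 0 < frac < 1:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    counts = (mat.values.to_numpy() > rpkm_cut).sum(axis=1)
    keep = counts > frac * mat.n_sections
    if not keep.any():
        raise ValidationError(
            "low-expression filter removed every gene; "
            f"review rpkm_cut={rpkm_cut} / frac={frac}"
        )
    return ExpressionMatrix(mat.species_code, mat.values.loc[keep])


def min_sections_required(n_sections: int, frac: float = 0.10) -> int:
    """Smallest per-gene section count that survives the filter rule."""
    return int(np.floor(frac * n_sections)) + 1


@dataclass
class OutlierReport:
    outliers: list[str]
    reasons: dict[str, str]  # section -> "low_correlation" | "degenerate"
    correlation: pd.DataFrame  # section x section Pearson correlations


def detect_outlier_sections(
    mat: ExpressionMatrix, min_cor: float = 0.6, log_transform: bool = True
) -> OutlierReport:
    """Flag sections whose best correlation to any other section is < `min_cor`.

    Correlations are computed across genes, by default on log2(RPKM+1).
    Constant (zero-variance) sections are flagged with reason "degenerate".
    """
    if mat.n_genes < 50:
        warnings.warn(
            f"only {mat.n_genes} genes; section correlations may be unstable",
            stacklevel=2,
        )
    x = mat.values.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    sd = x.std(axis=0)
    labels = mat.section_labels
    reasons: dict[str, str] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x.T)
    for j, lab in enumerate(labels):
        if sd[j] == 0:
            reasons[lab] = "degenerate"
            continue
        others = [cor[j, k] for k in range(len(labels)) if k != j and sd[k] > 0]
        if others and max(others) < min_cor:
            reasons[lab] = "low_correlation"
    cor_df = pd.DataFrame(cor, index=labels, columns=labels)
    return OutlierReport(list(reasons), reasons, cor_df)


def drop_sections(mat: ExpressionMatrix, labels: list[str]) -> ExpressionMatrix:
    """Remove the named sections, preserving the order of the rest."""
    unknown = [lab for lab in labels if lab not in mat.section_labels]
    if unknown:
        raise ValidationError(f"unknown section label(s): {unknown}")
    remaining = [lab for lab in mat.section_labels if lab not in set(labels)]
    if len(remaining) == 0:
        raise ValidationError("cannot drop every section")
    return ExpressionMatrix(mat.species_code, mat.values[remaining])
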