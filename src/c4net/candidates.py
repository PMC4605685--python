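"""Anchoring of C4 modules on classic marker genes and candidate typing.

Candidate C4 genes are orthologue groups whose members sit in a C4 module
(a photosynthesis-enriched, tip-ward-rising module anchored on the classic
C4 shuttle genes) in at least two of the three C4 species.  Candidates are
then compared with their rice orthologue and typed:

* type I   — rice follows the same tip-ward pattern but at a lower level
             (tip-third mean >= 1.5-fold lower in rice than in each
             supporting C4 species);
* type II  — rice shows a different pattern, supported by sign-consistent
             differential co-expression in at least two of the three
             C4-vs-rice comparisons;
* type III — the syntenic orthologue is present in all three C4 species
             but absent from rice.

Pool members matching no rule are reported "unclassified" with a reason;
genes present in the orthologue map but missing from the rice expression
matrix are reported "untestable".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .diffcoex import DiffModulePartition
from .io import ExpressionMatrix, MarkerSet, OrthologueMap, ValidationError
from .network import GREY, ModulePartition


def resample_profile(profile: np.ndarray, n_grid: int = 20) -> np.ndarray:
    """Standardized profile on `n_grid` equally spaced relative positions.

    Sections map to relative positions 0 (base) .. 1 (tip); values are
    linearly interpolated onto the grid and then z-scored, so profiles of
    species with different section counts become directly comparable.
    """
    y = np.asarray(profile, dtype=float)
    if len(y) < 3:
        raise ValueError("profile needs >= 3 sections")
    x = np.linspace(0.0, 1.0, len(y))
    grid = np.linspace(0.0, 1.0, n_grid)
    z = np.interp(grid, x, y)
    sd = z.std()
    if sd == 0:
        raise ValidationError("constant profile cannot be standardized")
    return (z - z.mean()) / sd


def tip_third_mean(mat: ExpressionMatrix, gene: str) -> float:
    """Mean raw RPKM over the tip-most ceil(n_sections / 3) sections."""
    if gene not in mat.values.index:
        raise ValidationError(f"unknown gene {gene!r} in species {mat.species_code}")
    n_tip = math.ceil(mat.n_sections / 3)
    return float(mat.values.loc[gene].to_numpy()[-n_tip:].mean())


def _rising(eigengene: np.ndarray) -> bool:
    rho = spearmanr(eigengene, np.arange(len(eigengene))).statistic
    return bool(rho > 0)


def identify_c4_modules(
    parts: dict[str, ModulePartition],
    markers: MarkerSet,
    ps_modules: dict[str, set[str]],
    ref_cor: float = 0.9,
) -> dict[str, set[str]]:
    """Per C4 species: PS-enriched, tip-ward-rising modules anchored on markers.

    A module qualifies when it is PS-flagged, its eigengene rises base->tip,
    and it either contains a classic marker gene or its eigengene correlates
    at >= `ref_cor` with a marker-containing module's eigengene.
    """
    out: dict[str, set[str]] = {}
    unresolved: list[str] = []
    for sp, part in parts.items():
        marker_genes = [g for g in markers.genes(sp) if g in part.labels.index]
        marker_mods = {
            part.labels[g] for g in marker_genes if part.labels[g] != GREY
        }
        if not marker_mods:
            unresolved.append(f"{sp}: {markers.genes(sp)}")
            continue
        eig = part.eigengenes
        chosen: set[str] = set()
        for m in ps_modules.get(sp, set()):
            if m not in eig.index or not _rising(eig.loc[m].to_numpy()):
                continue
            if m in marker_mods:
                chosen.add(m)
                continue
            best = max(
                float(np.corrcoef(eig.loc[m], eig.loc[mm])[0, 1])
                for mm in marker_mods
            )
            if best >= ref_cor:
                chosen.add(m)
        out[sp] = chosen
    if unresolved:
        raise ValidationError(
            "no marker gene found in any module for: " + "; ".join(unresolved)
        )
    return out


@dataclass
class TypingConfig:
    fold_cut: float = 1.5
    pattern_cut: float = 0.5
    n_grid: int = 20
    min_support: int = 2      # C4 species whose C4 modules must hold the gene
    min_diff_support: int = 2  # same-direction diff comparisons for type II


def _reference_eigengene(
    supporting: list[str],
    parts: dict[str, ModulePartition],
    module_of: dict[str, str],
    n_grid: int,
) -> np.ndarray:
    """Size-weighted mean of the supporting species' C4-module eigengenes."""
    acc = np.zeros(n_grid)
    total = 0.0
    for sp in supporting:
        part = parts[sp]
        module = module_of[sp]
        w = float(len(part.members(module)))
        acc += w * resample_profile(part.eigengenes.loc[module].to_numpy(), n_grid)
        total += w
    ref = acc / total
    return (ref - ref.mean()) / ref.std()


def classify_candidates(
    c4_modules: dict[str, set[str]],
    parts: dict[str, ModulePartition],
    mats: dict[str, ExpressionMatrix],
    orth: OrthologueMap,
    diff: dict[str, DiffModulePartition],
    c3_code: str = "R",
    config: TypingConfig | None = None,
) -> pd.DataFrame:
    """Type every pooled orthologue group; one row per group.

    `diff` maps each C4 species code to the retained differential modules of
    its comparison against rice, indexed by orthologue group id.
    """
    cfg = config or TypingConfig()
    c4_codes = sorted(c4_modules)
    diff_membership = {sp: diff[sp].module_of() for sp in diff}

    rows = []
    for og in orth.table.index:
        genes = {sp: orth.table.loc[og, sp] for sp in orth.species_codes}
        supporting = []
        module_of: dict[str, str] = {}
        for sp in c4_codes:
            g = genes.get(sp, "NA")
            if g == "NA" or g not in parts[sp].labels.index:
                continue
            m = parts[sp].labels[g]
            if m in c4_modules[sp]:
                supporting.append(sp)
                module_of[sp] = m
        if len(supporting) < cfg.min_support:
            continue

        row = {
            "group_id": og,
            **{f"gene_{sp}": genes.get(sp, "NA") for sp in orth.species_codes},
            "supporting_species": ",".join(supporting),
            "n_support": len(supporting),
            "pattern_cor": np.nan,
            "min_fold": np.nan,
            "diff_support": 0,
            "diff_direction": "",
            "type": "unclassified",
            "reason": "",
        }
        for sp in c4_codes + [c3_code]:
            g = genes.get(sp, "NA")
            row[f"tip_mean_{sp}"] = (
                tip_third_mean(mats[sp], g)
                if g != "NA" and g in mats[sp].values.index
                else np.nan
            )

        rice_gene = genes.get(c3_code, "NA")
        if rice_gene == "NA":
            if all(genes.get(sp, "NA") != "NA" for sp in c4_codes):
                row["type"] = "III"
                row["reason"] = "map-absent"
            else:
                row["reason"] = "rice absent but not all C4 species present"
            rows.append(row)
            continue
        if rice_gene not in mats[c3_code].values.index:
            row["type"] = "untestable"
            row["reason"] = "rice gene not in expression matrix"
            rows.append(row)
            continue

        ref = _reference_eigengene(supporting, parts, module_of, cfg.n_grid)
        rice_profile = np.log2(
            mats[c3_code].values.loc[rice_gene].to_numpy(dtype=float) + 1.0
        )
        try:
            rice_resampled = resample_profile(rice_profile, cfg.n_grid)
        except ValidationError:
            row["reason"] = "degenerate (constant) rice profile"
            rows.append(row)
            continue
        pattern = float(np.corrcoef(ref, rice_resampled)[0, 1])
        row["pattern_cor"] = pattern

        rice_tip = row[f"tip_mean_{c3_code}"]
        folds = []
        for sp in supporting:
            c4_tip = row[f"tip_mean_{sp}"]
            folds.append(np.inf if rice_tip == 0 else c4_tip / rice_tip)
        row["min_fold"] = float(min(folds))

        directions = [
            diff[sp].direction[diff_membership[sp][og]]
            for sp in sorted(diff)
            if og in diff_membership[sp]
        ]
        best_dir, best_count = "", 0
        for d in set(directions):
            if directions.count(d) > best_count:
                best_dir, best_count = d, directions.count(d)
        row["diff_support"] = best_count
        row["diff_direction"] = best_dir

        if pattern >= cfg.pattern_cut:
            if row["min_fold"] >= cfg.fold_cut:
                row["type"] = "I"
                row["reason"] = "level-shifted"
            else:
                row["reason"] = (
                    f"similar pattern but fold {row['min_fold']:.2f} < "
                    f"{cfg.fold_cut}"
                )
        else:
            if best_count >= cfg.min_diff_support:
                row["type"] = "II"
                row["reason"] = "pattern-changed with diff-coexpression support"
            else:
                row["reason"] = (
                    "different pattern but differential co-expression support "
                    f"in only {best_count} comparison(s)"
                )
        rows.append(row)

    columns = (
        ["group_id"]
        + [f"gene_{sp}" for sp in orth.species_codes]
        + ["supporting_species", "n_support"]
        + [f"tip_mean_{sp}" for sp in c4_codes + [c3_code]]
        + ["pattern_cor", "min_fold", "diff_support", "diff_direction",
           "type", "reason"]
    )
    return pd.DataFrame(rows, columns=columns)


def candidate_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Counts per type and per supporting-species combination."""
    if table.empty:
        return pd.DataFrame(columns=["type", "supporting_species", "count"])
    out = (
        table.groupby(["type", "supporting_species"])
        .size()
        .reset_index(name="count")
        .sort_values(["type", "supporting_species"])
        .reset_index(drop=True)
    )
    return out
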