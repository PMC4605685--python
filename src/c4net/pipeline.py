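"""End-to-end orchestration: filtering, networks, comparisons, candidates.

The pipeline runs the full comparative design from one configuration:
per-species low-expression filtering and outlier-section removal, module
detection, functional enrichment and cross-species module overlaps, the
three C4-vs-rice differential co-expression comparisons, and candidate
typing.  Every stage writes its result table under the output directory
and every parameter (plus the seed, when synthetic input is used) is
recorded in ``run_log.yaml``, so each summary number is recomputable from
the stage TSVs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from . import io as cio
from .candidates import (
    TypingConfig,
    candidate_summary,
    classify_candidates,
    identify_c4_modules,
)
from .diffcoex import DiffModulePartition, run_diffcoex
from .io import ExpressionMatrix, ValidationError
from .network import CorrelationMatrix, ModulePartition, build_correlation, build_species_network
from .preprocessing import detect_outlier_sections, drop_sections, filter_low_expression

log = logging.getLogger("c4net")


@dataclass
class PipelineParams:
    """Every tunable threshold of the pipeline, with its default."""

    c3_code: str = "R"
    ps_bins: list[str] = field(default_factory=lambda: ["PS"])
    # filtering
    rpkm_cut: float = 1.0
    filter_frac: float = 0.10
    detect_outliers: bool = True
    outlier_min_cor: float = 0.6
    # network
    transform: str = "log2p1"
    betas: dict[str, int] = field(default_factory=dict)  # empty -> select
    min_module_size: int = 30
    merge_cor: float = 0.9
    cut_height: float = 0.90
    split_gap: float = 0.25
    # enrichment / overlap
    enrich_q_cut: float = 0.05
    # diffcoex
    diff_beta: int = 6
    diff_delta: float = 0.7
    diff_frac_cut: float = 0.10
    diff_min_size: int = 30
    diff_cut_height: float = 0.99
    # candidates
    fold_cut: float = 1.5
    pattern_cut: float = 0.5
    n_grid: int = 20
    ref_cor: float = 0.9

    @classmethod
    def from_config(cls, cfg: dict) -> "PipelineParams":
        params = cls()
        flat = {}
        for section in ("io", "filtering", "network", "diffcoex", "candidates"):
            flat.update(cfg.get(section, {}) or {})
        for key, value in flat.items():
            if hasattr(params, key):
                setattr(params, key, value)
        return params


@dataclass
class PipelineResult:
    matrices: dict[str, ExpressionMatrix]
    partitions: dict[str, ModulePartition]
    betas: dict[str, int]
    outliers: dict[str, list[str]]
    ps_modules: dict[str, set[str]]
    c4_modules: dict[str, set[str]]
    diff: dict[str, DiffModulePartition]
    candidates: pd.DataFrame
    summary: dict


def _comparison_correlations(
    mat_c4: ExpressionMatrix,
    mat_c3: ExpressionMatrix,
    orth: cio.OrthologueMap,
    transform: str,
) -> tuple[CorrelationMatrix, CorrelationMatrix, list[str]]:
    """Correlation matrices over the shared, expressed orthologue universe,
    re-indexed by orthologue group id."""
    map_a = orth.present(mat_c4.species_code)
    map_b = orth.present(mat_c3.species_code)
    shared = [
        og
        for og in map_a.index.intersection(map_b.index)
        if map_a[og] in mat_c4.values.index and map_b[og] in mat_c3.values.index
    ]
    shared = sorted(shared)
    sub_a = ExpressionMatrix(
        mat_c4.species_code,
        mat_c4.values.loc[[map_a[og] for og in shared]].set_axis(shared, axis=0),
    )
    sub_b = ExpressionMatrix(
        mat_c3.species_code,
        mat_c3.values.loc[[map_b[og] for og in shared]].set_axis(shared, axis=0),
    )
    # genes flat in one species would break Pearson correlation; drop them
    def _ok(m: ExpressionMatrix) -> pd.Index:
        x = m.values.to_numpy()
        return m.values.index[x.std(axis=1) > 0]

    keep = sorted(set(_ok(sub_a)) & set(_ok(sub_b)))
    sub_a = sub_a.subset_genes(keep)
    sub_b = sub_b.subset_genes(keep)
    return (
        build_correlation(sub_a, transform),
        build_correlation(sub_b, transform),
        keep,
    )


def run_stages(
    matrices: dict[str, ExpressionMatrix],
    orth: cio.OrthologueMap,
    markers: cio.MarkerSet,
    annotations: dict[str, cio.AnnotationMap],
    params: PipelineParams,
    out_dir: Path | str | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write stage TSVs."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    c3 = params.c3_code
    if c3 not in matrices:
        raise ValidationError(
            f"reference C3 species required: no matrix for {c3!r}"
        )
    c4_codes = sorted(sp for sp in matrices if sp != c3)

    # --- preprocessing + per-species networks ----------------------------
    filtered: dict[str, ExpressionMatrix] = {}
    partitions: dict[str, ModulePartition] = {}
    betas: dict[str, int] = {}
    outliers: dict[str, list[str]] = {}
    for sp in sorted(matrices):
        mat = filter_low_expression(
            matrices[sp], rpkm_cut=params.rpkm_cut, frac=params.filter_frac
        )
        if params.detect_outliers:
            report = detect_outlier_sections(mat, min_cor=params.outlier_min_cor)
            outliers[sp] = report.outliers
            if report.outliers:
                log.info("%s: dropping outlier sections %s", sp, report.outliers)
                mat = drop_sections(mat, report.outliers)
        else:
            outliers[sp] = []
        filtered[sp] = mat
        part, beta = build_species_network(
            mat,
            beta=params.betas.get(sp),
            transform=params.transform,
            min_module_size=params.min_module_size,
            merge_cor=params.merge_cor,
            cut_height=params.cut_height,
            split_gap=params.split_gap,
        )
        partitions[sp] = part
        betas[sp] = beta
        log.info(
            "%s: %d genes, %d sections, beta=%d, %d modules",
            sp, mat.n_genes, mat.n_sections, beta, len(part.modules),
        )
        if out is not None:
            cio.write_table(
                part.labels.rename("module").reset_index(),
                out / f"modules_{sp}.tsv",
            )
            eig = part.eigengenes.reset_index()
            cio.write_table(eig, out / f"eigengenes_{sp}.tsv")

    # --- enrichment, PS flags, cross-species overlaps --------------------
    ps_modules: dict[str, set[str]] = {}
    for sp in sorted(matrices):
        enr = cmp.bin_enrichment(partitions[sp], annotations[sp])
        ps_modules[sp] = cmp.flag_ps_modules(
            enr, params.ps_bins, q_cut=params.enrich_q_cut
        )
        if out is not None:
            cio.write_table(
                cmp.enrichment_table(enr), out / f"enrichment_{sp}.tsv"
            )
    overlaps = []
    codes = sorted(matrices)
    for i, sa in enumerate(codes):
        for sb in codes[i + 1:]:
            overlaps.extend(
                cmp.fisher_overlap(partitions[sa], partitions[sb], orth)
            )
    if out is not None:
        cio.write_table(cmp.overlap_table(overlaps), out / "module_overlaps.tsv")

    # --- differential co-expression (each C4 species vs rice) ------------
    diff: dict[str, DiffModulePartition] = {}
    for sp in c4_codes:
        cor_a, cor_b, _ = _comparison_correlations(
            filtered[sp], filtered[c3], orth, params.transform
        )
        diff[sp] = run_diffcoex(
            cor_a, cor_b,
            beta=params.diff_beta,
            delta=params.diff_delta,
            frac_cut=params.diff_frac_cut,
            min_size=params.diff_min_size,
            cut_height=params.diff_cut_height,
            c4_code=sp, c3_code=c3,
        )
        log.info("%s vs %s: %d differential modules retained",
                 sp, c3, len(diff[sp].modules))
    if out is not None:
        rows = []
        for sp in c4_codes:
            for label, genes in diff[sp].modules.items():
                for g in genes:
                    rows.append(
                        {
                            "comparison": diff[sp].comparison,
                            "module": label,
                            "group_id": g,
                            "direction": diff[sp].direction[label],
                            "qualifying_pair_fraction":
                                diff[sp].qualifying_fraction[label],
                        }
                    )
        cio.write_table(
            pd.DataFrame(
                rows,
                columns=["comparison", "module", "group_id", "direction",
                         "qualifying_pair_fraction"],
            ),
            out / "diff_modules.tsv",
        )

    # --- candidate typing -------------------------------------------------
    c4_parts = {sp: partitions[sp] for sp in c4_codes}
    c4_mods = identify_c4_modules(
        c4_parts, markers, ps_modules, ref_cor=params.ref_cor
    )
    table = classify_candidates(
        c4_mods, partitions, filtered, orth, diff,
        c3_code=c3,
        config=TypingConfig(
            fold_cut=params.fold_cut,
            pattern_cut=params.pattern_cut,
            n_grid=params.n_grid,
        ),
    )
    summary_df = candidate_summary(table)
    if out is not None:
        cio.write_table(table, out / "candidates.tsv")
        cio.write_table(summary_df, out / "candidate_summary.tsv")

    summary = {
        "species": codes,
        "c3_reference": c3,
        "comparisons": [f"{sp}-vs-{c3}" for sp in c4_codes],
        "n_genes_post_filter": {sp: filtered[sp].n_genes for sp in codes},
        "n_sections_used": {sp: filtered[sp].n_sections for sp in codes},
        "outlier_sections": {sp: list(outliers[sp]) for sp in codes},
        "soft_power": betas,
        "n_modules": {sp: len(partitions[sp].modules) for sp in codes},
        "ps_modules": {sp: sorted(ps_modules[sp]) for sp in codes},
        "c4_modules": {sp: sorted(c4_mods[sp]) for sp in c4_codes},
        "n_diff_modules": {f"{sp}-vs-{c3}": len(diff[sp].modules)
                           for sp in c4_codes},
        "candidates_per_type": {
            t: int((table["type"] == t).sum())
            for t in ("I", "II", "III", "unclassified", "untestable")
        },
    }
    if out is not None:
        with open(out / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=False)
        with open(out / "run_log.yaml", "w") as fh:
            yaml.safe_dump({"params": asdict(params)}, fh, sort_keys=False)
    return PipelineResult(
        matrices=filtered,
        partitions=partitions,
        betas=betas,
        outliers=outliers,
        ps_modules=ps_modules,
        c4_modules=c4_mods,
        diff=diff,
        candidates=table,
        summary=summary,
    )


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> PipelineResult:
    """Run the pipeline from a YAML configuration file."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    params = PipelineParams.from_config(cfg)
    io_cfg = cfg.get("io", {}) or {}
    species_files = io_cfg.get("species", [])
    if not species_files:
        raise ValidationError("config io.species must list the expression tables")
    matrices = {
        entry["code"]: cio.read_expression_table(entry["path"], entry["code"])
        for entry in species_files
    }
    if params.c3_code not in matrices:
        raise ValidationError(
            f"reference C3 species required: {params.c3_code!r} not in config"
        )
    orth = cio.read_orthologue_map(
        io_cfg["orthologue_map"], sorted(matrices)
    )
    markers = cio.read_marker_table(io_cfg["markers"])
    annotations = {
        entry["code"]: cio.read_annotation_map(entry["path"])
        for entry in io_cfg.get("annotations", [])
    }
    return run_stages(matrices, orth, markers, annotations, params, out_dir)
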