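"""Synthetic multi-species leaf-gradient expression data with planted truth.

The generator emulates the comparative design: four grass species (three C4
— maize-like M, green-foxtail-like G, sorghum-like S — and rice-like R)
sampled as ordered leaf sections from base to tip, with species-specific
section counts (15/10/13/11).  Gene profiles follow smooth latent curves of
relative leaf position (logistic rising, reversed-logistic falling,
Gaussian-bump transient, or flat), scaled by a gene-level base expression
and perturbed by multiplicative lognormal noise.

Planted structure, recorded in :class:`SyntheticTruth`:

* co-expression modules — groups of genes sharing a latent curve in every
  species (the rising module carries the six classic C4 marker genes and is
  preferentially annotated with the photosynthesis bin);
* type I candidates — rising in all species, base expression divided by a
  fold factor in rice;
* type II candidates — rising in the C4 species, swapped to a gene-specific
  transient latent in rice (a changed pattern that also decorrelates them
  from their C4 co-expression partners);
* type III candidates — rising in the C4 species, absent from rice (both
  from the orthologue map and from the rice matrix);
* per-comparison differential blocks — each type II gene plus
  comparison-specific padding genes that rise in exactly one C4 species and
  follow transient latents elsewhere, so each C4-vs-rice comparison holds
  one block of genes more correlated in the C4 species than in rice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ABSENT,
    MARKER_NAMES,
    AnnotationMap,
    ExpressionMatrix,
    MarkerSet,
    OrthologueMap,
)

PS_BIN = "PS"
OTHER_BINS = ("protein", "RNA", "transport", "misc")


@dataclass
class ModuleSpec:
    size: int
    shape: str  # "rising" | "falling" | "transient" | "flat"
    center: float = 0.5   # transient bump center (relative position)
    width: float = 0.05   # transient bump width


@dataclass
class SimulationConfig:
    """Study conditions of the simulated four-species design."""

    species_sections: dict[str, int] = field(
        default_factory=lambda: {"M": 15, "G": 10, "S": 13, "R": 11}
    )
    c3_code: str = "R"
    n_genes: int = 2000
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec(100, "rising"),
            ModuleSpec(100, "transient", center=0.15),
            ModuleSpec(100, "transient", center=0.40),
            ModuleSpec(100, "transient", center=0.62),
            ModuleSpec(100, "transient", center=0.85),
        ]
    )
    noise_sd: float = 0.3       # sd of additive noise on the log2 scale
    n_type1: int = 20
    n_type2: int = 20
    n_type3: int = 10
    type1_fold: float = 2.0     # rice base-expression reduction for type I
    n_diff_padding: int = 40    # per-comparison single-species diff genes
    orthologue_coverage: float = 0.9
    ps_rate_module: float = 0.8  # PS annotation rate in the rising module
    ps_rate_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m.size < 2 for m in self.modules):
            raise ValueError("module sizes must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if self.type1_fold <= 1:
            raise ValueError("type I fold factor must exceed 1")
        n_c4 = len(self.species_sections) - 1
        planted = (
            sum(m.size for m in self.modules)
            + len(MARKER_NAMES)
            + self.n_type1 + self.n_type2 + self.n_type3
            + n_c4 * self.n_diff_padding
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class SyntheticTruth:
    module_of: dict[str, dict[str, int]]   # species -> gene -> module index
    candidates: pd.DataFrame               # group_id, type, per-species genes
    diff_blocks: dict[str, list[str]]      # C4 code -> orthologue group ids
    diff_direction: dict[str, str]


def _logistic(t: np.ndarray, mid: float = 0.5, slope: float = 8.0) -> np.ndarray:
    y = 1.0 / (1.0 + np.exp(-slope * (t - mid)))
    return (y - y.min()) / (y.max() - y.min())


def latent_curve(shape: str, t: np.ndarray, center: float = 0.5,
                 width: float = 0.09) -> np.ndarray:
    """Latent expression level (0..1) at relative positions `t`."""
    if shape == "rising":
        return _logistic(t)
    if shape == "falling":
        return 1.0 - _logistic(t)
    if shape == "transient":
        return np.exp(-((t - center) ** 2) / (2 * width**2))
    if shape == "flat":
        return np.ones_like(t)
    raise ValueError(f"unknown latent shape {shape!r}")


def _profile(base: float, latent: np.ndarray, noise_sd: float,
             rng: np.random.Generator, floor: float = 0.05) -> np.ndarray:
    signal = base * (floor + (1 - floor) * latent)
    return signal * 2.0 ** rng.normal(0.0, noise_sd, size=latent.shape)


@dataclass
class SyntheticDataset:
    matrices: dict[str, ExpressionMatrix]
    orthologues: OrthologueMap
    markers: MarkerSet
    annotations: dict[str, AnnotationMap]
    truth: SyntheticTruth


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate expression matrices, orthologue map, markers, annotations
    and the planted ground truth.  Fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    species = list(cfg.species_sections)
    c3 = cfg.c3_code
    if c3 not in species:
        raise ValueError(f"C3 code {c3!r} not among species")
    c4_species = [s for s in species if s != c3]
    n = cfg.n_genes
    rel_pos = {
        sp: np.linspace(0.0, 1.0, ns) for sp, ns in cfg.species_sections.items()
    }

    # ---- gene roles ------------------------------------------------------
    idx = 0
    module_genes: list[tuple[int, int]] = []  # (gene index, module index)
    for mi, spec in enumerate(cfg.modules):
        for _ in range(spec.size):
            module_genes.append((idx, mi))
            idx += 1
    marker_idx = list(range(idx, idx + len(MARKER_NAMES)))
    idx += len(MARKER_NAMES)
    type1_idx = list(range(idx, idx + cfg.n_type1)); idx += cfg.n_type1
    type2_idx = list(range(idx, idx + cfg.n_type2)); idx += cfg.n_type2
    type3_idx = list(range(idx, idx + cfg.n_type3)); idx += cfg.n_type3
    padding_idx: dict[str, list[int]] = {}
    for sp in c4_species:
        padding_idx[sp] = list(range(idx, idx + cfg.n_diff_padding))
        idx += cfg.n_diff_padding
    background_idx = list(range(idx, n))
    planted_set = set(range(idx))

    gene_ids = {sp: [f"{sp}{i:05d}" for i in range(n)] for sp in species}

    # gene-level base expression, shared across species
    base = np.exp(rng.normal(np.log(10.0), 1.2, size=n))
    base[sorted(planted_set)] = np.maximum(
        np.exp(rng.normal(np.log(30.0), 0.6, size=len(planted_set))), 4.0
    )

    # Type II genes and diff-padding genes lose their gradient regulation
    # outside the species where they rise: their "changed" latent is flat,
    # so only noise remains — uncorrelated with every planted curve.

    # ---- expression matrices --------------------------------------------
    matrices: dict[str, ExpressionMatrix] = {}
    module_of: dict[str, dict[str, int]] = {sp: {} for sp in species}
    rising_latents = {sp: latent_curve("rising", rel_pos[sp]) for sp in species}
    for sp in species:
        t = rel_pos[sp]
        vals = np.empty((n, len(t)))
        for i, mi in module_genes:
            spec = cfg.modules[mi]
            lat = latent_curve(spec.shape, t, spec.center, spec.width)
            vals[i] = _profile(base[i], lat, cfg.noise_sd, rng)
            module_of[sp][gene_ids[sp][i]] = mi
        for i in marker_idx:
            vals[i] = _profile(base[i], rising_latents[sp], cfg.noise_sd, rng)
        for i in type1_idx:
            b = base[i] / cfg.type1_fold if sp == c3 else base[i]
            vals[i] = _profile(b, rising_latents[sp], cfg.noise_sd, rng)
        for i in type2_idx:
            lat = np.ones_like(t) if sp == c3 else rising_latents[sp]
            vals[i] = _profile(base[i], lat, cfg.noise_sd, rng)
        for i in type3_idx:
            # rice rows are generated for rng-stream stability, then dropped
            vals[i] = _profile(base[i], rising_latents[sp], cfg.noise_sd, rng)
        for c4 in c4_species:
            for i in padding_idx[c4]:
                lat = rising_latents[sp] if sp == c4 else np.ones_like(t)
                vals[i] = _profile(base[i], lat, cfg.noise_sd, rng)
        for i in background_idx:
            vals[i] = _profile(base[i], np.ones_like(t), cfg.noise_sd, rng)
        df = pd.DataFrame(
            vals,
            index=pd.Index(gene_ids[sp], name="gene_id"),
            columns=[f"sec{k + 1:02d}" for k in range(len(t))],
        )
        if sp == c3:
            df = df.drop(index=[gene_ids[sp][i] for i in type3_idx])
        matrices[sp] = ExpressionMatrix(sp, df)

    # ---- orthologue map --------------------------------------------------
    rows = {}
    for i in range(n):
        row = {}
        for sp in species:
            if sp == c3 and i in set(type3_idx):
                row[sp] = ABSENT
            elif i in planted_set:
                row[sp] = gene_ids[sp][i]
            else:
                row[sp] = (
                    gene_ids[sp][i]
                    if rng.random() < cfg.orthologue_coverage
                    else ABSENT
                )
        if all(v == ABSENT for v in row.values()):
            row[species[0]] = gene_ids[species[0]][i]
        rows[f"og{i:05d}"] = row
    orth_table = pd.DataFrame.from_dict(rows, orient="index")[species]
    orth_table.index.name = "group_id"
    orthologues = OrthologueMap(species, orth_table)

    # ---- markers and annotations ----------------------------------------
    markers = MarkerSet(
        {
            sp: {
                name: [gene_ids[sp][i]]
                for name, i in zip(MARKER_NAMES, marker_idx)
            }
            for sp in species
        }
    )
    rising_members = [i for i, mi in module_genes if cfg.modules[mi].shape == "rising"]
    rising_members += marker_idx
    annotations: dict[str, AnnotationMap] = {}
    for sp in species:
        bins: dict[str, set[str]] = {}
        for i in range(n):
            gid = gene_ids[sp][i]
            rate = (
                cfg.ps_rate_module
                if i in set(rising_members)
                else cfg.ps_rate_background
            )
            if rng.random() < rate:
                bins.setdefault(gid, set()).add(PS_BIN)
            if rng.random() < 0.3:
                bins.setdefault(gid, set()).add(
                    OTHER_BINS[int(rng.integers(len(OTHER_BINS)))]
                )
        annotations[sp] = AnnotationMap(bins)

    # ---- truth -----------------------------------------------------------
    cand_rows = []
    for i in type1_idx:
        cand_rows.append({"group_id": f"og{i:05d}", "type": "I"})
    for i in type2_idx:
        cand_rows.append({"group_id": f"og{i:05d}", "type": "II"})
    for i in type3_idx:
        cand_rows.append({"group_id": f"og{i:05d}", "type": "III"})
    candidates = pd.DataFrame(cand_rows, columns=["group_id", "type"])
    diff_blocks = {
        sp: [f"og{i:05d}" for i in sorted(type2_idx + padding_idx[sp])]
        for sp in c4_species
    }
    truth = SyntheticTruth(
        module_of=module_of,
        candidates=candidates,
        diff_blocks=diff_blocks,
        diff_direction={sp: "higher_in_C4" for sp in c4_species},
    )
    return SyntheticDataset(matrices, orthologues, markers, annotations, truth)


def write_dataset(ds: SyntheticDataset, out_dir) -> dict:
    """Write all standard input files plus truth TSVs; returns a config
    mapping suitable for the pipeline runner."""
    from pathlib import Path

    from .io import write_expression_table, write_orthologue_map, write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species_entries = []
    ann_entries = []
    for sp, mat in ds.matrices.items():
        path = out / f"expression_{sp}.tsv"
        write_expression_table(mat, path)
        species_entries.append({"code": sp, "path": str(path)})
        rows = [
            {"gene_id": g, "bin": b}
            for g, bs in sorted(ds.annotations[sp].bins.items())
            for b in sorted(bs)
        ]
        apath = out / f"annotation_{sp}.tsv"
        write_table(pd.DataFrame(rows, columns=["gene_id", "bin"]), apath)
        ann_entries.append({"code": sp, "path": str(apath)})
    write_orthologue_map(ds.orthologues, out / "orthologues.tsv")
    marker_rows = [
        {"species": sp, "marker": name, "gene_id": g}
        for sp, mm in sorted(ds.markers.mapping.items())
        for name, gids in mm.items()
        for g in gids
    ]
    write_table(
        pd.DataFrame(marker_rows, columns=["species", "marker", "gene_id"]),
        out / "markers.tsv",
    )
    # truth tables
    truth_rows = [
        {"species": sp, "gene_id": g, "module": mi}
        for sp, m in sorted(ds.truth.module_of.items())
        for g, mi in sorted(m.items())
    ]
    write_table(
        pd.DataFrame(truth_rows, columns=["species", "gene_id", "module"]),
        out / "truth_modules.tsv",
    )
    write_table(ds.truth.candidates, out / "truth_candidates.tsv")
    diff_rows = [
        {"c4_species": sp, "group_id": og,
         "direction": ds.truth.diff_direction[sp]}
        for sp, ogs in sorted(ds.truth.diff_blocks.items())
        for og in ogs
    ]
    write_table(
        pd.DataFrame(diff_rows, columns=["c4_species", "group_id", "direction"]),
        out / "truth_diff_blocks.tsv",
    )
    return {
        "io": {
            "species": species_entries,
            "orthologue_map": str(out / "orthologues.tsv"),
            "markers": str(out / "markers.tsv"),
            "annotations": ann_entries,
        }
    }


def null_dataset(cfg: SimulationConfig, mode: str) -> SyntheticDataset:
    """A matched dataset with the named structure destroyed.

    ``shuffle_sections`` permutes every gene's section values independently
    (destroys all co-expression); ``shuffle_orthologues`` permutes each
    species column of the orthologue map (destroys cross-species
    correspondence).
    """
    if mode not in ("shuffle_sections", "shuffle_orthologues"):
        raise ValueError(f"unknown null mode {mode!r}")
    ds = generate_dataset(cfg)
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    if mode == "shuffle_sections":
        for sp, mat in ds.matrices.items():
            vals = mat.values.to_numpy().copy()
            for r in range(vals.shape[0]):
                rng.shuffle(vals[r])
            ds.matrices[sp] = ExpressionMatrix(
                sp, pd.DataFrame(vals, index=mat.values.index,
                                 columns=mat.values.columns)
            )
    else:
        tab = ds.orthologues.table.copy()
        for sp in ds.orthologues.species_codes:
            col = tab[sp].to_numpy().copy()
            rng.shuffle(col)
            tab[sp] = col
        keep = ~(tab == ABSENT).all(axis=1)
        ds = SyntheticDataset(
            ds.matrices,
            OrthologueMap(ds.orthologues.species_codes, tab[keep]),
            ds.markers, ds.annotations, ds.truth,
        )
    return ds
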