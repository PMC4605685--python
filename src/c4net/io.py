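"""Input/output for expression tables, orthologue maps, markers and annotations.

All files are UTF-8, tab-delimited, with a header row; lines starting with
``#`` are ignored.  Expression tables have one gene per row and one ordered
leaf section per column (first column = leaf base, last = tip).  Orthologue
maps have one orthologue group per row with one column per species; an empty
cell or ``NA`` marks absence of that species from the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ABSENT = "NA"

#: fixed vocabulary of classic C4-shuttle marker names
MARKER_NAMES = ("CA", "PEPC", "NADP-MDH", "NADP-ME", "PPDK", "PPDK-RP")


class ValidationError(ValueError):
    """Raised when an input table violates its documented contract."""


@dataclass
class ExpressionMatrix:
    """One species' gene x ordered-section RPKM table.

    Sections are ordered base -> tip; the order is never re-sorted.
    """

    species_code: str
    values: pd.DataFrame  # genes x sections, non-negative RPKM

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate section label {dup!r}")
        if df.shape[1] < 3:
            raise ValidationError(
                f"expression matrix needs >= 3 sections, got {df.shape[1]}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric expression values")
        if (df.dtypes != np.float64).any():
            self.values = df = df.astype(np.float64)
            arr = df.to_numpy()
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {df.index[i]!r}, section {df.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative RPKM {arr[i, j]} at gene {df.index[i]!r}, "
                f"section {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def section_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sections(self) -> int:
        return self.values.shape[1]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"unknown gene id(s): {missing[:5]}")
        return ExpressionMatrix(self.species_code, self.values.loc[list(gene_ids)])


@dataclass
class OrthologueMap:
    """Cross-species gene correspondence; one row per orthologue group.

    ``table`` is indexed by group id with one column per species code;
    missing members are the string ``NA``.
    """

    species_codes: list[str]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = self.table
        for sp in self.species_codes:
            if sp not in tab.columns:
                raise ValidationError(f"orthologue map lacks species column {sp!r}")
            col = tab[sp]
            present = col[col != ABSENT]
            if present.duplicated().any():
                dup = present[present.duplicated()].iloc[0]
                raise ValidationError(
                    f"gene {dup!r} appears in more than one orthologue group"
                )
        all_absent = (tab[self.species_codes] == ABSENT).all(axis=1)
        if all_absent.any():
            gid = tab.index[all_absent][0]
            raise ValidationError(f"orthologue group {gid!r} has no member")

    def present(self, species: str) -> pd.Series:
        """Group id -> gene id for groups where `species` is present."""
        col = self.table[species]
        return col[col != ABSENT]

    def gene_to_group(self, species: str) -> dict[str, str]:
        return {g: og for og, g in self.present(species).items()}


@dataclass
class MarkerSet:
    """Per-species mapping from classic C4 marker name to gene id(s)."""

    mapping: dict[str, dict[str, list[str]]]  # species -> marker -> gene ids

    def __post_init__(self) -> None:
        for sp, markers in self.mapping.items():
            for name in markers:
                if name not in MARKER_NAMES:
                    raise ValidationError(
                        f"unknown marker name {name!r} for species {sp!r}; "
                        f"expected one of {MARKER_NAMES}"
                    )

    def genes(self, species: str) -> list[str]:
        out: list[str] = []
        for ids in self.mapping.get(species, {}).values():
            out.extend(ids)
        return out


@dataclass
class AnnotationMap:
    """Gene id -> set of functional bin labels (MapMan-style)."""

    bins: dict[str, set[str]] = field(default_factory=dict)

    def genes_in_bin(self, bin_label: str) -> set[str]:
        return {g for g, bs in self.bins.items() if bin_label in bs}

    def vocabulary(self) -> set[str]:
        out: set[str] = set()
        for bs in self.bins.values():
            out |= bs
        return out


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_expression_table(path, species_code: str) -> ExpressionMatrix:
    """Read a gene x section RPKM table; column order defines base->tip order."""
    raw = _read_tsv(path)
    if raw.shape[1] < 4:
        raise ValidationError(
            f"{path}: expression table needs a gene column and >= 3 sections"
        )
    gene_col = raw.columns[0]
    try:
        values = raw.set_index(gene_col).apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric expression value ({exc})") from exc
    values.index.name = "gene_id"
    return ExpressionMatrix(species_code, values)


def read_orthologue_map(path, species_codes: list[str]) -> OrthologueMap:
    raw = _read_tsv(path)
    group_col = raw.columns[0]
    tab = raw.set_index(group_col)
    tab = tab.replace("", ABSENT)
    return OrthologueMap(list(species_codes), tab)


def read_marker_table(path) -> MarkerSet:
    """Markers as TSV with columns species, marker, gene_id (one row each)."""
    raw = _read_tsv(path)
    mapping: dict[str, dict[str, list[str]]] = {}
    for _, row in raw.iterrows():
        sp, name, gid = row.iloc[0], row.iloc[1], row.iloc[2]
        mapping.setdefault(sp, {}).setdefault(name, []).append(gid)
    return MarkerSet(mapping)


def read_annotation_map(path) -> AnnotationMap:
    """Annotations as TSV with columns gene_id, bin (one row per pair)."""
    raw = _read_tsv(path)
    bins: dict[str, set[str]] = {}
    for _, row in raw.iterrows():
        gid, b = row.iloc[0], row.iloc[1]
        if not b:
            raise ValidationError(f"empty bin label for gene {gid!r}")
        bins.setdefault(gid, set()).add(b)
    return AnnotationMap(bins)


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV; re-reading yields identical content.

    Floats are rendered with 6 significant digits; fields must be tab-free.
    """
    for col in records.columns:
        if records[col].dtype == object:
            bad = records[col].astype(str).str.contains("\t")
            if bad.any():
                raise ValidationError(
                    f"field contains a tab character (column {col!r})"
                )
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_expression_table(mat: ExpressionMatrix, path) -> None:
    df = mat.values.reset_index()
    df.columns = ["gene_id"] + mat.section_labels
    write_table(df, path)


def write_orthologue_map(orth: OrthologueMap, path) -> None:
    df = orth.table.reset_index()
    df.columns = ["group_id"] + list(orth.table.columns)
    write_table(df, path)
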