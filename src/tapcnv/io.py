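"""Domain types and readers/writers for the tab-separated files the tool consumes.

File formats (all plain TSV/JSON, coordinates 1-based inclusive):

* ``counts.tsv``    — header ``amplicon_id<TAB>cell1<TAB>...``; one row per amplicon.
* ``baf.tsv``       — header ``variant_id<TAB>cell1<TAB>...``; values in [0, 1];
  missing values written as empty field or ``NA``.
* ``panel.tsv``     — columns ``amplicon_id, chrom, start, end``.
* ``variants.tsv``  — columns ``variant_id, amplicon_id, pos``.
* ``reference.json``— ``{"reference_cells": [...], "reference_cn": {"10": 3}}``;
  chromosomes omitted from ``reference_cn`` default to copy number 2.
* ``calls.tsv``     — rows = cells, columns = chromosomes, integer entries.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LoadError",
    "CountMatrix",
    "AmpliconPanel",
    "BafTable",
    "ReferenceSpec",
    "CallSet",
    "natural_chrom_key",
    "read_count_matrix",
    "write_count_matrix",
    "read_baf_table",
    "write_baf_table",
    "read_panel",
    "write_panel",
    "read_reference_spec",
    "write_reference_spec",
    "read_callset",
    "write_callset",
    "write_metrics",
]


class LoadError(ValueError):
    """Raised when an input file violates its format contract."""


def natural_chrom_key(label: str):
    """Sort key putting chromosomes in genome order 1..22, X, Y, then others.

    A plain string sort would give 1, 10, 11, ..., 2; this key parses numeric
    labels (with or without a "chr" prefix) numerically.
    """
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        return (0, int(s), "")
    if s.upper() == "X":
        return (0, 23, "")
    if s.upper() == "Y":
        return (0, 24, "")
    return (1, 0, s)


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise LoadError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Amplicon x cell matrix of raw read counts or normalized values."""

    amplicon_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # shape (n_amplicons, n_cells), non-negative

    def __post_init__(self) -> None:
        self.amplicon_ids = [str(a) for a in self.amplicon_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.amplicon_ids, "amplicon")
        _check_unique(self.cell_ids, "cell")
        if self.values.shape != (len(self.amplicon_ids), len(self.cell_ids)):
            raise LoadError(
                f"count matrix shape {self.values.shape} does not match "
                f"{len(self.amplicon_ids)} amplicons x {len(self.cell_ids)} cells"
            )
        if np.any(np.nan_to_num(self.values, nan=0.0) < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise LoadError(
                f"negative count at amplicon {self.amplicon_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicon_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.amplicon_ids, columns=self.cell_ids)

    def cell_index(self, cell_ids) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([pos[c] for c in cell_ids], dtype=int)
        except KeyError as e:
            raise LoadError(f"unknown cell id {e.args[0]!r}") from None

    def subset_amplicons(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        ids = [self.amplicon_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool else [
            self.amplicon_ids[i] for i in keep
        ]
        return CountMatrix(ids, list(self.cell_ids), self.values[keep])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.amplicon_ids == other.amplicon_ids
            and self.cell_ids == other.cell_ids
            and np.allclose(self.values, other.values, equal_nan=True)
        )


@dataclass
class AmpliconPanel:
    """Panel design: amplicon genomic intervals and variant-to-amplicon mapping.

    ``amplicons`` columns: amplicon_id, chrom, start, end (1-based inclusive).
    ``variants`` columns: variant_id, amplicon_id, pos.
    """

    amplicons: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        amp = self.amplicons.reset_index(drop=True).copy()
        var = self.variants.reset_index(drop=True).copy()
        for col in ("amplicon_id", "chrom", "start", "end"):
            if col not in amp.columns:
                raise LoadError(f"panel table missing column {col!r}")
        for col in ("variant_id", "amplicon_id", "pos"):
            if col not in var.columns:
                raise LoadError(f"variants table missing column {col!r}")
        amp["amplicon_id"] = amp["amplicon_id"].astype(str)
        amp["chrom"] = amp["chrom"].astype(str)
        var["variant_id"] = var["variant_id"].astype(str)
        var["amplicon_id"] = var["amplicon_id"].astype(str)
        _check_unique(amp["amplicon_id"], "amplicon")
        _check_unique(var["variant_id"], "variant")
        known = set(amp["amplicon_id"])
        orphan = [a for a in var["amplicon_id"] if a not in known]
        if orphan:
            raise LoadError(f"variant references unknown amplicon {orphan[0]!r}")
        self.amplicons = amp
        self.variants = var

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in natural genome order."""
        return sorted(set(self.amplicons["chrom"]), key=natural_chrom_key)

    def sorted_amplicons(self) -> pd.DataFrame:
        """Amplicons ordered by (chromosome in genome order, start position)."""
        amp = self.amplicons.copy()
        amp["_ck"] = amp["chrom"].map(natural_chrom_key)
        out = amp.sort_values(["_ck", "start"], kind="stable").drop(columns="_ck")
        return out.reset_index(drop=True)

    def variants_per_amplicon(self) -> pd.Series:
        """V_i: number of panel variants hosted by each amplicon (0 allowed)."""
        counts = self.variants.groupby("amplicon_id").size()
        return counts.reindex(self.amplicons["amplicon_id"], fill_value=0)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AmpliconPanel)
            and self.amplicons.equals(other.amplicons)
            and self.variants.equals(other.variants)
        )


@dataclass
class BafTable:
    """Variant x cell B-allele frequencies in [0, 1]; NaN marks missing."""

    variant_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # (n_variants, n_cells), NaN allowed

    def __post_init__(self) -> None:
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.variant_ids, "variant")
        _check_unique(self.cell_ids, "cell")
        if self.values.shape != (len(self.variant_ids), len(self.cell_ids)):
            raise LoadError(
                f"BAF shape {self.values.shape} does not match "
                f"{len(self.variant_ids)} variants x {len(self.cell_ids)} cells"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise LoadError(
                f"BAF value {self.values[i, j]} outside [0, 1] at variant "
                f"{self.variant_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variant_ids, columns=self.cell_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BafTable)
            and self.variant_ids == other.variant_ids
            and self.cell_ids == other.cell_ids
            and np.allclose(self.values, other.values, equal_nan=True)
        )


@dataclass
class ReferenceSpec:
    """Designated reference cells plus the per-chromosome copy-number template.

    Chromosomes absent from ``reference_cn`` are assumed diploid (copy 2);
    non-diploid reference regions (e.g. a known trisomy) are encoded explicitly.
    """

    reference_cells: list[str]
    reference_cn: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reference_cells = [str(c) for c in self.reference_cells]
        if not self.reference_cells:
            raise LoadError("reference_cells must be non-empty")
        _check_unique(self.reference_cells, "reference cell")
        self.reference_cn = {str(k): int(v) for k, v in self.reference_cn.items()}
        for chrom, cn in self.reference_cn.items():
            if not 1 <= cn <= 5:
                raise LoadError(f"reference copy number {cn} for chromosome {chrom!r} outside 1..5")

    def cn(self, chrom: str) -> int:
        return self.reference_cn.get(str(chrom), 2)


@dataclass
class CallSet:
    """Cell x chromosome integer copy-number calls in 1..5.

    ``amplicon_paths`` optionally carries the per-amplicon Viterbi states
    (cells x amplicons, same cell order) before segment aggregation.
    """

    cell_ids: list[str]
    chromosomes: list[str]
    calls: np.ndarray  # (n_cells, n_chromosomes) int
    amplicon_ids: list[str] | None = None
    amplicon_paths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.chromosomes = [str(c) for c in self.chromosomes]
        self.calls = np.asarray(self.calls, dtype=int)
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.chromosomes, "chromosome")
        if self.calls.shape != (len(self.cell_ids), len(self.chromosomes)):
            raise LoadError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.chromosomes)} chromosomes"
            )
        if self.calls.size and (self.calls.min() < 1 or self.calls.max() > 5):
            raise LoadError("copy-number calls must lie in 1..5")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.cell_ids, columns=self.chromosomes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CallSet)
            and self.cell_ids == other.cell_ids
            and self.chromosomes == other.chromosomes
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_matrix_tsv(path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"], keep_default_na=False)
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise LoadError(f"cannot parse {path}: {e}") from e
    if df.shape[1] < 1 or df.columns[0] != index_name:
        raise LoadError(f"{path}: first column must be {index_name!r}, got {df.columns[0]!r}")
    ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        numeric = pd.to_numeric(body[col], errors="coerce")
        bad = numeric.isna() & body[col].notna() & (body[col].astype(str).str.strip() != "")
        if bad.any():
            row = ids[int(np.flatnonzero(bad.to_numpy())[0])]
            raise LoadError(f"{path}: non-numeric value in column {col!r}, row {row!r}")
        values[:, j] = numeric.to_numpy()
    return pd.DataFrame(values, index=ids, columns=[str(c) for c in body.columns])


def read_count_matrix(path) -> CountMatrix:
    """Load a counts.tsv (amplicons x cells) preserving file order."""
    df = _read_matrix_tsv(path, "amplicon_id")
    if df.isna().any().any():
        raise LoadError(f"{path}: missing values are not allowed in count matrices")
    return CountMatrix(list(df.index), list(df.columns), df.to_numpy())


def write_count_matrix(counts: CountMatrix, path) -> None:
    df = counts.to_frame()
    df.index.name = "amplicon_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_baf_table(path) -> BafTable:
    """Load a baf.tsv (variants x cells); empty fields / NA become NaN."""
    df = _read_matrix_tsv(path, "variant_id")
    return BafTable(list(df.index), list(df.columns), df.to_numpy())


def write_baf_table(baf: BafTable, path) -> None:
    df = baf.to_frame()
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def read_panel(panel_path, variants_path=None) -> AmpliconPanel:
    """Load panel.tsv and (optionally) variants.tsv into an AmpliconPanel.

    With no variants file the panel carries zero variants (depth-only mode).
    """
    amp = pd.read_csv(panel_path, sep="\t", dtype={"amplicon_id": str, "chrom": str})
    missing = {"amplicon_id", "chrom", "start", "end"} - set(amp.columns)
    if missing:
        raise LoadError(f"{panel_path}: missing columns {sorted(missing)}")
    if variants_path is not None:
        var = pd.read_csv(
            variants_path, sep="\t", dtype={"variant_id": str, "amplicon_id": str}
        )
    else:
        var = pd.DataFrame(columns=["variant_id", "amplicon_id", "pos"])
    return AmpliconPanel(amp, var)


def write_panel(panel: AmpliconPanel, panel_path, variants_path=None) -> None:
    panel.amplicons.to_csv(panel_path, sep="\t", index=False)
    if variants_path is not None:
        panel.variants.to_csv(variants_path, sep="\t", index=False)


def read_reference_spec(path) -> ReferenceSpec:
    with open(path) as fh:
        obj = json.load(fh)
    if "reference_cells" not in obj:
        raise LoadError(f"{path}: missing 'reference_cells'")
    return ReferenceSpec(obj["reference_cells"], obj.get("reference_cn", {}))


def write_reference_spec(spec: ReferenceSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"reference_cells": spec.reference_cells, "reference_cn": spec.reference_cn},
            fh,
            indent=1,
        )
        fh.write("\n")


def read_callset(path) -> CallSet:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "cell_id":
        raise LoadError(f"{path}: first column must be 'cell_id'")
    cells = df.iloc[:, 0].astype(str).tolist()
    chroms = [str(c) for c in df.columns[1:]]
    return CallSet(cells, chroms, df.iloc[:, 1:].to_numpy(dtype=int))


def write_callset(calls: CallSet, path) -> None:
    df = calls.to_frame()
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t")


def write_metrics(report, path) -> None:
    """Write a metrics report (mapping or MetricReport) as JSON, one key per metric."""
    if hasattr(report, "to_dict"):
        report = report.to_dict()

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_default)
        fh.write("\n")
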