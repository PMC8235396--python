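"""Readers, writers and cell-line matching for alteration and drug-response data.

The alteration dataset is a binary indicator table (cell line x genomic
alteration) distributed in the GCT dialect: a ``#1.2`` version line, a
``<nrows>\\t<ncols>`` dimensions line, a header row starting with
``Name``/``Description``, then one row per alteration.  Alteration labels take
the form ``<GENE>_MUT``, ``<GENE>_DEL`` or ``<GENE>_AMP`` (optionally
variant-qualified, e.g. ``BRAF.V600E_MUT``).  Cell-line columns may carry an
``_ORGAN`` suffix naming the tissue of origin.

The response dataset is a delimited-text or spreadsheet table with one row per
pharmacological compound and one column per cell line; entries are areas under
the dose-response curve (AUC) in [0, 1], where 0 is the highest cytotoxicity
and 1 the lowest.  Missing entries (cell lines never screened for a compound)
are allowed and are canonicalised to a single missing mask: blank cells,
``NA`` and ``NaN`` all map to missing.

Internally, cell lines are always rows and alterations/compounds are columns
(samples x features), regardless of file orientation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AlterationMatrix",
    "ResponseMatrix",
    "DriverGeneSet",
    "MatchedStudy",
    "CCLE_TISSUES",
    "parse_alteration_gct",
    "parse_response_table",
    "load_driver_genes",
    "normalize_cell_line_name",
    "match_cell_lines",
]

#: Tissue/organ tokens used as cell-line name suffixes in CCLE-style exports.
#: Matching is on the full suffix after an underscore, so multi-word organs
#: such as HAEMATOPOIETIC_AND_LYMPHOID_TISSUE are recognised as one token.
CCLE_TISSUES = frozenset(
    {
        "LUNG",
        "HAEMATOPOIETIC_AND_LYMPHOID_TISSUE",
        "BREAST",
        "LARGE_INTESTINE",
        "CENTRAL_NERVOUS_SYSTEM",
        "SKIN",
        "OVARY",
        "PANCREAS",
        "OESOPHAGUS",
        "STOMACH",
        "LIVER",
        "URINARY_TRACT",
        "UPPER_AERODIGESTIVE_TRACT",
        "SOFT_TISSUE",
        "KIDNEY",
        "AUTONOMIC_GANGLIA",
        "BONE",
        "ENDOMETRIUM",
        "THYROID",
        "PLEURA",
        "PROSTATE",
        "BILIARY_TRACT",
        "SMALL_INTESTINE",
        "SALIVARY_GLAND",
        "ADRENAL_GLAND",
        "ADRENAL_CORTEX",
        "CERVIX",
        "TESTIS",
        "PLACENTA",
        "VULVA",
        "FIBROBLAST",
    }
)

_DRIVER_HEADER_TOKENS = {"gene", "genes", "symbol", "gene_symbol", "hugo_symbol"}


def _as_text(source: str | Path | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    return Path(source).read_text()


@dataclass
class AlterationMatrix:
    """Binary cell-line x alteration indicator matrix.

    ``values`` has cell lines as the index and alteration labels as columns;
    every entry is 0 or 1 with no missing values, and both label sets are
    unique.  ``tissue`` optionally records a per-cell-line tissue of origin
    (filled in by :func:`match_cell_lines` when suffixes are stripped).
    """

    values: pd.DataFrame
    tissue: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate cell-line label: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate alteration label: {dup!r}")
        arr = v.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = arr[~np.isin(arr, (0, 1))].flat[0]
            raise ValueError(f"non-binary entry in alteration matrix: {bad!r}")
        self.values = v.astype(np.int8)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def alterations(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cell_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_alterations(self) -> int:
        return self.values.shape[1]

    def select_alterations(self, labels: Iterable[str]) -> "AlterationMatrix":
        return AlterationMatrix(self.values.loc[:, list(labels)], self.tissue)

    def select_cell_lines(self, names: Iterable[str]) -> "AlterationMatrix":
        names = list(names)
        tissue = self.tissue.loc[names] if self.tissue is not None else None
        return AlterationMatrix(self.values.loc[names], tissue)

    def rename_cell_lines(self, mapping: dict[str, str]) -> "AlterationMatrix":
        renamed = self.values.rename(index=mapping)
        if renamed.index.has_duplicates:
            dup = renamed.index[renamed.index.duplicated()][0]
            raise ValueError(f"cell-line names ambiguous after normalization: {dup!r}")
        tissue = self.tissue.rename(index=mapping) if self.tissue is not None else None
        return AlterationMatrix(renamed, tissue)

    def to_gct(self, target: str | Path | IO[str]) -> None:
        """Write the matrix back to GCT dialect (alterations as rows)."""
        buf = io.StringIO()
        buf.write("#1.2\n")
        buf.write(f"{self.n_alterations}\t{self.n_cell_lines}\n")
        table = self.values.T
        buf.write("Name\tDescription\t" + "\t".join(map(str, table.columns)) + "\n")
        for label, row in table.iterrows():
            buf.write(f"{label}\t{label}\t" + "\t".join(str(int(x)) for x in row) + "\n")
        if hasattr(target, "write"):
            target.write(buf.getvalue())  # type: ignore[union-attr]
        else:
            Path(target).write_text(buf.getvalue())


@dataclass
class ResponseMatrix:
    """Cell-line x compound AUC matrix with a missing mask.

    Non-missing entries lie in [0, 1]; compound labels are unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate compound label: {dup!r}")
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate cell-line label: {dup!r}")
        v = v.astype(float)
        arr = v.to_numpy()
        finite = arr[~np.isnan(arr)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            bad = finite[(finite < 0) | (finite > 1)][0]
            raise ValueError(f"AUC out of range [0, 1]: {bad}")
        self.values = v

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def select_cell_lines(self, names: Iterable[str]) -> "ResponseMatrix":
        return ResponseMatrix(self.values.loc[list(names)])

    def rename_cell_lines(self, mapping: dict[str, str]) -> "ResponseMatrix":
        renamed = self.values.rename(index=mapping)
        if renamed.index.has_duplicates:
            dup = renamed.index[renamed.index.duplicated()][0]
            raise ValueError(f"cell-line names ambiguous after normalization: {dup!r}")
        return ResponseMatrix(renamed)

    def to_csv(self, target: str | Path | IO[str]) -> None:
        """Write with compounds as rows (the distribution orientation)."""
        self.values.T.to_csv(target, index_label="Compound")


@dataclass(frozen=True)
class DriverGeneSet:
    """Deduplicated, non-empty set of driver gene symbols."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty driver gene list")
        if any(not g or g != g.strip() for g in self.genes):
            raise ValueError("blank or whitespace-padded gene symbol")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MatchedStudy:
    """Alteration and response matrices restricted to shared cell lines.

    Both components carry the same cell lines in the same order (the order
    in which they appear in the alteration matrix).
    """

    alterations: AlterationMatrix
    responses: ResponseMatrix

    def __post_init__(self) -> None:
        if list(self.alterations.values.index) != list(self.responses.values.index):
            raise ValueError("alteration and response cell-line ordering differ")

    @property
    def cell_lines(self) -> list[str]:
        return self.alterations.cell_lines

    @property
    def n_cell_lines(self) -> int:
        return self.alterations.n_cell_lines


def parse_alteration_gct(source: str | Path | IO[str]) -> AlterationMatrix:
    """Parse a GCT-dialect binary alteration table.

    Rows of the file are alterations, columns are cell lines; the returned
    matrix is transposed to the internal samples-x-features orientation.

    Raises ``ValueError`` on a malformed version line, a dimension mismatch
    with the declared ``<nrows>\\t<ncols>``, a non-binary entry, or a
    duplicated alteration label.
    """
    text = _as_text(source)
    lines = text.splitlines()
    if len(lines) < 3:
        raise ValueError("truncated GCT stream")
    if not lines[0].startswith("#1."):
        raise ValueError(f"not a GCT version line: {lines[0]!r}")
    dims = lines[1].split("\t")
    if len(dims) < 2:
        raise ValueError(f"malformed GCT dimensions line: {lines[1]!r}")
    nrows, ncols = int(dims[0]), int(dims[1])
    table = pd.read_csv(
        io.StringIO("\n".join(lines[2:])), sep="\t", header=0, index_col=0, dtype=str
    )
    # first remaining column is the free-text Description, dropped on parse
    desc_col = table.columns[0]
    data = table.drop(columns=desc_col)
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"dimension mismatch: declared {nrows}x{ncols}, found "
            f"{data.shape[0]}x{data.shape[1]}"
        )
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()][0]
        raise ValueError(f"duplicate alteration label: {dup!r}")
    arr = data.to_numpy()
    if not np.isin(arr, ("0", "1", "0.0", "1.0")).all():
        bad = arr[~np.isin(arr, ("0", "1", "0.0", "1.0"))].flat[0]
        raise ValueError(f"non-binary entry: {bad!r}")
    values = data.astype(float).astype(np.int8).T
    values.index = values.index.astype(str)
    return AlterationMatrix(values)


def parse_response_table(source: str | Path | IO[str]) -> ResponseMatrix:
    """Parse a compound x cell-line AUC table (CSV/TSV or .xlsx spreadsheet).

    The first column holds compound identifiers; blank, ``NA`` and ``NaN``
    cells map to missing.  Non-missing AUCs outside [0, 1] and duplicate
    compound labels raise ``ValueError``.
    """
    if not hasattr(source, "read") and str(source).lower().endswith((".xlsx", ".xls")):
        df = pd.read_excel(source, index_col=0)
    else:
        text = _as_text(source)
        first = text.splitlines()[0] if text else ""
        sep = "\t" if "\t" in first else ","
        df = pd.read_csv(
            io.StringIO(text),
            sep=sep,
            index_col=0,
            na_values=["NA", "NaN", "nan", ""],
            keep_default_na=True,
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric AUC entry: {exc}") from exc
    return ResponseMatrix(df.T)


def load_driver_genes(source: str | Path | IO[str]) -> DriverGeneSet:
    """Load a one-symbol-per-line driver gene list.

    A first line equal to a common header token (``gene``, ``symbol``, ...)
    is skipped; symbols are whitespace-stripped and deduplicated.
    """
    lines = [ln.strip() for ln in _as_text(source).splitlines()]
    lines = [ln for ln in lines if ln]
    if lines and lines[0].lower() in _DRIVER_HEADER_TOKENS:
        lines = lines[1:]
    if not lines:
        raise ValueError("empty driver gene list")
    return DriverGeneSet(frozenset(lines))


def normalize_cell_line_name(
    name: str,
    *,
    strip_tissue_suffix: bool = True,
    tissue_vocabulary: frozenset[str] = CCLE_TISSUES,
) -> tuple[str, str | None]:
    """Uppercase a cell-line name and optionally strip a known tissue suffix.

    Scans underscore positions left to right and strips from the first ``_``
    whose remainder is a known tissue token, so ``KMH2_HAEMATOPOIETIC_AND_
    LYMPHOID_TISSUE`` normalises to ``KMH2``.  Returns ``(sample, tissue)``
    with ``tissue`` ``None`` when nothing was stripped.
    """
    name = str(name).strip().upper()
    if strip_tissue_suffix:
        pos = name.find("_")
        while pos != -1:
            suffix = name[pos + 1 :]
            if suffix in tissue_vocabulary:
                return name[:pos], suffix
            pos = name.find("_", pos + 1)
    return name, None


def match_cell_lines(
    alt: AlterationMatrix,
    resp: ResponseMatrix,
    *,
    strip_tissue_suffix: bool = True,
    tissue_vocabulary: frozenset[str] = CCLE_TISSUES,
) -> MatchedStudy:
    """Restrict both datasets to the intersection of normalized cell lines.

    Alteration-side names are uppercased with the tissue suffix stripped
    (configurable); response-side names are uppercased only.  The shared cell
    lines keep the alteration matrix's original order.  Raises ``ValueError``
    when the intersection is empty.
    """
    alt_map: dict[str, str] = {}
    tissues: dict[str, str | None] = {}
    for name in alt.cell_lines:
        norm, tissue = normalize_cell_line_name(
            name, strip_tissue_suffix=strip_tissue_suffix, tissue_vocabulary=tissue_vocabulary
        )
        alt_map[name] = norm
        tissues[norm] = tissue
    resp_map = {name: str(name).strip().upper() for name in resp.cell_lines}

    alt_norm = alt.rename_cell_lines(alt_map)
    resp_norm = resp.rename_cell_lines(resp_map)
    shared = [n for n in alt_norm.cell_lines if n in set(resp_norm.cell_lines)]
    if not shared:
        raise ValueError("no shared cell lines between alteration and response data")
    alt_shared = alt_norm.select_cell_lines(shared)
    alt_shared.tissue = pd.Series({n: tissues.get(n) for n in shared}, name="tissue")
    resp_shared = resp_norm.select_cell_lines(shared)
    return MatchedStudy(alterations=alt_shared, responses=resp_shared)
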