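"""Reading and validation of expression matrices, sample annotations and probe maps.

The unit of analysis throughout the package is a probe-by-sample grid of
positive, linear-scale intensities (``ExpressionMatrix``).  Samples come in
tumor pairs — one laser-microdissected stroma sample and one epithelium
sample per tumor — captured by the ``CohortDesign``.  All downstream
statistics (housekeeping correction, stroma/epithelium ratios, anchor
correlations) are defined on this paired design.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("stroma", "epithelium")
SUBTYPES = ("luminal", "HER2", "TNBC", "unknown")

ANNOTATION_COLUMNS = ["sample_id", "tumor_id", "compartment", "subtype"]


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe x sample grid of linear-scale intensities.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by probe id, columns by sample id, float values.
        Validated on construction: ids unique, values finite and >= 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise LoadError(f"duplicate probe id(s): {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise LoadError(f"duplicate sample id(s): {dup}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise LoadError("non-numeric values in expression matrix")
        bad = ~np.isfinite(values)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise LoadError(
                f"non-finite value at probe {idx[r]!r}, sample {cols[c]!r}"
            )
        neg = values < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise LoadError(
                f"negative value {values[r, c]} at probe {idx[r]!r}, "
                f"sample {cols[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.data.equals(other.data)


@dataclass(frozen=True)
class TumorPair:
    tumor_id: str
    stroma_sample_id: str
    epithelium_sample_id: str
    subtype: str = "unknown"


@dataclass(frozen=True)
class CohortDesign:
    """Paired stroma/epithelium design: one entry per tumor with both compartments."""

    tumors: tuple[TumorPair, ...]

    @property
    def n_tumors(self) -> int:
        return len(self.tumors)

    @property
    def stroma_samples(self) -> list[str]:
        return [t.stroma_sample_id for t in self.tumors]

    @property
    def epithelium_samples(self) -> list[str]:
        return [t.epithelium_sample_id for t in self.tumors]

    def subset_by_subtype(self, subtype: str) -> "CohortDesign":
        kept = tuple(t for t in self.tumors if t.subtype == subtype)
        return CohortDesign(tumors=kept)


@dataclass
class ProbeMap:
    """Probe id -> gene symbol map; many probes may share a gene symbol."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, symbol in self.mapping.items():
            if not symbol:
                raise LoadError(f"empty gene symbol for probe {probe!r}")

    def symbol(self, probe_id: str) -> str:
        """Gene symbol for a probe; unmapped probes keep their probe id."""
        sym = self.mapping.get(probe_id)
        if sym is None:
            logger.warning("probe %s absent from probe map; using probe id", probe_id)
            return probe_id
        return sym

    def probes_for(self, gene_symbol: str) -> list[str]:
        return [p for p, s in self.mapping.items() if s == gene_symbol]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a probes-as-rows, samples-as-columns tab-separated matrix.

    The first column holds probe ids; the header row holds sample ids.
    Duplicate ids, non-numeric cells and negative cells are load errors
    reported with their coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise LoadError(f"{path.name}: duplicate probe id(s): {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise LoadError(f"{path.name}: duplicate sample id(s): {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LoadError(
            f"{path.name}: non-numeric value {df.iat[r, c]!r} at "
            f"probe {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    try:
        return ExpressionMatrix(numeric.astype(float))
    except LoadError as err:
        raise LoadError(f"{path.name}: {err}") from None


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probe_id")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (sample_id, tumor_id, compartment, subtype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise LoadError(f"annotation file missing column(s): {missing}")
    if "subtype" not in df.columns:
        df["subtype"] = "unknown"
    df = df[ANNOTATION_COLUMNS].copy()
    return validate_annotation(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    bad_comp = set(df["compartment"]) - set(COMPARTMENTS)
    if bad_comp:
        raise LoadError(f"unknown compartment value(s): {sorted(bad_comp)}")
    bad_sub = set(df["subtype"]) - set(SUBTYPES)
    if bad_sub:
        raise LoadError(f"unknown subtype value(s): {sorted(bad_sub)}")
    pairs = df[["tumor_id", "compartment"]]
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].iloc[0]
        raise LoadError(
            f"duplicate (tumor_id, compartment) pair: "
            f"({dup['tumor_id']!r}, {dup['compartment']!r})"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise LoadError(f"duplicate sample_id: {dup!r}")
    return df.reset_index(drop=True)


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_probe_map_tsv(path: str | Path) -> ProbeMap:
    """Read a two-column probe_id / gene_symbol table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"} <= set(df.columns):
        raise LoadError("probe map must have columns probe_id, gene_symbol")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise LoadError(f"duplicate probe_id in probe map: {dup!r}")
    return ProbeMap(dict(zip(df["probe_id"], df["gene_symbol"])))


def write_probe_map_tsv(probe_map: ProbeMap, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(probe_map.mapping), "gene_symbol": list(probe_map.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(path: str | Path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read a GEO series-matrix file into a matrix plus a draft annotation.

    Metadata lines are prefixed "!"; the expression table sits between the
    table-begin and table-end marker lines.  Compartment and subtype are
    filled best-effort from the sample characteristics lines (looking for
    the tokens "stroma"/"epithelium" and the molecular subtype names) and
    default to "unknown" — a user-supplied annotation file completes them.
    If the metadata declares log2-transformed values the table is un-logged
    (2**x), since ratio and magnitude statistics are only meaningful on the
    linear scale.
    """
    path = Path(path)
    meta_lines: list[str] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.strip() == _TABLE_BEGIN:
                in_table, saw_begin = True, True
                continue
            if line.strip() == _TABLE_END:
                in_table, saw_end = False, True
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!"):
                meta_lines.append(line)
    if not saw_begin or not saw_end:
        raise LoadError(f"{path.name}: missing series-matrix table marker line(s)")
    if not table_lines:
        raise LoadError(f"{path.name}: empty expression table")

    rows = [line.split("\t") for line in table_lines]
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise LoadError(
                f"{path.name}: ragged table — row {i} has {len(r)} fields, expected {width}"
            )
    header = [_dequote(c) for c in rows[0][1:]]
    probe_ids = [_dequote(r[0]) for r in rows[1:]]
    try:
        values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    except ValueError as err:
        raise LoadError(f"{path.name}: non-numeric table cell ({err})") from None

    if _metadata_declares_log2(meta_lines):
        values = np.exp2(values)

    matrix = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=header))
    draft = _draft_annotation(meta_lines, header)
    return matrix, draft


def _dequote(token: str) -> str:
    return token.strip().strip('"')


def _metadata_declares_log2(meta_lines: list[str]) -> bool:
    pat = re.compile(r"log[\s_]?2", re.IGNORECASE)
    for line in meta_lines:
        key = line.split("\t", 1)[0].lower()
        if "data_processing" in key or "value_definition" in key:
            if pat.search(line):
                return True
    return False


def _draft_annotation(meta_lines: list[str], sample_ids: list[str]) -> pd.DataFrame:
    """Best-effort per-sample fields from "!Sample_*" metadata lines."""
    n = len(sample_ids)
    compartment = ["unknown"] * n
    subtype = ["unknown"] * n
    tumor = [""] * n
    for line in meta_lines:
        parts = line.split("\t")
        key = parts[0].lower()
        fields = [_dequote(p) for p in parts[1:]]
        if len(fields) != n:
            continue
        if key.startswith("!sample_characteristics") or key.startswith("!sample_title") or key.startswith("!sample_source"):
            for j, text in enumerate(fields):
                low = text.lower()
                if "stroma" in low:
                    compartment[j] = "stroma"
                elif "epitheli" in low:
                    compartment[j] = "epithelium"
                if "tnbc" in low or "triple" in low:
                    subtype[j] = "TNBC"
                elif "her2" in low:
                    subtype[j] = "HER2"
                elif "luminal" in low:
                    subtype[j] = "luminal"
                m = re.search(r"(?:tumor|patient|case)[\s_:]*([A-Za-z0-9]+)", low)
                if m and not tumor[j]:
                    tumor[j] = m.group(1)
    draft = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tumor_id": tumor,
            "compartment": compartment,
            "subtype": subtype,
        }
    )
    return draft


def build_design(annotation: pd.DataFrame, matrix: ExpressionMatrix) -> CohortDesign:
    """Pair samples into tumors; tumors missing a compartment are dropped with a log entry.

    The pairing key is always the annotation's tumor_id, never a sample-id
    naming pattern.  Output tumors are ordered by tumor_id, so the design is
    independent of annotation row order.
    """
    annotation = validate_annotation(annotation.copy())
    known = set(matrix.sample_ids)
    missing = sorted(set(annotation["sample_id"]) - known)
    if missing:
        raise LoadError(f"annotation references sample id(s) absent from matrix: {missing}")
    tumors: list[TumorPair] = []
    for tumor_id, grp in sorted(annotation.groupby("tumor_id"), key=lambda kv: str(kv[0])):
        by_comp = dict(zip(grp["compartment"], grp["sample_id"]))
        if set(by_comp) != set(COMPARTMENTS):
            lacking = sorted(set(COMPARTMENTS) - set(by_comp))
            logger.warning("tumor %s excluded: missing compartment(s) %s", tumor_id, lacking)
            continue
        subtypes = set(grp["subtype"])
        subtype = subtypes.pop() if len(subtypes) == 1 else "unknown"
        tumors.append(
            TumorPair(
                tumor_id=str(tumor_id),
                stroma_sample_id=by_comp["stroma"],
                epithelium_sample_id=by_comp["epithelium"],
                subtype=subtype,
            )
        )
    if not tumors:
        raise LoadError("no paired tumors")
    return CohortDesign(tumors=tuple(tumors))
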