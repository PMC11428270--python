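"""Cross-cohort comparison: reference-list overlap and subtype-restricted screening.

The screen is probe-level but external reference lists (such as the CRC
CAFG catalogue) are gene-level; a gene is represented by its *best probe*,
the probe with the highest mean stromal expression, and "passes" when that
probe's anchor correlation is defined and at or above the chosen threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import ExpressionMatrix, LoadError
from .screen import ScreenError, _stromal_correlations


@dataclass(frozen=True)
class ReferenceGeneSet:
    """A named external gene list, optionally with reference SE values."""

    name: str
    genes: frozenset[str]
    source_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise LoadError(f"reference gene set {self.name!r} is empty")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceGeneSet":
        """Read a two-column TSV (gene_symbol, optional reference_SE).

        A leading line beginning '#' names the set; otherwise the file stem
        is used.
        """
        path = Path(path)
        name = path.stem
        genes: list[str] = []
        values: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    name = line.lstrip("#").strip() or name
                    continue
                parts = line.split("\t")
                if parts[0] == "gene_symbol":
                    continue
                genes.append(parts[0])
                if len(parts) > 1 and parts[1]:
                    values[parts[0]] = float(parts[1])
        if len(genes) != len(set(genes)):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise LoadError(f"duplicate gene symbol(s) in reference set: {dup}")
        return cls(name=name, genes=frozenset(genes), source_values=values)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {self.name}\n")
            fh.write("gene_symbol\treference_SE\n")
            for g in sorted(self.genes):
                v = self.source_values.get(g)
                fh.write(f"{g}\t{'' if v is None else v}\n")


@dataclass(frozen=True)
class OverlapReport:
    """Overlap of a screen against a reference gene list at one R threshold."""

    reference_name: str
    r_min: float
    n_reference: int
    n_on_chip: int
    n_passing: int
    fraction_passing: float  # NaN when nothing on chip
    mean_se_passing: float  # NaN when nothing passes
    passing_genes: tuple[str, ...]

    @property
    def flagged(self) -> bool:
        return self.n_on_chip == 0

    def to_dict(self) -> dict:
        return {
            "reference_name": self.reference_name,
            "r_min": self.r_min,
            "n_reference": self.n_reference,
            "n_on_chip": self.n_on_chip,
            "n_passing": self.n_passing,
            "fraction_passing": None if math.isnan(self.fraction_passing) else self.fraction_passing,
            "mean_se_passing": None if math.isnan(self.mean_se_passing) else self.mean_se_passing,
            "passing_genes": list(self.passing_genes),
        }


def best_probe_per_gene(
    screen: pd.DataFrame,
    matrix: ExpressionMatrix,
    stroma_samples: list[str],
) -> pd.DataFrame:
    """One row per gene: the probe with highest mean stromal expression.

    Ties are broken by probe id so the choice is deterministic.
    """
    mean_str = matrix.data.loc[:, stroma_samples].mean(axis=1)
    tab = screen.copy()
    tab["_mean_stromal"] = tab["probe_id"].map(mean_str).astype(float)
    tab = tab.sort_values(["gene_symbol", "_mean_stromal", "probe_id"], ascending=[True, False, True])
    best = tab.drop_duplicates("gene_symbol", keep="first").drop(columns="_mean_stromal")
    return best.reset_index(drop=True)


def overlap_with_reference(
    screen: pd.DataFrame,
    ref: ReferenceGeneSet,
    matrix: ExpressionMatrix,
    stroma_samples: list[str],
    r_min: float = 0.6,
    any_probe: bool = False,
) -> OverlapReport:
    """Fraction of reference genes whose expression tracks the anchor in stroma.

    A reference gene is *on chip* if at least one probe maps to it.  It
    *passes* when its best probe (or, with ``any_probe``, any of its probes)
    has a defined anchor correlation >= ``r_min``.  ``mean_se_passing`` is
    the arithmetic mean of the passing genes' best-probe SE ratios.
    """
    on_chip_genes = set(screen["gene_symbol"]) & set(ref.genes)
    best = best_probe_per_gene(screen, matrix, stroma_samples)
    best = best[best["gene_symbol"].isin(on_chip_genes)]
    if any_probe:
        sub = screen[screen["gene_symbol"].isin(on_chip_genes)]
        passing_mask = sub.groupby("gene_symbol")["anchor_r"].max() >= r_min
        passing = sorted(passing_mask[passing_mask].index)
        best_pass = best[best["gene_symbol"].isin(passing)]
    else:
        best_pass = best[best["anchor_r"].notna() & (best["anchor_r"] >= r_min)]
        passing = sorted(best_pass["gene_symbol"])
    n_on_chip = len(on_chip_genes)
    n_passing = len(passing)
    frac = n_passing / n_on_chip if n_on_chip else math.nan
    mean_se = float(best_pass["se_ratio"].mean()) if n_passing else math.nan
    return OverlapReport(
        reference_name=ref.name,
        r_min=r_min,
        n_reference=len(ref.genes),
        n_on_chip=n_on_chip,
        n_passing=n_passing,
        fraction_passing=frac,
        mean_se_passing=mean_se,
        passing_genes=tuple(passing),
    )


def subgroup_mean_se(
    screen: pd.DataFrame,
    ref: ReferenceGeneSet,
    matrix: ExpressionMatrix,
    stroma_samples: list[str],
    r_min: float = 0.6,
) -> float:
    """Mean SE ratio over the reference genes passing the anchor-correlation filter.

    NaN when no reference gene passes (flagged undefined).
    """
    report = overlap_with_reference(screen, ref, matrix, stroma_samples, r_min=r_min)
    return report.mean_se_passing


@dataclass(frozen=True)
class SubtypeScreenResult:
    """Subtype-restricted re-screen of anchor correlations.

    ``shared`` probes track the anchor both within the subtype and in the
    full cohort (both correlations >= r_subset_min); ``subtype_specific``
    probes track it only within the subtype (subset correlation >=
    r_subset_min, full-cohort correlation < r_full_max).  The two lists are
    disjoint whenever r_full_max <= r_subset_min.
    """

    subtype: str
    n_subset: int
    r_subset_min: float
    r_full_max: float
    shared: tuple[str, ...]
    subtype_specific: tuple[str, ...]
    subset_r: pd.Series = field(repr=False, compare=False, default=None)
    full_r: pd.Series = field(repr=False, compare=False, default=None)


def subtype_restricted_screen(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    subtype: str,
    anchor_probe: str,
    r_subset_min: float = 0.9,
    r_full_max: float = 0.6,
) -> SubtypeScreenResult:
    """Re-screen anchor correlations within one molecular subtype's stroma.

    Needs at least 3 stroma samples of the requested subtype.  The anchor
    probe itself is excluded from both output lists.
    """
    sub_design = design.subset_by_subtype(subtype)
    if sub_design.n_tumors < 3:
        raise ScreenError(
            f"subset too small for correlation: {sub_design.n_tumors} "
            f"{subtype!r} tumors (need >= 3)"
        )
    subset_r = _stromal_correlations(matrix, sub_design.stroma_samples, anchor_probe)
    full_r = _stromal_correlations(matrix, design.stroma_samples, anchor_probe)
    probes = [p for p in matrix.probe_ids if p != anchor_probe]
    shared = tuple(
        p
        for p in probes
        if not math.isnan(subset_r[p])
        and not math.isnan(full_r[p])
        and subset_r[p] >= r_subset_min
        and full_r[p] >= r_subset_min
    )
    specific = tuple(
        p
        for p in probes
        if not math.isnan(subset_r[p])
        and not math.isnan(full_r[p])
        and subset_r[p] >= r_subset_min
        and full_r[p] < r_full_max
    )
    return SubtypeScreenResult(
        subtype=subtype,
        n_subset=sub_design.n_tumors,
        r_subset_min=r_subset_min,
        r_full_max=r_full_max,
        shared=shared,
        subtype_specific=specific,
        subset_r=subset_r,
        full_r=full_r,
    )
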