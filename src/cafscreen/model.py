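"""Model-style front end: build a screen from data, fit it, inspect results.

``CAFGeneScreen`` bundles an expression matrix, the paired cohort design
and the screening configuration; ``fit()`` runs housekeeping correction
followed by the per-probe screen and returns a ``ScreenResults`` object
carrying the screen table, tier and threshold counts, and methods for
reference-list overlap, expression ranking and the subtype-restricted
re-screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import (
    OverlapReport,
    ReferenceGeneSet,
    SubtypeScreenResult,
    overlap_with_reference,
    subgroup_mean_se,
    subtype_restricted_screen,
)
from .io import (
    CohortDesign,
    ExpressionMatrix,
    ProbeMap,
    build_design,
    read_annotation_tsv,
    read_expression_tsv,
    read_probe_map_tsv,
)
from .normalize import NormalizationConfig, housekeeping_normalize
from .screen import (
    ScreenConfig,
    ScreenError,
    count_probes_at_threshold,
    rank_by_expression,
    screen_genes,
)


class CAFGeneScreen:
    """CAF-associated-gene screen on a paired stroma/epithelium cohort.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Raw linear-scale intensities, probes x samples.
    annotation : pandas.DataFrame
        Sample annotation (sample_id, tumor_id, compartment, subtype).
    config : ScreenConfig
        Anchor probe, thresholds, reference sample and ratio mode.
    probe_map : ProbeMap, optional
        Probe -> gene-symbol map; unmapped probes keep their probe id.
    normalization : NormalizationConfig, optional
        Housekeeping probe (GAPDH probe by default).
    normalize : bool
        Apply housekeeping correction before screening (the default; turn
        off only for sensitivity analysis).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        annotation: pd.DataFrame,
        config: ScreenConfig,
        probe_map: ProbeMap | None = None,
        normalization: NormalizationConfig | None = None,
        normalize: bool = True,
    ) -> None:
        self.raw_matrix = matrix
        self.annotation = annotation
        self.config = config
        self.probe_map = probe_map
        self.normalization = normalization or NormalizationConfig()
        self.normalize = normalize
        self.design: CohortDesign = build_design(annotation, matrix)

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        annotation_path: str | Path,
        config: ScreenConfig,
        probe_map_path: str | Path | None = None,
        **kwargs,
    ) -> "CAFGeneScreen":
        matrix = read_expression_tsv(matrix_path)
        annotation = read_annotation_tsv(annotation_path)
        probe_map = read_probe_map_tsv(probe_map_path) if probe_map_path else None
        return cls(matrix, annotation, config, probe_map=probe_map, **kwargs)

    def fit(self) -> "ScreenResults":
        if self.normalize:
            matrix = housekeeping_normalize(self.raw_matrix, self.normalization)
        else:
            matrix = self.raw_matrix
        records = screen_genes(matrix, self.design, self.config, self.probe_map)
        return ScreenResults(model=self, matrix=matrix, records=records)


@dataclass
class ScreenResults:
    """Fitted screen: per-probe table plus derived reports."""

    model: CAFGeneScreen
    matrix: ExpressionMatrix  # normalized matrix the statistics were computed on
    records: pd.DataFrame

    @property
    def config(self) -> ScreenConfig:
        return self.model.config

    @property
    def design(self) -> CohortDesign:
        return self.model.design

    def tier_counts(self) -> dict[str, int]:
        counts = self.records["tier"].value_counts()
        return {t: int(counts.get(t, 0)) for t in ("CAFG", "semi_CAFG", "L_CAFG")}

    def threshold_counts(self) -> dict[str, int]:
        """Probes (anchor excluded) with defined anchor correlation at each R threshold."""
        cfg = self.config
        out = {}
        for label, r_min in (
            ("r_strong", cfg.r_strong),
            ("r_mid", cfg.r_mid),
            ("r_weak", cfg.r_weak),
        ):
            out[label] = count_probes_at_threshold(
                self.matrix, self.design.stroma_samples, cfg.anchor_probe, r_min
            )
        return out

    def overlap_with(
        self, ref: ReferenceGeneSet, r_min: float | None = None, any_probe: bool = False
    ) -> OverlapReport:
        r_min = self.config.r_weak if r_min is None else r_min
        return overlap_with_reference(
            self.records,
            ref,
            self.matrix,
            self.design.stroma_samples,
            r_min=r_min,
            any_probe=any_probe,
        )

    def subgroup_mean_se(self, ref: ReferenceGeneSet, r_min: float | None = None) -> float:
        r_min = self.config.r_weak if r_min is None else r_min
        return subgroup_mean_se(
            self.records, ref, self.matrix, self.design.stroma_samples, r_min=r_min
        )

    def subtype_screen(
        self,
        subtype: str,
        r_subset_min: float | None = None,
        r_full_max: float | None = None,
    ) -> SubtypeScreenResult:
        return subtype_restricted_screen(
            self.matrix,
            self.design,
            subtype,
            self.config.anchor_probe,
            r_subset_min=self.config.r_strong if r_subset_min is None else r_subset_min,
            r_full_max=self.config.r_weak if r_full_max is None else r_full_max,
        )

    def ranked_expression(self, probes: list[str] | None = None) -> list[str]:
        if self.config.reference_sample is None:
            raise ScreenError("no reference sample configured")
        return rank_by_expression(self.matrix, self.config.reference_sample, probes)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def summary(self, top: int = 10) -> str:
        """Human-readable summary.

        R is shown to 2 decimals and SE to 1 decimal here only; the stored
        table keeps full precision.
        """
        cfg = self.config
        tiers = self.tier_counts()
        thr = self.threshold_counts()
        lines = [
            f"CAF-associated gene screen (cafscreen {__version__})",
            f"  tumors: {self.design.n_tumors} paired stroma/epithelium",
            f"  probes: {len(self.records)}",
            f"  anchor probe: {cfg.anchor_probe}   ratio mode: {cfg.ratio_mode}",
            (
                f"  tiers: CAFG (SE >= {cfg.se_high:g}): {tiers['CAFG']}   "
                f"semi-CAFG [{cfg.se_mid:g}, {cfg.se_high:g}): {tiers['semi_CAFG']}   "
                f"L-CAFG (< {cfg.se_mid:g}): {tiers['L_CAFG']}"
            ),
            (
                f"  probes correlated with anchor: R >= {cfg.r_strong:g}: {thr['r_strong']}   "
                f"R >= {cfg.r_mid:g}: {thr['r_mid']}   R >= {cfg.r_weak:g}: {thr['r_weak']}"
            ),
        ]
        cols = ["probe_id", "gene_symbol", "se_ratio", "anchor_r", "tier"]
        head = self.records.nlargest(top, "anchor_r")[cols]
        lines.append(f"  top {len(head)} probes by anchor correlation:")
        for _, row in head.iterrows():
            lines.append(
                f"    {row.probe_id:<16} {row.gene_symbol:<10} "
                f"SE={row.se_ratio:6.1f}  R={row.anchor_r:5.2f}  {row.tier}"
            )
        return "\n".join(lines)
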