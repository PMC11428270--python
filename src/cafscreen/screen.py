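"""Core screening statistics.

Three quantities drive the CAF-associated-gene (CAFG) screen:

* the **SE ratio** — per-probe stroma-to-epithelium expression ratio on the
  housekeeping-corrected matrix, computable either as the mean of the
  per-tumor paired ratios or as the ratio of compartment means;
* the **anchor correlation** (R-index) — Pearson correlation between a
  probe's stromal expression vector and the anchor marker's (SPARC by
  default) across tumors, stroma compartment only;
* the **tier** — CAFG (SE >= 10), semi-CAFG (5 <= SE < 10) or L-CAFG
  (SE < 5), all thresholds inclusive at the lower bound.

Screening is probe-level: probes mapping to the same gene are never
collapsed before the statistics are taken.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortDesign, ExpressionMatrix, ProbeMap

logger = logging.getLogger(__name__)

RATIO_MODES = ("mean_of_paired_ratios", "ratio_of_means")
TIERS = ("CAFG", "semi_CAFG", "L_CAFG")


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and anchors of the screen.

    The default anchor plays the role of SPARC; ACTA2 is the natural
    alternative anchor in breast cancer.  The correlation thresholds 0.9 /
    0.8 / 0.6 and SE thresholds 10 / 5 reproduce the tiering used to define
    CAFGs; all are inclusive.
    """

    anchor_probe: str
    r_strong: float = 0.9
    r_mid: float = 0.8
    r_weak: float = 0.6
    se_high: float = 10.0
    se_mid: float = 5.0
    reference_sample: str | None = None
    ratio_mode: str = "mean_of_paired_ratios"

    def __post_init__(self) -> None:
        if not (0 < self.r_weak <= self.r_mid <= self.r_strong <= 1):
            raise ScreenError(
                "correlation thresholds must satisfy 0 < r_weak <= r_mid <= r_strong <= 1"
            )
        if not (0 < self.se_mid < self.se_high):
            raise ScreenError("SE thresholds must satisfy 0 < se_mid < se_high")
        if self.ratio_mode not in RATIO_MODES:
            raise ScreenError(f"ratio_mode must be one of {RATIO_MODES}")


def se_ratio(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    probe: str,
    mode: str = "mean_of_paired_ratios",
) -> float:
    """Stroma/epithelium ratio for one probe on a normalized matrix.

    ``mean_of_paired_ratios`` averages the per-tumor ratio s_t / e_t, which
    lets each tumor act as its own control; ``ratio_of_means`` divides the
    pooled stroma mean by the pooled epithelium mean.  Tumors with an
    epithelium value of zero are skipped (with a warning) in paired mode;
    if every tumor is skipped, or the pooled epithelium mean is zero, the
    ratio is undefined and NaN is returned.
    """
    if mode not in RATIO_MODES:
        raise ScreenError(f"unknown ratio mode {mode!r}")
    if probe not in matrix.data.index:
        raise ScreenError(f"probe {probe!r} not in matrix")
    s = matrix.data.loc[probe, design.stroma_samples].to_numpy(dtype=float)
    e = matrix.data.loc[probe, design.epithelium_samples].to_numpy(dtype=float)
    if mode == "mean_of_paired_ratios":
        ok = e != 0
        if not ok.all():
            skipped = [t.tumor_id for t, good in zip(design.tumors, ok) if not good]
            logger.warning(
                "probe %s: skipping tumor(s) %s with zero epithelium value", probe, skipped
            )
        if not ok.any():
            return math.nan
        return float(np.mean(s[ok] / e[ok]))
    mean_e = float(np.mean(e))
    if mean_e == 0:
        return math.nan
    return float(np.mean(s)) / mean_e


#: Relative tolerance below which a vector's spread is treated as rounding
#: noise rather than signal; such probes get an undefined correlation.
ZERO_VARIANCE_RTOL = 1e-12


def _variance_floor(x: np.ndarray) -> float:
    """Centered-norm threshold under which a vector counts as constant."""
    scale = float(np.max(np.abs(x))) if x.size else 0.0
    return ZERO_VARIANCE_RTOL * math.sqrt(len(x)) * scale


def anchor_correlation(
    matrix: ExpressionMatrix,
    stroma_samples: list[str],
    probe: str,
    anchor_probe: str,
) -> float:
    """Pearson correlation of probe vs anchor across the given stroma samples.

    Returns NaN (undefined) when either vector has zero variance; undefined
    correlations are excluded from all threshold counts downstream.
    """
    if len(stroma_samples) < 3:
        raise ScreenError("need at least 3 stroma samples for a correlation")
    for p in (probe, anchor_probe):
        if p not in matrix.data.index:
            raise ScreenError(f"probe {p!r} not in matrix")
    x = matrix.data.loc[probe, stroma_samples].to_numpy(dtype=float)
    y = matrix.data.loc[anchor_probe, stroma_samples].to_numpy(dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx <= _variance_floor(x) or sy <= _variance_floor(y):
        return math.nan
    r = float(np.sum(xc * yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


def classify_tier(se: float, config: ScreenConfig) -> str | None:
    """Map a defined SE ratio to its tier; undefined (NaN) ratios get None."""
    if se is None or math.isnan(se):
        return None
    if se >= config.se_high:
        return "CAFG"
    if se >= config.se_mid:
        return "semi_CAFG"
    return "L_CAFG"


def _stromal_correlations(
    matrix: ExpressionMatrix, stroma_samples: list[str], anchor_probe: str
) -> pd.Series:
    """Vectorised per-probe Pearson correlation with the anchor over stroma samples."""
    sub = matrix.data.loc[:, stroma_samples].to_numpy(dtype=float)
    anchor = matrix.data.loc[anchor_probe, stroma_samples].to_numpy(dtype=float)
    xc = sub - sub.mean(axis=1, keepdims=True)
    yc = anchor - anchor.mean()
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = float(np.sqrt((yc * yc).sum()))
    n = sub.shape[1]
    floor_x = ZERO_VARIANCE_RTOL * math.sqrt(n) * np.max(np.abs(sub), axis=1)
    floor_y = _variance_floor(anchor)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r[(sx <= floor_x) | (sy <= floor_y)] = np.nan
    return pd.Series(np.clip(r, -1.0, 1.0), index=matrix.data.index)


def _se_ratios_all(
    matrix: ExpressionMatrix, design: CohortDesign, mode: str
) -> pd.Series:
    """Vectorised SE ratio for every probe; same contract as :func:`se_ratio`."""
    s = matrix.data.loc[:, design.stroma_samples].to_numpy(dtype=float)
    e = matrix.data.loc[:, design.epithelium_samples].to_numpy(dtype=float)
    if mode == "mean_of_paired_ratios":
        ok = e != 0
        n_skipped = int((~ok).sum())
        if n_skipped:
            logger.warning("skipping %d (probe, tumor) pairs with zero epithelium value", n_skipped)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(ok, s / np.where(ok, e, 1.0), np.nan)
        n_ok = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.nansum(ratios, axis=1) / n_ok
        vals[n_ok == 0] = np.nan
    elif mode == "ratio_of_means":
        mean_e = e.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(mean_e == 0, np.nan, s.mean(axis=1) / mean_e)
    else:
        raise ScreenError(f"unknown ratio mode {mode!r}")
    return pd.Series(vals, index=matrix.data.index)


def screen_genes(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    config: ScreenConfig,
    probe_map: ProbeMap | None = None,
) -> pd.DataFrame:
    """Run the full per-probe screen on a normalized matrix.

    Returns one row per probe with columns probe_id, gene_symbol, se_ratio,
    anchor_r, tier, ref_expression, rank_by_expression, ordered by rank and
    then probe id.  ``ref_expression`` is the normalized intensity in the
    configured reference stroma sample (NaN when no reference sample is
    configured); ranking is by descending reference expression with ties
    broken by probe id.
    """
    if design.n_tumors == 0:
        raise ScreenError("empty cohort design")
    if config.anchor_probe not in matrix.data.index:
        raise ScreenError(f"anchor probe {config.anchor_probe!r} not in matrix")
    probes = matrix.probe_ids
    stroma = design.stroma_samples

    anchor_r = _stromal_correlations(matrix, stroma, config.anchor_probe)
    se = _se_ratios_all(matrix, design, config.ratio_mode)
    tiers = se.map(lambda v: classify_tier(v, config))

    if config.reference_sample is not None:
        if config.reference_sample not in matrix.data.columns:
            raise ScreenError(f"reference sample {config.reference_sample!r} not in matrix")
        ref = matrix.data[config.reference_sample].astype(float)
    else:
        ref = pd.Series(np.nan, index=probes)

    table = pd.DataFrame(
        {
            "probe_id": probes,
            "gene_symbol": [probe_map.symbol(p) if probe_map else p for p in probes],
            "se_ratio": se.to_numpy(),
            "anchor_r": anchor_r.to_numpy(),
            "tier": tiers.to_numpy(),
            "ref_expression": ref.to_numpy(),
        }
    )
    order = table.sort_values(
        ["ref_expression", "probe_id"], ascending=[False, True], na_position="last"
    )
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table["rank_by_expression"] = rank
    table = table.sort_values(["rank_by_expression", "probe_id"]).reset_index(drop=True)
    return table


def rank_by_expression(
    matrix: ExpressionMatrix, reference_sample: str, probes: list[str] | None = None
) -> list[str]:
    """Probes sorted by descending intensity in the reference sample, ties by probe id."""
    if reference_sample not in matrix.data.columns:
        raise ScreenError(f"reference sample {reference_sample!r} not in matrix")
    probes = list(probes) if probes is not None else matrix.probe_ids
    vals = matrix.data.loc[probes, reference_sample]
    order = sorted(probes, key=lambda p: (-vals[p], p))
    return order


def count_probes_at_threshold(
    matrix: ExpressionMatrix,
    stroma_samples: list[str],
    anchor_probe: str,
    r_min: float,
) -> int:
    """Number of probes (anchor excluded) with defined anchor correlation >= r_min."""
    r = _stromal_correlations(matrix, stroma_samples, anchor_probe)
    r = r.drop(index=anchor_probe)
    return int((r >= r_min).sum())
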