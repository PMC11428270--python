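"""Housekeeping correction.

Each sample (column) is divided by that sample's intensity on a single
housekeeping probe — by default the GAPDH probe 217398_x_at of the
HG U133A 2.0 chip.  This removes per-sample scale (labelling efficiency,
amount of captured material), which is essential for a paired
stroma/epithelium design where the two compartments are dissected and
hybridised separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ExpressionMatrix

DEFAULT_HOUSEKEEPING_PROBE = "217398_x_at"


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationConfig:
    housekeeping_probe_id: str = DEFAULT_HOUSEKEEPING_PROBE


def housekeeping_normalize(
    matrix: ExpressionMatrix, config: NormalizationConfig | None = None
) -> ExpressionMatrix:
    """Divide every sample column by its housekeeping-probe value.

    The housekeeping probe must be present and strictly positive in every
    sample; after normalization its row is exactly 1.0 everywhere, which
    makes the operation idempotent.
    """
    config = config or NormalizationConfig()
    probe = config.housekeeping_probe_id
    if probe not in matrix.data.index:
        raise NormalizationError(f"housekeeping probe {probe!r} not in matrix")
    hk = matrix.data.loc[probe]
    bad = hk[hk <= 0]
    if len(bad) > 0:
        sample = bad.index[0]
        raise NormalizationError(
            f"housekeeping probe {probe!r} is {bad.iloc[0]} in sample {sample!r}; "
            "must be strictly positive"
        )
    return ExpressionMatrix(matrix.data.div(hk, axis=1))
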