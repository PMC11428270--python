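"""End-to-end pipeline: read -> normalize -> screen -> compare -> report files.

``run_full_screen`` executes the whole analysis from a :class:`RunConfig`
and writes a deterministic artifact bundle: the screen table, overlap
report(s), tier-count summary, the ranked expression list for the
reference sample, and a machine-readable manifest (effective config, input
checksums, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .compare import ReferenceGeneSet
from .io import LoadError
from .model import CAFGeneScreen
from .normalize import NormalizationConfig
from .reference import crc_cafg_reference
from .screen import ScreenConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths plus screening/normalization settings for one pipeline run."""

    matrix_path: Path
    annotation_path: Path
    out_dir: Path
    probe_map_path: Path | None = None
    reference_paths: list[Path] = field(default_factory=list)
    use_builtin_reference: bool = True
    screen: ScreenConfig = None
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    normalize: bool = True
    subtype: str | None = None

    def validate(self) -> None:
        paths = [self.matrix_path, self.annotation_path]
        if self.probe_map_path:
            paths.append(self.probe_map_path)
        paths.extend(self.reference_paths)
        for p in paths:
            if not Path(p).exists():
                raise LoadError(f"input path does not exist: {p}")
        if self.screen is None:
            raise LoadError("a ScreenConfig (at least the anchor probe) is required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_screen(config: RunConfig) -> dict:
    """Run the complete screen and write the artifact bundle.

    Returns the manifest dict.  Raises on any stage failure with the stage
    named in the log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage read: loading inputs")
    model = CAFGeneScreen.from_files(
        config.matrix_path,
        config.annotation_path,
        config.screen,
        probe_map_path=config.probe_map_path,
        normalization=config.normalization,
        normalize=config.normalize,
    )

    logger.info("stage screen: normalizing and screening %d probes", model.raw_matrix.n_probes)
    results = model.fit()
    results.to_tsv(out / "screen_table.tsv")

    refs: list[ReferenceGeneSet] = []
    if config.use_builtin_reference:
        refs.append(crc_cafg_reference())
    for p in config.reference_paths:
        refs.append(ReferenceGeneSet.from_tsv(p))

    logger.info("stage compare: %d reference set(s)", len(refs))
    overlaps = {}
    for ref in refs:
        report = results.overlap_with(ref)
        overlaps[ref.name] = report.to_dict()
        with open(out / f"overlap_{ref.name}.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)

    subtype_report = None
    if config.subtype:
        logger.info("stage subtype-screen: %s", config.subtype)
        sub = results.subtype_screen(config.subtype)
        subtype_report = {
            "subtype": sub.subtype,
            "n_subset": sub.n_subset,
            "r_subset_min": sub.r_subset_min,
            "r_full_max": sub.r_full_max,
            "shared": list(sub.shared),
            "subtype_specific": list(sub.subtype_specific),
        }
        with open(out / "subtype_screen.json", "w") as fh:
            json.dump(subtype_report, fh, indent=2)

    if config.screen.reference_sample is not None:
        ranked = results.ranked_expression()
        with open(out / "ranked_expression.tsv", "w") as fh:
            fh.write("rank\tprobe_id\n")
            for i, p in enumerate(ranked, 1):
                fh.write(f"{i}\t{p}\n")

    summary = {
        "tier_counts": results.tier_counts(),
        "threshold_counts": results.threshold_counts(),
        "n_probes": len(results.records),
        "n_tumors": results.design.n_tumors,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    inputs = {"matrix": config.matrix_path, "annotation": config.annotation_path}
    if config.probe_map_path:
        inputs["probe_map"] = config.probe_map_path
    manifest = {
        "version": __version__,
        "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in inputs.items()},
        "config": {
            "screen": dataclasses.asdict(config.screen),
            "normalization": dataclasses.asdict(config.normalization),
            "normalize": config.normalize,
            "subtype": config.subtype,
        },
        "summary": summary,
        "overlaps": overlaps,
        "subtype_screen": subtype_report,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", out)
    return manifest
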