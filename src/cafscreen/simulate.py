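"""Synthetic paired-compartment cohorts with planted ground truth.

The generator emulates the statistical structure the screen assumes in a
microdissected cohort: a per-tumor latent CAF-activation factor f_t that
synchronises a block of stromal genes (the anchor among them), per-gene
stroma/epithelium fold-changes, multiplicative log-normal measurement
noise, a constant housekeeping probe, and per-sample scale jitter that the
housekeeping correction must remove.

Generative model (linear scale), for tumor t and gene g:

    stroma_{g,t}     = b_g * rho_g * exp(lambda_g * f_t) * eps
    epithelium_{g,t} = b_g * eps'

with f_t ~ N(0, 1) and eps, eps' independent log-normal with log2-scale
standard deviation ``noise_sigma_log2``.  Subtype-block genes follow the
anchor factor only in tumors of the target subtype; elsewhere they carry
gene-private tumor-to-tumor variability (log-sd ``subtype_private_sd``)
uncoupled from f_t, so their full-cohort anchor correlation stays low while
the within-subtype correlation is high.

Every draw is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    ProbeMap,
    write_annotation_tsv,
    write_expression_tsv,
    write_probe_map_tsv,
)

ANCHOR_PROBE = "sim_anchor_at"
ANCHOR_GENE = "SPARC"
HOUSEKEEPING_PROBE = "217398_x_at"
CONSTANT_PROBE = "sim_const_at"

BLOCKS = ("background", "anchor_block", "subtype_block")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationParams:
    """Cohort shape, planted effects and noise levels.

    Defaults mirror the breast-cancer cohort the screen targets: 28 tumors,
    two compartments each, ~5 TNBC tumors.  Per-gene fold-changes and
    loadings may be supplied explicitly; otherwise they are drawn from
    documented distributions (anchor-block SE ratios log-uniform in
    [5, 25], i.e. CAFG-like; background log-uniform in [0.5, 2];
    subtype-block in [2, 6], matching the low stromal specificity seen for
    subtype-restricted genes).
    """

    n_tumors: int = 28
    n_background_genes: int = 200
    n_block_genes: int = 30
    n_subtype_block_genes: int = 0
    n_subtype_tumors: int = 5
    subtype: str = "TNBC"
    baseline_b: float = 100.0
    noise_sigma_log2: float = 0.3
    housekeeping_value: float = 1000.0
    sample_scale_jitter: bool = True
    jitter_sigma_log2: float = 0.5
    subtype_private_sd: float = 2.0
    include_constant_gene: bool = False
    seed: int = 0
    # optional explicit per-gene parameters, keyed by block
    planted_se_rho: dict[str, np.ndarray] | None = None
    loading_lambda: dict[str, np.ndarray] | None = None

    def validate(self) -> None:
        if self.n_tumors < 1:
            raise SimulationError("n_tumors must be >= 1")
        if self.n_subtype_tumors > self.n_tumors:
            raise SimulationError("n_subtype_tumors cannot exceed n_tumors")
        if self.n_subtype_block_genes > 0 and self.n_subtype_tumors < 1:
            raise SimulationError("subtype block requires at least one subtype tumor")
        for name, v in (
            ("baseline_b", self.baseline_b),
            ("housekeeping_value", self.housekeeping_value),
        ):
            if v <= 0:
                raise SimulationError(f"{name} must be strictly positive")
        for name, v in (
            ("noise_sigma_log2", self.noise_sigma_log2),
            ("jitter_sigma_log2", self.jitter_sigma_log2),
            ("subtype_private_sd", self.subtype_private_sd),
        ):
            if v < 0:
                raise SimulationError(f"{name} must be non-negative")
        for d in (self.planted_se_rho, self.loading_lambda):
            if d:
                for block, arr in d.items():
                    if block not in BLOCKS:
                        raise SimulationError(f"unknown block {block!r}")
                    if np.any(np.asarray(arr) < 0):
                        raise SimulationError("planted parameters must be non-negative")


@dataclass
class SimTruth:
    """Planted parameters of a simulated cohort."""

    genes: pd.DataFrame  # probe_id, gene_symbol, block, se_rho, loading_lambda
    tumors: pd.DataFrame  # tumor_id, latent_f, subtype

    def rho(self, probe_id: str) -> float:
        return float(self.genes.set_index("probe_id").loc[probe_id, "se_rho"])


def _draw_gene_params(params: SimulationParams, rng: np.random.Generator):
    """Per-gene baselines, fold-changes and loadings for each block."""
    nb, nk, ns = params.n_background_genes, params.n_block_genes, params.n_subtype_block_genes
    rho = {
        "background": np.exp(rng.uniform(np.log(0.5), np.log(2.0), nb)),
        "anchor_block": np.exp(rng.uniform(np.log(5.0), np.log(25.0), nk)),
        "subtype_block": np.exp(rng.uniform(np.log(2.0), np.log(6.0), ns)),
    }
    lam = {
        "background": np.zeros(nb),
        "anchor_block": rng.uniform(0.6, 0.95, nk),
        "subtype_block": rng.uniform(0.9, 1.0, ns),
    }
    if nk > 0:
        lam["anchor_block"][0] = 1.0  # the anchor carries the largest loading
    if params.planted_se_rho:
        for block, arr in params.planted_se_rho.items():
            rho[block] = np.asarray(arr, dtype=float)
    if params.loading_lambda:
        for block, arr in params.loading_lambda.items():
            lam[block] = np.asarray(arr, dtype=float)
    baselines = {
        block: params.baseline_b * np.exp2(rng.uniform(-2.0, 2.0, len(rho[block])))
        for block in BLOCKS
    }
    return rho, lam, baselines


def simulate_cohort(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth, ProbeMap]:
    """Simulate one paired-compartment cohort.

    Returns the raw (jittered, un-normalized) expression matrix, the sample
    annotation, the planted truth and a probe map.  The anchor probe is
    ``sim_anchor_at`` (gene symbol SPARC); the housekeeping probe keeps the
    id of the GAPDH probe the pipeline defaults to.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nt = params.n_tumors
    tumor_ids = [f"T{i + 1:02d}" for i in range(nt)]

    subtype_idx = np.sort(rng.choice(nt, size=params.n_subtype_tumors, replace=False))
    subtypes = np.array(["luminal"] * nt, dtype=object)
    subtypes[subtype_idx] = params.subtype
    is_subtype = np.zeros(nt, dtype=bool)
    is_subtype[subtype_idx] = True

    f = rng.standard_normal(nt)
    rho, lam, baselines = _draw_gene_params(params, rng)

    probe_ids: list[str] = []
    gene_symbols: list[str] = []
    blocks: list[str] = []
    rows_s: list[np.ndarray] = []
    rows_e: list[np.ndarray] = []
    truth_rho: list[float] = []
    truth_lam: list[float] = []

    sigma_ln = params.noise_sigma_log2 * np.log(2.0)

    def noise(size):
        return np.exp(sigma_ln * rng.standard_normal(size))

    for block in ("anchor_block", "subtype_block", "background"):
        for j in range(len(rho[block])):
            b, r_g, l_g = baselines[block][j], rho[block][j], lam[block][j]
            if block == "anchor_block":
                pid = ANCHOR_PROBE if j == 0 else f"sim_blk{j:04d}_at"
                gene = ANCHOR_GENE if j == 0 else f"BLK{j:04d}"
                drive = l_g * f
            elif block == "subtype_block":
                pid, gene = f"sim_sub{j:04d}_at", f"SUB{j:04d}"
                private = params.subtype_private_sd * rng.standard_normal(nt)
                drive = np.where(is_subtype, l_g * f, private)
            else:
                pid, gene = f"sim_bg{j:04d}_at", f"BG{j:04d}"
                drive = np.zeros(nt)
            rows_s.append(b * r_g * np.exp(drive) * noise(nt))
            rows_e.append(b * noise(nt))
            probe_ids.append(pid)
            gene_symbols.append(gene)
            blocks.append(block)
            truth_rho.append(float(r_g))
            truth_lam.append(float(l_g))

    if params.include_constant_gene:
        probe_ids.append(CONSTANT_PROBE)
        gene_symbols.append("CONST")
        blocks.append("background")
        rows_s.append(np.full(nt, 5.0))
        rows_e.append(np.full(nt, 5.0))
        truth_rho.append(1.0)
        truth_lam.append(0.0)

    probe_ids.append(HOUSEKEEPING_PROBE)
    gene_symbols.append("GAPDH")
    blocks.append("background")
    rows_s.append(np.full(nt, params.housekeeping_value))
    rows_e.append(np.full(nt, params.housekeeping_value))
    truth_rho.append(1.0)
    truth_lam.append(0.0)

    stroma = np.vstack(rows_s)
    epith = np.vstack(rows_e)
    values = np.empty((len(probe_ids), 2 * nt))
    values[:, 0::2] = stroma
    values[:, 1::2] = epith

    sample_ids = []
    for tid in tumor_ids:
        sample_ids.extend([f"{tid}_str", f"{tid}_epi"])
    if params.sample_scale_jitter:
        scales = np.exp2(params.jitter_sigma_log2 * rng.standard_normal(2 * nt))
        values = values * scales[np.newaxis, :]

    matrix = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))
    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tumor_id": np.repeat(tumor_ids, 2),
            "compartment": ["stroma", "epithelium"] * nt,
            "subtype": np.repeat(subtypes, 2),
        }
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene_symbol": gene_symbols,
                "block": blocks,
                "se_rho": truth_rho,
                "loading_lambda": truth_lam,
            }
        ),
        tumors=pd.DataFrame({"tumor_id": tumor_ids, "latent_f": f, "subtype": subtypes}),
    )
    probe_map = ProbeMap(dict(zip(probe_ids, gene_symbols)))
    return matrix, annotation, truth, probe_map


FIXTURE_PARAMS: dict[str, SimulationParams] = {
    "noisefree": SimulationParams(
        n_tumors=12, n_background_genes=40, n_block_genes=8, noise_sigma_log2=0.0, seed=11
    ),
    "noisy": SimulationParams(
        n_tumors=28, n_background_genes=60, n_block_genes=12, noise_sigma_log2=0.3, seed=12
    ),
    "subtype": SimulationParams(
        n_tumors=28,
        n_background_genes=60,
        n_block_genes=10,
        n_subtype_block_genes=6,
        n_subtype_tumors=5,
        noise_sigma_log2=0.0,
        seed=13,
    ),
    "degenerate": SimulationParams(
        n_tumors=10,
        n_background_genes=20,
        n_block_genes=5,
        noise_sigma_log2=0.2,
        include_constant_gene=True,
        seed=14,
    ),
    "missing_compartment": SimulationParams(
        n_tumors=6, n_background_genes=15, n_block_genes=4, noise_sigma_log2=0.2, seed=15
    ),
}


def write_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the deterministic fixture family used by the test suite.

    Each fixture directory holds expression.tsv, annotation.tsv,
    probe_map.tsv, truth_genes.tsv and truth_tumors.tsv.  The
    ``missing_compartment`` fixture drops one tumor's epithelium sample to
    exercise the design-building exclusion path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, params in FIXTURE_PARAMS.items():
        matrix, annotation, truth, probe_map = simulate_cohort(params)
        if name == "missing_compartment":
            drop = annotation.iloc[-1]["sample_id"]  # last tumor's epithelium
            matrix = ExpressionMatrix(matrix.data.drop(columns=[drop]))
            annotation = annotation[annotation["sample_id"] != drop]
        d = out_dir / name
        d.mkdir(exist_ok=True)
        write_expression_tsv(matrix, d / "expression.tsv")
        write_annotation_tsv(annotation, d / "annotation.tsv")
        write_probe_map_tsv(probe_map, d / "probe_map.tsv")
        truth.genes.to_csv(d / "truth_genes.tsv", sep="\t", index=False)
        truth.tumors.to_csv(d / "truth_tumors.tsv", sep="\t", index=False)
        written[name] = d
    return written
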