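"""Deterministic synthetic-data generation with planted, recoverable structure.

Every bundle is fully determined by its spec (including the mandatory seed):
base per-gene expression is drawn from one of the six distribution families,
designated DE genes are multiplied by a fold change in the second condition,
a per-sample multiplicative "unwanted" factor is applied to all genes
(controls included), optional lognormal cell noise is layered on, and the
result is rounded to integer counts (rounded, not truncated, to preserve
means).  The truth record stores every planted parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from transtat.exceptions import ValidationError
from transtat.io_formats import (
    ControlGeneSet,
    DETable,
    ExpressionMatrix,
    GeneLengthTable,
    SampleMetadata,
    write_matrix,
    write_table,
)

__all__ = ["FixtureSpec", "FixtureBundle", "sample_family", "generate", "write_bundle"]

_FAMILY_DEFAULTS = {
    "lognormal": {"mu": 4.0, "sigma": 1.0},
    "pareto": {"alpha": 1.5, "xmin": 5.0},
    "loglogistic": {"shape": 3.0, "scale": 50.0},
    "gamma": {"shape": 2.0, "scale": 50.0},
    "weibull": {"shape": 1.5, "scale": 100.0},
    "burr": {"c": 2.0, "k": 1.5, "scale": 80.0},
}


def sample_family(family: str, params: dict[str, float], size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` values from one of the six families via inverse CDF."""
    u = rng.random(size)
    if family == "lognormal":
        return np.exp(params["mu"] + params["sigma"] * rng.standard_normal(size))
    if family == "pareto":
        return params["xmin"] * (1.0 - u) ** (-1.0 / params["alpha"])
    if family == "loglogistic":
        return params["scale"] * (u / (1.0 - u)) ** (1.0 / params["shape"])
    if family == "gamma":
        return params["scale"] * rng.gamma(params["shape"], size=size)
    if family == "weibull":
        return params["scale"] * rng.weibull(params["shape"], size=size)
    if family == "burr":
        return params["scale"] * ((1.0 - u) ** (-1.0 / params["k"]) - 1.0) ** (
            1.0 / params["c"]
        )
    raise ValidationError(f"unknown distribution family: {family!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic bundle; the seed is mandatory."""

    seed: int
    n_genes: int = 200
    n_samples: int = 6
    conditions: tuple[str, str] = ("Control", "Treated")
    family: str = "lognormal"
    family_params: dict | None = None
    sample_factors: tuple[float, ...] | None = None
    de_fraction: float = 0.1
    de_fold: float = 4.0
    n_controls: int = 20
    noise_sd: float = 0.0
    gene_length_range: tuple[int, int] = (500, 5000)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValidationError("need n_genes >= 1 and n_samples >= 2")
        if self.n_controls > self.n_genes:
            raise ValidationError("control-gene count exceeds n_genes")
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.de_fold <= 0:
            raise ValidationError("de_fold must be > 0")
        if self.family not in _FAMILY_DEFAULTS:
            raise ValidationError(f"unknown distribution family: {self.family!r}")
        if self.sample_factors is not None and len(self.sample_factors) != self.n_samples:
            raise ValidationError("sample_factors length must equal n_samples")


@dataclass
class FixtureBundle:
    matrix: ExpressionMatrix
    lengths: GeneLengthTable
    controls: ControlGeneSet
    metadata: SampleMetadata
    de_table: DETable
    truth: dict = field(repr=False, default_factory=dict)


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate a bundle; identical specs yield byte-identical CSV output."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]
    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    half = spec.n_samples // 2
    cond_of = {
        s: (spec.conditions[0] if i < half else spec.conditions[1])
        for i, s in enumerate(samples)
    }

    params = dict(_FAMILY_DEFAULTS[spec.family])
    if spec.family_params:
        params.update(spec.family_params)
    base = sample_family(spec.family, params, spec.n_genes, rng)

    n_de = int(round(spec.de_fraction * spec.n_genes))
    # DE genes never overlap controls: controls must stay stable by design.
    perm = rng.permutation(spec.n_genes)
    de_idx = np.sort(perm[:n_de])
    control_pool = perm[n_de:]
    if len(control_pool) < spec.n_controls:
        raise ValidationError("not enough non-DE genes to serve as controls")
    control_idx = np.sort(control_pool[: spec.n_controls])

    if spec.sample_factors is not None:
        factors = np.asarray(spec.sample_factors, dtype=float)
    else:
        factors = np.ones(spec.n_samples)

    values = np.tile(base[:, None], (1, spec.n_samples))
    treated_cols = np.array([cond_of[s] == spec.conditions[1] for s in samples])
    if n_de:
        values[np.ix_(de_idx, treated_cols)] *= spec.de_fold
    values = values * factors[None, :]
    if spec.noise_sd > 0:
        values = values * np.exp(
            spec.noise_sd * rng.standard_normal(values.shape)
        )
    counts = np.round(values)

    matrix = ExpressionMatrix(
        gene_ids=genes, sample_ids=samples, values=counts, is_raw_counts=True
    )
    lengths = GeneLengthTable(
        lengths={
            g: int(l)
            for g, l in zip(
                genes,
                rng.integers(
                    spec.gene_length_range[0], spec.gene_length_range[1] + 1, spec.n_genes
                ),
            )
        }
    )
    controls = ControlGeneSet(genes={genes[i] for i in control_idx})
    metadata = SampleMetadata(conditions=cond_of)

    de_genes = {genes[i] for i in de_idx}
    log2fc = np.where(np.isin(np.arange(spec.n_genes), de_idx), np.log2(spec.de_fold), 0.0)
    pvals = np.where(
        np.isin(np.arange(spec.n_genes), de_idx),
        rng.uniform(1e-8, 1e-4, spec.n_genes),
        rng.uniform(0.05, 1.0, spec.n_genes),
    )
    de_table = DETable(
        table=pd.DataFrame({"gene": genes, "log2fc": log2fc, "pvalue": pvals})
    )

    truth = {
        "seed": spec.seed,
        "family": spec.family,
        "family_params": params,
        "de_genes": sorted(de_genes),
        "de_fold": spec.de_fold,
        "sample_factors": factors.tolist(),
        "control_genes": sorted(controls.genes),
        "conditions": {s: cond_of[s] for s in samples},
        "noise_sd": spec.noise_sd,
    }
    return FixtureBundle(
        matrix=matrix,
        lengths=lengths,
        controls=controls,
        metadata=metadata,
        de_table=de_table,
        truth=truth,
    )


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the five CSVs plus truth.json; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.csv",
        "lengths": outdir / "gene_lengths.csv",
        "controls": outdir / "control_genes.csv",
        "metadata": outdir / "metadata.csv",
        "de_table": outdir / "de_table.csv",
        "truth": outdir / "truth.json",
    }
    write_matrix(bundle.matrix, paths["matrix"])
    write_table(
        pd.DataFrame(
            {"gene": list(bundle.lengths.lengths), "length": list(bundle.lengths.lengths.values())}
        ),
        paths["lengths"],
    )
    paths["controls"].write_text("\n".join(sorted(bundle.controls.genes)) + "\n")
    write_table(
        pd.DataFrame(
            {
                "sample": list(bundle.metadata.conditions),
                "condition": list(bundle.metadata.conditions.values()),
            }
        ),
        paths["metadata"],
    )
    write_table(bundle.de_table.table, paths["de_table"])
    paths["truth"].write_text(json.dumps(bundle.truth, indent=2, sort_keys=True) + "\n")
    return paths
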