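"""Synthetic-data generators for every stage of the pipeline.

The expression generator embodies the model's central assumption — that
relative expression is an affine function of the probability of RNAPII
occupancy — over the combinatorial targeting design used throughout
(control, each single site, each pair, all three sites, for three sites),
with Gaussian replicate noise on the linear fold-change scale.  Companion
generators produce Ct tables that round-trip exactly through the ddCt
pipeline at zero noise, and Poisson region-count matrices with known
enrichment for the ChIP normalization.  Every generator is a pure function
of its seed and configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip import CountMatrix, RegionSet
from .expression import CtTable
from .fitting import ExpressionTable
from .model import ACTIVATION, ExperimentalState, ModelSpec, ParameterSet, p_rnapii

__all__ = [
    "SimulationConfig",
    "default_design",
    "gen_parameters",
    "simulate_expression",
    "gen_ct_table",
    "gen_chip_fixture",
]


def default_design(n_sites: int = 3, mode: str = ACTIVATION) -> list[ExperimentalState]:
    """Control plus every nonempty targeted combination (8 states for 3 sites)."""
    states = [ExperimentalState(frozenset(), mode)]
    for size in range(1, n_sites + 1):
        for combo in itertools.combinations(range(n_sites), size):
            states.append(ExperimentalState(frozenset(combo), mode))
    return states


def gen_parameters(
    n_sites: int, seed: int, bounds: tuple[float, float] = (-5.0, 5.0)
) -> ParameterSet:
    """Uniform i.i.d. ground-truth energies within ``bounds`` (10 values for 3 sites)."""
    lo, hi = bounds
    if lo > hi:
        raise ValueError("bounds must satisfy lo <= hi")
    rng = np.random.default_rng(seed)
    spec = ModelSpec(n_sites)
    theta = rng.uniform(lo, hi, size=spec.n_parameters)
    return ParameterSet.from_vector(theta, n_sites)


@dataclass
class SimulationConfig:
    """Ground truth and observation model for a simulated expression study.

    ``affine_scale`` (a) and ``affine_offset`` (b) map occupancy probability
    to relative fold change, truth = a * p(RNAPII) + b; defaults a=30, b=1
    span fold changes of roughly 1-30, matching strong synthetic
    activation.  ``noise_sd`` is the replicate SD as a fraction of the
    scale a.  ``noise`` may be "normal" (linear-scale Gaussian, default)
    or "lognormal" (Gaussian on log fold change).
    """

    n_sites: int = 3
    ground_truth: ParameterSet | None = None
    design: list[ExperimentalState] | None = None
    affine_scale: float = 30.0
    affine_offset: float = 1.0
    noise_sd: float = 0.05
    n_replicates: int = 4
    seed: int = 0
    noise: str = "normal"
    spec: ModelSpec = field(default_factory=lambda: None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.affine_scale <= 0:
            raise ValueError("affine_scale must be positive")
        if self.affine_offset < 0 or self.noise_sd < 0:
            raise ValueError("affine_offset and noise_sd must be nonnegative")
        if self.noise not in ("normal", "lognormal"):
            raise ValueError(f"noise must be 'normal' or 'lognormal', got {self.noise!r}")
        if self.spec is None:
            self.spec = ModelSpec(self.n_sites)
        if self.ground_truth is None:
            self.ground_truth = gen_parameters(self.n_sites, self.seed)
        if self.design is None:
            self.design = default_design(self.n_sites)
        if len(set(self.design)) != len(self.design):
            raise ValueError("design states must be distinct")


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionTable, pd.DataFrame]:
    """Simulate a replicate expression table plus its noiseless truth.

    Returns the aggregated :class:`ExpressionTable` (replicate mean, SEM, n
    per condition) and a truth frame with each condition's p(RNAPII) and
    noiseless relative expression (including the control's, so downstream
    checks can renormalize).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E1]))
    a, b = config.affine_scale, config.affine_offset
    records, truth_rows = [], []
    for state in config.design:
        p = p_rnapii(config.ground_truth, state, config.spec)
        truth = a * p + b
        if config.noise_sd == 0:
            reps = np.full(config.n_replicates, truth)
        elif config.noise == "normal":
            reps = truth + rng.normal(0.0, config.noise_sd * a, size=config.n_replicates)
            reps = np.maximum(reps, 1e-9)  # fold changes stay positive
        else:
            reps = truth * np.exp(rng.normal(0.0, config.noise_sd, size=config.n_replicates))
        n = reps.size
        sem = float(np.std(reps, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        records.append((state, float(reps.mean()), sem, n))
        truth_rows.append(
            {"targeted": state.to_label(), "mode": state.mode, "p_rnapii": p, "truth": truth}
        )
    table = ExpressionTable.from_records(records)
    return table, pd.DataFrame(truth_rows)


def gen_ct_table(
    conditions: list[str],
    fold_changes: dict[str, float],
    reference_gene: str = "CTCF",
    target_gene: str = "GENE",
    control_condition: str = "control",
    base_ct: float = 28.0,
    reference_ct: float = 20.0,
    n_replicates: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CtTable:
    """Ct fixture whose noiseless ddCt round-trip returns ``fold_changes`` exactly.

    The target gene's Ct sits ``log2(fold)`` cycles below the control
    condition's baseline; the reference gene is flat.  Gaussian noise of
    ``noise_sd`` cycles is added independently to every measurement.
    """
    if control_condition not in conditions:
        raise ValueError("conditions must include the control condition")
    if abs(fold_changes.get(control_condition, 1.0) - 1.0) > 1e-12:
        raise ValueError("control condition must have fold change 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC7]))
    rows = []
    for cond in conditions:
        fc = fold_changes.get(cond, 1.0)
        if fc <= 0:
            raise ValueError(f"fold change for {cond!r} must be positive")
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "condition": cond,
                    "gene": target_gene,
                    "replicate": rep,
                    "ct": base_ct - np.log2(fc) + rng.normal(0, noise_sd),
                }
            )
            rows.append(
                {
                    "condition": cond,
                    "gene": reference_gene,
                    "replicate": rep,
                    "ct": reference_ct + rng.normal(0, noise_sd),
                }
            )
    return CtTable(pd.DataFrame(rows))


def gen_chip_fixture(
    n_regions: int = 20,
    enrichment_map: dict[str, float] | None = None,
    library_sizes: dict[str, float] | None = None,
    n_controls: int = 4,
    base_rate_rpm: float = 50.0,
    seed: int = 0,
) -> tuple[CountMatrix, RegionSet, RegionSet]:
    """Poisson region-count fixture with known enrichment structure.

    Returns ``(counts, regions, control_regions)``.  Expected counts are
    ``base_rate_rpm * enrichment * library_size / 1e6``; ``enrichment_map``
    maps ``(region, sample)`` keys written as "region:sample" to fold
    enrichment over baseline (default 1 everywhere).  The last
    ``n_controls`` regions are background controls with enrichment fixed
    at 1 in every sample, mirroring the promoter control regions used to
    normalize HA ChIP.
    """
    if library_sizes is None:
        library_sizes = {"targeted": 2_000_000.0, "control": 1_000_000.0}
    enrichment_map = enrichment_map or {}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCB1]))

    names = [f"region_{i:03d}" for i in range(n_regions)]
    ctrl_names = [f"control_{i + 1}" for i in range(n_controls)]
    all_names = names + ctrl_names
    frame = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.arange(len(all_names)) * 5000,
            "end": np.arange(len(all_names)) * 5000 + 2000,
            "name": all_names,
        }
    )
    regions = RegionSet(frame)
    controls = RegionSet(frame[frame["name"].isin(ctrl_names)])

    samples = list(library_sizes)
    counts = np.empty((len(all_names), len(samples)))
    for j, sample in enumerate(samples):
        lib = library_sizes[sample]
        for i, region in enumerate(all_names):
            enr = 1.0 if region in ctrl_names else enrichment_map.get(f"{region}:{sample}", 1.0)
            counts[i, j] = rng.poisson(base_rate_rpm * enr * lib / 1e6)
    matrix = CountMatrix(
        pd.DataFrame(counts, index=all_names, columns=samples),
        pd.Series(library_sizes),
    )
    return matrix, regions, controls
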