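"""Synthetic data generation for every pipeline stage.

Emulates an HPLC detector with a linear response ``area = F * C + a`` plus
optional multiplicative (CV-style) noise, two-fold serial-dilution
calibration series, multi-batch content tables with two planted groups and
optional outlier batches, spike-recovery designs, and small random
interaction graphs.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .network import InteractionNetwork
from .qams import SamplePrep

__all__ = [
    "AnalyteSpec",
    "SimulationConfig",
    "gen_calibration",
    "gen_batches",
    "gen_recovery_design",
    "gen_network",
    "default_config",
]


@dataclass(frozen=True)
class AnalyteSpec:
    """Ground-truth detector response for one analyte."""

    name: str
    true_slope: float
    true_intercept: float
    top_conc: float  # ug/ml, highest calibration level
    rt: float = 10.0  # nominal retention time, minutes

    def __post_init__(self) -> None:
        if self.true_slope <= 0:
            raise ValueError(f"{self.name}: slope must be positive")
        if self.top_conc <= 0:
            raise ValueError(f"{self.name}: top concentration must be positive")


@dataclass
class SimulationConfig:
    """All knobs for the synthetic dataset.

    ``group_means`` holds one dict of per-analyte true w/w% per latent
    group; ``group_sizes`` must sum to ``batches - n_outliers``.  Outlier
    batches draw their contents from the first group's means shifted by
    ``outlier_shift_sd`` group standard deviations.
    """

    seed: int = 1
    analytes: list[AnalyteSpec] = field(default_factory=list)
    n_levels: int = 6
    dilution_factor: float = 2.0
    noise_cv: float = 0.0
    additive_noise_sd: float = 0.0
    batches: int = 14
    group_means: list[dict[str, float]] = field(default_factory=list)
    group_sd: dict[str, float] = field(default_factory=dict)
    group_sizes: list[int] | None = None
    n_outliers: int = 0
    outlier_shift_sd: float = 6.0
    prep: SamplePrep = field(default_factory=lambda: SamplePrep(mass=0.5, volume=100.0))

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.additive_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.group_means:
            sizes = self.resolved_group_sizes()
            if sum(sizes) != self.batches - self.n_outliers:
                raise ValueError(
                    "group sizes must sum to batches minus outliers"
                )

    def resolved_group_sizes(self) -> list[int]:
        if self.group_sizes is not None:
            return list(self.group_sizes)
        n = self.batches - self.n_outliers
        k = len(self.group_means)
        base = n // k
        sizes = [base] * k
        for i in range(n - base * k):
            sizes[i] += 1
        return sizes


def default_config(seed: int = 1, noise_cv: float = 0.01) -> SimulationConfig:
    """A four-analyte, six-level, fourteen-batch configuration.

    Two latent groups of 5 and 6 batches plus 3 outliers, matching the
    scale of a typical multi-batch herbal quality study.
    """
    analytes = [
        AnalyteSpec("GA", 8.6962, 10.2544, 365.0, rt=4.0),
        AnalyteSpec("TEGG", 6.84, -61.1284, 1018.0, rt=18.66),
        AnalyteSpec("EA", 43.0207, -89.5458, 123.0, rt=19.46),
        AnalyteSpec("PEGG", 5.6759, -50.9605, 436.0, rt=27.64),
    ]
    group_means = [
        {"GA": 3.4, "TEGG": 4.5, "EA": 0.62, "PEGG": 2.6},
        {"GA": 4.1, "TEGG": 6.2, "EA": 0.50, "PEGG": 3.1},
    ]
    group_sd = {"GA": 0.25, "TEGG": 0.45, "EA": 0.05, "PEGG": 0.15}
    return SimulationConfig(
        seed=seed,
        analytes=analytes,
        noise_cv=noise_cv,
        batches=14,
        group_means=group_means,
        group_sd=group_sd,
        group_sizes=[5, 6],
        n_outliers=3,
    )


def _noisy_area(
    rng: np.random.Generator, clean: float, noise_cv: float, additive_sd: float
) -> float:
    area = clean
    if noise_cv > 0:
        area += rng.normal(0.0, noise_cv * abs(clean))
    if additive_sd > 0:
        area += rng.normal(0.0, additive_sd)
    return area


def gen_calibration(config: SimulationConfig) -> pd.DataFrame:
    """Serial-dilution calibration series for every analyte.

    Returns a long frame with columns ``analyte, conc_ug_ml, area``.
    """
    if not config.analytes:
        raise ValueError("no analytes configured")
    rng = np.random.default_rng(config.seed)
    rows = []
    for spec in config.analytes:
        for i in range(config.n_levels):
            conc = spec.top_conc / config.dilution_factor**i
            clean = spec.true_slope * conc + spec.true_intercept
            rows.append(
                {
                    "analyte": spec.name,
                    "conc_ug_ml": conc,
                    "area": _noisy_area(
                        rng, clean, config.noise_cv, config.additive_noise_sd
                    ),
                }
            )
    return pd.DataFrame(rows)


def content_to_concentration(w_pct: float, prep: SamplePrep) -> float:
    """Invert the w/w% formula back to a solution concentration (ug/ml)."""
    return w_pct * prep.mass * 1e6 / (100.0 * prep.volume * prep.dilution)


def gen_batches(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch peak areas plus the ground-truth content table.

    Returns ``(peaks, truth)``: peaks with columns ``batch_id, analyte,
    rt_min, area``; truth with ``batch_id, analyte, true_w_pct, group,
    outlier``.  Outlier batches are flagged with group 0.
    """
    if not config.group_means:
        raise ValueError("no group means configured")
    sizes = config.resolved_group_sizes()
    rng = np.random.default_rng(config.seed + 1)
    assignments: list[int] = []
    for g, size in enumerate(sizes, start=1):
        assignments.extend([g] * size)
    assignments.extend([0] * config.n_outliers)  # 0 marks outliers
    peak_rows, truth_rows = [], []
    for idx, group in enumerate(assignments, start=1):
        batch_id = f"B{idx:02d}"
        means = (
            config.group_means[0]
            if group == 0
            else config.group_means[group - 1]
        )
        for spec in config.analytes:
            sd = config.group_sd.get(spec.name, 0.0)
            mean = means[spec.name]
            if group == 0:
                mean = mean + config.outlier_shift_sd * (sd if sd > 0 else 0.1 * mean)
            w_true = mean if sd == 0 else rng.normal(mean, sd)
            w_true = max(w_true, 0.0)
            conc = content_to_concentration(w_true, config.prep)
            clean = spec.true_slope * conc + spec.true_intercept
            area = _noisy_area(rng, clean, config.noise_cv, config.additive_noise_sd)
            peak_rows.append(
                {
                    "batch_id": batch_id,
                    "analyte": spec.name,
                    "rt_min": spec.rt,
                    "area": max(area, 0.0),
                }
            )
            truth_rows.append(
                {
                    "batch_id": batch_id,
                    "analyte": spec.name,
                    "true_w_pct": w_true,
                    "group": group,
                    "outlier": group == 0,
                }
            )
    return pd.DataFrame(peak_rows), pd.DataFrame(truth_rows)


def gen_recovery_design(
    config: SimulationConfig,
    base_amounts_mg: dict[str, float],
    levels: Sequence[float] = (0.8, 1.0, 1.2),
    replicates: int = 3,
    recovery_sd: float = 0.0,
) -> pd.DataFrame:
    """Spike-recovery rows at fractions of the known content per analyte.

    Found amounts are sample + spike with optional relative noise; returns
    ``analyte, sample_mg, spiked_mg, found_mg``.
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for spec in config.analytes:
        base = base_amounts_mg[spec.name]
        for level in levels:
            spike = base * level
            for _ in range(replicates):
                found = base + spike
                if recovery_sd > 0:
                    found += rng.normal(0.0, recovery_sd * spike)
                rows.append(
                    {
                        "analyte": spec.name,
                        "sample_mg": base,
                        "spiked_mg": spike,
                        "found_mg": found,
                    }
                )
    return pd.DataFrame(rows)


def gen_network(n_nodes: int, n_edges: int, seed: int = 1) -> InteractionNetwork:
    """Uniform random simple graph with exactly the requested size."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    possible = list(combinations(range(n_nodes), 2))
    if n_edges > len(possible):
        raise ValueError(
            f"{n_edges} edges infeasible for {n_nodes} nodes (max {len(possible)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(possible), size=n_edges, replace=False)
    nodes = [f"N{i + 1}" for i in range(n_nodes)]
    edges = [(nodes[possible[i][0]], nodes[possible[i][1]]) for i in chosen]
    return InteractionNetwork.from_edges(edges, nodes=nodes)
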