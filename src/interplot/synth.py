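"""Synthetic marker panels, kinship and field layouts.

Provides self-contained stand-ins for a breeding trial's inputs so the
whole analysis stack can run without external downloads: biallelic SNP
dosages under Hardy-Weinberg proportions (optionally with full-sib
family structure via shared parents), the relationship matrix derived
from them, and a rectangular Range x Column layout with replicated check
clones interspersed among mostly-unreplicated test clones.

Defaults mirror the simulation study's source trial: 829 genotypes of
which 11 are checks, on 2 m x 1 m plots whose long edge is shared
between Ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import FieldLayout, LongEdgeAxis
from .kinship import DosageMatrix, KinshipMatrix, additive_grm

__all__ = [
    "SyntheticConfig",
    "simulate_markers",
    "generate_layout",
    "generate_dataset",
]

DEFAULT_N_GENOTYPES = 829
DEFAULT_N_CHECKS = 11


@dataclass(frozen=True)
class SyntheticConfig:
    n_genotypes: int = DEFAULT_N_GENOTYPES
    n_checks: int = DEFAULT_N_CHECKS
    n_markers: int = 1000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_ranges: int | None = None
    n_columns: int | None = None
    plot_width: float = 1.0
    plot_length: float = 2.0
    family_structure: bool = False
    family_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_checks < self.n_genotypes):
            raise ValueError("need 0 < n_checks < n_genotypes")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < low <= high <= 0.5")
        if self.n_markers < 1:
            raise ValueError("need at least one marker")

    @property
    def check_ids(self) -> list:
        return [f"check{i + 1:02d}" for i in range(self.n_checks)]

    @property
    def test_ids(self) -> list:
        return [f"clone{i + 1:04d}" for i in range(self.n_genotypes - self.n_checks)]

    @property
    def genotype_ids(self) -> list:
        return self.check_ids + self.test_ids

    def family_of(self, test_index: int) -> int:
        return test_index // self.family_size


def simulate_markers(config: SyntheticConfig, rng: np.random.Generator | None = None) -> DosageMatrix:
    """Biallelic dosages under Hardy-Weinberg proportions.

    Allele frequencies are uniform on [maf_low, maf_high].  With
    ``family_structure`` test clones are full-sib progeny of per-family
    parent pairs (checks stay unrelated), which raises within-family
    kinship above the background.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_markers
    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    n_tests = len(config.test_ids)
    checks = rng.binomial(2, p, size=(config.n_checks, m)).astype(float)
    if not config.family_structure:
        tests = rng.binomial(2, p, size=(n_tests, m)).astype(float)
    else:
        n_fam = math.ceil(n_tests / config.family_size)
        parents = rng.binomial(2, p, size=(n_fam, 2, m))
        tests = np.empty((n_tests, m))
        for i in range(n_tests):
            p1, p2 = parents[config.family_of(i)]
            # one gamete from each parent: P(transmit alt) = dosage / 2
            tests[i] = rng.binomial(1, p1 / 2.0) + rng.binomial(1, p2 / 2.0)
    dosages = np.vstack([checks, tests])
    return DosageMatrix(dosages, config.genotype_ids, [f"snp{j + 1:05d}" for j in range(m)])


def _grid_shape(n_plots: int, config: SyntheticConfig) -> tuple[int, int]:
    n_cols = config.n_columns
    if n_cols is None:
        # roughly square field in metres given the default 2 x 1 plots
        n_cols = max(2, round(math.sqrt(n_plots * config.plot_width / (2 * config.plot_length))) * 2)
    n_ranges = config.n_ranges or math.ceil(n_plots / n_cols)
    if n_ranges * n_cols < n_plots:
        raise ValueError(
            f"field {n_ranges} x {n_cols} cannot hold {n_plots} plots"
        )
    return n_ranges, n_cols


def layout_from_clone_sequence(
    clones: list, config: SyntheticConfig
) -> FieldLayout:
    """Fill the Range x Column grid row-major with the given clone order."""
    n = len(clones)
    n_ranges, n_cols = _grid_shape(n, config)
    idx = np.arange(n)
    return FieldLayout(
        plot_ids=np.array([f"plot{i + 1:05d}" for i in idx]),
        range_idx=idx // n_cols + 1,
        col_idx=idx % n_cols + 1,
        clone_ids=np.array(clones, dtype=object),
        plot_width=config.plot_width,
        plot_length=config.plot_length,
        long_edge_axis=LongEdgeAxis.BETWEEN_RANGES,
    )


def generate_layout(config: SyntheticConfig, rng: np.random.Generator | None = None) -> FieldLayout:
    """Unreplicated-tests layout: checks twice, tests once.

    Checks are interspersed at evenly spaced plot positions.  Without
    family structure the test order is randomised; with it, families
    stay contiguous (so sibs sit in adjacent plots of a Range) while the
    family order is randomised.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    tests = list(config.test_ids)
    if config.family_structure:
        n_fam = math.ceil(len(tests) / config.family_size)
        fam_order = rng.permutation(n_fam)
        tests = [
            t
            for f in fam_order
            for t in tests[f * config.family_size : (f + 1) * config.family_size]
        ]
    else:
        tests = [tests[i] for i in rng.permutation(len(tests))]
    check_plots = list(config.check_ids) * 2
    n_total = len(tests) + len(check_plots)
    positions = np.linspace(0, n_total - 1, num=len(check_plots), dtype=int)
    clones: list = []
    it_tests = iter(tests)
    it_checks = iter(check_plots)
    pos_set = set(positions.tolist())
    for i in range(n_total):
        clones.append(next(it_checks) if i in pos_set else next(it_tests))
    return layout_from_clone_sequence(clones, config)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[FieldLayout, DosageMatrix, KinshipMatrix]:
    """Layout, markers and kinship from one seeded configuration."""
    rng = np.random.default_rng(config.seed)
    dosages = simulate_markers(config, rng)
    layout = generate_layout(config, rng)
    return layout, dosages, additive_grm(dosages)
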