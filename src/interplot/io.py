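"""File readers/writers and dataset cleaning.

Field files are plain CSVs with columns ``clone``, ``Range``, ``Column``
(1-based grid indices) and one column per trait.  Kinship and dosage
matrices are labelled CSVs; dosages may alternatively come from a VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import remove_outliers
from .geometry import FieldLayout, LongEdgeAxis, build_incidence
from .kinship import DosageMatrix, KinshipMatrix, additive_grm, filter_maf
from .mixed_model import ModelKind, ModelSpec

logger = logging.getLogger("interplot")

FIELD_COLUMNS = ("clone", "Range", "Column")


@dataclass
class CleanDataset:
    """Analysis-ready trait data: one averaged record per plot, clones
    matched to the kinship matrix, Base-model outliers removed."""

    layout: FieldLayout
    y: np.ndarray
    K: np.ndarray
    clone_index: dict
    genotype_ids: list
    n_dropped_missing: int = 0
    n_dropped_unmatched: int = 0
    n_averaged: int = 0
    removed_outlier_plots: list = field(default_factory=list)


def read_field_csv(
    path,
    plot_width: float = 1.0,
    plot_length: float = 2.0,
    long_edge: str = "ranges",
) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"field CSV lacks required column(s) {missing}")
    df.attrs["plot_width"] = plot_width
    df.attrs["plot_length"] = plot_length
    df.attrs["long_edge"] = long_edge
    return df


def layout_from_frame(
    df: pd.DataFrame,
    plot_width: float = 1.0,
    plot_length: float = 2.0,
    long_edge: str = "ranges",
) -> FieldLayout:
    axis = (
        LongEdgeAxis.BETWEEN_RANGES if long_edge == "ranges" else LongEdgeAxis.BETWEEN_COLUMNS
    )
    return FieldLayout(
        plot_ids=np.array(
            [f"R{r}C{c}" for r, c in zip(df["Range"].astype(int), df["Column"].astype(int))]
        ),
        range_idx=df["Range"].to_numpy(int),
        col_idx=df["Column"].to_numpy(int),
        clone_ids=df["clone"].astype(str).to_numpy(object),
        plot_width=plot_width,
        plot_length=plot_length,
        long_edge_axis=axis,
    )


def write_field_csv(path, layout: FieldLayout, traits: dict) -> None:
    df = pd.DataFrame(
        {
            "clone": layout.clone_ids,
            "Range": layout.range_idx,
            "Column": layout.col_idx,
        }
    )
    for name, values in traits.items():
        df[name] = values
    df.to_csv(path, index=False)


def load_and_clean(
    field: pd.DataFrame,
    trait: str,
    kinship: KinshipMatrix,
    plot_width: float = 1.0,
    plot_length: float = 2.0,
    long_edge: str = "ranges",
    drop_outliers: bool = True,
    seed: int = 0,
) -> CleanDataset:
    """Initial processing for one trait.

    Removes records missing the trait, averages duplicate records per
    (Range, Column) plot, intersects clones with the kinship matrix
    (dropped clones are logged), and screens Base-model outliers.
    """
    if trait not in field.columns:
        raise ValueError(f"trait column {trait!r} not in field file")
    df = field.dropna(subset=[trait]).copy()
    n_missing = len(field) - len(df)
    before = len(df)
    df = (
        df.groupby(["Range", "Column", "clone"], as_index=False, sort=False)[trait]
        .mean()
    )
    n_avg = before - len(df)
    known = set(map(str, kinship.genotype_ids))
    matched = df["clone"].astype(str).isin(known)
    n_unmatched = int((~matched).sum())
    if n_unmatched:
        examples = sorted(set(df.loc[~matched, "clone"].astype(str)))[:5]
        logger.warning("dropping %d plots with clones absent from K: %s", n_unmatched, examples)
    df = df[matched]
    if df.empty:
        raise ValueError(
            "no overlap between field clones and the kinship matrix; e.g. "
            f"K has {list(map(str, kinship.genotype_ids[:3]))}"
        )
    used = sorted(set(df["clone"].astype(str)), key=str)
    K = kinship.subset(used)
    layout = layout_from_frame(df, plot_width, plot_length, long_edge)
    y = df[trait].to_numpy(float)
    clone_index = {gid: i for i, gid in enumerate(used)}
    removed: list = []
    if drop_outliers:
        inc = build_incidence(layout, clone_index, _nn_long())
        base_spec = ModelSpec(ModelKind.BASE, inc, K.values)
        report = remove_outliers(y, base_spec, plot_ids=layout.plot_ids, seed=seed)
        if len(report.removed_rows):
            keep = report.keep_rows
            df = df.iloc[keep]
            layout = layout_from_frame(df, plot_width, plot_length, long_edge)
            y = y[keep]
            removed = list(report.removed_plot_ids)
            logger.info("removed %d outlier plot(s): %s", len(removed), removed[:10])
    return CleanDataset(
        layout=layout,
        y=y,
        K=K.values,
        clone_index=clone_index,
        genotype_ids=used,
        n_dropped_missing=n_missing,
        n_dropped_unmatched=n_unmatched,
        n_averaged=n_avg,
        removed_outlier_plots=removed,
    )


def _nn_long():
    from .geometry import CompetitionFunction, FunctionKind

    return CompetitionFunction(FunctionKind.NN_LONG)


def load_kinship(path) -> KinshipMatrix:
    return KinshipMatrix.from_csv(path)


def dosages_to_kinship(path, maf_threshold: float = 0.01, vcf: bool = False) -> KinshipMatrix:
    d = DosageMatrix.from_vcf(path) if vcf else DosageMatrix.from_csv(path)
    return additive_grm(filter_maf(d, maf_threshold))
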