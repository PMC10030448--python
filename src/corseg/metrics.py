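"""Contour comparison metrics: DSC, mean distance to agreement, Hausdorff
distance and volume ratio, plus cohort summaries.

Surfaces are represented by boundary voxel centres (labelled voxels with at
least one 6-neighbour outside the mask); all distances are Euclidean in
world mm using the physical voxel spacing.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask

__all__ = [
    "dsc",
    "surface_distances",
    "volume_ratio",
    "MetricReport",
    "compare_structure_sets",
    "cohort_summary",
]

METRIC_COLUMNS = ("dsc", "mda_mm", "hd_mm", "volume_ratio")


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    if not a.grid.same_geometry(b.grid):
        raise ValueError("masks are on different grids")
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        raise ValueError("DSC undefined for two empty masks")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def _boundary(values: np.ndarray) -> np.ndarray:
    """Boundary voxels: labelled with a 6-neighbour outside the mask."""
    m = values.astype(bool)
    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1))
    return m & ~eroded


def surface_distances(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    """Symmetric mean distance to agreement and maximum Hausdorff distance.

    Returns ``(mda_mm, hd_mm)``: the MDA averages the two directed mean
    boundary-to-boundary distances; the HD is the maximum of the two
    directed maxima (the 100th percentile, not HD95).
    """
    if a.is_empty or b.is_empty:
        raise ValueError("surface distances require non-empty masks")
    if not a.grid.same_geometry(b.grid):
        raise ValueError("masks are on different grids")
    spacing = a.grid.spacing
    sa, sb = _boundary(a.values), _boundary(b.values)
    # distance from every voxel to the nearest boundary voxel centre of the
    # other mask, in physical units
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = dist_to_b[sa]
    d_ba = dist_to_a[sb]
    mda = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    hd = max(float(d_ab.max()), float(d_ba.max()))
    return mda, hd


def volume_ratio(auto: BinaryMask, ref: BinaryMask) -> float:
    """Physical volume quotient automatic / reference."""
    if ref.is_empty:
        raise ValueError("volume ratio undefined for empty reference")
    return auto.volume_mm3 / ref.volume_mm3


class MetricReport:
    """Per-structure DSC / MDA / HD / volume-ratio records for one case."""

    def __init__(self, records: Mapping[str, Mapping[str, float]], case_id: str = ""):
        self.case_id = case_id
        self._df = pd.DataFrame.from_dict(dict(records), orient="index").reindex(
            columns=list(METRIC_COLUMNS)
        )
        self._df.index.name = "structure"

    @property
    def table(self) -> pd.DataFrame:
        return self._df.copy()

    def __getitem__(self, structure: str) -> pd.Series:
        return self._df.loc[structure]

    def structures(self) -> list[str]:
        return list(self._df.index)

    def to_csv(self, path) -> None:
        df = self._df.reset_index()
        df.insert(0, "case", self.case_id)
        df.to_csv(path, index=False)


def compare_structure_sets(auto, reference, case_id: str = "") -> MetricReport:
    """Metric report over the structures present in both sets."""
    records: dict[str, dict[str, float]] = {}
    for name in auto.names():
        if name not in reference:
            continue
        a, r = auto[name], reference[name]
        if a.is_empty and r.is_empty:
            continue
        rec: dict[str, float] = {}
        rec["dsc"] = dsc(a, r)
        if not a.is_empty and not r.is_empty:
            rec["mda_mm"], rec["hd_mm"] = surface_distances(a, r)
            rec["volume_ratio"] = volume_ratio(a, r)
        else:
            rec["mda_mm"] = rec["hd_mm"] = float("nan")
            rec["volume_ratio"] = 0.0 if a.is_empty else float("inf")
        records[name] = rec
    return MetricReport(records, case_id=case_id)


def cohort_summary(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Per-structure, per-metric summary across cases.

    Columns: median, median absolute deviation, mean, standard deviation,
    quartiles, and the case ids whose value falls beyond 1.5 x IQR outside
    the quartiles (the usual box-plot outlier rule).
    """
    if not reports:
        raise ValueError("cohort_summary requires at least one report")
    frames = []
    for i, rep in enumerate(reports):
        df = rep.table.reset_index()
        df["case"] = rep.case_id or f"case_{i}"
        frames.append(df)
    long = pd.concat(frames, ignore_index=True).melt(
        id_vars=["case", "structure"], value_vars=list(METRIC_COLUMNS),
        var_name="metric", value_name="value",
    ).dropna(subset=["value"])

    rows = []
    for (structure, metric), grp in long.groupby(["structure", "metric"], sort=True):
        v = grp["value"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        out = grp["case"][(grp["value"] < q1 - 1.5 * iqr) | (grp["value"] > q3 + 1.5 * iqr)]
        rows.append({
            "structure": structure,
            "metric": metric,
            "median": med,
            "mad": float(np.median(np.abs(v - med))),
            "mean": float(v.mean()),
            "std": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "q1": q1,
            "q3": q3,
            "n": len(v),
            "outliers": ",".join(sorted(out)),
        })
    return pd.DataFrame(rows)
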