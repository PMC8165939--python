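"""Per-timepoint shape measurements on refined Delta masks.

The feature set is the standard morphometric panel used in high-content
screening (CellProfiler-style): area, perimeter, form factor 4*pi*A/P^2
(1 for a perfect disk, lower for branched shapes), eccentricity, solidity,
extent, moment-ellipse axis lengths, and the width-to-length ratio
(minor/major axis — the elongation readout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from .delta import SpheroidMask
from .io_plate import PlateLayout

TABLE_COLUMNS = [
    "well_id",
    "timepoint",
    "condition",
    "area_px2",
    "area_um2",
    "perimeter",
    "form_factor",
    "eccentricity",
    "solidity",
    "extent",
    "major_axis_len",
    "minor_axis_len",
    "width_to_length_ratio",
    "centroid_row",
    "centroid_col",
    "empty",
]

#: numeric shape features consumed by the PCA profiling stage
FEATURE_NAMES = [
    "area_px2",
    "perimeter",
    "form_factor",
    "eccentricity",
    "solidity",
    "extent",
    "major_axis_len",
    "minor_axis_len",
    "width_to_length_ratio",
]


@dataclass
class FeatureRecord:
    well_id: str
    timepoint: int
    condition: str | None
    area_px2: float
    area_um2: float
    perimeter: float
    form_factor: float
    eccentricity: float
    solidity: float
    extent: float
    major_axis_len: float
    minor_axis_len: float
    width_to_length_ratio: float
    centroid_row: float
    centroid_col: float
    empty: bool

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class FeatureTable:
    """Ordered per-(well, timepoint) feature records."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        self.df = self.df[TABLE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_dataframe(self) -> pd.DataFrame:
        return self.df.copy()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        df = df.copy()
        df["empty"] = df["empty"].astype(bool)
        return cls(df)

    @classmethod
    def from_records(cls, records: list[FeatureRecord]) -> "FeatureTable":
        return cls(pd.DataFrame([r.as_dict() for r in records], columns=TABLE_COLUMNS))

    @property
    def feature_names(self) -> list[str]:
        return list(FEATURE_NAMES)

    def equals(self, other: "FeatureTable", atol: float = 1e-9) -> bool:
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype.kind in "fc" or b[c].dtype.kind in "fc":
                av = a[c].to_numpy(dtype=float)
                bv = b[c].to_numpy(dtype=float)
                both_nan = np.isnan(av) & np.isnan(bv)
                close = np.isclose(av, bv, rtol=0, atol=atol)
                if not np.all(both_nan | close):
                    return False
            elif not a[c].equals(b[c]):
                return False
        return True


def _empty_record(mask: SpheroidMask, well_id: str, condition: str | None) -> FeatureRecord:
    nan = float("nan")
    return FeatureRecord(
        well_id=well_id,
        timepoint=mask.timepoint,
        condition=condition,
        area_px2=nan,
        area_um2=nan,
        perimeter=nan,
        form_factor=nan,
        eccentricity=nan,
        solidity=nan,
        extent=nan,
        major_axis_len=nan,
        minor_axis_len=nan,
        width_to_length_ratio=nan,
        centroid_row=nan,
        centroid_col=nan,
        empty=True,
    )


def measure(
    mask: SpheroidMask,
    pixel_size: float | None = None,
    well_id: str = "",
    condition: str | None = None,
) -> FeatureRecord:
    """Measure the shape of a mask's retained object.

    Perimeter uses the Crofton boundary-length estimator (accurate for
    smooth rasterized outlines, where pixel-edge counting overshoots); the axis
    lengths and eccentricity come from the image-moment equivalent ellipse.
    An empty mask yields an empty-flagged record with missing features.
    """
    if mask.empty:
        return _empty_record(mask, well_id, condition)
    lab = label(mask.mask, connectivity=2)
    props = regionprops(lab)
    r = max(props, key=lambda p: p.area)  # the single retained object
    area = float(r.area)
    perim = float(r.perimeter_crofton)
    form_factor = 4.0 * math.pi * area / (perim * perim) if perim > 0 else float("nan")
    major = float(r.axis_major_length)
    minor = float(r.axis_minor_length)
    wlr = minor / major if major > 0 else float("nan")
    return FeatureRecord(
        well_id=well_id,
        timepoint=mask.timepoint,
        condition=condition,
        area_px2=area,
        area_um2=area * pixel_size**2 if pixel_size is not None else float("nan"),
        perimeter=perim,
        form_factor=form_factor,
        eccentricity=float(r.eccentricity),
        solidity=float(r.solidity),
        extent=float(r.extent),
        major_axis_len=major,
        minor_axis_len=minor,
        width_to_length_ratio=wlr,
        centroid_row=float(r.centroid[0]),
        centroid_col=float(r.centroid[1]),
        empty=False,
    )


def assemble_table(records: list[FeatureRecord], layout: PlateLayout) -> FeatureTable:
    """Join conditions from the layout and sort records by (well, timepoint).

    Raises on wells missing from the layout, duplicate (well, timepoint)
    pairs, and gaps in a well's timepoint range.
    """
    if not records:
        raise ValueError("no records to assemble")
    rows = []
    for r in records:
        if r.well_id not in layout.conditions:
            raise KeyError(f"record well {r.well_id!r} not present in plate layout")
        d = r.as_dict()
        d["condition"] = layout.condition_of(r.well_id)
        rows.append(d)
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    dup = df.duplicated(subset=["well_id", "timepoint"])
    if dup.any():
        pair = df.loc[dup, ["well_id", "timepoint"]].iloc[0]
        raise ValueError(f"duplicate record for well {pair.well_id} timepoint {pair.timepoint}")
    df = df.sort_values(["well_id", "timepoint"], kind="mergesort").reset_index(drop=True)
    for well, grp in df.groupby("well_id"):
        tps = grp["timepoint"].to_numpy()
        if not np.array_equal(tps, np.arange(tps[0], tps[0] + len(tps))):
            raise ValueError(f"well {well}: timepoints are not contiguous")
    return FeatureTable(df)
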