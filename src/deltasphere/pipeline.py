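"""End-to-end conveniences tying the stages together."""

from __future__ import annotations

from .delta import SegmentationConfig, SpheroidMask, segment_series
from .io_plate import FrameSeries, PlateLayout
from .morphometry import FeatureTable, assemble_table, measure


def segment_plate(
    series_list: list[FrameSeries], config: SegmentationConfig = SegmentationConfig()
) -> dict[str, list[SpheroidMask]]:
    """Segment every well independently; returns masks keyed by well id."""
    return {s.well_id: segment_series(s, config) for s in series_list}


def plate_feature_table(
    series_list: list[FrameSeries],
    masks_by_well: dict[str, list[SpheroidMask]],
    layout: PlateLayout,
) -> FeatureTable:
    """Measure every mask and assemble the plate-wide feature table."""
    records = []
    for series in series_list:
        for m in masks_by_well[series.well_id]:
            records.append(
                measure(m, pixel_size=series.pixel_size, well_id=series.well_id)
            )
    return assemble_table(records, layout)
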