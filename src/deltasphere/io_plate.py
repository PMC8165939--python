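"""Plate-level I/O: image series, layouts, and result tables.

Time-lapse images live on disk as one grayscale TIFF/PNG per (well, field,
timepoint), with metadata encoded in the filename. Wells are acquired
independently, so each well becomes one :class:`FrameSeries`. Plates imaged
with a 2x2 field grid are tiled into a single frame per timepoint by plain
abutment (no registration or blending).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

DEFAULT_PATTERN = "{well}_f{field:02d}_t{timepoint:03d}.tif"


@dataclass(frozen=True)
class PlateLayout:
    """Mapping from well id (e.g. ``"B02"``) to condition label."""

    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise ValueError("layout must contain at least one well")

    @property
    def wells(self) -> list[str]:
        return list(self.conditions)

    def condition_of(self, well_id: str) -> str:
        try:
            return self.conditions[well_id]
        except KeyError:
            raise KeyError(f"well {well_id!r} not present in plate layout") from None

    def wells_for(self, condition: str) -> list[str]:
        return [w for w, c in self.conditions.items() if c == condition]

    @property
    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions.values():
            if c not in seen:
                seen.append(c)
        return seen

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        df = pd.read_csv(path, dtype=str)
        missing = {"well", "condition"} - set(df.columns)
        if missing:
            raise ValueError(f"layout file {path} missing columns: {sorted(missing)}")
        if df["well"].duplicated().any():
            dups = df.loc[df["well"].duplicated(), "well"].tolist()
            raise ValueError(f"duplicate well ids in layout: {dups}")
        return cls(dict(zip(df["well"], df["condition"])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"well": list(self.conditions), "condition": list(self.conditions.values())}
        ).to_csv(path, index=False)


@dataclass
class FrameSeries:
    """One well's ordered grayscale time-lapse.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"B02"``.
    frames : ndarray, shape (T, H, W)
        Unsigned-integer grayscale frames, uniform shape and dtype.
    condition : str or None
        Culture-condition label, if known.
    interval : float
        Hours between consecutive frames (> 0).
    pixel_size : float or None
        Micrometres per pixel, if calibrated.
    t0_index : int
        Timepoint index of the first frame (timepoints are 1-based).
    """

    well_id: str
    frames: np.ndarray
    condition: str | None = None
    interval: float = 1.0
    pixel_size: float | None = None
    t0_index: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frames.shape[0] < 2:
            raise ValueError("a FrameSeries needs at least 2 frames")
        if not np.issubdtype(self.frames.dtype, np.unsignedinteger):
            raise ValueError(
                f"frames must be unsigned integer, got {self.frames.dtype}"
            )
        if self.interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return int(self.frames.shape[0])

    @property
    def timepoints(self) -> np.ndarray:
        """1-based timepoint indices of the stored frames."""
        return np.arange(self.t0_index, self.t0_index + self.n_timepoints)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def frame_at(self, timepoint: int) -> np.ndarray:
        i = timepoint - self.t0_index
        if not 0 <= i < self.n_timepoints:
            raise IndexError(
                f"timepoint {timepoint} outside series range "
                f"[{self.t0_index}, {self.t0_index + self.n_timepoints - 1}]"
            )
        return self.frames[i]


def tile_fields(fields: Sequence[np.ndarray], grid: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Tile per-field rasters into one well image by row-major abutment."""
    rows, cols = grid
    if len(fields) != rows * cols:
        raise ValueError(f"expected {rows * cols} fields for a {grid} grid, got {len(fields)}")
    arrs = [np.asarray(f) for f in fields]
    shape0, dtype0 = arrs[0].shape, arrs[0].dtype
    for i, a in enumerate(arrs):
        if a.shape != shape0 or a.dtype != dtype0:
            raise ValueError(
                f"field {i} has shape {a.shape} dtype {a.dtype}, expected {shape0} {dtype0}"
            )
    return np.block([[arrs[r * cols + c] for c in range(cols)] for r in range(rows)])


_PLACEHOLDER_RE = re.compile(r"\{(well|field|timepoint)(?::0?(\d+)d)?\}")


def _pattern_to_regex(pattern: str) -> re.Pattern:
    """Compile a ``{well}{field}{timepoint}`` filename template to a regex."""
    out: list[str] = []
    pos = 0
    seen: set[str] = set()
    for m in _PLACEHOLDER_RE.finditer(pattern):
        out.append(re.escape(pattern[pos : m.start()]))
        name = m.group(1)
        if name in seen:
            raise ValueError(f"placeholder {{{name}}} repeated in pattern {pattern!r}")
        seen.add(name)
        if name == "well":
            out.append(r"(?P<well>[A-Za-z0-9]+?)")
        else:
            width = m.group(2)
            out.append(rf"(?P<{name}>\d{{{width},}})" if width else rf"(?P<{name}>\d+)")
        pos = m.end()
    out.append(re.escape(pattern[pos:]))
    if "well" not in seen or "timepoint" not in seen:
        raise ValueError("pattern must contain {well} and {timepoint} placeholders")
    return re.compile("".join(out) + r"$")


def format_filename(pattern: str, well: str, field: int, timepoint: int) -> str:
    """Render the filename template for one image."""
    return pattern.format(well=well, field=field, timepoint=timepoint)


def load_series(
    directory: str | Path,
    pattern: str = DEFAULT_PATTERN,
    layout: PlateLayout | None = None,
    interval: float = 1.0,
    pixel_size: float | None = None,
) -> list[FrameSeries]:
    """Load every well's time-lapse from a directory of per-image files.

    Filenames are parsed against ``pattern``; per-well timepoints must form a
    contiguous integer range. When several fields exist per timepoint they are
    tiled (2x2, row-major field order) before insertion.
    """
    directory = Path(directory)
    rx = _pattern_to_regex(pattern)
    found: dict[str, dict[int, dict[int, Path]]] = {}
    for p in sorted(directory.iterdir()):
        m = rx.match(p.name)
        if not m:
            continue
        well = m.group("well")
        tp = int(m.group("timepoint"))
        fld = int(m.group("field")) if "field" in m.groupdict() and m.group("field") else 1
        found.setdefault(well, {}).setdefault(tp, {})[fld] = p
    if not found:
        raise FileNotFoundError(f"no files matching pattern {pattern!r} in {directory}")

    series: list[FrameSeries] = []
    for well in sorted(found):
        tps = sorted(found[well])
        expected = list(range(tps[0], tps[-1] + 1))
        missing = sorted(set(expected) - set(tps))
        if missing:
            raise ValueError(f"well {well}: missing timepoint {missing[0]} (gaps: {missing})")
        frames: list[np.ndarray] = []
        for tp in expected:
            by_field = found[well][tp]
            imgs = [np.asarray(iio.imread(by_field[f])) for f in sorted(by_field)]
            for img in imgs:
                if img.ndim != 2:
                    raise ValueError(f"{well} t{tp}: expected 2-D grayscale, got shape {img.shape}")
            frame = imgs[0] if len(imgs) == 1 else tile_fields(imgs)
            frames.append(frame)
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"well {well}: mixed frame shapes {sorted(shapes)}")
        condition = layout.condition_of(well) if layout is not None else None
        series.append(
            FrameSeries(
                well_id=well,
                frames=np.stack(frames),
                condition=condition,
                interval=interval,
                pixel_size=pixel_size,
                t0_index=expected[0],
            )
        )
    return series


def write_series(
    series: FrameSeries,
    directory: str | Path,
    pattern: str = DEFAULT_PATTERN,
    field: int = 1,
) -> list[Path]:
    """Write one frame per timepoint using the filename convention."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for tp, frame in zip(series.timepoints, series.frames):
        p = directory / format_filename(pattern, series.well_id, field, int(tp))
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def write_feature_table(table, path: str | Path) -> None:
    """Write a FeatureTable to CSV (one row per well x timepoint)."""
    from .morphometry import FeatureTable  # local import avoids a cycle

    if not isinstance(table, FeatureTable):
        raise TypeError("expected a FeatureTable")
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    table.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path):
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    from .morphometry import FeatureTable, TABLE_COLUMNS

    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in TABLE_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns in {path}: {unknown}")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} missing columns: {missing}")
    return FeatureTable.from_dataframe(df[TABLE_COLUMNS])
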