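"""Step-wedge calibration: per-step reference attenuation ranges.

A measuring line is placed transversely through the center of each wedge
step; the minimum and maximum HU sampled along it define that step's
relative-density range.  Ranges are kept per radiograph; replicate tables
(one per subject) are summarized as mean +- SD per step and bound, and the
summary supports coverage/gap analysis of the HU scale per tube setting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .phantom import ExposureSetting, Radiograph, WedgeSpec

__all__ = [
    "MeasuringLine",
    "StepRange",
    "CalibrationTable",
    "CalibrationSummary",
    "sample_measuring_line",
    "step_range",
    "line_for_step",
    "build_calibration_table",
    "summarize_replicates",
    "coverage_interval",
    "range_gaps",
    "load_reference_ranges",
]


@dataclass(frozen=True)
class MeasuringLine:
    """Sampling segment across one wedge step (band of ``width`` pixels)."""

    step_index: int
    start: tuple[float, float]  # (row, col)
    end: tuple[float, float]
    width: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.step_index <= 10:
            raise ValueError("step_index must be in 1..10")
        if self.width < 1:
            raise ValueError("band width must be >= 1 pixel")


@dataclass(frozen=True)
class StepRange:
    """Relative-density range of one step: [min_hu, max_hu], inclusive."""

    step: int
    min_hu: float
    max_hu: float

    def __post_init__(self) -> None:
        if not 1 <= self.step <= 10:
            raise ValueError("step must be in 1..10")
        if self.min_hu > self.max_hu:
            raise ValueError("min_hu must not exceed max_hu")


@dataclass
class CalibrationTable:
    """Per-radiograph ranges for all ten steps, in step order."""

    exposure: ExposureSetting
    ranges: list[StepRange]
    source_id: str = ""

    def __post_init__(self) -> None:
        steps = [r.step for r in self.ranges]
        if sorted(steps) != list(range(1, 11)):
            raise ValueError("calibration table needs steps 1..10 exactly once")
        self.ranges = sorted(self.ranges, key=lambda r: r.step)

    def __getitem__(self, step: int) -> StepRange:
        return self.ranges[step - 1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.ranges:
            rows.append((self.exposure.kv, self.exposure.mas, r.step, "Min", r.min_hu))
            rows.append((self.exposure.kv, self.exposure.mas, r.step, "Max", r.max_hu))
        return pd.DataFrame(rows, columns=["kv", "mas", "step", "bound", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, source_id: str = "") -> "CalibrationTable":
        kv = frame["kv"].unique()
        mas = frame["mas"].unique()
        if len(kv) != 1 or len(mas) != 1:
            raise ValueError("frame holds more than one exposure setting")
        wide = frame.pivot_table(index="step", columns="bound", values="value")
        ranges = [
            StepRange(int(s), float(wide.loc[s, "Min"]), float(wide.loc[s, "Max"]))
            for s in wide.index
        ]
        return cls(ExposureSetting(float(kv[0]), float(mas[0])), ranges, source_id)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        return cls.from_frame(pd.read_csv(path), source_id=str(path))

    def to_json(self, path) -> None:
        payload = {
            "kv": self.exposure.kv,
            "mas": self.exposure.mas,
            "source_id": self.source_id,
            "ranges": [
                {"step": r.step, "min_hu": r.min_hu, "max_hu": r.max_hu}
                for r in self.ranges
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            ExposureSetting(payload["kv"], payload["mas"]),
            [StepRange(r["step"], r["min_hu"], r["max_hu"]) for r in payload["ranges"]],
            payload.get("source_id", ""),
        )


@dataclass
class CalibrationSummary:
    """Replicate summary: mean +- SD per (setting, step, bound).

    Backed by a tidy frame with columns kv, mas, step, bound, mean, sd, n.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("kv", "mas", "step", "bound", "mean", "sd", "n")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValueError(f"summary frame missing columns {sorted(missing)}")
        if (self.frame["n"] < 1).any() or (self.frame["sd"] < 0).any():
            raise ValueError("summary requires n >= 1 and sd >= 0")

    def settings(self) -> list[ExposureSetting]:
        pairs = self.frame[["kv", "mas"]].drop_duplicates().itertuples(index=False)
        return [ExposureSetting(kv, mas) for kv, mas in pairs]

    def for_setting(self, kv: float, mas: float) -> "CalibrationSummary":
        sub = self.frame[(self.frame["kv"] == kv) & (self.frame["mas"] == mas)]
        if sub.empty:
            raise KeyError(f"no summary rows for {kv:g} kV; {mas:g} mAs")
        return CalibrationSummary(sub.reset_index(drop=True))

    def mean_ranges(self) -> list[StepRange]:
        """Per-step ranges built from the replicate means (single setting)."""
        if len(self.frame[["kv", "mas"]].drop_duplicates()) != 1:
            raise ValueError("select a single setting first (for_setting)")
        wide = self.frame.pivot_table(index="step", columns="bound", values="mean")
        return [
            StepRange(int(s), float(wide.loc[s, "Min"]), float(wide.loc[s, "Max"]))
            for s in wide.index
        ]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationSummary":
        return cls(pd.read_csv(path))


def sample_measuring_line(radiograph: Radiograph, line: MeasuringLine) -> np.ndarray:
    """HU values along the segment, nearest-pixel, averaged across the band.

    The band is taken perpendicular to the dominant direction of the
    segment (rows for a mostly-horizontal line).
    """
    nrow, ncol = radiograph.shape
    (r0, c0), (r1, c1) = line.start, line.end
    n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
    if n < 2:
        raise ValueError("measuring line must span at least 2 pixels")
    rows = np.linspace(r0, r1, n)
    cols = np.linspace(c0, c1, n)
    horizontal = abs(c1 - c0) >= abs(r1 - r0)
    offsets = np.arange(line.width) - (line.width - 1) // 2
    acc = np.zeros(n, dtype=float)
    for off in offsets:
        rr = np.rint(rows + (off if horizontal else 0)).astype(int)
        cc = np.rint(cols + (0 if horizontal else off)).astype(int)
        if (rr < 0).any() or (rr >= nrow).any() or (cc < 0).any() or (cc >= ncol).any():
            raise ValueError("measuring line (or its band) falls outside the image")
        acc += radiograph.pixels[rr, cc]
    return acc / line.width


def step_range(samples) -> tuple[float, float]:
    """Raw (min, max) of the sampled HU values; no outlier rejection."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot take min/max of an empty sample list")
    return float(samples.min()), float(samples.max())


def line_for_step(layout: WedgeSpec, step: int, width: int = 1) -> MeasuringLine:
    """Auto-placed line: horizontal, through the footprint centroid, spanning
    the footprint from one edge to the opposite edge."""
    r0, r1, c0, c1 = layout.footprint(step)
    row = (r0 + r1 - 1) / 2.0
    return MeasuringLine(step, (row, float(c0)), (row, float(c1 - 1)), width)


def build_calibration_table(
    radiograph: Radiograph, layout: WedgeSpec | None = None, width: int = 1
) -> CalibrationTable:
    """One StepRange per step from its auto-placed center measuring line."""
    layout = layout or radiograph.wedge_layout
    if layout is None:
        raise ValueError("no wedge layout supplied and none attached to the radiograph")
    ranges = []
    for step in range(1, 11):
        try:
            line = line_for_step(layout, step, width)
        except (IndexError, ValueError) as exc:
            raise ValueError(f"missing or invalid footprint for step S{step}") from exc
        lo, hi = step_range(sample_measuring_line(radiograph, line))
        ranges.append(StepRange(step, lo, hi))
    return CalibrationTable(radiograph.exposure, ranges, radiograph.source_id)


def summarize_replicates(tables: list[CalibrationTable]) -> CalibrationSummary:
    """Mean and sample SD (n-1) per step and bound over replicate tables.

    All tables must share one exposure setting.  With a single replicate the
    SD is reported as 0 with n = 1.
    """
    if not tables:
        raise ValueError("need at least one calibration table")
    exposures = {(t.exposure.kv, t.exposure.mas) for t in tables}
    if len(exposures) != 1:
        raise ValueError(f"mixed exposure settings in replicates: {sorted(exposures)}")
    kv, mas = exposures.pop()
    rows = []
    for step in range(1, 11):
        for bound, attr in (("Min", "min_hu"), ("Max", "max_hu")):
            vals = np.array([getattr(t[step], attr) for t in tables], dtype=float)
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            rows.append((kv, mas, step, bound, float(vals.mean()), sd, vals.size))
    return CalibrationSummary(
        pd.DataFrame(rows, columns=list(CalibrationSummary.REQUIRED))
    )


def _as_ranges(table_or_summary) -> list[StepRange]:
    if isinstance(table_or_summary, CalibrationTable):
        return table_or_summary.ranges
    if isinstance(table_or_summary, CalibrationSummary):
        return table_or_summary.mean_ranges()
    ranges = list(table_or_summary)
    if len(ranges) != 10 or not all(isinstance(r, StepRange) for r in ranges):
        raise TypeError("expected a CalibrationTable, CalibrationSummary, or 10 StepRanges")
    return sorted(ranges, key=lambda r: r.step)


def coverage_interval(table_or_summary) -> tuple[float, float]:
    """(lowest Min, highest Max) over the ten steps: the HU span the density
    standard can decompose at this setting."""
    ranges = _as_ranges(table_or_summary)
    return min(r.min_hu for r in ranges), max(r.max_hu for r in ranges)


def range_gaps(table_or_summary) -> list[float]:
    """Nine consecutive gap widths max(0, Min(S_{k+1}) - Max(S_k)).

    Positive gaps mark dispersion of the density scale (HU values between
    steps that no step covers); zero means adjacency or overlap.
    """
    ranges = _as_ranges(table_or_summary)
    return [
        max(0.0, b.min_hu - a.max_hu) for a, b in zip(ranges[:-1], ranges[1:])
    ]


def load_reference_ranges() -> CalibrationSummary:
    """Published feline-knee reference ranges (mean +- SD over nine limbs) for
    the ten wedge steps at the five study tube settings."""
    with resources.files("cdakit.data").joinpath("reference_ranges.csv").open() as fh:
        return CalibrationSummary(pd.read_csv(fh))
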