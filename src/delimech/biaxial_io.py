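"""Raw biaxial recordings -> Piola stress-stretch curves, and dataset I/O.

A planar biaxial test records forces (mN) and gauge lengths (mm) along two
orthogonal axes while a thin square sample is cycled through one of five
stretch modes.  With reference gauge lengths L1, L2 (mm, taken at the first
step after the pre-load) and sample thickness t (mm), the stretches and
Piola stresses are

    lambda1 = l1/L1      lambda2 = l2/L2
    P11 = F1/(L2*t)      P22 = F2/(L1*t)

and with mN and mm inputs the stresses come out directly in kPa.

The tabular exchange format is a long CSV with columns
``product,mode,direction,stretch,stress_kPa[,stderr_kPa]``; the packaged
reference dataset (eight deli meat products, five modes, eleven points per
curve, mean of loading and unloading over n=8 samples) ships in this
dialect and is returned by :func:`load_reference_dataset`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODES",
    "DIRECTIONS",
    "PRODUCTS",
    "BiaxialRecording",
    "TestProtocol",
    "StretchStressCurve",
    "MeatDataset",
    "to_stretch_stress",
    "set_gauge_reference",
    "trim_to_reference",
    "slice_cycle",
    "extract_cycle",
    "resample_and_average",
    "average_mode",
    "process_recordings",
    "load_dataset",
    "save_dataset",
    "load_reference_dataset",
]

MODES = ("strip-x", "strip-y", "off-x", "off-y", "equibiax")
DIRECTIONS = ("x", "y")
#: Product codes of the packaged reference dataset: four plant-based
#: (turkey, ham, deli, prosciutto) and four animal (turkey, chicken, ham,
#: prosciutto) deli meats.
PRODUCTS = ("PT", "PH", "PD", "PP", "AT", "AC", "AH", "AP")

#: Direction held at stretch 1 in each strip mode.
_HOLD_DIRECTION = {"strip-x": "y", "strip-y": "x"}


class DatasetFormatError(ValueError):
    """A tabular dataset file violates the exchange dialect."""


@dataclass(frozen=True)
class TestProtocol:
    """Loading protocol of a biaxial test.

    preload : mN, slack-removal force applied on both axes before the
        reference gauge lengths are taken.
    stretch_rate : fraction per second of quasi-static stretching.
    max_stretch : target stretch of the leading axis (1.25 for
        prosciutto-style products, 1.10 otherwise).
    cycles : stretch-recovery cycles per mode; curves are conventionally
        taken from the last (third) cycle.
    """

    preload: float = 30.0
    stretch_rate: float = 0.01
    max_stretch: float = 1.10
    cycles: int = 3
    mode_order: tuple[str, ...] = ("strip-y", "off-y", "equibiax", "off-x", "strip-x")

    def __post_init__(self):
        if self.max_stretch <= 1:
            raise ValueError("max_stretch must exceed 1")
        if self.preload < 0:
            raise ValueError("preload must be non-negative")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        unknown = set(self.mode_order) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes in mode_order: {sorted(unknown)}")


@dataclass(frozen=True)
class BiaxialRecording:
    """One raw biaxial time series: forces in mN, lengths in mm."""

    time: np.ndarray
    force_x: np.ndarray
    force_y: np.ndarray
    gauge_x: np.ndarray
    gauge_y: np.ndarray
    thickness: float
    mode_label: str
    cycle_index: int = 1
    phase: str | None = None

    def __post_init__(self):
        arrays = {
            "time": self.time,
            "force_x": self.force_x,
            "force_y": self.force_y,
            "gauge_x": self.gauge_x,
            "gauge_y": self.gauge_y,
        }
        n = None
        for name, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError("all recording channels must have equal length")
        if self.mode_label not in MODES:
            raise ValueError(f"mode_label must be one of {MODES}, got {self.mode_label!r}")
        if not (np.isfinite(self.thickness) and self.thickness > 0):
            raise ValueError("thickness must be positive")
        if np.any(self.gauge_x <= 0) or np.any(self.gauge_y <= 0):
            raise ValueError("gauge lengths must be positive")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.cycle_index < 1:
            raise ValueError("cycle_index must be >= 1")

    def __len__(self) -> int:
        return self.time.size

    def select(self, idx) -> "BiaxialRecording":
        """A new recording restricted to the given index slice/array."""
        return replace(
            self,
            time=self.time[idx],
            force_x=self.force_x[idx],
            force_y=self.force_y[idx],
            gauge_x=self.gauge_x[idx],
            gauge_y=self.gauge_y[idx],
        )


@dataclass
class StretchStressCurve:
    """Paired stretch/Piola-stress samples for one mode and one direction."""

    mode: str
    direction: str
    stretch: np.ndarray
    stress: np.ndarray
    stderr: np.ndarray | None = None

    def __post_init__(self):
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be 'x' or 'y'")
        if self.stretch.shape != self.stress.shape:
            raise ValueError("stretch and stress must have equal length")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.stretch.shape:
                raise ValueError("stderr must match stretch length")
        if np.any(~np.isfinite(self.stress)):
            raise ValueError("stress must be finite")
        if self.stretch.size and self.stretch[0] < 1 - 1e-6:
            raise ValueError("curves start at the reference state (stretch >= 1)")

    @property
    def is_hold(self) -> bool:
        """True for the held (non-stretched) channel of a strip mode."""
        return _HOLD_DIRECTION.get(self.mode) == self.direction

    def __len__(self) -> int:
        return self.stretch.size


@dataclass
class MeatDataset:
    """Five-mode, two-direction stress-stretch curves for one product."""

    product_id: str
    curves: dict[str, dict[str, StretchStressCurve]]
    n_samples: int | None = None
    thickness_mm: float | None = None
    thickness_sd_mm: float | None = None

    def __post_init__(self):
        missing = set(MODES) - set(self.curves)
        if missing:
            raise ValueError(f"dataset {self.product_id}: missing modes {sorted(missing)}")
        for mode, per_dir in self.curves.items():
            if set(per_dir) != set(DIRECTIONS):
                raise ValueError(
                    f"dataset {self.product_id}: mode {mode} must have both directions"
                )

    def curve(self, mode: str, direction: str) -> StretchStressCurve:
        return self.curves[mode][direction]

    def iter_curves(self, include_hold: bool = True) -> Iterator[StretchStressCurve]:
        """Curves in canonical mode/direction order.

        With ``include_hold=False`` the held channels of the strip modes
        are skipped (the convention used for goodness-of-fit).
        """
        for mode in MODES:
            for direction in DIRECTIONS:
                c = self.curves[mode][direction]
                if not include_hold and c.is_hold:
                    continue
                yield c

    def stacked(self, include_hold: bool = True):
        """Stack all curves into arrays (lambda1, lambda2, P, component).

        ``component`` is 0 for the x (11) stress component and 1 for y (22).
        The two directions of one mode share a common stretch pair per row,
        so each curve contributes its own direction's stress at the joint
        (lambda_x, lambda_y) states.
        """
        l1, l2, p, comp = [], [], [], []
        for mode in MODES:
            cx, cy = self.curves[mode]["x"], self.curves[mode]["y"]
            if len(cx) != len(cy):
                raise ValueError(f"mode {mode}: x and y curves are not aligned")
            for c, k in ((cx, 0), (cy, 1)):
                if not include_hold and c.is_hold:
                    continue
                l1.append(cx.stretch)
                l2.append(cy.stretch)
                p.append(c.stress)
                comp.append(np.full(len(c), k))
        return (
            np.concatenate(l1),
            np.concatenate(l2),
            np.concatenate(p),
            np.concatenate(comp).astype(int),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.iter_curves():
            for i in range(len(c)):
                row = {
                    "product": self.product_id,
                    "mode": c.mode,
                    "direction": c.direction,
                    "stretch": c.stretch[i],
                    "stress_kPa": c.stress[i],
                }
                if c.stderr is not None:
                    row["stderr_kPa"] = c.stderr[i]
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recording -> curves


def to_stretch_stress(
    recording: BiaxialRecording, reference_lengths: tuple[float, float]
) -> tuple[StretchStressCurve, StretchStressCurve]:
    """Convert a raw recording to x- and y-direction stress-stretch curves.

    ``reference_lengths`` are the post-preload gauge lengths (L1, L2) in mm,
    typically from :func:`set_gauge_reference`.  Stresses are Piola (force
    over reference area): P11 = F1/(L2*t), P22 = F2/(L1*t), in kPa.
    """
    L1, L2 = reference_lengths
    if L1 <= 0 or L2 <= 0:
        raise ValueError("reference lengths must be positive")
    t = recording.thickness
    lam1 = recording.gauge_x / L1
    lam2 = recording.gauge_y / L2
    P11 = recording.force_x / (L2 * t)
    P22 = recording.force_y / (L1 * t)
    cx = StretchStressCurve(recording.mode_label, "x", lam1, P11)
    cy = StretchStressCurve(recording.mode_label, "y", lam2, P22)
    return cx, cy


def set_gauge_reference(
    recording: BiaxialRecording, protocol: TestProtocol
) -> tuple[float, float]:
    """Reference gauge lengths (L1, L2) at the first step reaching the pre-load.

    The reference is the pair of gauge lengths at the first time step at
    which *both* measured forces are at least ``protocol.preload``.
    """
    ok = (recording.force_x >= protocol.preload) & (recording.force_y >= protocol.preload)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError(
            f"pre-load of {protocol.preload} mN never reached on both axes; "
            "recording unusable"
        )
    k = idx[0]
    return float(recording.gauge_x[k]), float(recording.gauge_y[k])


def trim_to_reference(
    recording: BiaxialRecording, protocol: TestProtocol
) -> tuple[BiaxialRecording, tuple[float, float]]:
    """Drop the slack-removal steps before the pre-load reference.

    Returns the recording from the reference step onward together with the
    reference gauge lengths, so converted curves start at stretch 1.
    """
    ok = (recording.force_x >= protocol.preload) & (recording.force_y >= protocol.preload)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError(
            f"pre-load of {protocol.preload} mN never reached on both axes; "
            "recording unusable"
        )
    k = int(idx[0])
    ref = (float(recording.gauge_x[k]), float(recording.gauge_y[k]))
    return recording.select(slice(k, None)), ref


def _leading_signal(recording: BiaxialRecording) -> np.ndarray:
    """Gauge channel with the larger relative excursion (the driven axis)."""
    gx, gy = recording.gauge_x, recording.gauge_y
    rx = np.ptp(gx) / gx[0]
    ry = np.ptp(gy) / gy[0]
    return gx if rx >= ry else gy


def _monotone_segments(sig: np.ndarray, tol: float = 1e-12):
    """Split a signal into maximal non-decreasing / non-increasing runs.

    Returns a list of (start, stop, sign) index ranges (stop inclusive);
    zero increments extend the current run.
    """
    d = np.diff(sig)
    signs = np.where(d > tol, 1, np.where(d < -tol, -1, 0))
    # zero increments inherit the previous non-zero sign
    last = 0
    for i, s in enumerate(signs):
        if s == 0:
            signs[i] = last
        else:
            last = s
    segments = []
    start = 0
    cur = signs[0] if len(signs) else 0
    for i, s in enumerate(signs):
        if cur == 0:
            cur = s
        if s != cur and s != 0:
            segments.append((start, i, cur))
            start = i
            cur = s
    segments.append((start, len(sig) - 1, cur if cur != 0 else 1))
    return segments


def slice_cycle(
    recording: BiaxialRecording, cycle_index: int, phase: str
) -> BiaxialRecording:
    """Restrict a recording to one loading or unloading leg of one cycle.

    Cycles are counted from 1 as successive (ascending, descending) pairs of
    the driven gauge signal; ``phase`` is ``"loading"`` (non-decreasing
    stretch) or ``"unloading"``.
    """
    if phase not in ("loading", "unloading"):
        raise ValueError("phase must be 'loading' or 'unloading'")
    sig = _leading_signal(recording)
    segments = _monotone_segments(sig)
    wanted_sign = 1 if phase == "loading" else -1
    matches = [seg for seg in segments if seg[2] == wanted_sign]
    if cycle_index > len(matches):
        raise ValueError(
            f"cycle {cycle_index} ({phase}) absent: recording holds only "
            f"{len(matches)} such segment(s)"
        )
    start, stop, _ = matches[cycle_index - 1]
    out = recording.select(slice(start, stop + 1))
    return replace(out, cycle_index=cycle_index, phase=phase)


def extract_cycle(
    recording: BiaxialRecording,
    cycle_index: int,
    phase: str,
    reference_lengths: tuple[float, float],
) -> tuple[StretchStressCurve, StretchStressCurve]:
    """Stress-stretch curves of a single cycle leg (see :func:`slice_cycle`)."""
    return to_stretch_stress(
        slice_cycle(recording, cycle_index, phase), reference_lengths
    )


# ---------------------------------------------------------------------------
# resampling and averaging


def resample_and_average(
    curves: Sequence[StretchStressCurve],
    n_points: int = 11,
    anchor: bool = True,
) -> StretchStressCurve:
    """Average curves of one mode/direction on a common equidistant grid.

    The grid spans stretch 1 to the smallest maximum stretch shared by all
    curves (``n_points`` points, default 11); stresses are linearly
    interpolated onto it and averaged.  ``stderr`` holds the standard error
    across curves.  With ``anchor=True`` the mean curve is shifted so the
    first grid point is exactly (1, 0), which removes any constant pre-load
    offset and matches the convention of the packaged reference data.
    """
    if not curves:
        raise ValueError("need at least one curve")
    mode, direction = curves[0].mode, curves[0].direction
    for c in curves:
        if (c.mode, c.direction) != (mode, direction):
            raise ValueError("all curves must share mode and direction")
        if len(c) < 2:
            raise ValueError("cannot resample a single-point curve")
    lam_max = min(c.stretch.max() for c in curves)
    if lam_max <= 1 + 1e-9:
        raise ValueError(
            "curves share no stretch range above 1 (hold channels must be "
            "averaged against the driven axis; see average_mode)"
        )
    grid = np.linspace(1.0, lam_max, n_points)
    stack = np.empty((len(curves), n_points))
    for i, c in enumerate(curves):
        order = np.argsort(c.stretch, kind="stable")
        stack[i] = np.interp(grid, c.stretch[order], c.stress[order])
    mean = stack.mean(axis=0)
    if len(curves) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(curves))
    else:
        sem = np.zeros(n_points)
    if anchor:
        mean = mean - mean[0]
    return StretchStressCurve(mode, direction, grid, mean, sem)


def average_mode(
    pairs: Sequence[tuple[StretchStressCurve, StretchStressCurve]],
    n_points: int = 11,
    anchor: bool = True,
) -> tuple[StretchStressCurve, StretchStressCurve]:
    """Average aligned (x, y) curve pairs of one mode across samples/legs.

    Both stress components are interpolated as functions of the *driven*
    stretch, so the held channel of a strip mode (stretch pinned at 1, but
    stress varying with the driven axis) is averaged consistently and
    returned with stretch identically 1.
    """
    if not pairs:
        raise ValueError("need at least one curve pair")
    mode = pairs[0][0].mode
    hold_dir = _HOLD_DIRECTION.get(mode)
    # driven direction: x unless strip-y
    lead = "y" if mode == "strip-y" else "x"
    lead_idx = 0 if lead == "x" else 1
    lam_max = min(p[lead_idx].stretch.max() for p in pairs)
    if lam_max <= 1 + 1e-9:
        raise ValueError(f"mode {mode}: no stretch excursion on the driven axis")
    grid = np.linspace(1.0, lam_max, n_points)
    out = []
    for k, direction in enumerate(DIRECTIONS):
        stack = np.empty((len(pairs), n_points))
        for i, pair in enumerate(pairs):
            lead_lam = pair[lead_idx].stretch
            order = np.argsort(lead_lam, kind="stable")
            stack[i] = np.interp(grid, lead_lam[order], pair[k].stress[order])
        mean = stack.mean(axis=0)
        sem = (
            stack.std(axis=0, ddof=1) / np.sqrt(len(pairs))
            if len(pairs) > 1
            else np.zeros(n_points)
        )
        if anchor:
            mean = mean - mean[0]
        lam = np.ones(n_points) if direction == hold_dir else (
            grid if direction == lead else _follower_grid(pairs, k, lead_idx, grid)
        )
        out.append(StretchStressCurve(mode, direction, lam, mean, sem))
    return out[0], out[1]


def _follower_grid(pairs, k, lead_idx, grid):
    """Mean follower-axis stretch evaluated on the driven-axis grid."""
    stack = np.empty((len(pairs), grid.size))
    for i, pair in enumerate(pairs):
        lead_lam = pair[lead_idx].stretch
        order = np.argsort(lead_lam, kind="stable")
        stack[i] = np.interp(grid, lead_lam[order], pair[k].stretch[order])
    return np.maximum(stack.mean(axis=0), 1.0)


def process_recordings(
    recordings_by_mode: Mapping[str, Sequence[BiaxialRecording]],
    protocol: TestProtocol,
    product_id: str = "SYN",
    cycle: int | None = None,
    n_points: int = 11,
) -> MeatDataset:
    """Full pipeline from raw recordings to an averaged dataset.

    For every mode: per recording, take the last cycle's loading and
    unloading legs, convert to stress-stretch with the pre-load gauge
    reference, then average all legs of all samples on a common grid.
    """
    cycle = protocol.cycles if cycle is None else cycle
    curves: dict[str, dict[str, StretchStressCurve]] = {}
    for mode, recs in recordings_by_mode.items():
        pairs = []
        for rec in recs:
            rec, ref = trim_to_reference(rec, protocol)
            for phase in ("loading", "unloading"):
                pairs.append(extract_cycle(rec, cycle, phase, ref))
        cx, cy = average_mode(pairs, n_points=n_points)
        curves[mode] = {"x": cx, "y": cy}
    thickness = [r.thickness for recs in recordings_by_mode.values() for r in recs]
    return MeatDataset(
        product_id,
        curves,
        n_samples=max(len(r) for r in recordings_by_mode.values()),
        thickness_mm=float(np.mean(thickness)),
        thickness_sd_mm=float(np.std(thickness, ddof=1)) if len(thickness) > 1 else None,
    )


# ---------------------------------------------------------------------------
# dataset files

_REQUIRED_COLUMNS = ["product", "mode", "direction", "stretch", "stress_kPa"]


def _frame_to_datasets(df: pd.DataFrame, n_samples=None) -> dict[str, MeatDataset]:
    datasets = {}
    for product, dfp in df.groupby("product", sort=False):
        curves: dict[str, dict[str, StretchStressCurve]] = {}
        for (mode, direction), g in dfp.groupby(["mode", "direction"], sort=False):
            stderr = g["stderr_kPa"].to_numpy() if "stderr_kPa" in g else None
            curve = StretchStressCurve(
                mode, direction, g["stretch"].to_numpy(), g["stress_kPa"].to_numpy(), stderr
            )
            curves.setdefault(mode, {})[direction] = curve
        datasets[product] = MeatDataset(str(product), curves, n_samples=n_samples)
    return datasets


def load_dataset(path, n_samples: int | None = None) -> dict[str, MeatDataset]:
    """Read a long-format dataset CSV into per-product datasets.

    Raises :class:`DatasetFormatError` with the offending row/column for
    files violating the dialect (missing columns, unknown modes, non-numeric
    cells, incomplete mode/direction blocks).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DatasetFormatError(f"{path}: empty dataset file") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")
    bad_mode = ~df["mode"].isin(MODES)
    if bad_mode.any():
        row = int(np.flatnonzero(bad_mode)[0]) + 2  # header is line 1
        raise DatasetFormatError(
            f"{path}: unknown mode {df['mode'][bad_mode].iloc[0]!r} at line {row}"
        )
    bad_dir = ~df["direction"].isin(DIRECTIONS)
    if bad_dir.any():
        row = int(np.flatnonzero(bad_dir)[0]) + 2
        raise DatasetFormatError(f"{path}: bad direction at line {row}")
    for col in ("stretch", "stress_kPa"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0]) + 2
            raise DatasetFormatError(f"{path}: non-numeric {col} at line {row}")
        df[col] = vals
    try:
        return _frame_to_datasets(df, n_samples=n_samples)
    except ValueError as exc:
        raise DatasetFormatError(f"{path}: {exc}") from exc


def save_dataset(datasets: Mapping[str, MeatDataset] | MeatDataset, path) -> None:
    """Write one or more datasets to a long-format CSV."""
    if isinstance(datasets, MeatDataset):
        datasets = {datasets.product_id: datasets}
    frames = [d.to_frame() for d in datasets.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def load_reference_dataset() -> dict[str, MeatDataset]:
    """The packaged mean biaxial dataset for the eight deli meat products.

    Eleven points per mode and direction, mean of loading and unloading
    curves over n=8 samples per product.
    """
    ref = resources.files("delimech.data").joinpath("deli_biaxial_mean.csv")
    with resources.as_file(ref) as path:
        return load_dataset(path, n_samples=8)
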