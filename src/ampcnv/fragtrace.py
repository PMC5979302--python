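"""Fragment-analysis trace processing.

Capillary-electrophoresis electropherograms arrive as intensity-vs-scan
arrays, one channel per dye: the sample channel carries the amplicon
peaks, a second channel carries an internal size standard (a ladder of
fragments of known lengths, e.g. the 36-fragment LIZ-600 standard).
Processing is a four-step chain:

1. :func:`detect_peaks` -- local maxima of the smoothed signal;
2. :func:`identify_standard_peaks` -- pair detected ladder peaks with the
   known fragment sizes (the *n* tallest peaks, ordered by position);
3. :func:`fit_size_standard` -- ordinary least-squares line
   ``bp = slope * scan + intercept``, gated on r-squared;
4. :func:`scan_to_bp` + :func:`assign_amplicons` -- convert peaks to bp
   and greedily match each expected amplicon to the nearest unassigned
   peak within a tolerance.

Peak *height* (not area) is the quantitative statistic carried forward;
heights are read from the raw, unsmoothed signal at the detected scan so
smoothing never biases the downstream ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

SCAN = "scan"
BP = "bp"

#: GeneScan 600 LIZ (v2) fragment sizes in bp.
LIZ_600_SIZES: tuple[float, ...] = (
    20, 40, 60, 80, 100, 114, 120, 140, 160, 180, 200, 214, 220, 240, 250,
    260, 280, 300, 314, 320, 340, 360, 380, 400, 414, 420, 440, 460, 480,
    500, 514, 520, 540, 560, 580, 600,
)


class CalibrationError(RuntimeError):
    """Raised when the size-standard calibration cannot be established."""


@dataclass(frozen=True)
class Peak:
    """A detected electropherogram peak.

    ``unit`` tags whether ``position`` is in raw scan numbers or in
    calibrated base pairs.
    """

    position: float
    height: float
    unit: str = SCAN
    area: Optional[float] = None

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError(f"peak height must be > 0, got {self.height}")
        if self.unit not in (SCAN, BP):
            raise ValueError(f"unknown position unit {self.unit!r}")


@dataclass(frozen=True)
class SizeStandardDef:
    """An internal size standard: ordered known fragment sizes."""

    name: str
    fragment_sizes_bp: tuple[float, ...]

    def __post_init__(self) -> None:
        sizes = self.fragment_sizes_bp
        if len(sizes) < 2:
            raise ValueError("size standard needs >= 2 fragments")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("fragment sizes must be strictly increasing")


LIZ_600 = SizeStandardDef("LIZ-600", LIZ_600_SIZES)


@dataclass
class RawTrace:
    """A raw electropherogram: named intensity channels on a shared scan axis."""

    sample_id: str
    plex_id: str
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {name: len(arr) for name, arr in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            self.channels[name] = arr

    # -- tabular text I/O (scan, channel, intensity) ---------------------

    def to_tsv(self, path: str | Path) -> None:
        frames = []
        for name, arr in self.channels.items():
            frames.append(
                pd.DataFrame(
                    {"scan": np.arange(len(arr)), "channel": name, "intensity": arr}
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, sample_id: str, plex_id: str
    ) -> "RawTrace":
        df = pd.read_csv(path, sep="\t")
        required = {"scan", "channel", "intensity"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"trace file {path} must have columns {sorted(required)}"
            )
        channels = {}
        for name, sub in df.groupby("channel", sort=False):
            sub = sub.sort_values("scan")
            channels[str(name)] = sub["intensity"].to_numpy(dtype=float)
        return cls(sample_id=sample_id, plex_id=plex_id, channels=channels)


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares scan-to-bp calibration line."""

    slope: float
    intercept: float
    r_squared: float
    residuals_bp: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")

    def predict(self, scan: float | np.ndarray) -> float | np.ndarray:
        return self.slope * scan + self.intercept


MISSING = None  # sentinel for an amplicon with no matched peak


@dataclass
class CalibratedPeakSet:
    """Peaks in bp units with per-amplicon assignments for one plex."""

    sample_id: str
    plex_id: str
    peaks: list[Peak]
    assignments: dict[str, Optional[Peak]]
    unexpected_peaks: list[Peak] = field(default_factory=list)

    def height(self, amplicon_id: str) -> Optional[float]:
        peak = self.assignments.get(amplicon_id)
        return None if peak is None else peak.height

    def missing_ids(self) -> list[str]:
        return [a for a, p in self.assignments.items() if p is None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for aid, peak in self.assignments.items():
            rows.append(
                {
                    "amplicon_id": aid,
                    "bp": peak.position if peak else np.nan,
                    "height": peak.height if peak else np.nan,
                    "status": "ASSIGNED" if peak else "MISSING",
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations


def smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge padding (window odd, >= 1)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    if window == 1:
        return np.asarray(y, dtype=float)
    pad = window // 2
    ypad = np.pad(np.asarray(y, dtype=float), pad, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(ypad, kernel, mode="valid")


def detect_peaks(
    trace: RawTrace,
    channel: str,
    min_height: float = 50.0,
    smooth_window: int = 5,
) -> list[Peak]:
    """Local maxima of the smoothed channel above ``min_height``.

    Plateau ties break to the leftmost scan.  Heights are read from the
    *raw* signal at the detected scan.  A flat or empty channel yields an
    empty list.
    """
    if channel not in trace.channels:
        raise KeyError(f"channel {channel!r} not in trace (has {list(trace.channels)})")
    if min_height <= 0:
        raise ValueError("min_height must be > 0")
    raw = trace.channels[channel]
    if raw.size < 3:
        return []
    y = smooth(raw, smooth_window)
    idx, props = sps.find_peaks(y, height=min_height, plateau_size=1)
    positions = props["left_edges"]  # leftmost scan of each (possibly flat) top
    return [
        Peak(position=float(p), height=float(raw[p]), unit=SCAN)
        for p in positions
        if raw[p] > 0
    ]


def identify_standard_peaks(
    peaks: Sequence[Peak], standard: SizeStandardDef
) -> list[tuple[Peak, float]]:
    """Pair detected ladder peaks with the standard's known sizes.

    Takes the *n* tallest peaks (n = number of ladder fragments), orders
    them by position and pairs them 1:1 with the ascending known sizes.
    Noise spikes smaller than the true ladder peaks are thereby ignored.
    """
    n = len(standard.fragment_sizes_bp)
    if len(peaks) < n:
        raise CalibrationError(
            f"insufficient ladder peaks: detected {len(peaks)}, "
            f"standard {standard.name!r} has {n} fragments"
        )
    tallest = sorted(peaks, key=lambda p: p.height, reverse=True)[:n]
    ordered = sorted(tallest, key=lambda p: p.position)
    return list(zip(ordered, standard.fragment_sizes_bp))


def fit_size_standard(
    pairs: Sequence[tuple[Peak, float]], min_r_squared: float = 0.99
) -> CalibrationFit:
    """Ordinary least-squares line ``bp = slope * scan + intercept``.

    The fit is rejected (:class:`CalibrationError`) when r-squared falls
    below ``min_r_squared`` -- a mis-identified ladder produces a visibly
    non-linear scan/bp relation.
    """
    if len(pairs) < 2:
        raise CalibrationError("need >= 2 ladder pairs to fit a line")
    scans = np.array([p.position for p, _ in pairs], dtype=float)
    bps = np.array([bp for _, bp in pairs], dtype=float)
    if np.unique(scans).size < 2:
        raise CalibrationError("ladder pairs have < 2 distinct scan positions")
    res = spstats.linregress(scans, bps)
    r2 = float(res.rvalue**2)
    fit = CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        residuals_bp=tuple(bps - (res.slope * scans + res.intercept)),
    )
    if r2 < min_r_squared:
        raise CalibrationError(
            f"calibration quality too low: r^2 = {r2:.5f} < {min_r_squared}"
        )
    return fit


def scan_to_bp(peaks: Sequence[Peak], fit: CalibrationFit) -> list[Peak]:
    """Map peak positions through the calibration line; heights unchanged."""
    out = []
    for p in peaks:
        if p.unit != SCAN:
            raise ValueError(f"peak already in {p.unit} units")
        out.append(
            Peak(position=float(fit.predict(p.position)), height=p.height,
                 unit=BP, area=p.area)
        )
    return out


def assign_amplicons(
    peaks_bp: Sequence[Peak],
    panel,
    plex_id: str,
    sample_id: str = "",
    tolerance_bp: float = 2.0,
) -> CalibratedPeakSet:
    """Greedily match plex amplicons to the nearest unassigned peak.

    Candidate (amplicon, peak) pairs within ``tolerance_bp`` are taken in
    ascending order of |peak bp - expected bp|; exact distance ties break
    to the amplicon with the smaller expected size.  Each peak serves at
    most one amplicon; unmatched amplicons are MISSING, unmatched peaks
    are reported as unexpected.
    """
    if tolerance_bp <= 0:
        raise ValueError("tolerance_bp must be > 0")
    amps = panel.amplicons_in_plex(plex_id)
    if not amps:
        raise ValueError(f"plex {plex_id!r} not in panel")
    for p in peaks_bp:
        if p.unit != BP:
            raise ValueError("assign_amplicons requires peaks in bp units")

    sizes = sorted(a.expected_length_bp for a in amps)
    close = [
        (a, b) for a, b in zip(sizes, sizes[1:]) if b - a < 2 * tolerance_bp
    ]
    if close:
        warnings.warn(
            f"plex {plex_id!r}: amplicon expected sizes {close} differ by "
            f"< 2x tolerance ({tolerance_bp} bp); assignment may be ambiguous",
            stacklevel=2,
        )

    candidates = []
    for a in amps:
        for j, p in enumerate(peaks_bp):
            d = abs(p.position - a.expected_length_bp)
            if d <= tolerance_bp:
                candidates.append((d, a.expected_length_bp, a.id, j))
    candidates.sort()

    assignments: dict[str, Optional[Peak]] = {a.id: MISSING for a in amps}
    used_peaks: set[int] = set()
    assigned_amps: set[str] = set()
    for _d, _size, aid, j in candidates:
        if aid in assigned_amps or j in used_peaks:
            continue
        assignments[aid] = peaks_bp[j]
        assigned_amps.add(aid)
        used_peaks.add(j)

    unexpected = [p for j, p in enumerate(peaks_bp) if j not in used_peaks]
    return CalibratedPeakSet(
        sample_id=sample_id,
        plex_id=plex_id,
        peaks=list(peaks_bp),
        assignments=assignments,
        unexpected_peaks=unexpected,
    )


def calibrate_trace(
    trace: RawTrace,
    panel,
    sample_channel: str = "sample",
    ladder_channel: str = "ladder",
    standard: SizeStandardDef = LIZ_600,
    min_height: float = 50.0,
    smooth_window: int = 5,
    tolerance_bp: float = 2.0,
    min_r_squared: float = 0.99,
) -> tuple[CalibratedPeakSet, CalibrationFit]:
    """Full chain: detect -> identify -> fit -> convert -> assign."""
    ladder_peaks = detect_peaks(trace, ladder_channel, min_height, smooth_window)
    pairs = identify_standard_peaks(ladder_peaks, standard)
    fit = fit_size_standard(pairs, min_r_squared=min_r_squared)
    sample_peaks = detect_peaks(trace, sample_channel, min_height, smooth_window)
    peaks_bp = scan_to_bp(sample_peaks, fit)
    peakset = assign_amplicons(
        peaks_bp, panel, trace.plex_id, sample_id=trace.sample_id,
        tolerance_bp=tolerance_bp,
    )
    return peakset, fit
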