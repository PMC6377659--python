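"""CE-SSCP signal analysis: from raw electropherograms to isoform proportions.

The pipeline follows the five analysis steps of the assay:

1. check the ROX migration standards and build a unified time basis
   (:func:`build_time_base`);
2. deconvolve and standardise the editing-standard areas and
3. define their retention times (:func:`calibrate_standards`);
4. detect the editing isoforms present in a sample profile
   (:func:`detect_isoforms`);
5. quantify their relative proportions by best fitting
   (:func:`quantify_isoforms`).

"Best fitting" is realised as non-negative least squares of the aligned,
baseline-subtracted sample trace against the unit-area standard
references, solved jointly over the FAM and VIC channels as one stacked
system.  On noise-free, undistorted input this inverts the forward model
exactly; with noise it is the maximum-likelihood unmixing under an
additive Gaussian error model with a non-negativity constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.optimize import nnls
from scipy.signal import find_peaks

from .model import UNEDITED, EditingProfile
from .synth import TraceSet

SIGNAL_CHANNELS = ("FAM", "VIC")


class AlignmentError(RuntimeError):
    """Ladder peaks could not be matched to the expected positions."""


class CalibrationError(RuntimeError):
    """An editing standard could not be calibrated."""


class QuantificationError(RuntimeError):
    """Best fitting failed to produce a usable composition."""


@dataclass
class TimeBase:
    """Monotone map from raw scan index to the unified retention-time axis.

    ``anchors`` are (raw apex, expected ladder time) pairs; the map is
    the piecewise-linear interpolant through them, extended linearly
    with the end-segment slopes outside the anchor range.  ``quality``
    is the maximum absolute residual of the anchors about a straight
    line, a drift-severity diagnostic (zero for a purely affine warp).
    """

    anchors: list[tuple[float, float]]
    quality: float = 0.0

    def __post_init__(self) -> None:
        raw = [a for a, _ in self.anchors]
        uni = [u for _, u in self.anchors]
        if any(b <= a for a, b in zip(raw, raw[1:])) or any(
            b <= a for a, b in zip(uni, uni[1:])
        ):
            raise AlignmentError("time-base anchors must be strictly increasing")

    def warp(self, scan: np.ndarray) -> np.ndarray:
        raw = np.array([a for a, _ in self.anchors])
        uni = np.array([u for _, u in self.anchors])
        scan = np.asarray(scan, dtype=float)
        out = np.interp(scan, raw, uni)
        s0 = (uni[1] - uni[0]) / (raw[1] - raw[0])
        s1 = (uni[-1] - uni[-2]) / (raw[-1] - raw[-2])
        lo, hi = scan < raw[0], scan > raw[-1]
        out[lo] = uni[0] + s0 * (scan[lo] - raw[0])
        out[hi] = uni[-1] + s1 * (scan[hi] - raw[-1])
        return out

    def resample(self, y: np.ndarray) -> np.ndarray:
        """Re-grid a raw-scan series onto integer unified time.

        Inverts the warp by interpolation; because the map is strictly
        monotone the inverse is well defined.  Peak areas are preserved
        on the unified axis, which is what makes quantification
        warp-invariant.
        """
        scan = np.arange(len(y), dtype=float)
        unified = self.warp(scan)
        grid = np.arange(len(y), dtype=float)
        raw_pos = np.interp(grid, unified, scan)
        return np.interp(raw_pos, scan, y)


def _noise_sigma(y: np.ndarray) -> float:
    """Robust noise-scale estimate via the median absolute deviation.

    Peaks occupy a small fraction of an electropherogram, so the MAD of
    the full trace tracks the baseline noise, not the signal.
    """
    med = np.median(y)
    return 1.4826 * float(np.median(np.abs(y - med)))


def subtract_baseline(y: np.ndarray, window: int = 501, smooth: int = 51) -> np.ndarray:
    """Remove slow baseline drift with a smoothed rolling-minimum filter.

    The trace is pre-smoothed (suppresses the downward bias a rolling
    minimum would otherwise pick up from noise), the rolling minimum over
    ``window`` points is taken as the local baseline, smoothed again, and
    subtracted.  ``window`` must exceed the peak support so minima fall
    between peaks.  The result is recentred on its median so the noise
    floor sits at zero: peaks are sparse, so the median tracks the
    residual offset the minimum filter leaves behind.
    """
    smoothed = uniform_filter1d(y, size=smooth, mode="nearest")
    base = minimum_filter1d(smoothed, size=window, mode="nearest")
    base = uniform_filter1d(base, size=window, mode="nearest")
    out = y - base
    return out - np.median(out)


def build_time_base(
    rox: np.ndarray,
    ladder_times: tuple[float, ...] | list[float],
    min_peaks: int = 3,
    prominence_frac: float = 0.25,
) -> TimeBase:
    """Detect ladder peaks in the ROX channel and anchor the time basis.

    Peaks are picked by prominence, the ``len(ladder_times)`` most
    prominent retained, and matched in elution order to the expected
    ladder positions.  With fewer detected peaks than expected, each is
    assigned to its nearest expected position (after an end-to-end affine
    prefit), preserving order; ambiguous assignments raise.
    """
    rox = np.asarray(rox, dtype=float)
    ladder_times = list(ladder_times)
    floor = max(5.0 * _noise_sigma(rox), prominence_frac * float(rox.max(initial=0.0)))
    peaks, props = find_peaks(rox, prominence=max(floor, 1e-12))
    if len(peaks) < max(min_peaks, 3):
        raise AlignmentError(
            f"only {len(peaks)} ladder peaks detected; at least {max(min_peaks, 3)} required"
        )
    order = np.argsort(props["prominences"])[::-1]
    keep = np.sort(peaks[order[: len(ladder_times)]])

    if len(keep) == len(ladder_times):
        anchors = list(zip(keep.astype(float), map(float, ladder_times)))
    else:
        # affine prefit from the endpoints, then order-preserving nearest
        # assignment of each detected peak to an expected ladder position
        span_raw = keep[-1] - keep[0]
        span_uni = ladder_times[-1] - ladder_times[0]
        slope = span_uni / span_raw if span_raw else 1.0
        est = ladder_times[0] + slope * (keep - keep[0])
        assigned = []
        for e in est:
            j = int(np.argmin([abs(e - t) for t in ladder_times]))
            assigned.append(j)
        if len(set(assigned)) != len(assigned) or assigned != sorted(assigned):
            raise AlignmentError("non-monotone ladder peak match")
        anchors = [
            (float(k), float(ladder_times[j])) for k, j in zip(keep, assigned)
        ]

    raw = np.array([a for a, _ in anchors])
    uni = np.array([u for _, u in anchors])
    coef = np.polyfit(raw, uni, 1)
    quality = float(np.max(np.abs(uni - np.polyval(coef, raw))))
    return TimeBase(anchors=anchors, quality=quality)


@dataclass
class StandardLibrary:
    """Calibrated editing standards on the unified time basis.

    ``references[iso][channel]`` is the aligned, baseline-subtracted,
    unit-area reference trace; ``retention_times[iso]`` its apex position
    in unified time.
    """

    references: dict[str, dict[str, np.ndarray]]
    retention_times: dict[str, float]
    n_points: int

    @property
    def isoforms(self) -> list[str]:
        return list(self.references)


def calibrate_standards(
    standards: dict[str, TraceSet],
    ladder_times: tuple[float, ...] | list[float],
    min_separation: float = 1.0,
    baseline_window: int = 501,
) -> StandardLibrary:
    """Align each editing standard to the unified basis and normalise its area.

    Each standard carries its own ROX ladder, so each gets its own time
    base; after alignment and baseline subtraction every channel is
    scaled to integrate to exactly 1 so that fitted weights read directly
    as signal fractions.  Standards whose apexes sit closer than
    ``min_separation`` unified-time units are rejected: they could not be
    told apart by best fitting.
    """
    references: dict[str, dict[str, np.ndarray]] = {}
    retention: dict[str, float] = {}
    n_points = None
    for iso, ts in standards.items():
        tb = build_time_base(ts.channels["ROX"], ladder_times)
        refs = {}
        for ch in SIGNAL_CHANNELS:
            aligned = subtract_baseline(tb.resample(ts.channels[ch]), baseline_window)
            area = float(aligned.sum())
            if area <= 0:
                raise CalibrationError(f"standard {iso}: zero total area on {ch}")
            refs[ch] = aligned / area
        references[iso] = refs
        retention[iso] = float(np.argmax(refs["FAM"]))
        n_points = ts.n_points
    times = sorted(retention.items(), key=lambda kv: kv[1])
    for (iso_a, ta), (iso_b, tb_) in zip(times, times[1:]):
        if tb_ - ta < min_separation:
            raise CalibrationError(
                f"standards {iso_a} and {iso_b} have indistinguishable retention "
                f"times ({ta:g} vs {tb_:g})"
            )
    return StandardLibrary(references, retention, n_points)


def detect_isoforms(
    aligned: dict[str, np.ndarray],
    lib: StandardLibrary,
    detection_snr: float = 5.0,
) -> set[str]:
    """Matched-filter detection of isoforms in an aligned sample trace.

    For each standard, the matched-filter statistic ``<y, r> / ||r||``
    has standard deviation equal to the noise scale under the null, so
    the isoform is reported present when that statistic exceeds
    ``detection_snr`` noise units.  The matched filter integrates over
    the whole peak support, which is what lets components well below
    the apex-height noise floor (but above the assay's 0.5% reporting
    floor) be picked up.  The result is a candidate superset for
    quantification, not a final call: weak true components cost little
    if passed on, missed ones cannot be recovered.
    """
    present: set[str] = set()
    for ch in SIGNAL_CHANNELS:
        y = aligned[ch]
        sigma = max(_noise_sigma(y), 1e-9 * float(np.max(np.abs(y), initial=0.0)))
        if sigma <= 0:  # dead channel: nothing can clear the filter
            continue
        for iso in lib.isoforms:
            r = lib.references[iso][ch]
            norm = float(np.linalg.norm(r))
            if norm <= 0:
                continue
            snr = float(y @ r) / norm / sigma
            if snr > detection_snr:
                present.add(iso)
    return present


@dataclass
class QuantResult:
    """Relative quantification of one sample.

    ``proportions`` sums to 100 over the isoforms surviving the
    reporting threshold; ``below_threshold_mass`` is the percentage
    removed by that rule before renormalisation; ``fit_residual`` is the
    relative L2 misfit of the stacked two-channel system.
    """

    proportions: EditingProfile
    fit_residual: float
    detected: set[str] = field(default_factory=set)
    below_threshold_mass: float = 0.0
    time_base: TimeBase | None = None


def quantify_isoforms(
    sample: TraceSet,
    lib: StandardLibrary,
    ladder_times: tuple[float, ...] | list[float],
    threshold: float = 0.5,
    detection_snr: float = 5.0,
    sample_id: str = "sample",
    baseline_window: int = 501,
) -> QuantResult:
    """Quantify isoform proportions in one sample by best fitting.

    The sample is aligned through its own ROX ladder, baseline
    subtracted, screened for candidate isoforms, and unmixed by
    non-negative least squares against the candidate references (the
    unedited isoform is always kept as a candidate).  Weights are
    converted to percent of the total fitted signal; isoforms below
    ``threshold`` percent are removed and the survivors renormalised to
    100, mirroring the assay's reporting floor.
    """
    tb = build_time_base(sample.channels["ROX"], ladder_times)
    aligned = {
        ch: subtract_baseline(tb.resample(sample.channels[ch]), baseline_window)
        for ch in SIGNAL_CHANNELS
    }
    candidates = detect_isoforms(aligned, lib, detection_snr)
    if UNEDITED in lib.references:
        candidates.add(UNEDITED)
    if not candidates:
        raise QuantificationError(f"{sample_id}: no isoform detected above noise")
    names = sorted(candidates)

    A = np.column_stack(
        [
            np.concatenate([lib.references[iso][ch] for ch in SIGNAL_CHANNELS])
            for iso in names
        ]
    )
    y = np.concatenate([aligned[ch] for ch in SIGNAL_CHANNELS])
    w, _ = nnls(A, y)
    total = float(w.sum())
    if total <= 0:
        raise QuantificationError(f"{sample_id}: best fit assigned zero total signal")

    resid = float(np.linalg.norm(A @ w - y) / np.linalg.norm(y))
    percents = 100.0 * w / total
    kept = {n: p for n, p in zip(names, percents) if p >= threshold}
    removed = float(sum(p for p in percents if p < threshold))
    if not kept:
        raise QuantificationError(
            f"{sample_id}: no isoform at or above the {threshold}% reporting floor"
        )
    norm = 100.0 / sum(kept.values())
    profile = EditingProfile(sample_id, {n: p * norm for n, p in kept.items()})
    return QuantResult(
        proportions=profile,
        fit_residual=resid,
        detected=candidates,
        below_threshold_mass=removed,
        time_base=tb,
    )


@dataclass
class BatchReport:
    results: list[QuantResult]
    failures: list[tuple[str, str]]


def quantify_batch(
    samples: dict[str, TraceSet],
    lib: StandardLibrary,
    ladder_times: tuple[float, ...] | list[float],
    threshold: float = 0.5,
    detection_snr: float = 5.0,
) -> BatchReport:
    """Quantify a batch of samples, isolating per-sample failures."""
    results: list[QuantResult] = []
    failures: list[tuple[str, str]] = []
    for sid, ts in samples.items():
        try:
            results.append(
                quantify_isoforms(
                    ts, lib, ladder_times, threshold, detection_snr, sample_id=sid
                )
            )
        except (AlignmentError, QuantificationError, ValueError) as exc:
            failures.append((sid, str(exc)))
    return BatchReport(results, failures)
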