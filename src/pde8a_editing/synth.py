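"""Synthetic cohorts and synthetic CE-SSCP trace sets.

Two generative layers mirror the two layers of real input:

* :func:`simulate_cohort` draws per-sample isoform-proportion profiles
  for a paired two-group (control / suicide) by two-region (BA9 / BA24)
  design.  Profiles are compositional, so draws come from a Dirichlet
  distribution centred on stratum mean vectors, with a per-subject
  multiplicative random effect shared between that subject's two regions
  to induce the within-subject correlation a paired design assumes.

* :func:`simulate_traces` renders a profile into a raw electropherogram:
  FAM and VIC channels are a proportion-weighted sum of unit-area
  Gaussian peaks at isoform-specific retention times, composed with a
  monotone piecewise-linear time warp (run-to-run migration drift),
  plus a slow baseline drift and white noise; the ROX channel carries
  the co-injected migration-standard ladder through the same warp.

Every simulated object records its ground truth, so the quantification
and statistics modules can be scored against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import (
    GROUPS,
    REGIONS,
    EditingProfile,
    SampleMeta,
    canonical_name,
)

# ---------------------------------------------------------------------------
# Default stratum means
# ---------------------------------------------------------------------------

# Mean relative proportion (percent) per isoform for the four strata
# (control BA24, control BA9, suicide BA24, suicide BA9).  The table is
# shaped to the study conditions: 30 isoforms of which 27 carry site B;
# only D and M occur as single-site isoforms besides B; A appears only
# together with B and N only within ABN; B near 29% in control BA24 and
# 21.5% in control BA9; NE stable at 6%; the fully edited ABCDEFG rare;
# AB about 2.6-fold higher in BA24 than BA9 in controls; ABCEF doubled
# and B / ABDE reduced in suicide BA24; ABEFG about 3-fold increased in
# suicide BA9; ten rare isoforms sit below the 0.5% reporting floor with
# under 2% cumulative mass.  Each column sums to exactly 100.
DEFAULT_MEANS: dict[str, tuple[float, float, float, float]] = {
    "NE":      (6.00, 6.00, 6.00, 6.00),
    "B":       (29.00, 21.50, 21.00, 21.50),
    "AB":      (10.80, 4.20, 11.00, 3.30),
    "ABC":     (5.92, 7.00, 7.66, 6.57),
    "BD":      (3.81, 5.11, 3.72, 6.09),
    "D":       (1.59, 2.15, 1.55, 1.95),
    "ABDE":    (3.90, 3.50, 3.00, 2.45),
    "ABCEF":   (3.00, 3.00, 6.00, 2.80),
    "BCEG":    (4.02, 4.57, 5.38, 5.60),
    "ABEFG":   (3.20, 2.10, 4.20, 6.60),
    "ABG":     (1.40, 5.00, 1.60, 4.70),
    "BEG":     (3.49, 4.98, 3.41, 2.86),
    "BFG":     (2.75, 3.90, 3.52, 3.65),
    "ABF":     (2.64, 3.50, 2.59, 4.26),
    "ABE":     (3.60, 4.31, 4.04, 3.89),
    "BCDEFG":  (2.33, 3.23, 2.64, 2.92),
    "ABCE":    (3.28, 3.90, 3.62, 3.53),
    "ABCDE":   (1.16, 1.35, 1.24, 1.22),
    "ABCDEFG": (0.60, 1.20, 0.60, 1.20),
    "BC":      (5.81, 7.80, 5.38, 7.06),
    "M":       (0.20, 0.20, 0.20, 0.20),
    "ABN":     (0.30, 0.30, 0.45, 0.45),
    "BE":      (0.15, 0.15, 0.15, 0.15),
    "BF":      (0.15, 0.15, 0.15, 0.15),
    "BG":      (0.15, 0.15, 0.15, 0.15),
    "BCE":     (0.15, 0.15, 0.15, 0.15),
    "BEF":     (0.15, 0.15, 0.15, 0.15),
    "BEFG":    (0.15, 0.15, 0.15, 0.15),
    "ABCG":    (0.15, 0.15, 0.15, 0.15),
    "BDE":     (0.15, 0.15, 0.15, 0.15),
}

_STRATA = [("control", "BA24"), ("control", "BA9"), ("suicide", "BA24"), ("suicide", "BA9")]


def default_isoform_means() -> dict[tuple[str, str], dict[str, float]]:
    """Default (group, region) -> isoform -> mean percent table."""
    out: dict[tuple[str, str], dict[str, float]] = {}
    for j, stratum in enumerate(_STRATA):
        out[stratum] = {iso: row[j] for iso, row in DEFAULT_MEANS.items()}
    return out


class SpecError(ValueError):
    """Raised when a simulation specification is internally inconsistent."""


@dataclass
class CohortSpec:
    """Specification of a paired 2-group x 2-region synthetic cohort.

    Parameters
    ----------
    n_pairs
        Number of matched case-control pairs (the study used 8).
    isoform_means
        (group, region) -> isoform -> mean percent; each stratum must sum
        to 100.  Defaults to :func:`default_isoform_means`.
    dispersion
        Dirichlet concentration: draws use alpha = dispersion * mean/100.
        Larger values give tighter within-stratum spread.  The default
        500 puts the coefficient of variation near 9% for the most
        abundant isoform and 25-30% for the ~1-3% isoforms, consistent
        with the tight standard errors of a well-controlled CE assay.
    subject_effect_sd
        Log-scale SD of the per-subject multiplicative effect shared by
        the subject's two regions (induces within-subject correlation).
    seed
        RNG seed; identical spec + seed reproduces the cohort exactly.
    """

    n_pairs: int = 8
    isoform_means: Mapping[tuple[str, str], Mapping[str, float]] | None = None
    dispersion: float = 500.0
    subject_effect_sd: float = 0.10
    seed: int = 0

    def resolved_means(self) -> dict[tuple[str, str], dict[str, float]]:
        means = (
            default_isoform_means()
            if self.isoform_means is None
            else {k: dict(v) for k, v in self.isoform_means.items()}
        )
        for stratum, table in means.items():
            tot = sum(table.values())
            if abs(tot - 100.0) > 1e-6:
                raise SpecError(
                    f"isoform means for stratum {stratum} sum to {tot:g}, not 100"
                )
        return means

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise SpecError("n_pairs must be at least 2")
        if self.dispersion <= 0:
            raise SpecError("dispersion must be positive")
        self.resolved_means()


def simulate_cohort(spec: CohortSpec) -> tuple[list[EditingProfile], list[SampleMeta]]:
    """Draw a synthetic cohort of editing profiles with known structure.

    Returns one profile per (subject, region): 2 groups x n_pairs
    subjects x 2 regions.  Subject s in group g gets a multiplicative
    lognormal effect vector applied to both regional mean vectors before
    the Dirichlet draw, so the same donor's BA9 and BA24 profiles are
    correlated.  Every profile sums to exactly 100.
    """
    spec.validate()
    means = spec.resolved_means()
    isoforms = list(next(iter(means.values())))
    rng = np.random.default_rng(spec.seed)

    profiles: list[EditingProfile] = []
    meta: list[SampleMeta] = []
    for i in range(spec.n_pairs):
        pair_id = f"P{i + 1:02d}"
        for group in GROUPS:
            subject_id = f"{'C' if group == 'control' else 'S'}{i + 1:02d}"
            effect = np.exp(
                rng.normal(0.0, spec.subject_effect_sd, size=len(isoforms))
            )
            for region in REGIONS:
                mu = np.array([means[(group, region)][iso] for iso in isoforms])
                mu = mu * effect
                mu = mu / mu.sum()
                alpha = spec.dispersion * mu
                draw = rng.dirichlet(alpha)
                props = 100.0 * draw / draw.sum()
                sample_id = f"{subject_id}_{region}"
                profiles.append(
                    EditingProfile(sample_id, dict(zip(isoforms, props)))
                )
                meta.append(
                    SampleMeta(sample_id, subject_id, group, region, pair_id)
                )
    return profiles, meta


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------

def _default_retention_times() -> dict[str, float]:
    """Nominal unified-time peak positions, one per catalogue isoform.

    Spaced 250 scan units apart across the usable window of an 11,000
    point trace: comfortably wider than the default peak width so the
    standards are linearly independent, as single-conformer references
    resolved by CE-SSCP should be.
    """
    isoforms = list(DEFAULT_MEANS)
    return {iso: 2200.0 + 250.0 * k for k, iso in enumerate(isoforms)}


@dataclass
class TraceSpec:
    """Forward-model parameters for synthetic electropherograms.

    ``warp`` maps raw scan index to unified retention time via monotone
    piecewise-linear interpolation through ``(raw, unified)`` anchor
    pairs; the identity when empty.  ``noise_sd`` is additive white
    noise in intensity units (a unit-area peak of the default width has
    apex height ~0.027 per percent of signal).
    """

    n_points: int = 11000
    peak_width: float = 15.0
    retention_times: dict[str, float] = field(default_factory=_default_retention_times)
    ladder_times: tuple[float, ...] = tuple(float(t) for t in range(1500, 10501, 600))
    warp_anchors: tuple[tuple[float, float], ...] = ()
    noise_sd: float = 0.0
    baseline: float = 0.0
    baseline_period: float = 4000.0
    ladder_height: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_points < 100:
            raise SpecError("n_points must be at least 100")
        times = sorted(self.retention_times.values())
        if any(b - a <= 0 for a, b in zip(times, times[1:])):
            raise SpecError("retention times must be distinct")
        if self.warp_anchors:
            raw = [a for a, _ in self.warp_anchors]
            uni = [u for _, u in self.warp_anchors]
            if any(b <= a for a, b in zip(raw, raw[1:])) or any(
                b <= a for a, b in zip(uni, uni[1:])
            ):
                raise SpecError("warp anchors must be strictly increasing")

    def warp(self, scan: np.ndarray) -> np.ndarray:
        """Unified retention time at each raw scan index."""
        if not self.warp_anchors:
            return np.asarray(scan, dtype=float)
        raw = np.array([a for a, _ in self.warp_anchors])
        uni = np.array([u for _, u in self.warp_anchors])
        scan = np.asarray(scan, dtype=float)
        out = np.interp(scan, raw, uni)
        # linear extrapolation with the end-segment slopes keeps the map
        # strictly increasing beyond the anchor range
        lo = scan < raw[0]
        hi = scan > raw[-1]
        s0 = (uni[1] - uni[0]) / (raw[1] - raw[0])
        s1 = (uni[-1] - uni[-2]) / (raw[-1] - raw[-2])
        out[lo] = uni[0] + s0 * (scan[lo] - raw[0])
        out[hi] = uni[-1] + s1 * (scan[hi] - raw[-1])
        return out


@dataclass
class TraceSet:
    """FAM/VIC/ROX intensity series for one sample or standard."""

    channels: dict[str, np.ndarray]
    truth: dict[str, float] | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name} contains non-finite values")

    @property
    def n_points(self) -> int:
        return len(next(iter(self.channels.values())))


def _gaussian(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-area Gaussian peak on the unified-time axis."""
    return np.exp(-0.5 * ((t - center) / width) ** 2) / (width * np.sqrt(2.0 * np.pi))


def simulate_traces(profile: EditingProfile, tspec: TraceSpec) -> TraceSet:
    """Render an editing profile into a raw three-channel trace set.

    FAM and VIC observe ``sum_i p_i * g_i(warp(scan))`` where ``g_i`` is
    the unit-area peak of isoform *i* at its unified retention time, so
    in the unwarped (unified-time) frame each isoform's peak area equals
    its proportion in percent.  ROX observes the ladder through the same
    warp.  Baseline drift and white noise are added per channel.
    """
    tspec.validate()
    missing = [
        canonical_name(iso)
        for iso, p in profile.proportions.items()
        if p > 0 and canonical_name(iso) not in tspec.retention_times
    ]
    if missing:
        raise SpecError(f"no retention time configured for isoform(s): {missing}")

    rng = np.random.default_rng(tspec.seed)
    scan = np.arange(tspec.n_points, dtype=float)
    t = tspec.warp(scan)

    signal = np.zeros_like(t)
    for iso, p in profile.proportions.items():
        if p > 0:
            signal += p * _gaussian(t, tspec.retention_times[canonical_name(iso)], tspec.peak_width)

    rox = np.zeros_like(t)
    for lt in tspec.ladder_times:
        rox += tspec.ladder_height * np.exp(-0.5 * ((t - lt) / tspec.peak_width) ** 2)

    channels = {}
    for name, clean in (("FAM", signal), ("VIC", signal), ("ROX", rox)):
        drift = tspec.baseline * (
            0.5 + 0.5 * np.sin(2.0 * np.pi * scan / tspec.baseline_period)
        ) if tspec.baseline else 0.0
        noise = rng.normal(0.0, tspec.noise_sd, size=t.shape) if tspec.noise_sd else 0.0
        channels[name] = clean + drift + noise

    truth = {
        canonical_name(k): float(v) for k, v in profile.proportions.items()
    }
    return TraceSet(channels=channels, truth=truth)


def simulate_standards(
    tspec: TraceSpec, isoforms: list[str] | None = None, noise_free: bool = True
) -> dict[str, TraceSet]:
    """One single-component trace set per isoform, each with its own ladder.

    Editing standards are reference preparations of a single known
    isoform run alongside the samples; with ``noise_free=True`` (the
    default) they are rendered without noise or baseline, as calibration
    inputs for :func:`pde8a_editing.quant.calibrate_standards`.
    """
    tspec.validate()
    names = list(tspec.retention_times) if isoforms is None else isoforms
    out: dict[str, TraceSet] = {}
    for k, iso in enumerate(names):
        sspec = TraceSpec(
            n_points=tspec.n_points,
            peak_width=tspec.peak_width,
            retention_times=dict(tspec.retention_times),
            ladder_times=tspec.ladder_times,
            warp_anchors=tspec.warp_anchors,
            noise_sd=0.0 if noise_free else tspec.noise_sd,
            baseline=0.0 if noise_free else tspec.baseline,
            baseline_period=tspec.baseline_period,
            ladder_height=tspec.ladder_height,
            seed=tspec.seed + 1 + k,
        )
        out[iso] = simulate_traces(
            EditingProfile(f"standard_{iso}", {iso: 100.0}), sspec
        )
    return out


# ---------------------------------------------------------------------------
# Trace file I/O
# ---------------------------------------------------------------------------

def write_trace_csv(path, traces: TraceSet) -> None:
    """Write a trace set as a ``scan,FAM,VIC,ROX`` CSV (plus a ``.truth.json``
    sidecar when ground truth is attached)."""
    import json
    import pandas as pd

    n = traces.n_points
    frame = pd.DataFrame({"scan": np.arange(n)})
    for ch in ("FAM", "VIC", "ROX"):
        frame[ch] = traces.channels[ch]
    frame.to_csv(path, index=False)
    if traces.truth is not None:
        sidecar = str(path) + ".truth.json"
        with open(sidecar, "w") as fh:
            json.dump(traces.truth, fh, indent=1, sort_keys=True)


def read_trace_csv(path) -> TraceSet:
    """Read a ``scan,FAM,VIC,ROX`` CSV back into a :class:`TraceSet`."""
    import pandas as pd

    frame = pd.read_csv(path)
    channels = {ch: frame[ch].to_numpy(dtype=float) for ch in ("FAM", "VIC", "ROX")}
    return TraceSet(channels=channels)
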