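"""End-to-end pipeline: simulate -> quantify -> differential -> discriminate.

A :class:`RunConfig` fully determines a run: a single seed feeds named
substreams for each randomised stage, thresholds are recorded in the
output manifest, and rerunning the same config reproduces byte-identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    GROUP_AXIS,
    REGION_AXIS,
    ContrastSpec,
    include_isoforms,
    results_frame,
    run_contrast,
)
from .model import (
    GROUPS,
    REGIONS,
    frame_to_profiles,
    profiles_to_frame,
    write_profiles,
)
from .mroc import mroc_fit, panel_report
from .quant import calibrate_standards, quantify_batch
from .synth import (
    CohortSpec,
    TraceSpec,
    simulate_cohort,
    simulate_standards,
    simulate_traces,
)

DEFAULT_PANELS = {"BA24": ["ABC", "BCEG", "ABDE"], "BA9": ["BD", "BCEG", "ABF"]}


class ConfigError(ValueError):
    """Raised when a run configuration is invalid before any stage runs."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Thresholds default to the analysis constants of the assay: a 0.5%
    relative-proportion floor for inclusion, a 20% median-variation
    selection band, and an FDR ceiling of 0.05.
    """

    seed: int = 0
    out_dir: str = "run"
    n_pairs: int = 8
    dispersion: float = 500.0
    subject_effect_sd: float = 0.10
    quantify_traces: bool = False
    inclusion_threshold: float = 0.5
    medvar_threshold: float = 20.0
    q_threshold: float = 0.05
    test: str = "rank-sum"
    panels: dict[str, list[str]] = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_PANELS.items()
    })

    def validate(self) -> None:
        for name in ("inclusion_threshold", "medvar_threshold", "q_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_pairs < 2:
            raise ConfigError("n_pairs must be at least 2")
        for region in self.panels:
            if region not in REGIONS:
                raise ConfigError(f"unknown panel region {region!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def default_contrasts() -> list[ContrastSpec]:
    """The four study contrasts: BA24 vs BA9 within each group, and
    suicide vs control within each region."""
    specs = [
        ContrastSpec(REGION_AXIS, "BA9", "BA24", group) for group in GROUPS
    ]
    specs += [
        ContrastSpec(GROUP_AXIS, "control", "suicide", region) for region in REGIONS
    ]
    return specs


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts plus a reproducibility manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]

    # -- stage: simulate cohort ------------------------------------------
    cspec = CohortSpec(
        n_pairs=config.n_pairs,
        dispersion=config.dispersion,
        subject_effect_sd=config.subject_effect_sd,
        seed=_stage_seed(config.seed, "cohort"),
    )
    profiles, meta = simulate_cohort(cspec)
    write_profiles(out / "profiles.csv", profiles, meta)
    manifest["stages"]["simulate"] = {"n_profiles": len(profiles)}

    # -- stage: trace-level round trip (optional) ------------------------
    if config.quantify_traces:
        tspec = TraceSpec(seed=_stage_seed(config.seed, "traces"))
        standards = simulate_standards(tspec)
        lib = calibrate_standards(standards, tspec.ladder_times)
        traces = {}
        for i, p in enumerate(profiles):
            pt = TraceSpec(
                noise_sd=0.01,
                baseline=0.05,
                warp_anchors=((0.0, 0.0), (5500.0, 5550.0), (10999.0, 10999.0)),
                seed=_stage_seed(config.seed, f"trace-{p.sample_id}"),
            )
            traces[p.sample_id] = simulate_traces(p, pt)
        report = quantify_batch(
            traces, lib, tspec.ladder_times, threshold=config.inclusion_threshold
        )
        if report.failures:
            manifest["stages"]["quantify"] = {"failures": report.failures}
            raise RuntimeError(
                f"quantification stage failed for {len(report.failures)} samples; "
                f"partial outputs in {out}"
            )
        profiles = [r.proportions for r in report.results]
        write_profiles(out / "quantified_profiles.csv", profiles, meta)
        manifest["stages"]["quantify"] = {
            "n_quantified": len(profiles),
            "max_fit_residual": max(r.fit_residual for r in report.results),
        }

    # -- stage: differential ---------------------------------------------
    included = include_isoforms(profiles, meta, min_prop=config.inclusion_threshold)
    manifest["stages"]["include"] = {"n_isoforms": len(included), "isoforms": included}
    contrast_files = {}
    for spec in default_contrasts():
        results = run_contrast(
            profiles, meta, spec,
            isoforms=included,
            test=config.test,
            medvar_threshold=config.medvar_threshold,
            q_threshold=config.q_threshold,
        )
        frame = results_frame(results)
        name = f"contrast_{spec.label()}.csv"
        frame.to_csv(out / name, index=False)
        contrast_files[spec.label()] = {
            "file": name,
            "n_isoforms": len(results),
            "n_selected": int(frame["selected"].sum()),
        }
    manifest["stages"]["differential"] = contrast_files

    # -- stage: discriminate ---------------------------------------------
    frame = profiles_to_frame(profiles, meta)
    panel_out = {}
    for region, isoforms in config.panels.items():
        sub = frame[frame["region"] == region]
        labels = (sub["group"] == "suicide").to_numpy(int)
        X = sub[isoforms].to_numpy(float)
        panel = mroc_fit(X, labels, isoforms=isoforms)
        rep = panel_report(panel, labels)
        path = out / f"panel_{region}.json"
        with open(path, "w") as fh:
            json.dump(rep, fh, indent=1, sort_keys=True)
        panel_out[region] = {"file": path.name, "auc": panel.auc}
    manifest["stages"]["discriminate"] = panel_out

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def stratum_mean_table(profiles, meta) -> pd.DataFrame:
    """Mean +/- SEM of each isoform per (group, region) stratum, ordered by
    abundance: the profile-overview table of a run."""
    frame = profiles_to_frame(profiles, meta)
    iso_cols = [c for c in frame.columns if c not in
                ("sample_id", "subject_id", "group", "region", "pair_id")]
    rows = []
    for (group, region), sub in frame.groupby(["group", "region"]):
        for iso in iso_cols:
            v = sub[iso].to_numpy(float)
            rows.append({
                "group": group, "region": region, "isoform": iso,
                "mean": v.mean(), "sem": v.std(ddof=1) / np.sqrt(len(v)),
            })
    return pd.DataFrame(rows)
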