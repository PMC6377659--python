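"""Differential-editing statistics for region and group contrasts.

For a pair of experimental conditions the per-isoform effect summary is
the set of deviations

    dDeviation = %editing(condition 2) - %editing(condition 1)

taken over all condition-2 x condition-1 sample pairs, together with the
percent change of the group median ("median variation").  An isoform is
*selected* when its FDR-adjusted p-value is at most 0.05 and the
absolute median variation is at least 20%.

Two tests are exposed.  The default, the exact Wilcoxon-Mann-Whitney
rank-sum test on the two condition samples, is the calibrated test of
H0: the cross-condition deviations are centred at zero (its statistic is
the sign count of exactly those deviations).  A one-sample Wilcoxon
signed-rank test on per-pair deviations along the declared matching is
available for strictly paired analyses; note that with 8 pairs its
smallest attainable two-sided p is 2/2^8 ~ 0.0078, which caps the
resolution of any downstream FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import EditingProfile, SampleMeta

REGION_AXIS = "region-within-group"
GROUP_AXIS = "group-within-region"


class ContrastError(ValueError):
    """Raised for malformed contrast specifications or broken pairings."""


@dataclass(frozen=True)
class ContrastSpec:
    """One two-condition comparison.

    ``axis`` is either ``"region-within-group"`` (condition levels are
    regions, ``within`` fixes the group) or ``"group-within-region"``
    (condition levels are groups, ``within`` fixes the region).  The
    order of ``condition1``/``condition2`` defines the sign of the
    deviations.  Pairing is implied by the design: the same subject
    across regions, the matched case-control pair across groups.
    """

    axis: str
    condition1: str
    condition2: str
    within: str

    def __post_init__(self) -> None:
        if self.axis not in (REGION_AXIS, GROUP_AXIS):
            raise ContrastError(f"unknown contrast axis {self.axis!r}")
        if self.condition1 == self.condition2:
            raise ContrastError("condition1 and condition2 must differ")

    def label(self) -> str:
        return f"{self.condition2}-vs-{self.condition1}-within-{self.within}"


@dataclass
class DifferentialResult:
    """Per-isoform outcome of one contrast."""

    isoform: str
    median1: float
    median2: float
    median_variation_pct: float
    delta_deviations: np.ndarray
    p_value: float
    q_value: float
    selected: bool


def include_isoforms(
    profiles: Sequence[EditingProfile],
    meta: Sequence[SampleMeta],
    min_prop: float = 0.5,
    reference_stratum: tuple[str, str] = ("control", "BA24"),
) -> list[str]:
    """Apply the reporting floor at the analysis level.

    An isoform enters the analysis when its mean relative proportion
    reaches ``min_prop`` percent in at least one group x region stratum;
    the returned list is ordered by descending mean in the reference
    stratum so downstream tables read from most to least abundant.
    """
    if not profiles:
        raise ContrastError("no profiles supplied")
    by_id = {m.sample_id: m for m in meta}
    isoforms = sorted({iso for p in profiles for iso in p.proportions})
    strata: dict[tuple[str, str], list[EditingProfile]] = {}
    for p in profiles:
        m = by_id[p.sample_id]
        strata.setdefault((m.group, m.region), []).append(p)

    included = []
    for iso in isoforms:
        if any(
            np.mean([p[iso] for p in members]) >= min_prop
            for members in strata.values()
        ):
            included.append(iso)
    ref = strata.get(reference_stratum) or next(iter(strata.values()))
    ref_mean = {iso: float(np.mean([p[iso] for p in ref])) for iso in included}
    return sorted(included, key=lambda i: -ref_mean[i])


def delta_deviation(p1: EditingProfile, p2: EditingProfile, isoform: str) -> float:
    """Signed per-sample deviation, condition 2 minus condition 1.

    An isoform absent from a profile counts as zero percent.
    """
    return p2[isoform] - p1[isoform]


def all_deviations(values1: Sequence[float], values2: Sequence[float]) -> np.ndarray:
    """All condition2 x condition1 deviations, flattened."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    return (v2[:, None] - v1[None, :]).ravel()


def median_variation(values1: Sequence[float], values2: Sequence[float]) -> float:
    """Percent change of the median, 100 * (med2 - med1) / med1."""
    m1 = float(np.median(values1))
    m2 = float(np.median(values2))
    if m1 == 0:
        raise ContrastError("median variation undefined: baseline median is zero")
    return 100.0 * (m2 - m1) / m1


def signed_rank_test(deviations: Sequence[float]) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p for H0: median = 0.

    Exact zeros are dropped (Wilcoxon's convention); the null
    distribution is exact for n <= 25 without tied magnitudes, otherwise
    the mid-rank normal approximation with continuity correction is
    used.  With every deviation zero the data carry no evidence and
    p = 1.
    """
    d = np.asarray(deviations, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if d.size < 2:
        return 1.0
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", correction=True, method=method
    )
    return float(res.pvalue)


def rank_sum_test(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum p-value.

    Exact for combined n <= 20 without ties; with ties or larger samples
    the mid-rank normal approximation with continuity correction.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ContrastError("rank-sum test requires at least 2 values per group")
    pooled = np.concatenate([g1, g2])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        g2, g1, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _condition_samples(
    meta: Sequence[SampleMeta], spec: ContrastSpec
) -> tuple[list[SampleMeta], list[SampleMeta]]:
    if spec.axis == REGION_AXIS:
        pool = [m for m in meta if m.group == spec.within]
        side = lambda m: m.region  # noqa: E731
        key = lambda m: m.subject_id  # noqa: E731
    else:
        pool = [m for m in meta if m.region == spec.within]
        side = lambda m: m.group  # noqa: E731
        key = lambda m: m.pair_id  # noqa: E731
    c1 = sorted((m for m in pool if side(m) == spec.condition1), key=key)
    c2 = sorted((m for m in pool if side(m) == spec.condition2), key=key)
    if not c1 or not c2:
        raise ContrastError(
            f"contrast {spec.label()}: empty condition "
            f"({spec.condition1}: {len(c1)}, {spec.condition2}: {len(c2)})"
        )
    return c1, c2


def _paired(
    c1: list[SampleMeta], c2: list[SampleMeta], spec: ContrastSpec
) -> list[tuple[SampleMeta, SampleMeta]]:
    key = (lambda m: m.subject_id) if spec.axis == REGION_AXIS else (lambda m: m.pair_id)
    d1 = {key(m): m for m in c1}
    d2 = {key(m): m for m in c2}
    if len(d1) != len(c1) or len(d2) != len(c2) or set(d1) != set(d2):
        raise ContrastError(
            f"contrast {spec.label()}: pairing is not a bijection between conditions"
        )
    return [(d1[k], d2[k]) for k in sorted(d1)]


def run_contrast(
    profiles: Sequence[EditingProfile],
    meta: Sequence[SampleMeta],
    spec: ContrastSpec,
    isoforms: Iterable[str] | None = None,
    test: str = "rank-sum",
    min_prop: float = 0.5,
    medvar_threshold: float = 20.0,
    q_threshold: float = 0.05,
) -> list[DifferentialResult]:
    """Run one contrast over the included isoforms.

    Per isoform: the full set of cross-condition deviations, the median
    variation, a p-value from ``test`` (``"rank-sum"``, the default
    calibrated choice, or ``"signed-rank"`` on per-pair deviations along
    the design pairing), BH-FDR across the isoform family of this
    contrast, and the two-criterion selection flag.  Results are ordered
    by significance, then by condition-2 abundance.
    """
    if test not in ("rank-sum", "signed-rank"):
        raise ContrastError(f"unknown test {test!r}")
    if isoforms is None:
        isoforms = include_isoforms(profiles, meta, min_prop=min_prop)
    isoforms = list(isoforms)
    prof_by_id = {p.sample_id: p for p in profiles}
    c1, c2 = _condition_samples(meta, spec)
    pairs = _paired(c1, c2, spec) if test == "signed-rank" else None

    rows = []
    for iso in isoforms:
        v1 = np.array([prof_by_id[m.sample_id][iso] for m in c1])
        v2 = np.array([prof_by_id[m.sample_id][iso] for m in c2])
        devs = all_deviations(v1, v2)
        if test == "signed-rank":
            paired_devs = [
                delta_deviation(prof_by_id[a.sample_id], prof_by_id[b.sample_id], iso)
                for a, b in pairs
            ]
            p = signed_rank_test(paired_devs)
        else:
            p = rank_sum_test(v1, v2)
        m1, m2 = float(np.median(v1)), float(np.median(v2))
        if m1 != 0:
            medvar = 100.0 * (m2 - m1) / m1
        else:
            # zero baseline: no finite percent change; sign carries direction
            medvar = 0.0 if m2 == 0 else float(np.sign(m2)) * float("inf")
        rows.append((iso, m1, m2, medvar, devs, p))

    q = fdr_adjust([r[5] for r in rows])
    results = [
        DifferentialResult(
            isoform=iso,
            median1=m1,
            median2=m2,
            median_variation_pct=medvar,
            delta_deviations=devs,
            p_value=p,
            q_value=float(qv),
            selected=bool(abs(medvar) >= medvar_threshold and qv <= q_threshold),
        )
        for (iso, m1, m2, medvar, devs, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, -r.median2))
    return results


def results_frame(results: Sequence[DifferentialResult]):
    """Tabulate contrast results (one row per isoform)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "isoform": [r.isoform for r in results],
            "median_condition1": [r.median1 for r in results],
            "median_condition2": [r.median2 for r in results],
            "median_variation_pct": [r.median_variation_pct for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "selected": [r.selected for r in results],
        }
    )
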