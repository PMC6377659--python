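"""Domain model for the PDE8A intron-9 A-to-I editing island.

The unit of observation is the *editing isoform*: a single transcript
molecule characterised by the combination of adenosines it carries in the
edited (inosine) state.  Nine island sites are catalogued, labelled
A--G (previously described in T cells) plus the two novel brain sites M
and N.  An isoform is named by concatenating its edited-site labels in
canonical order (``"ABC"``); the fully unedited molecule is the sentinel
``"NE"``.

A sample's measurement is an :class:`EditingProfile`: the relative
proportion (percent of the total analytical CE-SSCP signal) of every
isoform, summing to 100 within each sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: Canonical ordering of site labels used for isoform names.
SITE_ORDER = "ABCDEFGMN"

#: Name of the unedited isoform.
UNEDITED = "NE"

#: Metadata columns expected in a profile table, in order.
META_COLUMNS = ["sample_id", "subject_id", "group", "region", "pair_id"]

GROUPS = ("control", "suicide")
REGIONS = ("BA9", "BA24")


class IsoformNameError(ValueError):
    """Raised when an isoform name contains characters outside the catalogue."""


@dataclass(frozen=True)
class EditingSite:
    """One adenosine position of the intron-9 editing island.

    Coordinates are 1-based GRCh38 positions on chromosome 15.  Sites B,
    M and N are anchored to published coordinates; the remaining labels
    carry representative positions within the island.
    """

    label: str
    position: int
    novel: bool = False


# B, M and N carry their published GRCh38 coordinates; A and C-G are
# representative positions inside the 175-bp amplicon (ascending, close
# proximity, consistent with an editing island).
_CANONICAL_SITES = [
    EditingSite("A", 85096684),
    EditingSite("B", 85096687),
    EditingSite("C", 85096692),
    EditingSite("D", 85096702),
    EditingSite("E", 85096713),
    EditingSite("F", 85096721),
    EditingSite("G", 85096731),
    EditingSite("M", 85096753, novel=True),
    EditingSite("N", 85096771, novel=True),
]


def load_site_table() -> list[EditingSite]:
    """Return the nine canonical island sites (A-G plus novel M, N)."""
    return list(_CANONICAL_SITES)


@dataclass(frozen=True)
class Isoform:
    """A combination of edited sites identifying one CE-SSCP-resolvable molecule."""

    sites: frozenset[str]

    @property
    def name(self) -> str:
        if not self.sites:
            return UNEDITED
        return "".join(s for s in SITE_ORDER if s in self.sites)

    def contains(self, site: str) -> bool:
        return site in self.sites


def parse_isoform_name(name: str) -> Isoform:
    """Parse an isoform name into its site set.

    Site letters may appear in any order; the canonical rendering sorts
    them into :data:`SITE_ORDER`.  ``"NE"`` denotes the empty set.
    """
    if name == UNEDITED:
        return Isoform(frozenset())
    sites = set()
    for ch in name:
        if ch not in SITE_ORDER:
            raise IsoformNameError(
                f"unknown site label {ch!r} in isoform name {name!r}; "
                f"expected letters from {SITE_ORDER!r} or {UNEDITED!r}"
            )
        sites.add(ch)
    return Isoform(frozenset(sites))


def canonical_name(name: str) -> str:
    """Render *name* with sites in canonical order (idempotent)."""
    return parse_isoform_name(name).name


def isoform_sort_key(name: str):
    """Canonical column order for profile tables: NE first, then by
    number of edited sites, then alphabetically."""
    iso = parse_isoform_name(name)
    return (len(iso.sites), iso.name) if iso.sites else (0, "")


@dataclass
class EditingProfile:
    """One sample's relative-proportion vector over isoforms (percent).

    ``proportions`` maps canonical isoform name to its share of the total
    analytical signal; a valid profile is non-negative and sums to 100.
    """

    sample_id: str
    proportions: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, isoform: str) -> float:
        return self.proportions.get(canonical_name(isoform), 0.0)

    def total(self) -> float:
        return float(sum(self.proportions.values()))

    def normalized(self) -> "EditingProfile":
        """Return a copy rescaled to sum exactly to 100."""
        tot = self.total()
        if tot <= 0:
            raise ValueError(f"profile {self.sample_id!r} has no positive mass")
        return EditingProfile(
            self.sample_id, {k: 100.0 * v / tot for k, v in self.proportions.items()}
        )


@dataclass(frozen=True)
class SampleMeta:
    """Sample annotation: donor, diagnostic group, cortical region, matched pair."""

    sample_id: str
    subject_id: str
    group: str
    region: str
    pair_id: str


def site_level_editing(profile: EditingProfile) -> dict[str, float]:
    """Aggregate isoform proportions to per-site editing percentages.

    A site's editing level is the summed proportion of every isoform that
    carries the site; because isoforms are disjoint molecule classes this
    is linear in the profile and bounded by 100.
    """
    levels = {s: 0.0 for s in SITE_ORDER}
    for name, prop in profile.proportions.items():
        for site in parse_isoform_name(name).sites:
            levels[site] += prop
    return levels


@dataclass(frozen=True)
class Finding:
    """A validation finding: machine-readable kind plus human message."""

    kind: str
    message: str


def validate_profile(profile: EditingProfile, tolerance: float = 0.5) -> list[Finding]:
    """Check a profile for sum, sign and site-combination consistency.

    Returns findings rather than raising: the site-combination rules
    (A observed only together with B; N only together with A and B) are
    empirical regularities of brain PDE8A editing, not hard constraints,
    so violations are flagged as warnings.
    """
    findings: list[Finding] = []
    for name, prop in profile.proportions.items():
        if prop < 0:
            findings.append(
                Finding("negative", f"isoform {name}: negative proportion {prop}")
            )
    total = profile.total()
    if abs(total - 100.0) > tolerance:
        findings.append(
            Finding("sum", f"proportions sum to {total:g}, outside 100 ± {tolerance:g}")
        )
    for name, prop in profile.proportions.items():
        if prop <= 0:
            continue
        sites = parse_isoform_name(name).sites
        if "A" in sites and "B" not in sites:
            findings.append(
                Finding("A-without-B", f"isoform {name}: site A edited without B")
            )
        if "N" in sites and not {"A", "B"} <= sites:
            findings.append(
                Finding("N-without-AB", f"isoform {name}: site N edited without A and B")
            )
    return findings


# ---------------------------------------------------------------------------
# Profile table I/O
# ---------------------------------------------------------------------------

def profiles_to_frame(
    profiles: Iterable[EditingProfile], meta: Iterable[SampleMeta]
) -> pd.DataFrame:
    """Assemble profiles + metadata into a tidy wide table.

    Columns: the metadata columns followed by isoform columns in
    canonical order; proportions in percent.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    isoforms: set[str] = set()
    rows = []
    for p in profiles:
        m = meta_by_id[p.sample_id]
        row: dict[str, object] = {
            "sample_id": m.sample_id,
            "subject_id": m.subject_id,
            "group": m.group,
            "region": m.region,
            "pair_id": m.pair_id,
        }
        row.update({canonical_name(k): v for k, v in p.proportions.items()})
        isoforms.update(canonical_name(k) for k in p.proportions)
        rows.append(row)
    cols = META_COLUMNS + sorted(isoforms, key=isoform_sort_key)
    return pd.DataFrame(rows, columns=cols).fillna(0.0)


def frame_to_profiles(
    frame: pd.DataFrame,
) -> tuple[list[EditingProfile], list[SampleMeta]]:
    """Inverse of :func:`profiles_to_frame`."""
    iso_cols = [c for c in frame.columns if c not in META_COLUMNS]
    profiles, meta = [], []
    for _, row in frame.iterrows():
        profiles.append(
            EditingProfile(
                str(row["sample_id"]),
                {c: float(row[c]) for c in iso_cols},
            )
        )
        meta.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                region=str(row["region"]),
                pair_id=str(row["pair_id"]),
            )
        )
    return profiles, meta


def write_profiles(path, profiles, meta) -> None:
    profiles_to_frame(profiles, meta).to_csv(path, index=False)


def read_profiles(path) -> tuple[list[EditingProfile], list[SampleMeta]]:
    return frame_to_profiles(pd.read_csv(path))
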