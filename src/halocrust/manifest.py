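"""Sample manifest: which sample came from which site and plot.

The bundled default manifest encodes the 26-sample, three-site design of the
salt-crust survey: nine samples at the wettest site (Sw, 25.5 km from the
coast, 3113 h of recorded wetness), eight at the intermediate site (Qh,
44.1 km, 1560 h) and nine at the driest site (Qs, 54.2 km, 891 h).  Plot ids
group samples collected within the same 3 x 3 m plot.  Latitude/longitude in
the bundled file are synthetic stand-in coordinates placed along a realistic
coast-inland transect; the pipeline only uses them for between-sample
geographic distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd


class ManifestError(ValueError):
    """Raised when a sample manifest violates its invariants."""


@dataclass(frozen=True)
class Site:
    site_id: str
    distance_from_coast_km: float
    wetness_hours: float
    latitude: float
    longitude: float


@dataclass(frozen=True)
class Sample:
    sample_id: str
    site_id: str
    plot_id: str


@dataclass
class SampleManifest:
    """Validated collection of samples and the sites they came from."""

    samples: list[Sample]
    sites: list[Site]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate sample ids: {dups}")
        known = {s.site_id for s in self.sites}
        for s in self.samples:
            if s.site_id not in known:
                raise ManifestError(
                    f"sample {s.sample_id!r} references unknown site {s.site_id!r}"
                )
        per_site = self.site_sample_counts()
        empty = sorted(known - set(per_site))
        if empty:
            raise ManifestError(f"sites with no samples: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def site_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.site_id
        raise KeyError(sample_id)

    def site_sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.samples:
            counts[s.site_id] = counts.get(s.site_id, 0) + 1
        return counts

    def site(self, site_id: str) -> Site:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def environment_table(self) -> pd.DataFrame:
        """Per-sample environmental covariates (indexed by sample_id)."""
        rows = {}
        for s in self.samples:
            site = self.site(s.site_id)
            rows[s.sample_id] = {
                "distance_from_coast_km": site.distance_from_coast_km,
                "wetness_hours": site.wetness_hours,
                "latitude": site.latitude,
                "longitude": site.longitude,
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def group_labels(self) -> list[str]:
        """Site label per sample, in manifest order."""
        return [s.site_id for s in self.samples]


def load_sample_manifest(path: str | Path) -> SampleManifest:
    """Load and validate a tab-delimited sample manifest.

    Expected columns: sample_id, site_id, plot_id, distance_from_coast_km,
    wetness_hours, latitude, longitude (site attributes repeated per sample
    and required to be consistent within a site).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_id": str, "plot_id": str})
    required = {
        "sample_id", "site_id", "plot_id",
        "distance_from_coast_km", "wetness_hours", "latitude", "longitude",
    }
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    sites = []
    for site_id, grp in df.groupby("site_id", sort=False):
        attrs = grp[["distance_from_coast_km", "wetness_hours", "latitude", "longitude"]]
        if attrs.nunique().max() > 1:
            raise ManifestError(f"inconsistent site attributes for {site_id!r}")
        row = attrs.iloc[0]
        sites.append(
            Site(
                site_id=str(site_id),
                distance_from_coast_km=float(row["distance_from_coast_km"]),
                wetness_hours=float(row["wetness_hours"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
            )
        )
    samples = [
        Sample(sample_id=str(r.sample_id), site_id=str(r.site_id), plot_id=str(r.plot_id))
        for r in df.itertuples()
    ]
    return SampleManifest(samples=samples, sites=sites)


def default_manifest() -> SampleManifest:
    """The bundled 26-sample three-site manifest (Sw:9, Qh:8, Qs:9)."""
    with resources.as_file(resources.files("halocrust.data") / "samples.tsv") as p:
        return load_sample_manifest(p)
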