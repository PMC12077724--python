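"""Camera-trap event processing.

Turns raw time-stamped detection events plus deployment metadata into
model-ready detection/count histories:

* deployments within a small radius are merged into a single site,
* deployments are capped per site (one per year, at most four, longest kept),
* events are thinned to independent events using per-species minimum gaps,
* deployments are cut into fixed-length sampling occasions (7 days by
  default) and events are counted per occasion.

Tables are plain :class:`pandas.DataFrame` objects with documented columns;
the model-ready product is :class:`DetectionArray`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "DetectionArray",
    "read_events",
    "read_deployments",
    "merge_sites",
    "select_deployments",
    "filter_independent_events",
    "build_occasions",
    "build_count_histories",
    "compute_trap_rates",
]

#: Column schema for event tables.
EVENT_COLUMNS = ("site_id", "deployment_id", "timestamp", "species")
#: Column schema for deployment tables.
DEPLOYMENT_COLUMNS = ("deployment_id", "site_id", "easting", "northing", "start", "end")

PASSTHROUGH_SPECIES = ("human", "vehicle")


@dataclass
class DetectionArray:
    """Site x occasion x species detection histories.

    Attributes
    ----------
    counts
        Integer array ``(n_sites, n_occasions, n_species)``; number of
        independent events per sampling occasion (or 0/1 indicators when
        ``binary``).
    mask
        Boolean ``(n_sites, n_occasions)``; True where the occasion was
        surveyed. ``counts`` is zero wherever the mask is False.
    replicate
        Integer ``(n_sites, n_occasions)``; ordinal deployment number
        (1-based) each occasion belongs to, 0 where unsurveyed.
    effort
        Float ``(n_sites, n_occasions)``; active days within the occasion
        (trailing partial occasions have effort below the occasion length).
    site_ids, species
        Axis labels.
    binary
        Whether counts were clipped to detection/non-detection.
    """

    counts: np.ndarray
    mask: np.ndarray
    replicate: np.ndarray
    effort: np.ndarray
    site_ids: list = field(default_factory=list)
    species: list = field(default_factory=list)
    binary: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.replicate = np.asarray(self.replicate, dtype=np.int64)
        self.effort = np.asarray(self.effort, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (sites, occasions, species)")
        if self.mask.shape != self.counts.shape[:2]:
            raise ValueError("mask shape must match counts (sites, occasions)")
        if self.counts[~self.mask].any():
            raise ValueError("non-zero counts outside the surveyed mask")
        if (self.replicate[self.mask] < 1).any():
            raise ValueError("replicate index must be >= 1 on surveyed occasions")
        if (self.effort[self.mask] <= 0).any():
            raise ValueError("effort must be positive on surveyed occasions")
        if not self.site_ids:
            self.site_ids = list(range(self.counts.shape[0]))
        if not self.species:
            self.species = [f"sp{k}" for k in range(self.counts.shape[2])]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.counts.shape[1]

    @property
    def n_species(self) -> int:
        return self.counts.shape[2]

    @property
    def n_replicates(self) -> int:
        return int(self.replicate.max(initial=0))

    def binarize(self) -> "DetectionArray":
        """Clip counts to {0,1} (N-mixture history -> occupancy history)."""
        return DetectionArray(
            counts=np.clip(self.counts, 0, 1),
            mask=self.mask.copy(),
            replicate=self.replicate.copy(),
            effort=self.effort.copy(),
            site_ids=list(self.site_ids),
            species=list(self.species),
            binary=True,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format table (site, occasion, species, count, mask, replicate, effort)."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.n_sites),
            np.arange(self.n_occasions),
            np.arange(self.n_species),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "site_id": np.asarray(self.site_ids, dtype=object)[ii.ravel()],
                "occasion": jj.ravel(),
                "species": np.asarray(self.species, dtype=object)[kk.ravel()],
                "count": self.counts.ravel(),
                "mask": self.mask[ii.ravel(), jj.ravel()],
                "replicate": self.replicate[ii.ravel(), jj.ravel()],
                "effort": self.effort[ii.ravel(), jj.ravel()],
            }
        )

    def write(self, path: str | Path) -> None:
        """Write as delimited text plus a JSON sidecar of dimensions."""
        path = Path(path)
        self.to_long().to_csv(path, index=False, float_format="%.10g")
        sidecar = {
            "n_sites": self.n_sites,
            "n_occasions": self.n_occasions,
            "n_species": self.n_species,
            "site_ids": [str(s) for s in self.site_ids],
            "species": list(self.species),
            "binary": self.binary,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )

    @classmethod
    def read(cls, path: str | Path) -> "DetectionArray":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        long = pd.read_csv(path)
        I, J, K = sidecar["n_sites"], sidecar["n_occasions"], sidecar["n_species"]
        site_pos = {s: i for i, s in enumerate(sidecar["site_ids"])}
        sp_pos = {s: k for k, s in enumerate(sidecar["species"])}
        counts = np.zeros((I, J, K), dtype=np.int64)
        mask = np.zeros((I, J), dtype=bool)
        replicate = np.zeros((I, J), dtype=np.int64)
        effort = np.zeros((I, J))
        ii = long["site_id"].astype(str).map(site_pos).to_numpy()
        jj = long["occasion"].to_numpy()
        kk = long["species"].map(sp_pos).to_numpy()
        counts[ii, jj, kk] = long["count"].to_numpy()
        mask[ii, jj] = long["mask"].to_numpy()
        replicate[ii, jj] = long["replicate"].to_numpy()
        effort[ii, jj] = long["effort"].to_numpy()
        return cls(counts, mask, replicate, effort,
                   site_ids=sidecar["site_ids"], species=sidecar["species"],
                   binary=sidecar["binary"])


# ---------------------------------------------------------------------------
# table I/O and validation

def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event table (CSV, ISO-8601 timestamps)."""
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, "event table")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_deployments(path: str | Path) -> pd.DataFrame:
    """Read a deployment table (CSV, ISO-8601 dates, metric coordinates)."""
    df = pd.read_csv(path)
    _require_columns(df, DEPLOYMENT_COLUMNS, "deployment table")
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    _validate_deployments(df)
    return df


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {missing}")


def _validate_deployments(df: pd.DataFrame) -> None:
    if (df["end"] < df["start"]).any():
        bad = df.loc[df["end"] < df["start"], "deployment_id"].tolist()
        raise ValueError(f"deployments end before start: {bad}")
    # at most one active camera per site at a time
    for site, grp in df.sort_values("start").groupby("site_id"):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        if len(grp) > 1 and (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping deployments at site {site!r}")


def deployment_duration_days(df: pd.DataFrame) -> pd.Series:
    return (df["end"] - df["start"]) / pd.Timedelta(days=1)


# ---------------------------------------------------------------------------
# site merging

def merge_sites(deployments: pd.DataFrame, radius_m: float = 15.0) -> pd.DataFrame:
    """Merge deployments within ``radius_m`` of each other into one site.

    The within-radius relation is closed transitively (connected components
    of the proximity graph), so chains of nearby deployments collapse into a
    single site even when the endpoints are farther apart than the radius.
    The canonical site id of a component is the ``site_id`` of its earliest
    deployment (ties broken by ``deployment_id``).
    """
    df = deployments.copy()
    if df.empty:
        return df
    if df[["easting", "northing"]].isna().any().any():
        raise ValueError("merge_sites requires easting/northing for every deployment")
    xy = df[["easting", "northing"]].to_numpy(dtype=float)
    pairs = cKDTree(xy).query_pairs(r=radius_m, output_type="ndarray")
    n = len(df)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    order = np.lexsort((df["deployment_id"].to_numpy(), df["start"].to_numpy()))
    canonical: dict[int, object] = {}
    for idx in order:
        canonical.setdefault(labels[idx], df["site_id"].iloc[idx])
    df["site_id"] = [canonical[lab] for lab in labels]
    return df


# ---------------------------------------------------------------------------
# deployment selection

def select_deployments(deployments: pd.DataFrame, cap: int = 4) -> pd.DataFrame:
    """Apply the one-per-year rule and the per-site deployment cap.

    Per site: keep at most one deployment per calendar year (the longest;
    ties by earlier start), then, if more than ``cap`` remain, keep the
    ``cap`` longest (ties by earlier start). Surviving deployments get a
    ``replicate`` column numbered 1..cap in chronological order.
    """
    if deployments.empty:
        out = deployments.copy()
        out["replicate"] = pd.Series(dtype=np.int64)
        return out
    df = deployments.copy()
    df["_duration"] = deployment_duration_days(df)
    df["_year"] = df["start"].dt.year
    kept = []
    for _, site_grp in df.groupby("site_id", sort=False):
        per_year = (
            site_grp.sort_values(["_duration", "start"], ascending=[False, True])
            .groupby("_year", sort=False)
            .head(1)
        )
        top = per_year.sort_values(
            ["_duration", "start"], ascending=[False, True]
        ).head(cap)
        top = top.sort_values("start").copy()
        top["replicate"] = np.arange(1, len(top) + 1)
        kept.append(top)
    out = pd.concat(kept).drop(columns=["_duration", "_year"])
    return out.sort_index()


# ---------------------------------------------------------------------------
# independence filtering

def filter_independent_events(
    events: pd.DataFrame,
    gap_minutes: Mapping[str, float],
    passthrough: Iterable[str] = PASSTHROUGH_SPECIES,
) -> pd.DataFrame:
    """Thin each (site, species) event stream to independent events.

    Scanning in time order, a record is retained iff it is the first of its
    stream or at least ``gap_minutes[species]`` minutes after the last
    *retained* record of the stream. Human/vehicle streams pass through
    unfiltered.
    """
    passthrough = set(passthrough)
    focal = set(events["species"].unique()) - passthrough
    missing = sorted(focal - set(gap_minutes))
    if missing:
        raise ValueError(f"no independence gap configured for species: {missing}")
    if events.empty:
        return events.copy()

    keep = np.zeros(len(events), dtype=bool)
    order = events.sort_values("timestamp", kind="mergesort")
    for (site, sp), grp in order.groupby(["site_id", "species"], sort=False):
        if sp in passthrough:
            keep[grp.index] = True
            continue
        gap = pd.Timedelta(minutes=gap_minutes[sp])
        last_retained = None
        for idx, ts in zip(grp.index, grp["timestamp"]):
            if last_retained is None or ts - last_retained >= gap:
                keep[idx] = True
                last_retained = ts
    return events.loc[keep].copy()


# ---------------------------------------------------------------------------
# occasions and histories

def build_occasions(
    deployment: pd.Series | Mapping, occasion_length_days: int = 7
) -> list[tuple[pd.Timestamp, pd.Timestamp, float]]:
    """Cut one deployment into half-open occasion windows.

    Returns ``(window_start, window_end, effort_days)`` triples; the trailing
    partial window is retained with its reduced effort.
    """
    start = pd.Timestamp(deployment["start"])
    end = pd.Timestamp(deployment["end"])
    if end < start:
        raise ValueError("deployment ends before it starts")
    length = pd.Timedelta(days=occasion_length_days)
    windows = []
    t = start
    while t < end:
        w_end = min(t + length, end)
        effort = (w_end - t) / pd.Timedelta(days=1)
        windows.append((t, w_end, effort))
        t = t + length
    if not windows:  # zero-length deployment: single degenerate day
        windows.append((start, start + pd.Timedelta(days=1), 1.0))
    return windows


def build_count_histories(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species: Sequence[str],
    binary: bool = False,
    occasion_length_days: int = 7,
) -> DetectionArray:
    """Count independence-filtered events per sampling occasion.

    ``deployments`` must already be merged/selected (carry a ``replicate``
    column). Occasions from all retained deployments at a site are
    concatenated along the occasion axis, each tagged with its deployment's
    replicate number. Events of focal species that fall outside every
    occasion window of their deployment raise, signalling inconsistent
    inputs.
    """
    if "replicate" not in deployments.columns:
        raise ValueError("deployments must carry a replicate column "
                         "(run select_deployments first)")
    species = list(species)
    sp_pos = {s: k for k, s in enumerate(species)}
    site_ids = sorted(deployments["site_id"].unique(), key=str)
    site_pos = {s: i for i, s in enumerate(site_ids)}

    # per-site concatenated occasion windows
    site_windows: dict[object, list] = {s: [] for s in site_ids}
    windows_by_dep: dict[object, list] = {}
    for _, dep in deployments.sort_values(["site_id", "replicate"]).iterrows():
        wins = build_occasions(dep, occasion_length_days)
        windows_by_dep[dep["deployment_id"]] = wins
        site_windows[dep["site_id"]].extend(
            (w, dep["replicate"], dep["deployment_id"]) for w in wins
        )
    J = max(len(w) for w in site_windows.values())
    I, K = len(site_ids), len(species)
    counts = np.zeros((I, J, K), dtype=np.int64)
    mask = np.zeros((I, J), dtype=bool)
    replicate = np.zeros((I, J), dtype=np.int64)
    effort = np.zeros((I, J))
    occ_index: dict[tuple, list] = {}
    for s in site_ids:
        i = site_pos[s]
        for j, ((w_start, w_end, eff), rep, dep_id) in enumerate(site_windows[s]):
            mask[i, j] = True
            replicate[i, j] = rep
            effort[i, j] = eff
            occ_index.setdefault(dep_id, []).append((w_start, w_end, i, j))

    retained_deps = set(deployments["deployment_id"])
    focal = events[events["species"].isin(sp_pos)]
    for _, ev in focal.iterrows():
        dep_id = ev["deployment_id"]
        if dep_id not in retained_deps:
            continue  # event from a deployment dropped by selection
        ts = ev["timestamp"]
        for w_start, w_end, i, j in occ_index[dep_id]:
            if w_start <= ts < w_end:
                counts[i, j, sp_pos[ev["species"]]] += 1
                break
        else:
            raise ValueError(
                f"event at {ts} outside every occasion window of deployment "
                f"{dep_id!r}"
            )
    if binary:
        counts = np.clip(counts, 0, 1)
    return DetectionArray(counts, mask, replicate, effort,
                          site_ids=list(site_ids), species=species, binary=binary)


# ---------------------------------------------------------------------------
# trap-rate covariates

def compute_trap_rates(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    categories: Sequence[str] = PASSTHROUGH_SPECIES,
) -> pd.DataFrame:
    """Average daily detection rate of each background category per site.

    Per deployment the rate is category events divided by active days; the
    per-site value is the duration-weighted mean over retained deployments.
    """
    durations = deployment_duration_days(deployments)
    if (durations <= 0).any():
        bad = deployments.loc[durations <= 0, "deployment_id"].tolist()
        raise ValueError(f"zero-duration deployments: {bad}")
    dep_site = deployments.set_index("deployment_id")["site_id"]
    dep_days = pd.Series(durations.to_numpy(), index=deployments["deployment_id"])
    rows = {}
    for cat in categories:
        n_ev = (
            events[events["species"] == cat]
            .groupby("deployment_id")
            .size()
            .reindex(dep_days.index, fill_value=0)
        )
        rate = n_ev / dep_days
        weighted = (
            pd.DataFrame({"site_id": dep_site.values, "rate": rate.values,
                          "days": dep_days.values})
            .groupby("site_id")
            .apply(lambda g: np.average(g["rate"], weights=g["days"]),
                   include_groups=False)
        )
        rows[f"{cat}_rate"] = weighted
    return pd.DataFrame(rows)
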