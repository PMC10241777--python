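"""Pairwise connectivity matrices from raft fate ledgers.

P_ij is the number of rafts released from site i that produced a
connectivity event at site j, divided by the releases from i; the
matrix is asymmetric and includes retention on the diagonal. Yearly
matrices are averaged element-wise for a multi-year climatology, and
summary statistics over realized links (event distance, probability,
event counts) are computed as weighted mean ± population SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd

from .advection import FATE_EVENT, FATE_BEACHED, FATE_LOST, FATE_EXPIRED
from .geo import haversine_km


@dataclass
class ConnectivityMatrix:
    """site_ids (n,), n_released (n,), n_events (n, n), P (n, n)."""

    site_ids: np.ndarray
    n_released: np.ndarray
    n_events: np.ndarray
    P: np.ndarray
    label: str = "year"

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=int)
        self.n_released = np.asarray(self.n_released, dtype=int)
        self.n_events = np.asarray(self.n_events, dtype=int)
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.site_ids)
        if self.n_events.shape != (n, n) or self.P.shape != (n, n):
            raise ValueError("matrix shapes must be (n, n)")
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_long(self) -> pd.DataFrame:
        i, j = np.meshgrid(np.arange(len(self.site_ids)),
                           np.arange(len(self.site_ids)), indexing="ij")
        return pd.DataFrame({
            "source_id": self.site_ids[i.ravel()],
            "sink_id": self.site_ids[j.ravel()],
            "n_events": self.n_events.ravel(),
            "n_released": self.n_released[i.ravel()],
            "probability": self.P.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "csv") -> "ConnectivityMatrix":
        long = pd.read_csv(path)
        ids = np.unique(long["source_id"])
        pos = {s: k for k, s in enumerate(ids)}
        n = len(ids)
        ne = np.zeros((n, n), dtype=int)
        P = np.zeros((n, n))
        N = np.zeros(n, dtype=int)
        for _, row in long.iterrows():
            i, j = pos[row["source_id"]], pos[row["sink_id"]]
            ne[i, j] = row["n_events"]
            P[i, j] = row["probability"]
            N[i] = row["n_released"]
        return cls(site_ids=ids, n_released=N, n_events=ne, P=P, label=label)


@dataclass
class EventStats:
    """Connectivity-event summaries; ``defined`` is False when the
    simulation produced no events at all."""

    mean_distance_km: float
    sd_distance_km: float
    max_distance_km: float
    mean_probability: float
    sd_probability: float
    mean_events: float
    sd_events: float
    n_links: int
    n_events_total: int
    defined: bool = True

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def build_matrix(traj: pd.DataFrame, sites, label: str = "year") -> ConnectivityMatrix:
    """Count events per ordered site pair from a fate ledger.

    ``traj`` must be a run_period/run_year output; every referenced
    site id (sources and event sinks) must exist in ``sites``.
    """
    ids = sites.table["site_id"].to_numpy(dtype=int)
    pos = {int(s): k for k, s in enumerate(ids)}
    src = traj["site_id"].to_numpy(dtype=int)
    unknown = set(src) - set(pos)
    ev = traj.loc[traj["fate"] == FATE_EVENT, ["site_id", "event_site"]].to_numpy(dtype=int)
    unknown |= set(ev[:, 1]) - set(pos)
    if unknown:
        raise ValueError(f"unknown site id(s): {sorted(unknown)}")
    n = len(ids)
    N = np.zeros(n, dtype=int)
    np.add.at(N, [pos[s] for s in src], 1)
    ne = np.zeros((n, n), dtype=int)
    if len(ev):
        np.add.at(ne, ([pos[s] for s in ev[:, 0]], [pos[s] for s in ev[:, 1]]), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(N[:, None] > 0, ne / np.maximum(N[:, None], 1), 0.0)
    return ConnectivityMatrix(site_ids=ids, n_released=N, n_events=ne, P=P, label=label)


def mean_matrix(per_year: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise arithmetic mean of P across years; release and
    event counts are summed for bookkeeping."""
    if not per_year:
        raise ValueError("no matrices given")
    ids = per_year[0].site_ids
    for m in per_year[1:]:
        if not np.array_equal(m.site_ids, ids):
            raise ValueError("site sets differ between matrices")
    P = np.mean([m.P for m in per_year], axis=0)
    return ConnectivityMatrix(
        site_ids=ids,
        n_released=np.sum([m.n_released for m in per_year], axis=0),
        n_events=np.sum([m.n_events for m in per_year], axis=0),
        P=P, label="mean")


def fate_counts(traj: pd.DataFrame) -> pd.DataFrame:
    """Per-source tally of fates; rows sum to releases (conservation)."""
    out = (traj.groupby(["site_id", "fate"]).size().unstack(fill_value=0)
           .reindex(columns=[FATE_EVENT, FATE_BEACHED, FATE_LOST, FATE_EXPIRED],
                    fill_value=0))
    out["released"] = out.sum(axis=1)
    return out.reset_index()


def event_statistics(mat: ConnectivityMatrix, sites,
                     include_diagonal: bool = True,
                     conditional: bool = True) -> EventStats:
    """Distance / probability / event-count summaries.

    Distances are haversine between site cell centres, weighted by the
    pair's event count. By default statistics are taken over ordered
    pairs with at least one event (``conditional``), diagonal
    included; ``conditional=False`` averages P over all ordered pairs.
    SDs are population SDs over the event / link multiset.
    """
    tab = sites.table.set_index("site_id")
    lon = tab.loc[mat.site_ids, "lon"].to_numpy()
    lat = tab.loc[mat.site_ids, "lat"].to_numpy()
    D = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])

    linked = mat.n_events > 0
    if not include_diagonal:
        np.fill_diagonal(linked, False)
    if not linked.any():
        return EventStats(*(float("nan"),) * 7, n_links=0, n_events_total=0, defined=False)

    w = mat.n_events[linked].astype(float)
    d = D[linked]
    mean_d = float(np.average(d, weights=w))
    sd_d = float(np.sqrt(np.average((d - mean_d) ** 2, weights=w)))
    if conditional:
        p = mat.P[linked]
    else:
        mask = np.ones_like(mat.P, dtype=bool)
        if not include_diagonal:
            np.fill_diagonal(mask, False)
        p = mat.P[mask]
    ne = mat.n_events[linked].astype(float)
    return EventStats(
        mean_distance_km=mean_d, sd_distance_km=sd_d,
        max_distance_km=float(d.max()),
        mean_probability=float(p.mean()), sd_probability=float(p.std()),
        mean_events=float(ne.mean()), sd_events=float(ne.std()),
        n_links=int(linked.sum()), n_events_total=int(ne.sum()),
    )
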