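"""Exposure construction from raw field observations.

Two families of early-life social exposure are derived here:

* maternal care — per-cub proportions of observed minutes spent in close
  proximity (<=1 m) to the mother, nursing, and being groomed, computed from
  focal-animal-survey (FAS) records over qualifying sessions (mother and cub
  together >=5 min, cub under 13 months, mother lactating);
* social connectedness — degree, strength, and betweenness centrality from
  weighted association networks built from co-occurrence sessions inside each
  animal's communal-den (CD) and den-independent (DI) developmental windows.
  The DI window is duration-matched to the CD window per individual.

Edge weights are the simple ratio association index
x / (x + y_a + y_b) in [0, 1]; betweenness uses edge distance 1/weight
(stronger association = shorter path) and is normalized by (n-1)(n-2)/2.
Dates are day-resolution; windows include both endpoints.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CareSummary",
    "DevWindow",
    "NetworkMetrics",
    "maternal_care_proportions",
    "define_windows",
    "association_index",
    "build_network",
    "network_metrics",
]


@dataclass
class CareSummary:
    cub_id: str
    prop_close_proximity: float
    prop_nursing: float
    prop_grooming: float
    minutes_observed: float


@dataclass
class DevWindow:
    individual_id: str
    label: str  # "CD" or "DI"
    start_date: dt.date
    end_date: dt.date

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def contains(self, date: dt.date) -> bool:
        return self.start_date <= date <= self.end_date


@dataclass
class NetworkMetrics:
    individual_id: str
    window: str
    degree: int
    strength: float
    betweenness: float


def maternal_care_proportions(
    fas_records: pd.DataFrame,
    max_cub_age_months: float = 13.0,
    min_minutes: float = 5.0,
) -> pd.DataFrame:
    """Per-cub maternal-care proportions from FAS session records.

    Expected columns: ``cub_id, minutes_together, minutes_close,
    minutes_nursing, minutes_grooming, cub_age_months, mother_lactating``.
    Sessions qualify when the pair was together at least ``min_minutes``,
    the cub was under ``max_cub_age_months`` months old, and the mother was
    lactating.  Proportions are summed behavior minutes over summed
    co-observed minutes across qualifying sessions.  Cubs with no qualifying
    minutes are excluded (and logged).
    """
    req = {"cub_id", "minutes_together", "minutes_close", "minutes_nursing",
           "minutes_grooming", "cub_age_months", "mother_lactating"}
    missing = req - set(fas_records.columns)
    if missing:
        raise ValueError(f"FAS records missing columns: {sorted(missing)}")
    ok = (
        (fas_records["minutes_together"] >= min_minutes)
        & (fas_records["cub_age_months"] < max_cub_age_months)
        & fas_records["mother_lactating"].astype(bool)
    )
    qualifying = fas_records.loc[ok]
    excluded = set(fas_records["cub_id"]) - set(qualifying["cub_id"])
    if excluded:
        logger.info("maternal_care_proportions: %d cubs with no qualifying sessions excluded: %s",
                    len(excluded), sorted(excluded))
    agg = qualifying.groupby("cub_id")[
        ["minutes_together", "minutes_close", "minutes_nursing", "minutes_grooming"]
    ].sum()
    out = pd.DataFrame({
        "cub_id": agg.index,
        "prop_close_proximity": agg["minutes_close"] / agg["minutes_together"],
        "prop_nursing": agg["minutes_nursing"] / agg["minutes_together"],
        "prop_grooming": agg["minutes_grooming"] / agg["minutes_together"],
        "minutes_observed": agg["minutes_together"],
    }).reset_index(drop=True)
    return out


def define_windows(individual_id: str, cd_start: dt.date, cd_end: dt.date) -> tuple[DevWindow, DevWindow]:
    """Build the CD window and its duration-matched DI window.

    The DI window starts the day after the CD window ends and spans exactly
    as many days as the CD window (both windows include their endpoints).
    """
    if cd_end < cd_start:
        raise ValueError(f"cd_end ({cd_end}) must not precede cd_start ({cd_start})")
    cd = DevWindow(individual_id, "CD", cd_start, cd_end)
    di_start = cd_end + dt.timedelta(days=1)
    di_end = di_start + dt.timedelta(days=cd.n_days - 1)
    di = DevWindow(individual_id, "DI", di_start, di_end)
    assert di.n_days == cd.n_days
    return cd, di


def association_index(n_together: int, n_a_only: int, n_b_only: int) -> float:
    """Simple ratio index x / (x + y_a + y_b) in [0, 1]."""
    if min(n_together, n_a_only, n_b_only) < 0:
        raise ValueError("counts must be nonnegative")
    denom = n_together + n_a_only + n_b_only
    if denom == 0:
        raise ValueError("association index undefined for all-zero counts")
    return n_together / denom


def build_network(
    sessions: pd.DataFrame,
    window: DevWindow,
    focal_cohort: list[str] | None = None,
) -> nx.Graph:
    """Weighted association network from co-occurrence sessions in a window.

    ``sessions`` needs columns ``date`` (datetime.date or parseable) and
    ``present_ids`` (iterable of individual ids, or ';'-delimited string).
    Nodes are the individuals seen in at least one in-window session; edges
    carry the simple ratio index as ``weight`` and 1/weight as ``distance``.
    Zero-weight pairs carry no edge.
    """
    dates = sessions["date"].map(_as_date)
    in_win = sessions.loc[[window.contains(d) for d in dates]]
    G = nx.Graph()
    if in_win.empty:
        logger.warning("build_network: no sessions inside window %s %s–%s",
                       window.label, window.start_date, window.end_date)
        return G
    groups = [_as_id_set(v) for v in in_win["present_ids"]]
    individuals = sorted(set().union(*groups))
    G.add_nodes_from(individuals)
    idx = {ind: k for k, ind in enumerate(individuals)}
    B = np.zeros((len(individuals), len(groups)), dtype=np.int32)
    for s, g in enumerate(groups):
        for ind in g:
            B[idx[ind], s] = 1
    together = B @ B.T  # co-occurrence session counts
    seen = np.diag(together).copy()
    ii, jj = np.triu_indices(len(individuals), k=1)
    for a_i, b_i in zip(ii, jj):
        x = int(together[a_i, b_i])
        if x == 0:
            continue
        w = association_index(x, int(seen[a_i] - x), int(seen[b_i] - x))
        a, b = individuals[a_i], individuals[b_i]
        G.add_edge(a, b, weight=w, distance=1.0 / w)
    if focal_cohort is not None:
        # cohort filter applies to which metrics are reported, not network
        # membership; keep all observed individuals as nodes.
        pass
    return G


def network_metrics(network: nx.Graph, focal_id: str) -> NetworkMetrics:
    """Degree (count of associates), strength (summed edge weights), and
    normalized weighted betweenness (distance = 1/weight) for one node."""
    if focal_id not in network:
        raise KeyError(f"individual {focal_id!r} not in network")
    degree = int(network.degree(focal_id))
    strength = float(network.degree(focal_id, weight="weight"))
    n = network.number_of_nodes()
    if n < 3:
        betweenness = 0.0
    else:
        bc = nx.betweenness_centrality(network, weight="distance", normalized=True)
        betweenness = float(bc[focal_id])
    return NetworkMetrics(individual_id=focal_id, window="", degree=degree,
                          strength=strength, betweenness=betweenness)


def window_metrics_table(
    sessions: pd.DataFrame,
    windows: dict[str, tuple[DevWindow, DevWindow]],
) -> pd.DataFrame:
    """Per-individual CD/DI network metrics: one row per (individual, window)."""
    rows = []
    for ind, (cd, di) in windows.items():
        for win in (cd, di):
            G = build_network(sessions, win)
            if ind in G:
                m = network_metrics(G, ind)
            else:
                m = NetworkMetrics(ind, win.label, 0, 0.0, 0.0)
            rows.append({"individual_id": ind, "window": win.label,
                         "degree": m.degree, "strength": m.strength,
                         "betweenness": m.betweenness})
    return pd.DataFrame(rows)


def _as_date(v) -> dt.date:
    if isinstance(v, dt.datetime):
        return v.date()
    if isinstance(v, dt.date):
        return v
    return pd.Timestamp(v).date()


def _as_id_set(v) -> set:
    if isinstance(v, str):
        return {s for s in v.split(";") if s}
    return set(v)
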