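"""Spatial oscillation clusters.

An oscillation cluster is a spatially contiguous group of electrodes within
one subject that all show a narrowband spectral peak in the same frequency
band.  Contiguity is defined on the graph whose edges connect electrode
pairs closer than 20 mm; connected components with at least four members
become clusters.  Cluster band ranges default to theta 4-8 Hz and beta
12-30 Hz (the ranges used for cluster building, which are deliberately
wider/lower than the MODAL-derived ~6-9 / ~15-32 Hz gradient-analysis
ranges; both are configurable).
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

CLUSTER_BAND_RANGES = {"theta": (4.0, 8.0), "beta": (12.0, 30.0)}


@dataclasses.dataclass
class OscillationCluster:
    cluster_id: str
    subject_id: str
    hemisphere: str
    band: str
    members: list          # electrode names
    f_p: float             # cluster narrowband peak frequency, Hz

    def __post_init__(self):
        if len(self.members) < 4:
            raise ValueError("clusters require at least four members")


def find_oscillation_clusters(peaks: pd.DataFrame, electrodes: pd.DataFrame,
                              distance_mm: float = 20.0, min_size: int = 4,
                              band_ranges: dict | None = None
                              ) -> list[OscillationCluster]:
    """Connected components of the < ``distance_mm`` adjacency graph among
    electrodes holding a narrowband peak in each band.

    ``peaks`` is a long table with at least ``electrode_id`` and
    ``peak_freq`` columns (one row per detected peak, as produced by
    ``spectral.peaks_table``).  The cluster peak frequency ``f_p`` is the
    median of the members' in-band peak frequencies (each member's
    strongest in-band peak).  Edges use strict < ``distance_mm``.
    """

    if band_ranges is None:
        band_ranges = CLUSTER_BAND_RANGES
    clusters: list[OscillationCluster] = []
    for subject, sub_elec in electrodes.groupby("subject", sort=True):
        sub_elec = sub_elec.reset_index(drop=True)
        coords = sub_elec[["x", "y", "z"]].to_numpy(dtype=float)
        names = list(sub_elec["name"])
        dist = squareform(pdist(coords)) if len(names) > 1 else np.zeros((1, 1))
        sub_peaks = peaks[peaks["electrode_id"].isin(names)]
        for band, (lo, hi) in band_ranges.items():
            in_band = sub_peaks[(sub_peaks["peak_freq"] >= lo)
                                & (sub_peaks["peak_freq"] <= hi)]
            if in_band.empty:
                continue
            # strongest in-band peak per electrode
            best = (in_band.sort_values("peak_power", ascending=False)
                    .groupby("electrode_id", sort=False).head(1)
                    .set_index("electrode_id")["peak_freq"])
            idx = [i for i, n in enumerate(names) if n in best.index]
            g = nx.Graph()
            g.add_nodes_from(idx)
            for a_pos, i in enumerate(idx):
                for j in idx[a_pos + 1:]:
                    if dist[i, j] < distance_mm:
                        g.add_edge(i, j)
            for comp in sorted(nx.connected_components(g), key=min):
                if len(comp) < min_size:
                    continue
                comp = sorted(comp)
                members = [names[i] for i in comp]
                hemis = sub_elec.loc[comp, "hemisphere"]
                hemisphere = hemis.mode().iloc[0]
                f_p = float(np.median([best[m] for m in members]))
                clusters.append(OscillationCluster(
                    cluster_id=f"{subject}_{band}_{len(clusters)}",
                    subject_id=subject, hemisphere=hemisphere, band=band,
                    members=members, f_p=f_p))
    return clusters


def clusters_table(clusters: list[OscillationCluster]) -> pd.DataFrame:
    rows = [{
        "cluster_id": c.cluster_id, "subject": c.subject_id,
        "hemisphere": c.hemisphere, "band": c.band, "f_p": c.f_p,
        "n_members": len(c.members), "members": ",".join(c.members),
    } for c in clusters]
    return pd.DataFrame(rows, columns=["cluster_id", "subject", "hemisphere",
                                       "band", "f_p", "n_members", "members"])
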