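"""Delimited-text I/O for panels, matrices, networks, and rasters.

All on-disk formats are plain CSV/TSV: panels are timepoints x regions
with a header row of region labels; matrices and networks are square
with labels on both axes; rasters are steps x regions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, SignedBinaryNetwork, TimeSeriesPanel
from .dynamics import ActivityRaster, SERParams

__all__ = [
    "read_panel", "write_panel",
    "read_connectivity", "write_connectivity",
    "read_network", "write_network",
    "read_raster", "write_raster",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_panel(path: str | Path, subject_id: str | None = None) -> TimeSeriesPanel:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return TimeSeriesPanel(
        df.to_numpy(dtype=float),
        [str(c) for c in df.columns],
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(panel.values, columns=panel.region_labels).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError(f"{path}: row and column labels differ")
    return ConnectivityMatrix(df.to_numpy(dtype=float), labels)


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(conn.values, index=conn.region_labels,
                 columns=conn.region_labels).to_csv(path, sep=_sep_for(path))


def read_network(
    path: str | Path,
    positive_cost: float | None = None,
    negative_cost: float | None = None,
    scheme: str = "signed",
) -> SignedBinaryNetwork:
    """Read a ternary adjacency CSV; cost metadata defaults to the
    realized link fractions when not supplied."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    labels = [str(c) for c in df.columns]
    adj = df.to_numpy(dtype=int)
    n = adj.shape[0]
    p = n * (n - 1) // 2
    triu = adj[np.triu_indices(n, k=1)]
    if positive_cost is None:
        positive_cost = float((triu == 1).sum()) / p
    if negative_cost is None:
        negative_cost = float((triu == -1).sum()) / p
    return SignedBinaryNetwork(adj, positive_cost=positive_cost,
                               negative_cost=negative_cost, scheme=scheme,
                               region_labels=labels)


def write_network(network: SignedBinaryNetwork, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(network.adjacency, index=network.region_labels,
                 columns=network.region_labels).to_csv(path, sep=_sep_for(path))


def read_raster(path: str | Path, params: SERParams | None = None,
                seed: int = -1) -> ActivityRaster:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if params is None:
        params = SERParams(sop=0.0, nep=0.0, pi_p=0.0, pi_n=0.0)
    return ActivityRaster(df.to_numpy(dtype=np.int8), params=params, seed=seed)


def write_raster(raster: ActivityRaster, path: str | Path,
                 region_labels: list[str] | None = None) -> None:
    path = Path(path)
    if region_labels is None:
        region_labels = [f"r{i}" for i in range(raster.n_regions)]
    pd.DataFrame(raster.values, columns=region_labels).to_csv(
        path, sep=_sep_for(path), index=False
    )
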