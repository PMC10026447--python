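"""Plain-text readers/writers for networks, metrics and tables.

Network dialect (one directory per network):

* ``nodes.csv`` — ``id,x_um,y_um,z_um`` (z = cortical depth);
* ``segments.csv`` — ``id,node_a,node_b,r_v_um``;
* ``polylines.csv`` (optional) — ``segment_id,point_index,x_um,y_um,z_um``;
* ``meta.json`` (optional) — units, provenance, boundary pressures as
  ``{"bc_pressure": {node_id: Pa}}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import VascularNetwork
from .projection import AreaCorrectionTable, ProjectionConvention
from .tessellation import SheathMetrics

__all__ = [
    "write_network",
    "read_network",
    "metrics_to_frame",
    "correction_table_to_frame",
    "correction_table_from_frame",
]


def write_network(net: VascularNetwork, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(net.node_xyz, columns=["x_um", "y_um", "z_um"])
    nodes.insert(0, "id", np.arange(net.n_nodes))
    nodes.to_csv(d / "nodes.csv", index=False)
    segs = pd.DataFrame({
        "id": np.arange(net.n_segments),
        "node_a": net.segments[:, 0],
        "node_b": net.segments[:, 1],
        "r_v_um": net.r_v,
    })
    segs.to_csv(d / "segments.csv", index=False)
    if net.polylines is not None:
        rows = []
        for i, pl in enumerate(net.polylines):
            if pl is None:
                continue
            for j, (x, y, z) in enumerate(np.asarray(pl)):
                rows.append((i, j, x, y, z))
        pd.DataFrame(
            rows, columns=["segment_id", "point_index", "x_um", "y_um", "z_um"]
        ).to_csv(d / "polylines.csv", index=False)
    meta = dict(net.meta)
    meta.setdefault("units", "um")
    meta["bc_pressure"] = {str(k): v for k, v in net.bc_pressure.items()}
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def read_network(directory) -> VascularNetwork:
    d = Path(directory)
    nodes = pd.read_csv(d / "nodes.csv").sort_values("id")
    segs = pd.read_csv(d / "segments.csv").sort_values("id")
    meta = {}
    bc = {}
    meta_path = d / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("units", "um") != "um":
            raise ValueError(f"unsupported units {meta['units']!r}; expected 'um'")
        bc = {int(k): float(v) for k, v in meta.pop("bc_pressure", {}).items()}
    polylines = None
    pl_path = d / "polylines.csv"
    if pl_path.exists():
        pl_df = pd.read_csv(pl_path)
        polylines = [None] * len(segs)
        for sid, grp in pl_df.groupby("segment_id"):
            grp = grp.sort_values("point_index")
            polylines[int(sid)] = grp[["x_um", "y_um", "z_um"]].to_numpy()
    return VascularNetwork(
        node_xyz=nodes[["x_um", "y_um", "z_um"]].to_numpy(),
        segments=segs[["node_a", "node_b"]].to_numpy(),
        r_v=segs["r_v_um"].to_numpy(),
        polylines=polylines,
        bc_pressure=bc,
        meta=meta,
    )


def metrics_to_frame(metrics_list) -> pd.DataFrame:
    """Tidy per-realization table for one or more metric ensembles."""
    rows = []
    for m in metrics_list:
        assert isinstance(m, SheathMetrics)
        for i in range(m.n_realizations):
            rows.append({
                "realization": i,
                "r_o_um": m.r_o,
                "mean_area_um2": m.mean_area,
                "phi_g": m.phi_samples[i],
                "phi_perp": m.phi_perp_samples[i],
                "gaps_per_ring": m.gaps_samples[i],
                "n_cells": len(m.area_samples) // m.n_realizations,
                "seed": m.seed,
            })
    return pd.DataFrame(rows)


def correction_table_to_frame(table: AreaCorrectionTable) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(table.r_o):
        for j in range(table.A_true.shape[1]):
            rows.append({
                "r_o_um": r,
                "A_true_um2": table.A_true[i, j],
                "A_meas_um2": table.A_meas[i, j],
                "se_um2": table.se[i, j],
            })
    return pd.DataFrame(rows)


def correction_table_from_frame(
    df: pd.DataFrame, n_real: int = 0, convention: ProjectionConvention | None = None
) -> AreaCorrectionTable:
    radii = np.sort(df["r_o_um"].unique())
    na = len(df) // len(radii)
    A_true = np.empty((len(radii), na))
    A_meas = np.empty_like(A_true)
    se = np.empty_like(A_true)
    for i, r in enumerate(radii):
        sub = df[df["r_o_um"] == r].sort_values("A_true_um2")
        A_true[i] = sub["A_true_um2"].to_numpy()
        A_meas[i] = sub["A_meas_um2"].to_numpy()
        se[i] = sub["se_um2"].to_numpy()
    kwargs = {} if convention is None else {"convention": convention}
    return AreaCorrectionTable(r_o=radii, A_true=A_true, A_meas=A_meas, se=se,
                               n_real=n_real, **kwargs)
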