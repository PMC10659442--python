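"""Tabular file formats for snapshots, geometries, chains and summaries.

All formats are plain comma-separated text with headers:

* snapshots: ``cell_id,x`` (one row per particle; cells with zero particles
  appear only in the geometry table);
* geometries: ``cell_id,L,z``;
* chains: ``iter,chain,lam,mu``;
* HDPR polygon: ``lam,mu`` vertex list;
* det-I grids: long format ``row,col,det_I``.

Writers and readers round-trip bit-exactly on the decimal representations
written (full ``repr`` precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import HDPRegion, PosteriorChains
from .model import CellGeometry
from .simulate import Snapshot, SnapshotSet

__all__ = [
    "write_snapshot_set",
    "read_snapshot_set",
    "write_geometries",
    "read_geometries",
    "write_chains",
    "read_chains",
    "write_hdpr",
    "write_summary",
    "read_summary",
]

_FLOAT_FMT = "%.17g"


def write_geometries(path, geoms: dict[str, CellGeometry]) -> None:
    df = pd.DataFrame(
        {"cell_id": list(geoms), "L": [g.L for g in geoms.values()], "z": [g.z for g in geoms.values()]}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_geometries(path) -> dict[str, CellGeometry]:
    df = _read_csv(path, ["cell_id", "L", "z"])
    return {
        str(r.cell_id): CellGeometry(L=float(r.L), z=float(r.z)) for r in df.itertuples(index=False)
    }


def write_snapshot_set(positions_path, geometry_path, data: SnapshotSet) -> None:
    """Write the positions table and the per-cell geometry table."""
    rows = [(s.cell_id, x) for s in data for x in s.positions]
    df = pd.DataFrame(rows, columns=["cell_id", "x"])
    df.to_csv(positions_path, index=False, float_format=_FLOAT_FMT)
    write_geometries(geometry_path, {s.cell_id: s.geom for s in data})


def read_snapshot_set(positions_path, geometry_path) -> SnapshotSet:
    """Read a snapshot set; every geometry row yields a snapshot (possibly empty).

    Positions on or outside the absorbing boundary raise with the offending
    row numbers: the model puts zero intensity there, so such rows indicate a
    preprocessing error.
    """
    geoms = read_geometries(geometry_path)
    df = _read_csv(positions_path, ["cell_id", "x"])
    unknown = set(df.cell_id.astype(str)) - set(geoms)
    if unknown:
        raise ValueError(f"positions reference unknown cell ids: {sorted(unknown)}")
    snaps = []
    for cid, geom in geoms.items():
        x = df.loc[df.cell_id.astype(str) == cid, "x"].to_numpy(float)
        bad = np.nonzero((x <= 0) | (x >= geom.L))[0]
        if bad.size:
            rows = df.index[df.cell_id.astype(str) == cid][bad] + 2  # header + 1-based
            raise ValueError(
                f"cell {cid}: positions on/outside the boundary at file rows {list(rows)}"
            )
        snaps.append(Snapshot(cell_id=cid, geom=geom, positions=x))
    return SnapshotSet(snapshots=tuple(snaps))


def _read_csv(path, expected_cols) -> pd.DataFrame:
    # round_trip parsing: the default C float parser can be off by one ulp
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != expected_cols:
        raise ValueError(
            f"{path}: malformed header line 1: expected {expected_cols}, got {list(df.columns)}"
        )
    return df


def write_chains(path, chains: PosteriorChains) -> None:
    n_chains, n_kept = chains.lam_samples.shape
    df = pd.DataFrame(
        {
            "iter": np.tile(np.arange(n_kept), n_chains),
            "chain": np.repeat(np.arange(n_chains), n_kept),
            "lam": chains.lam_samples.ravel(),
            "mu": chains.mu_samples.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_chains(path) -> pd.DataFrame:
    return _read_csv(path, ["iter", "chain", "lam", "mu"])


def write_hdpr(path, region: HDPRegion) -> None:
    pd.DataFrame(region.vertices, columns=["lam", "mu"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_summary(path, summary: dict) -> None:
    """Structured key-value summary (JSON text)."""
    Path(path).write_text(json.dumps(summary, indent=2, default=float) + "\n")


def read_summary(path) -> dict:
    return json.loads(Path(path).read_text())
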