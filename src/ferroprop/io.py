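"""CSV / TIFF round-trip helpers for the pipeline's tables and stacks.

Tables (CellTable, EventTable, LipidTable) are plain CSV with their
documented headers; contact graphs are two-column edge lists; frame stacks
are multi-page TIFF ordered (T, C, H, W) with a JSON sidecar carrying the
physical calibration.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .synthetic_data import FrameStack

__all__ = [
    "write_table",
    "read_table",
    "write_edge_list",
    "read_edge_list",
    "write_stack",
    "read_stack",
]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [{"source": u, "target": v} for u, v in graph.edges]
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, index=False)


def read_edge_list(path, nodes=None) -> nx.Graph:
    df = pd.read_csv(path)
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(df[["source", "target"]].itertuples(index=False, name=None))
    return g


def write_stack(stack: FrameStack, tiff_path, sidecar_path=None) -> None:
    """Multi-page TIFF (T, C, H, W) plus a JSON sidecar with pixel_size,
    frame times and channel names."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.data, photometric="minisblack",
                     metadata={"axes": "TCYX"})
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": stack.pixel_size,
                "frame_times_min": stack.frame_times.tolist(),
                "channels": list(stack.channels),
            },
            indent=2,
        )
    )


def read_stack(tiff_path, sidecar_path=None) -> FrameStack:
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path)
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    if data.ndim == 3:  # single frame collapsed by the writer
        data = data[None]
    return FrameStack(
        data=np.asarray(data),
        frame_times=np.asarray(meta["frame_times_min"], dtype=float),
        channels=tuple(meta["channels"]),
        pixel_size=float(meta["pixel_size_um"]),
    )
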