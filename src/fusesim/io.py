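"""File I/O: VTU field export/import, history CSV, manifest, report plots.

The VTU writer emits plain ASCII VTK XML unstructured grids (tetra cells,
cell data arrays such as region/phenotype/stimuli, point data such as the
cell density), readable by ParaView; the reader handles the same ASCII
subset for round-tripping.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .construct import LabeledMesh

HISTORY_COLUMNS = [
    "iteration",
    "week",
    "bone_volume_pct",
    "stiffness_N_per_mm",
    "resorption_zone_pct",
    "bridged",
]

VTK_TETRA = 10


def _fmt(a: np.ndarray) -> str:
    flat = np.asarray(a).ravel()
    if flat.dtype.kind in "iub":
        return " ".join(str(int(v)) for v in flat)
    return " ".join(repr(float(v)) for v in flat)


def export_vtu(
    mesh: LabeledMesh,
    path: str | Path,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh and attached fields as an ASCII .vtu file."""
    n, e = mesh.n_nodes, mesh.n_elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{e}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(mesh.node_coords),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt(mesh.tets),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt(4 * np.arange(1, e + 1)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _fmt(np.full(e, VTK_TETRA, dtype=np.uint8)),
        "</DataArray>",
        "</Cells>",
    ]
    cell_data = {"region": mesh.element_region, **(cell_data or {})}
    lines.append("<CellData>")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        dtype = "Int64" if arr.dtype.kind in "iub" else "Float64"
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        lines += [
            f'<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            _fmt(arr),
            "</DataArray>",
        ]
    lines.append("</CellData>")
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            dtype = "Int64" if arr.dtype.kind in "iub" else "Float64"
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            lines += [
                f'<DataArray type="{dtype}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">',
                _fmt(arr),
                "</DataArray>",
            ]
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def import_vtu(path: str | Path):
    """Read an ASCII .vtu written by export_vtu.

    Returns (mesh, cell_data, point_data); the mesh's element_region is
    taken from the "region" cell array.
    """
    root = ET.parse(str(path)).getroot()
    piece = root.find("./UnstructuredGrid/Piece")

    def parse(da):
        text = da.text.split()
        if da.get("type") in ("Int64", "Int32", "UInt8"):
            arr = np.array([int(v) for v in text], dtype=np.int64)
        else:
            arr = np.array([float(v) for v in text])
        ncomp = int(da.get("NumberOfComponents", "1"))
        return arr.reshape(-1, ncomp) if ncomp > 1 else arr

    coords = parse(piece.find("./Points/DataArray"))
    cells = {da.get("Name"): parse(da) for da in piece.findall("./Cells/DataArray")}
    tets = cells["connectivity"].reshape(-1, 4)
    cell_data = {
        da.get("Name"): parse(da) for da in piece.findall("./CellData/DataArray")
    }
    point_data = {
        da.get("Name"): parse(da) for da in piece.findall("./PointData/DataArray")
    }
    region = cell_data.get("region", np.ones(len(tets), dtype=np.int64))
    mesh = LabeledMesh(coords, tets, region.astype(np.int32))
    return mesh, cell_data, point_data


# ---------------------------------------------------------------------------


def history_frame(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame.from_records(records)
    return df[HISTORY_COLUMNS]


def write_history(history, path: str | Path) -> None:
    """Fixed-column CSV, one row per weekly iteration."""
    df = history.to_frame() if hasattr(history, "to_frame") else history_frame(history)
    df.to_csv(path, index=False, float_format="%.10g")


def read_history(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def plot_report(history, path: str | Path) -> None:
    """Bone volume, biological stiffness, and resorption volume vs week."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = history.to_frame() if hasattr(history, "to_frame") else history
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    axes[0].plot(df["week"], df["bone_volume_pct"], "o-")
    axes[0].set_ylabel("bone volume in fusion region [%]")
    axes[1].plot(df["week"], df["stiffness_N_per_mm"], "s-", color="tab:green")
    axes[1].set_ylabel("stiffness without implants [N/mm]")
    axes[2].plot(df["week"], df["resorption_zone_pct"], "d-", color="tab:red")
    axes[2].set_ylabel("resorption-stimulus volume [%]")
    for ax in axes:
        ax.set_xlabel("week")
        ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
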