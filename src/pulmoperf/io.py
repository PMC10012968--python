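"""Plain-text file formats: network CSV tables, solution state CSVs,
legacy-ASCII VTK PolyData export, and the macro exchange record.

Network files are three CSV tables (0-based ids, SI units):

* ``nodes.csv`` - ``id,x,y,z``
* ``elements.csv`` - ``id,node_in,node_out,type,D0,order,generation``
* ``acini.csv`` - ``id,art_node,ven_node,art_elem,lung``

The exchange record is the hand-off payload of one macro half-step; it
round-trips through JSON bit-exactly (floats serialized with full
precision by the standard library).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TYPE_CODES, TYPE_NAMES, VesselNetwork


# -- network tables -------------------------------------------------------

def write_network(network: VesselNetwork, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame({
        "id": np.arange(network.n_nodes),
        "x": network.node_xyz[:, 0],
        "y": network.node_xyz[:, 1],
        "z": network.node_xyz[:, 2],
    })
    nodes.to_csv(d / "nodes.csv", index=False, float_format="%.17g")
    elems = pd.DataFrame({
        "id": np.arange(network.n_elements),
        "node_in": network.elem_node_in,
        "node_out": network.elem_node_out,
        "type": [TYPE_NAMES[t] for t in network.elem_type],
        "D0": network.elem_D0,
        "order": network.elem_order,
        "generation": network.elem_generation,
    })
    elems.to_csv(d / "elements.csv", index=False, float_format="%.17g")
    acini = pd.DataFrame({
        "id": np.arange(network.n_acini),
        "art_node": network.acinus_art_node,
        "ven_node": network.acinus_ven_node,
        "art_elem": network.acinus_art_elem,
        "lung": network.acinus_lung,
        "sa_weight": (network.acinus_sa_weight
                      if len(network.acinus_sa_weight)
                      else np.ones(network.n_acini)),
    })
    acini.to_csv(d / "acini.csv", index=False, float_format="%.17g")
    meta = {
        "inlet_node": int(network.inlet_node),
        "outlet_node": int(network.outlet_node),
        "interface_nodes": {k: int(v) for k, v in network.interface_nodes.items()},
        "macro_element_ids": [int(e) for e in network.macro_element_ids],
    }
    (d / "network_meta.json").write_text(json.dumps(meta, indent=1))


def read_network(directory) -> VesselNetwork:
    d = Path(directory)
    nodes = pd.read_csv(d / "nodes.csv")
    elems = pd.read_csv(d / "elements.csv")
    acini = pd.read_csv(d / "acini.csv")
    meta = json.loads((d / "network_meta.json").read_text())
    return VesselNetwork(
        node_xyz=nodes[["x", "y", "z"]].to_numpy(),
        elem_node_in=elems["node_in"].to_numpy(int),
        elem_node_out=elems["node_out"].to_numpy(int),
        elem_type=np.array([TYPE_CODES[t] for t in elems["type"]], int),
        elem_D0=elems["D0"].to_numpy(float),
        elem_order=elems["order"].to_numpy(int),
        elem_generation=elems["generation"].to_numpy(int),
        inlet_node=meta["inlet_node"],
        outlet_node=meta["outlet_node"],
        interface_nodes=meta["interface_nodes"],
        macro_element_ids=np.array(meta["macro_element_ids"], int),
        acinus_art_node=acini["art_node"].to_numpy(int) if len(acini) else np.array([], int),
        acinus_ven_node=acini["ven_node"].to_numpy(int) if len(acini) else np.array([], int),
        acinus_art_elem=acini["art_elem"].to_numpy(int) if len(acini) else np.array([], int),
        acinus_lung=acini["lung"].to_numpy("U8") if len(acini) else np.array([], "U8"),
        acinus_sa_weight=(acini["sa_weight"].to_numpy(float)
                          if "sa_weight" in acini and len(acini)
                          else np.ones(len(acini))),
    )


def write_state(state, network: VesselNetwork, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "node": np.arange(network.n_nodes),
        "pressure_Pa": state.node_pressure,
    }).to_csv(d / "node_pressure.csv", index=False, float_format="%.17g")
    pd.DataFrame({
        "element": np.arange(network.n_elements),
        "flow_m3s": state.elem_flow,
        "diameter_m": state.elem_diameter,
    }).to_csv(d / "element_state.csv", index=False, float_format="%.17g")
    pd.DataFrame({
        "acinus": np.arange(network.n_acini),
        "flow_m3s": state.acinar_flow,
        "height_m": state.acinar_height,
        "lung": network.acinus_lung,
    }).to_csv(d / "acinar_flow.csv", index=False, float_format="%.17g")


# -- exchange record ------------------------------------------------------

REQUIRED_EXCHANGE_FIELDS = ("iteration", "inlet_flow_m3s", "outlet",
                            "inlet_pressure_Pa")


class ExchangeFormatError(ValueError):
    pass


def write_exchange(record: dict, path) -> None:
    """Write one coupling half-step hand-off as JSON."""
    missing = [k for k in REQUIRED_EXCHANGE_FIELDS if k not in record]
    if missing:
        raise ExchangeFormatError(f"exchange record missing fields {missing}")
    Path(path).write_text(json.dumps(record, indent=1))


def read_exchange(path) -> dict:
    text = Path(path).read_text()
    try:
        record = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ExchangeFormatError(
            f"malformed exchange file {path}: line {exc.lineno}: {exc.msg}"
        ) from exc
    missing = [k for k in REQUIRED_EXCHANGE_FIELDS if k not in record]
    if missing:
        raise ExchangeFormatError(
            f"exchange file {path} missing fields {missing}")
    for o in record["outlet"]:
        for key in ("id", "pressure_Pa", "flow_m3s"):
            if key not in o:
                raise ExchangeFormatError(
                    f"exchange file {path}: outlet entry missing {key!r}")
    return record


def exchange_roundtrip(record: dict, path) -> dict:
    """Write then read an exchange record; the result is identical."""
    write_exchange(record, path)
    return read_exchange(path)


# -- VTK PolyData (legacy ASCII) ------------------------------------------

def export_vtk(network: VesselNetwork, path, state=None) -> None:
    """Export centerlines as legacy-ASCII VTK PolyData.

    Cell data: unstrained diameter, plus flow and strained diameter when a
    solution state is given; point data: nodal pressure when given.  The
    file loads in standard VTK viewers.
    """
    if state is not None and len(state.elem_flow) != network.n_elements:
        raise ValueError("state does not match network element count")
    p = Path(path)
    lines = ["# vtk DataFile Version 3.0", "pulmoperf vascular network",
             "ASCII", "DATASET POLYDATA",
             f"POINTS {network.n_nodes} double"]
    for xyz in network.node_xyz:
        lines.append(f"{float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}")
    ne = network.n_elements
    lines.append(f"LINES {ne} {3 * ne}")
    for a, b in zip(network.elem_node_in, network.elem_node_out):
        lines.append(f"2 {a} {b}")
    lines.append(f"CELL_DATA {ne}")
    lines.append("SCALARS diameter double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{float(d)!r}" for d in network.elem_D0)
    if state is not None:
        lines.append("SCALARS flow double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(q)!r}" for q in state.elem_flow)
        lines.append("SCALARS strained_diameter double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(d)!r}" for d in state.elem_diameter)
        lines.append(f"POINT_DATA {network.n_nodes}")
        lines.append("SCALARS pressure double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(v)!r}" for v in state.node_pressure)
    p.write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path) -> dict:
    """Minimal reader for the files written by :func:`export_vtk`.

    Returns ``{"points": (N,3), "lines": (E,2), "cell_data": {name: array},
    "point_data": {name: array}}``.
    """
    tokens = Path(path).read_text().splitlines()
    out = {"points": None, "lines": None, "cell_data": {}, "point_data": {}}
    i = 0
    section = None
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in tokens[i].split())
                i += 1
            out["points"] = np.array(vals).reshape(n, 3)
            continue
        if line.startswith("LINES"):
            n = int(line.split()[1])
            conn = []
            for j in range(n):
                parts = tokens[i + 1 + j].split()
                conn.append((int(parts[1]), int(parts[2])))
            out["lines"] = np.array(conn, int)
            i += n + 1
            continue
        if line.startswith("CELL_DATA"):
            section = "cell_data"
        elif line.startswith("POINT_DATA"):
            section = "point_data"
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            count = len(out["lines"]) if section == "cell_data" else len(out["points"])
            vals = []
            i += 2  # skip LOOKUP_TABLE
            while len(vals) < count:
                vals.extend(float(v) for v in tokens[i].split())
                i += 1
            out[section][name] = np.array(vals)
            continue
        i += 1
    return out
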