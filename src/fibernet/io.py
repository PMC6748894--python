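"""File formats: network JSON/INP/VTK, HDF5 results, CSV curves, TOML config.

The JSON network schema round-trips losslessly.  The Abaqus-flavoured INP
export writes NODE and ELEMENT (TYPE=B31) blocks plus NSETs for the six
boundary faces; the VTK export writes legacy polydata with one polyline per
fiber.  Simulation results persist to HDF5 under /stretch, /force, /pk1,
/segments/strain, /segments/stress, /nodes/displacement, /pivot.
"""

from __future__ import annotations

import json

import numpy as np

from .network import BoxDomain, FiberNetwork, FiberPath

__all__ = [
    "network_to_json",
    "network_from_json",
    "save_network",
    "load_network",
    "export_network",
    "write_inp",
    "write_vtk",
    "save_result",
    "load_result_curve",
    "read_curve_csv",
    "write_curve_csv",
    "load_config",
]

_FACE_TOL = 1e-6


# --------------------------------------------------------------------------
# network JSON
# --------------------------------------------------------------------------


def network_to_json(net: FiberNetwork) -> dict:
    return {
        "schema": "fibernet/network/1",
        "box": {"Lx": net.box.Lx, "Ly": net.box.Ly, "Lz": net.box.Lz,
                "axis": net.box.axis},
        "r_phys": net.r_phys,
        "seed": net.seed,
        "nodes": net.nodes.tolist(),
        "segments": net.segments.tolist(),
        "fiber_id": net.fiber_id.tolist(),
        "fibers": [
            {
                "vertices": f.vertices.tolist(),
                "theta": f.theta,
                "waviness": f.waviness,
                "seg_length": f.seg_length,
            }
            for f in net.fibers
        ],
    }


def network_from_json(doc: dict) -> FiberNetwork:
    if doc.get("schema") != "fibernet/network/1":
        raise ValueError("unrecognized network schema")
    box = BoxDomain(**doc["box"])
    fibers = [
        FiberPath(
            vertices=np.asarray(f["vertices"], dtype=float),
            theta=float(f["theta"]),
            waviness=float(f["waviness"]),
            seg_length=float(f["seg_length"]),
        )
        for f in doc["fibers"]
    ]
    return FiberNetwork(
        nodes=np.asarray(doc["nodes"], dtype=float),
        segments=np.asarray(doc["segments"], dtype=np.int64),
        fiber_id=np.asarray(doc["fiber_id"], dtype=np.int64),
        fibers=fibers,
        r_phys=float(doc["r_phys"]),
        box=box,
        seed=int(doc["seed"]),
    )


def save_network(net: FiberNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_json(net), fh)


def load_network(path) -> FiberNetwork:
    with open(path) as fh:
        return network_from_json(json.load(fh))


# --------------------------------------------------------------------------
# INP / VTK exports
# --------------------------------------------------------------------------


def _face_sets(net: FiberNetwork) -> dict:
    X = net.nodes
    b = net.box
    return {
        "X0": np.where(np.abs(X[:, 0]) < _FACE_TOL)[0],
        "X1": np.where(np.abs(X[:, 0] - b.Lx) < _FACE_TOL)[0],
        "Y0": np.where(np.abs(X[:, 1]) < _FACE_TOL)[0],
        "Y1": np.where(np.abs(X[:, 1] - b.Ly) < _FACE_TOL)[0],
        "Z0": np.where(np.abs(X[:, 2]) < _FACE_TOL)[0],
        "Z1": np.where(np.abs(X[:, 2] - b.Lz) < _FACE_TOL)[0],
    }


def write_inp(net: FiberNetwork, path) -> None:
    """Abaqus-flavoured input deck: nodes, B31 beam elements, face NSETs."""
    lines = ["*HEADING", "fiber network export", "*NODE"]
    for i, (x, y, z) in enumerate(net.nodes, start=1):
        lines.append(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}")
    lines.append("*ELEMENT, TYPE=B31, ELSET=FIBERS")
    for e, (a, b) in enumerate(net.segments, start=1):
        lines.append(f"{e}, {a + 1}, {b + 1}")
    for name, idx in _face_sets(net).items():
        lines.append(f"*NSET, NSET=FACE_{name}")
        ids = [str(i + 1) for i in idx]
        for k in range(0, len(ids), 8):
            lines.append(", ".join(ids[k : k + 8]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_vtk(net: FiberNetwork, path) -> None:
    """Legacy VTK polydata: one polyline per fiber."""
    lines = [
        "# vtk DataFile Version 3.0",
        "fiber network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(net.nodes)} double",
    ]
    for x, y, z in net.nodes:
        lines.append(f"{x:.9g} {y:.9g} {z:.9g}")
    polys = [net.fiber_node_indices(f) for f in range(net.n_fibers)]
    total = sum(len(p) + 1 for p in polys)
    lines.append(f"LINES {len(polys)} {total}")
    for p in polys:
        lines.append(" ".join([str(len(p))] + [str(int(i)) for i in p]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_network(net: FiberNetwork, path, fmt: str) -> None:
    if fmt == "json":
        save_network(net, path)
    elif fmt == "inp":
        write_inp(net, path)
    elif fmt == "vtk":
        write_vtk(net, path)
    else:
        raise ValueError(f"unknown format '{fmt}' (expected json, inp or vtk)")


# --------------------------------------------------------------------------
# results HDF5
# --------------------------------------------------------------------------


def save_result(result, path, include_network: bool = True) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("stretch", data=result.stretch)
        h5.create_dataset("force", data=result.force)
        h5.create_dataset("pk1", data=result.pk1)
        h5.create_dataset("pivot", data=result.pivot)
        seg = h5.create_group("segments")
        seg.create_dataset("strain", data=result.seg_strain)
        seg.create_dataset("stress", data=result.seg_stress)
        nodes = h5.create_group("nodes")
        nodes.create_dataset("displacement", data=result.displacements)
        h5.attrs["metadata"] = json.dumps(
            {k: v for k, v in result.metadata.items()
             if isinstance(v, (int, float, str, bool))}
        )
        if include_network:
            h5.attrs["network"] = json.dumps(network_to_json(result.network))


def load_result(path):
    """Load a saved simulation result back into a SimulationResult."""
    import h5py

    from .mechanics import SimulationResult

    with h5py.File(path, "r") as h5:
        metadata = json.loads(h5.attrs["metadata"])
        net = None
        if "network" in h5.attrs:
            net = network_from_json(json.loads(h5.attrs["network"]))
        return SimulationResult(
            stretch=h5["stretch"][...],
            force=h5["force"][...],
            pk1=h5["pk1"][...],
            displacements=h5["nodes/displacement"][...],
            seg_strain=h5["segments/strain"][...],
            seg_stress=h5["segments/stress"][...],
            pivot=h5["pivot"][...],
            network=net,
            metadata=metadata,
        )


def load_result_curve(path):
    import h5py

    from .mechanics import StressStretchCurve

    with h5py.File(path, "r") as h5:
        return StressStretchCurve(h5["stretch"][...], h5["pk1"][...])


# --------------------------------------------------------------------------
# CSV curves and TOML config
# --------------------------------------------------------------------------


def read_curve_csv(path):
    from .mechanics import StressStretchCurve

    data = np.loadtxt(path, delimiter=",", skiprows=_csv_header_rows(path))
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected a 2-column CSV (stretch, stress)")
    return StressStretchCurve(data[:, 0], data[:, 1])


def _csv_header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        [float(tok) for tok in first.strip().split(",")[:2]]
        return 0
    except ValueError:
        return 1


def write_curve_csv(curve, path, header: str = "stretch,pk1_stress_MPa") -> None:
    np.savetxt(
        path,
        np.column_stack([curve.stretch, curve.stress]),
        delimiter=",",
        header=header,
        comments="",
    )


def load_config(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
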