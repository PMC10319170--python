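"""Gating-ML 2.0 export/import of gate geometries.

Covers the subset this package produces: rectangle gates, polygon gates
and 1-D thresholds (serialized as single-dimension rectangle gates with
only a ``min`` or ``max`` bound, the Gating-ML idiom for thresholds).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .gating import Gate

__all__ = ["gates_to_gatingml", "gatingml_to_gates"]

GATING_NS = "http://www.isac-net.org/std/Gating-ML/v2.0/gating"
DTYPE_NS = "http://www.isac-net.org/std/Gating-ML/v2.0/datatypes"

ET.register_namespace("gating", GATING_NS)
ET.register_namespace("data-type", DTYPE_NS)


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def _dimension(parent: ET.Element, channel: str, lo: float | None, hi: float | None) -> None:
    dim = ET.SubElement(parent, _q(GATING_NS, "dimension"))
    if lo is not None and np.isfinite(lo):
        dim.set(_q(GATING_NS, "min"), repr(float(lo)))
    if hi is not None and np.isfinite(hi):
        dim.set(_q(GATING_NS, "max"), repr(float(hi)))
    fcs = ET.SubElement(dim, _q(DTYPE_NS, "fcs-dimension"))
    fcs.set(_q(DTYPE_NS, "name"), channel)


def gates_to_gatingml(gates: dict[str, Gate], path: str | Path | None = None) -> str:
    """Serialize named gates to a Gating-ML 2.0 document (returned as text)."""
    root = ET.Element(_q(GATING_NS, "Gating-ML"))
    for gate_id, gate in gates.items():
        if gate.kind == "threshold1d":
            cutoff, side = gate.geometry
            el = ET.SubElement(root, _q(GATING_NS, "RectangleGate"))
            el.set(_q(GATING_NS, "id"), gate_id)
            lo, hi = (cutoff, None) if side == "above" else (None, cutoff)
            _dimension(el, gate.axes[0], lo, hi)
        elif gate.kind == "rectangle":
            el = ET.SubElement(root, _q(GATING_NS, "RectangleGate"))
            el.set(_q(GATING_NS, "id"), gate_id)
            for ax in gate.axes:
                lo, hi = dict(gate.geometry)[ax]
                _dimension(el, ax, lo, hi)
        elif gate.kind == "polygon":
            el = ET.SubElement(root, _q(GATING_NS, "PolygonGate"))
            el.set(_q(GATING_NS, "id"), gate_id)
            for ax in gate.axes:
                _dimension(el, ax, None, None)
            for x, y in np.asarray(gate.geometry):
                v = ET.SubElement(el, _q(GATING_NS, "vertex"))
                for val in (x, y):
                    c = ET.SubElement(v, _q(GATING_NS, "coordinate"))
                    c.set(_q(DTYPE_NS, "value"), repr(float(val)))
        else:  # pragma: no cover - Gate validates kinds
            raise ValueError(f"cannot serialize gate kind {gate.kind!r}")
    text = ET.tostring(root, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def gatingml_to_gates(source: str | Path) -> dict[str, Gate]:
    """Parse a Gating-ML 2.0 document back into :class:`Gate` objects."""
    text = source if isinstance(source, str) and source.lstrip().startswith("<") else Path(source).read_text()
    root = ET.fromstring(text)
    gates: dict[str, Gate] = {}
    for el in root.findall(_q(GATING_NS, "RectangleGate")):
        gate_id = el.get(_q(GATING_NS, "id"), f"gate{len(gates)}")
        axes, bounds = [], []
        for dim in el.findall(_q(GATING_NS, "dimension")):
            fcs = dim.find(_q(DTYPE_NS, "fcs-dimension"))
            axes.append(fcs.get(_q(DTYPE_NS, "name")))
            lo = dim.get(_q(GATING_NS, "min"))
            hi = dim.get(_q(GATING_NS, "max"))
            bounds.append((None if lo is None else float(lo), None if hi is None else float(hi)))
        if len(axes) == 1 and (bounds[0][0] is None) != (bounds[0][1] is None):
            lo, hi = bounds[0]
            geometry = (lo, "above") if hi is None else (hi, "below")
            gates[gate_id] = Gate("threshold1d", (axes[0],), geometry)
        else:
            geometry = {
                ax: (-np.inf if lo is None else lo, np.inf if hi is None else hi)
                for ax, (lo, hi) in zip(axes, bounds)
            }
            gates[gate_id] = Gate("rectangle", tuple(axes), geometry)
    for el in root.findall(_q(GATING_NS, "PolygonGate")):
        gate_id = el.get(_q(GATING_NS, "id"), f"gate{len(gates)}")
        axes = [
            dim.find(_q(DTYPE_NS, "fcs-dimension")).get(_q(DTYPE_NS, "name"))
            for dim in el.findall(_q(GATING_NS, "dimension"))
        ]
        verts = [
            [float(c.get(_q(DTYPE_NS, "value"))) for c in v.findall(_q(GATING_NS, "coordinate"))]
            for v in el.findall(_q(GATING_NS, "vertex"))
        ]
        gates[gate_id] = Gate("polygon", tuple(axes), np.array(verts))
    return gates
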