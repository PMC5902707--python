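"""Network description files: a YAML schema for the range table.

A description names a set of minicolumn specs and a list of address ranges;
each range references a spec and carries its post-connection targets and
pre-connection rules.  Example::

    specs:
      default:
        type_counts: [32, 8, 16, 4, 32, 8, 0, 0]
        types:
          - {tau_epsc: 5.8, tau_ipsc: 5.8, tau_mem: 5.8, tau_rfc: 3.0,
             g_syn: 1.0, g_psc: 1.0}
          # fewer than 8 entries: the last one is repeated
    ranges:
      - threshold: 0
        spec: default
        post:
          - {offset: 0, delay_ms: 1, conn_id: 0}
        pre:
          - conn_id: 0
            conn_size: 8
            offset: 0
            dest_hc_size: 100
            weights: [3, -8, 3, -8, 3, -8, 0, 0]
            mask_pairs: [[0, 2], [1, 2]]   # [dest_type, src_type]

Validation errors name the offending range/field.
"""

from __future__ import annotations

import numpy as np
import yaml

from .lut import (
    ParameterLut,
    PostConnection,
    PostTarget,
    PreConnection,
    RangeEntry,
    TypeMask,
)
from .minicolumn import MinicolumnSpec, N_TYPES
from .neuron import NeuronTypeParams

__all__ = ["load_network", "parse_network", "network_to_dict"]


class NetworkFormatError(ValueError):
    pass


def _parse_type(d: dict, where: str) -> NeuronTypeParams:
    try:
        return NeuronTypeParams.from_time_constants(
            tau_epsc=float(d["tau_epsc"]),
            tau_ipsc=float(d["tau_ipsc"]),
            tau_mem=float(d["tau_mem"]),
            tau_rfc=float(d["tau_rfc"]),
            g_syn=float(d.get("g_syn", 1.0)),
            g_psc=float(d.get("g_psc", 1.0)),
            u_reset=int(d.get("u_reset", -8)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkFormatError(f"{where}: bad neuron type: {exc}") from None


def _parse_spec(name: str, d: dict) -> MinicolumnSpec:
    where = f"spec '{name}'"
    try:
        counts = tuple(int(c) for c in d["type_counts"])
    except (KeyError, TypeError, ValueError):
        raise NetworkFormatError(f"{where}: missing/bad type_counts") from None
    types = d.get("types", [])
    if not types:
        raise NetworkFormatError(f"{where}: at least one neuron type required")
    params = [_parse_type(t, where) for t in types]
    while len(params) < N_TYPES:
        params.append(params[-1])
    try:
        return MinicolumnSpec(counts, tuple(params[:N_TYPES]))
    except ValueError as exc:
        raise NetworkFormatError(f"{where}: {exc}") from None


def _parse_mask(d: dict, where: str) -> TypeMask:
    if "mask_pairs" in d:
        try:
            return TypeMask.from_pairs([(int(a), int(b)) for a, b in d["mask_pairs"]])
        except (TypeError, ValueError, IndexError):
            raise NetworkFormatError(f"{where}: bad mask_pairs") from None
    if "mask" in d:
        try:
            return TypeMask(np.asarray(d["mask"]))
        except ValueError as exc:
            raise NetworkFormatError(f"{where}: {exc}") from None
    raise NetworkFormatError(f"{where}: pre-connection needs mask or mask_pairs")


def parse_network(doc: dict) -> ParameterLut:
    if not isinstance(doc, dict) or "ranges" not in doc:
        raise NetworkFormatError("document must be a mapping with a 'ranges' list")
    specs = {
        name: _parse_spec(name, sd) for name, sd in (doc.get("specs") or {}).items()
    }
    lut = ParameterLut()
    for i, rd in enumerate(doc["ranges"]):
        where = f"range #{i}"
        try:
            threshold = int(rd["threshold"])
            spec = specs[rd["spec"]]
        except KeyError as exc:
            raise NetworkFormatError(f"{where}: missing {exc}") from None
        pre = {}
        for pd in rd.get("pre", []):
            pwhere = f"{where}, pre conn_id {pd.get('conn_id')}"
            try:
                pc = PreConnection(
                    conn_size=int(pd["conn_size"]),
                    offset=int(pd["offset"]),
                    weights=np.asarray(pd["weights"], dtype=np.int8),
                    dest_hc_size=int(pd["dest_hc_size"]),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise NetworkFormatError(f"{pwhere}: {exc}") from None
            pre[int(pd["conn_id"])] = (pc, _parse_mask(pd, pwhere))
        try:
            post = PostConnection(
                tuple(
                    PostTarget(
                        hc_offset=int(td["offset"]),
                        delay_ms=int(td["delay_ms"]),
                        conn_id=int(td["conn_id"]),
                    )
                    for td in rd.get("post", [])
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise NetworkFormatError(f"{where}: bad post target: {exc}") from None
        for tgt in post.targets:
            if tgt.conn_id not in pre:
                raise NetworkFormatError(
                    f"{where}: post target conn_id {tgt.conn_id} has no pre rule"
                )
        try:
            lut.add_range(threshold, RangeEntry(spec=spec, post=post, pre=pre))
        except ValueError as exc:
            raise NetworkFormatError(f"{where}: {exc}") from None
    return lut


def load_network(path) -> ParameterLut:
    """Load and validate a YAML network description."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise NetworkFormatError(f"{path}: {exc}") from None
    return parse_network(doc)


def network_to_dict(lut: ParameterLut) -> dict:
    """Inverse of :func:`parse_network` (spec names are synthesized)."""
    spec_names: dict[int, str] = {}
    specs_out: dict[str, dict] = {}
    ranges_out = []
    for threshold, entry in zip(lut.thresholds, lut.entries):
        key = id(entry.spec)
        if key not in spec_names:
            name = f"spec{len(spec_names)}"
            spec_names[key] = name
            specs_out[name] = {
                "type_counts": list(entry.spec.type_counts),
                "types": [
                    {
                        "tau_epsc": p.L_epsc / (256 - p.L_epsc),
                        "tau_ipsc": p.L_ipsc / (256 - p.L_ipsc),
                        "tau_mem": p.L_mem / (256 - p.L_mem),
                        "tau_rfc": p.L_rfc / (256 - p.L_rfc),
                        "g_syn": (p.g_syn_code + 1) / 16.0,
                        "g_psc": (p.g_psc_code + 1) / 16.0,
                        "u_reset": p.u_reset,
                    }
                    for p in entry.spec.params
                ],
            }
        ranges_out.append(
            {
                "threshold": int(threshold),
                "spec": spec_names[key],
                "post": [
                    {"offset": t.hc_offset, "delay_ms": t.delay_ms, "conn_id": t.conn_id}
                    for t in entry.post.targets
                ],
                "pre": [
                    {
                        "conn_id": cid,
                        "conn_size": pc.conn_size,
                        "offset": pc.offset,
                        "dest_hc_size": pc.dest_hc_size,
                        "weights": [int(w) for w in pc.weights],
                        "mask": mask.mask.tolist(),
                    }
                    for cid, (pc, mask) in sorted(entry.pre.items())
                ],
            }
        )
    return {"specs": specs_out, "ranges": ranges_out}
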