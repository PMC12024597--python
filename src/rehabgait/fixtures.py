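"""Readers, writers, and packaged fixtures for every file dialect the
toolkit touches.

Packaged fixtures (builtin names):

* ``"hip_P1"``, ``"knee_P2"``, ``"ankle_P3"`` — the published conditional
  probability tables of the three joint-level rehabilitation-goal nodes,
  transcribed verbatim (2-decimal probabilities).
* ``"rom"`` — physiological and normal-gait ranges of motion for hip, knee,
  and ankle per anatomical plane (degrees).
* ``"table7"`` — CAD-verified pose/push-rod-length triples used as
  calibration rows for the parallel-mechanism lumped offsets.

File dialects are comma-separated UTF-8 with ``.`` decimals and a
``# rehabgait-<kind> v1`` schema-version header; metadata lines are
``# key=value``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, FixtureError, ParseError
from .network import (
    ConditionalTable,
    Evidence,
    NetworkModel,
    NodeSpec,
    Posterior,
)

__all__ = [
    "load_cpt_table",
    "write_cpt_table",
    "load_rom_table",
    "load_calibration_rows",
    "load_evidence",
    "write_posterior",
    "load_model",
    "write_model",
    "builtin_path",
    "BUILTIN_FIXTURES",
]

BUILTIN_FIXTURES = {
    "hip_P1": "hip_P1.csv",
    "knee_P2": "knee_P2.csv",
    "ankle_P3": "ankle_P3.csv",
    "rom": "rom_table.csv",
    "table7": "table7_calibration.csv",
}


def builtin_path(name: str) -> Path:
    if name not in BUILTIN_FIXTURES:
        raise FixtureError(
            f"unknown builtin fixture {name!r}; available: "
            f"{sorted(BUILTIN_FIXTURES)}")
    return Path(str(resources.files("rehabgait.data")
                    .joinpath(BUILTIN_FIXTURES[name])))


def _resolve(source) -> Path:
    p = Path(source)
    if p.exists():
        return p
    if str(source) in BUILTIN_FIXTURES:
        return builtin_path(str(source))
    raise FixtureError(f"no such file or builtin fixture: {source!r}")


def _read_tagged_csv(path: Path, kind: str):
    """Split a fixture file into (metadata dict, header, rows-with-linenos)."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith(f"# rehabgait-{kind}"):
        raise ParseError(
            f"{path}: missing '# rehabgait-{kind}' schema header", line=1)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        cells = [c.strip() for c in line.split(",")]
        if header is None:
            header = cells
        else:
            rows.append((lineno, cells))
    if header is None:
        raise ParseError(f"{path}: no header line")
    return meta, header, rows


def load_cpt_table(source) -> ConditionalTable:
    """Load a conditional probability table from a path or builtin name.

    Raises :class:`ParseError` (with the line number) for malformed rows,
    duplicate parent tuples, or probabilities outside [0, 1].
    """
    path = _resolve(source)
    meta, header, rows = _read_tagged_csv(path, "cpt")
    child = meta.get("child")
    if not child:
        raise ParseError(f"{path}: missing '# child=' metadata")
    parents = tuple(p for p in meta.get("parents", "").split(",") if p)
    child_states = tuple(s for s in meta.get("child_states", "").split(",")
                         if s)
    rule = meta.get("completion_rule", "none")
    npar, nst = len(parents), len(child_states)
    if header != list(parents) + list(child_states):
        raise ParseError(f"{path}: header does not match declared parents "
                         "and child states")
    table_rows: dict[tuple[int, ...], tuple[float, ...]] = {}
    for lineno, cells in rows:
        if len(cells) != npar + nst:
            raise ParseError(
                f"{path}: expected {npar + nst} columns, got {len(cells)}",
                line=lineno)
        try:
            cfg = tuple(int(c) for c in cells[:npar])
            probs = tuple(float(c) for c in cells[npar:])
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}", line=lineno) from None
        if any(s not in (0, 1) for s in cfg):
            raise ParseError(f"{path}: parent states must be 0/1",
                             line=lineno)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParseError(f"{path}: probability outside [0, 1]",
                             line=lineno)
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ParseError(
                f"{path}: row {cfg} sums to {sum(probs):.4f}, not 1",
                line=lineno)
        if cfg in table_rows:
            raise ParseError(f"{path}: duplicate parent tuple {cfg}",
                             line=lineno)
        table_rows[cfg] = probs
    if rule == "none" and len(table_rows) != 2 ** npar:
        raise ParseError(
            f"{path}: {len(table_rows)} rows but completion_rule 'none' "
            f"requires {2 ** npar}")
    return ConditionalTable(child, parents, table_rows, completion_rule=rule,
                            child_states=child_states or None)


def _fmt(x: float) -> str:
    """Shortest round-tripping decimal (writes 0.6 as '0.6', not '0.60')."""
    return repr(float(x))


def write_cpt_table(table: ConditionalTable, dest) -> None:
    """Write a table in the CPT dialect; load(write(t)) round-trips exactly."""
    issues = table.validate()
    if issues:
        raise FixtureError(f"refusing to write invalid table: {issues}")
    states = table.child_states or tuple(
        f"state{i}" for i in range(table.n_child_states))
    lines = [
        "# rehabgait-cpt v1",
        f"# child={table.child}",
        f"# parents={','.join(table.parent_order)}",
        f"# child_states={','.join(states)}",
        f"# completion_rule={table.completion_rule}",
        ",".join(table.parent_order) + "," + ",".join(states),
    ]
    for cfg in sorted(table.rows):
        probs = table.rows[cfg]
        lines.append(",".join([str(s) for s in cfg]
                              + [_fmt(p) for p in probs]))
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_rom_table(source="rom"):
    """Load a range-of-motion table (degrees) from a path or the builtin.

    Returns a :class:`rehabgait.gait.JointROMTable`.  Entries printed as not
    applicable (knee coronal plane) are kept with an explicit marker.  A gait
    range exceeding its physiological range is a validation error.
    """
    from .gait import JointROMTable, RomEntry  # deferred: gait imports errors

    path = _resolve(source)
    meta, header, rows = _read_tagged_csv(path, "rom")
    del meta
    expected = ["joint", "plane", "direction", "phys_min_deg", "phys_max_deg",
                "gait_min_deg", "gait_max_deg", "applicable"]
    if header != expected:
        raise ParseError(f"{path}: unexpected header {header}")
    entries = {}
    for lineno, cells in rows:
        if len(cells) != len(expected):
            raise ParseError(f"{path}: wrong column count", line=lineno)
        joint, plane, direction = cells[0], cells[1], cells[2]
        applicable = cells[7].lower() == "yes"
        key = (joint, plane, direction)
        if not applicable:
            entries[key] = RomEntry(joint, plane, direction, None, None,
                                    applicable=False)
            continue
        try:
            pmin, pmax, gmin, gmax = (float(c) for c in cells[3:7])
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}", line=lineno) from None
        if not (pmin <= gmin and gmax <= pmax):
            raise ParseError(
                f"{path}: gait range [{gmin}, {gmax}] exceeds physiological "
                f"range [{pmin}, {pmax}] for {key}", line=lineno)
        entries[key] = RomEntry(joint, plane, direction, (pmin, pmax),
                                (gmin, gmax), applicable=True)
    return JointROMTable(entries)


def load_calibration_rows(source="table7"):
    """Load pose + measured push-rod lengths (mm) for geometry calibration.

    Returns a list of :class:`rehabgait.kinematics.CalibrationRow`.
    """
    from .kinematics import CalibrationRow, Pose

    path = _resolve(source)
    meta, header, rows = _read_tagged_csv(path, "calibration")
    del meta
    if header != ["Px_mm", "Py_mm", "Pz_mm", "L1_mm", "L2_mm", "L3_mm"]:
        raise ParseError(f"{path}: unexpected header {header}")
    out = []
    for lineno, cells in rows:
        try:
            vals = [float(c) if c else None for c in cells]
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}", line=lineno) from None
        if len(vals) != 6 or any(v is None for v in vals[:3]):
            raise ParseError(f"{path}: row needs a full pose", line=lineno)
        out.append(CalibrationRow(Pose(vals[0], vals[1], vals[2]),
                                  vals[3], vals[4], vals[5]))
    return out


# ---------------------------------------------------------------------------
# Evidence / posterior / model files


def load_evidence(source) -> Evidence:
    """Evidence file: JSON object mapping node id -> state index."""
    data = json.loads(Path(source).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ParseError(f"{source}: evidence must be a JSON object")
    return Evidence({str(k): int(v) for k, v in data.items()})


def write_posterior(posterior: Posterior, dest, fmt: str = "json") -> None:
    """Write marginals as JSON or tidy CSV (node, state, probability)."""
    dest = Path(dest)
    if fmt == "json":
        payload = {
            "schema": "rehabgait-posterior v1",
            "evidence": posterior.evidence,
            "marginals": {n: [float(p) for p in v]
                          for n, v in posterior.marginals.items()},
        }
        dest.write_text(json.dumps(payload, indent=2) + "\n",
                        encoding="utf-8")
    elif fmt == "csv":
        lines = ["node,state,probability"]
        for n, vec in posterior.marginals.items():
            for i, p in enumerate(vec):
                lines.append(f"{n},{i},{_fmt(float(p))}")
        dest.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ConfigError(f"unknown posterior format {fmt!r}")


def write_model(model: NetworkModel, dest) -> None:
    """Serialize a model to YAML (tables inline, rows keyed by state tuple)."""
    doc = {
        "schema": "rehabgait-model v1",
        "nodes": [{"id": s.id, "label": s.label, "role": s.role,
                   "states": list(s.states)} for s in model.nodes.values()],
        "edges": [list(e) for e in model.edges],
        "priors": {r: [float(p) for p in v]
                   for r, v in model.priors.items()},
        "tables": {
            child: {
                "parents": list(t.parent_order),
                "completion_rule": t.completion_rule,
                "child_states": list(t.child_states or ()),
                "rows": {",".join(map(str, cfg)): [float(p) for p in probs]
                         for cfg, probs in sorted(t.rows.items())},
            }
            for child, t in model.tables.items()
        },
        "weights": {k: float(v) for k, v in model.weights.items()},
        "stage_priorities": {k: float(v)
                             for k, v in model.stage_priorities.items()},
    }
    Path(dest).write_text(yaml.safe_dump(doc, sort_keys=False),
                          encoding="utf-8")


def load_model(source) -> NetworkModel:
    """Load a model serialized by :func:`write_model` (YAML or JSON)."""
    text = Path(source).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "nodes" not in doc:
        raise ParseError(f"{source}: not a rehabgait model file")
    nodes = [NodeSpec(d["id"], d.get("label", d["id"]), d["role"],
                      tuple(d["states"])) for d in doc["nodes"]]
    tables = {}
    for child, t in doc.get("tables", {}).items():
        rows = {tuple(int(x) for x in key.split(",")): tuple(vec)
                for key, vec in t["rows"].items()}
        tables[child] = ConditionalTable(
            child, tuple(t["parents"]), rows,
            completion_rule=t.get("completion_rule", "none"),
            child_states=tuple(t.get("child_states") or ()) or None)
    priors = {r: np.asarray(v, dtype=float)
              for r, v in doc.get("priors", {}).items()}
    return NetworkModel(nodes, [tuple(e) for e in doc.get("edges", [])],
                        tables, priors, doc.get("weights"),
                        doc.get("stage_priorities"))
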