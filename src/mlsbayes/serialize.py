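"""JSON / CSV / JSON-lines / DOT serialization.

This domain has no standard interchange format, so the package defines
and versions its own small JSON schemas (``schema_version`` field).
Floats go through :mod:`json`, whose repr round-trips IEEE doubles
exactly, so every writer/reader pair is lossless to full precision.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np
import pandas as pd

from .dynamics import FitnessTable, TrajectoryRecord
from .environment import EnvironmentProcess, SynergySpec
from .errors import ConfigError
from .hierarchy import ENV_NODE, HierarchyStructure, MultilevelDistribution

SCHEMA_VERSION = 1


# -- hierarchy structure ---------------------------------------------------

def structure_to_dict(structure: HierarchyStructure) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "levels": [{"name": lv.name, "types": list(lv.types)}
                   for lv in structure.levels],
        "deleted_links": sorted([list(l) for l in structure.deleted_links]),
    }


def structure_from_dict(d: dict) -> HierarchyStructure:
    try:
        return HierarchyStructure.from_levels(
            [(lv["name"], tuple(lv["types"])) for lv in d["levels"]],
            [tuple(l) for l in d.get("deleted_links", [])])
    except (KeyError, TypeError, ValueError) as err:
        raise ConfigError(f"invalid structure JSON: {err}") from None


# -- distributions and fitness tables --------------------------------------

def distribution_to_dict(dist: MultilevelDistribution) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "structure": structure_to_dict(dist.structure),
        "values": dist.values.tolist(),
    }


def distribution_from_dict(d: dict) -> MultilevelDistribution:
    try:
        structure = structure_from_dict(d["structure"])
        values = np.array(d["values"], dtype=float)
    except (KeyError, TypeError, ValueError) as err:
        raise ConfigError(f"invalid distribution JSON: {err}") from None
    return MultilevelDistribution(structure, values)


def distribution_to_frame(dist: MultilevelDistribution) -> pd.DataFrame:
    """Long-format table: one column per level (type label) + abundance."""
    s = dist.structure
    rows = []
    for idx in np.ndindex(*s.shape):
        row = {lv.name: lv.types[i] for lv, i in zip(s.levels, idx)}
        row["abundance"] = float(dist.values[idx])
        rows.append(row)
    return pd.DataFrame(rows)


def fitness_table_to_dict(table: FitnessTable) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "structure": structure_to_dict(table.structure),
        "env_state": table.env_state,
        "values": table.values.tolist(),
    }


def fitness_table_from_dict(d: dict) -> FitnessTable:
    try:
        structure = structure_from_dict(d["structure"])
        return FitnessTable(structure, d["env_state"],
                            np.array(d["values"], dtype=float))
    except (KeyError, TypeError, ValueError) as err:
        raise ConfigError(f"invalid fitness-table JSON: {err}") from None


# -- environment process ---------------------------------------------------

def synergy_spec_to_dict(spec: SynergySpec) -> dict:
    return {
        "base": {e: dict(m) for e, m in spec.base.items()},
        "synergy": {e: dict(m) for e, m in spec.synergy.items()},
        "group_synergy": {
            e: [{"members": sorted(members), "s": s} for members, s in m.items()]
            for e, m in spec.group_synergy.items()
        },
    }


def synergy_spec_from_dict(d: dict) -> SynergySpec:
    return SynergySpec(
        base={e: dict(m) for e, m in d.get("base", {}).items()},
        synergy={e: dict(m) for e, m in d.get("synergy", {}).items()},
        group_synergy={
            e: {frozenset(entry["members"]): float(entry["s"]) for entry in entries}
            for e, entries in d.get("group_synergy", {}).items()
        },
    )


def environment_to_dict(env: EnvironmentProcess) -> dict:
    d: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "env_states": list(env.env_states),
        "kind": env.kind,
    }
    if env.kind == "iid":
        d["probabilities"] = list(env.probabilities)
    else:
        d["transition_matrix"] = [list(r) for r in env.transition_matrix]
    if env.synergy is not None:
        d["synergy_spec"] = synergy_spec_to_dict(env.synergy)
    if env.tables is not None:
        d["tables"] = {e: fitness_table_to_dict(t) for e, t in env.tables.items()}
    return d


def environment_from_dict(d: dict) -> EnvironmentProcess:
    try:
        tables = None
        if "tables" in d:
            tables = {e: fitness_table_from_dict(t) for e, t in d["tables"].items()}
        synergy = None
        if "synergy_spec" in d:
            synergy = synergy_spec_from_dict(d["synergy_spec"])
        return EnvironmentProcess(
            env_states=tuple(d["env_states"]),
            kind=d.get("kind", "iid"),
            probabilities=tuple(d["probabilities"]) if "probabilities" in d else None,
            transition_matrix=(tuple(tuple(r) for r in d["transition_matrix"])
                               if "transition_matrix" in d else None),
            tables=tables,
            synergy=synergy,
        )
    except (KeyError, TypeError, ValueError) as err:
        raise ConfigError(f"invalid environment JSON: {err}") from None


# -- trajectories ----------------------------------------------------------

def trajectory_to_jsonl(record: TrajectoryRecord,
                        include_snapshots: bool = False) -> str:
    """One step per line: t, env_state, avg_fitness, cum_log_evidence."""
    lines = []
    for step in record.steps:
        d: dict[str, Any] = {
            "t": step.t,
            "env_state": step.env_state,
            "avg_fitness": step.avg_fitness,
            "log_evidence_increment": step.log_evidence_increment,
            "cum_log_evidence": step.cum_log_evidence,
        }
        if include_snapshots and step.distribution is not None:
            d["distribution"] = step.distribution.tolist()
        lines.append(json.dumps(d, sort_keys=True))
    return "\n".join(lines) + ("\n" if lines else "")


# -- DOT export ------------------------------------------------------------

def structure_to_dot(structure: HierarchyStructure) -> str:
    """Belief-network rendering: nodes e + levels, edges = surviving links.

    Every level conditions everything below it (and the environment
    node) unless the corresponding link is deleted; the repeatedly
    observed environment node sits on a plate.
    """
    names = structure.names
    deleted = structure.deleted_links
    lines = ["digraph belief_network {", "  rankdir=TB;"]
    lines.append('  subgraph cluster_plate {')
    lines.append('    label="t = 1, 2, 3, ...";')
    lines.append(f'    "{ENV_NODE}" [shape=circle, style=filled];')
    lines.append("  }")
    for name in names:
        lines.append(f'  "{name}" [shape=circle];')
    for hi in range(len(names) - 1, -1, -1):
        for lo in range(hi):
            if (names[lo], names[hi]) not in deleted:
                lines.append(f'  "{names[hi]}" -> "{names[lo]}";')
        if (ENV_NODE, names[hi]) not in deleted:
            lines.append(f'  "{names[hi]}" -> "{ENV_NODE}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


# -- file helpers ----------------------------------------------------------

def write_json(path, obj: dict):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError) as err:
        raise ConfigError(f"cannot read JSON from {path}: {err}") from None
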