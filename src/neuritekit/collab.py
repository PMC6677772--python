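"""Deterministic multi-annotator collaboration engine.

A headless server-client model of collaborative neuron annotation: each
editing operation becomes a command, the server assigns a strictly
increasing sequence number and applies commands in that order, so the shared
reconstruction is a pure fold over the command log.  Replaying a session log
from the empty state reproduces the final annotation byte-for-byte,
regardless of client submission timing — only the server order matters.
Avatar (working-location) updates are ephemeral broadcasts and never enter
the persistent log.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import IO, Iterable

from .morphology import NeuronNode, NeuronTree, write_swc

__all__ = [
    "Command",
    "SessionState",
    "AvatarUpdate",
    "CommandError",
    "SequencingError",
    "LogIntegrityError",
    "connect",
    "submit",
    "apply_command",
    "replay",
    "export_swc",
    "write_log",
    "read_log",
    "PALETTE",
]

SCHEMA_VERSION = 1

# 32 visually distinct colors, assigned to annotators by join order.
PALETTE: tuple[str, ...] = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
    "#98df8a", "#ff9896", "#c5b0d5", "#c49c94", "#f7b6d2", "#c7c7c7",
    "#dbdb8d", "#9edae5", "#393b79", "#637939", "#8c6d31", "#843c39",
    "#7b4173", "#5254a3", "#8ca252", "#bd9e39", "#ad494a", "#a55194",
    "#6b6ecf", "#b5cf6b",
)

VALID_KINDS = (
    "add_segment", "delete_segment", "add_marker", "delete_marker",
    "set_node_attr",
)


class CommandError(ValueError):
    """Rejected command: unknown client, malformed payload, or conflict."""


class SequencingError(ValueError):
    """Command applied out of server order."""


class LogIntegrityError(ValueError):
    """Session log has a gap or duplicate sequence number."""


@dataclass(frozen=True)
class Command:
    seq: int
    client_id: str
    kind: str
    payload: dict
    wall_time: float = 0.0  # informational only; never affects the state

    def to_json(self) -> dict:
        return {
            "v": SCHEMA_VERSION,
            "seq": self.seq,
            "client_id": self.client_id,
            "kind": self.kind,
            "payload": self.payload,
            "wall_time": self.wall_time,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Command":
        return cls(
            seq=int(obj["seq"]),
            client_id=str(obj["client_id"]),
            kind=str(obj["kind"]),
            payload=dict(obj["payload"]),
            wall_time=float(obj.get("wall_time", 0.0)),
        )


@dataclass(frozen=True)
class AvatarUpdate:
    """Transient working-location broadcast; never persisted."""

    client_id: str
    position: tuple[float, float, float]


@dataclass
class SessionState:
    """Shared annotation state: a node forest plus markers, with attribution.

    ``nodes`` maps global node id -> record {type, x, y, z, radius, parent
    (global id or -1), client_id, labels}; markers map global marker id ->
    {x, y, z, client_id}.  Node ids are allocated server-side and never
    reused.
    """

    nodes: dict[int, dict] = field(default_factory=dict)
    markers: dict[int, dict] = field(default_factory=dict)
    clients: dict[str, dict] = field(default_factory=dict)  # id -> {username, color, active}
    next_global_node_id: int = 1
    next_marker_id: int = 1
    last_seq: int = 0


def connect(state: SessionState, username: str) -> tuple[SessionState, str, str]:
    """Register an annotator; returns (new state, client id, assigned color).

    Colors come from a fixed 32-entry palette in join order and are unique
    among active clients; reconnecting with the same username reuses the
    prior color.
    """
    if not username:
        raise CommandError("username must be nonempty")
    state = copy.deepcopy(state)
    for cid, rec in state.clients.items():
        if rec["username"] == username:
            rec["active"] = True
            return state, cid, rec["color"]
    used = {rec["color"] for rec in state.clients.values()}
    color = next((c for c in PALETTE if c not in used), None)
    if color is None:
        raise CommandError("color palette exhausted (max 32 annotators)")
    cid = f"c{len(state.clients) + 1}"
    state.clients[cid] = {"username": username, "color": color, "active": True}
    return state, cid, color


def _validate_payload(state: SessionState, kind: str, payload: dict) -> None:
    if kind == "add_segment":
        nodes = payload.get("nodes")
        if not isinstance(nodes, list) or not nodes:
            raise CommandError("add_segment requires a nonempty node list")
        local_ids = set()
        for rec in nodes:
            for key in ("local_id", "x", "y", "z", "radius", "local_parent"):
                if key not in rec:
                    raise CommandError(f"add_segment node missing field {key!r}")
            if rec["local_id"] in local_ids:
                raise CommandError(f"duplicate local id {rec['local_id']}")
            local_ids.add(rec["local_id"])
        for rec in nodes:
            lp = rec["local_parent"]
            if lp != -1 and lp not in local_ids and lp not in state.nodes:
                raise CommandError(f"add_segment parent {lp} unresolved")
    elif kind == "delete_segment":
        ids = payload.get("node_ids")
        if not isinstance(ids, list) or not ids:
            raise CommandError("delete_segment requires node_ids")
        missing = [i for i in ids if i not in state.nodes]
        if missing:
            raise CommandError(f"delete of nonexistent node ids {missing}")
    elif kind == "add_marker":
        for key in ("x", "y", "z"):
            if key not in payload:
                raise CommandError(f"add_marker missing field {key!r}")
    elif kind == "delete_marker":
        mid = payload.get("marker_id")
        if mid not in state.markers:
            raise CommandError(f"delete of nonexistent marker {mid}")
    elif kind == "set_node_attr":
        nid = payload.get("node_id")
        if nid not in state.nodes:
            raise CommandError(f"set_node_attr on nonexistent node {nid}")
        if not payload.get("attrs"):
            raise CommandError("set_node_attr requires attrs")
    else:
        raise CommandError(f"unknown command kind {kind!r}")


def apply_command(state: SessionState, cmd: Command) -> SessionState:
    """Pure, deterministic state transition; enforces server sequencing."""
    if cmd.seq != state.last_seq + 1:
        raise SequencingError(
            f"command seq {cmd.seq} applied after seq {state.last_seq}"
        )
    if cmd.client_id not in state.clients:
        raise CommandError(f"unknown client {cmd.client_id!r}")
    _validate_payload(state, cmd.kind, cmd.payload)
    state = copy.deepcopy(state)
    if cmd.kind == "add_segment":
        mapping: dict[int, int] = {}
        for rec in cmd.payload["nodes"]:
            mapping[rec["local_id"]] = state.next_global_node_id
            state.next_global_node_id += 1
        for rec in cmd.payload["nodes"]:
            lp = rec["local_parent"]
            parent = -1 if lp == -1 else mapping.get(lp, lp)
            state.nodes[mapping[rec["local_id"]]] = {
                "type": int(rec.get("type", 3)),
                "x": float(rec["x"]), "y": float(rec["y"]), "z": float(rec["z"]),
                "radius": float(rec["radius"]),
                "parent": int(parent),
                "client_id": cmd.client_id,
                "labels": dict(rec.get("labels", {})),
            }
    elif cmd.kind == "delete_segment":
        doomed = set(cmd.payload["node_ids"])
        for nid in doomed:
            del state.nodes[nid]
        for rec in state.nodes.values():  # orphaned children become roots
            if rec["parent"] in doomed:
                rec["parent"] = -1
    elif cmd.kind == "add_marker":
        state.markers[state.next_marker_id] = {
            "x": float(cmd.payload["x"]),
            "y": float(cmd.payload["y"]),
            "z": float(cmd.payload["z"]),
            "client_id": cmd.client_id,
        }
        state.next_marker_id += 1
    elif cmd.kind == "delete_marker":
        del state.markers[cmd.payload["marker_id"]]
    elif cmd.kind == "set_node_attr":
        attrs = {str(k): str(v) for k, v in cmd.payload["attrs"].items()}
        state.nodes[cmd.payload["node_id"]]["labels"].update(attrs)
    state.last_seq = cmd.seq
    return state


def submit(
    state: SessionState, client_id: str, kind: str, payload: dict,
    log: list[Command] | None = None, wall_time: float = 0.0,
) -> tuple[SessionState, Command]:
    """Validate, sequence, apply, and log one command.

    Invalid commands are rejected with :class:`CommandError` and do not
    consume a sequence number.  For ``add_segment`` the local-to-global node
    id mapping is recoverable from the state's id counter (ids are assigned
    in payload order starting at the pre-submit counter value).
    """
    if client_id not in state.clients:
        raise CommandError(f"unknown client {client_id!r}")
    _validate_payload(state, kind, payload)
    cmd = Command(
        seq=state.last_seq + 1, client_id=client_id, kind=kind,
        payload=payload, wall_time=wall_time,
    )
    new_state = apply_command(state, cmd)
    if log is not None:
        log.append(cmd)
    return new_state, cmd


def replay(log: Iterable[Command], clients: dict[str, dict] | None = None) -> SessionState:
    """Fold a seq-contiguous command log from the empty state.

    ``clients`` pre-registers the client table (as the live session's
    connect calls did); when omitted, clients are auto-registered with
    palette colors in order of first appearance.
    """
    cmds = sorted(log, key=lambda c: c.seq)
    seqs = [c.seq for c in cmds]
    if seqs != list(range(1, len(seqs) + 1)):
        dup = {s for s in seqs if seqs.count(s) > 1}
        raise LogIntegrityError(
            f"log is not seq-contiguous from 1 (seqs={seqs[:10]}..., duplicates={sorted(dup)})"
        )
    state = SessionState()
    if clients:
        state.clients = copy.deepcopy(clients)
    for cmd in cmds:
        if cmd.client_id not in state.clients:
            used = {rec["color"] for rec in state.clients.values()}
            color = next((c for c in PALETTE if c not in used), None)
            if color is None:
                raise CommandError("color palette exhausted (max 32 annotators)")
            state.clients[cmd.client_id] = {
                "username": cmd.client_id, "color": color, "active": True,
            }
        state = apply_command(state, cmd)
    return state


def export_swc(state: SessionState, include_labels: bool = True) -> str:
    """Export the shared annotation as extended SWC with attribution columns.

    Nodes are written in ascending global id; each carries an ``annotator``
    label (the originating client id) alongside any other labels, so the
    export is byte-identical across replays.
    """
    nodes = []
    for nid in sorted(state.nodes):
        rec = state.nodes[nid]
        labels = dict(sorted(rec["labels"].items()))
        labels["annotator"] = rec["client_id"]
        nodes.append(NeuronNode(
            id=nid, type_code=rec["type"],
            x=rec["x"], y=rec["y"], z=rec["z"], radius=rec["radius"],
            parent_id=rec["parent"] if rec["parent"] in state.nodes else -1,
            labels=labels,
        ))
    tree = NeuronTree(nodes, provenance="collaborative session export")
    return write_swc(tree, include_labels=include_labels)


def write_log(log: Iterable[Command], stream: IO[str]) -> None:
    """Persist a session log as JSONL (one command per line, schema versioned)."""
    for cmd in sorted(log, key=lambda c: c.seq):
        stream.write(json.dumps(cmd.to_json(), sort_keys=True) + "\n")


def read_log(stream: IO[str]) -> list[Command]:
    cmds = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise LogIntegrityError(f"line {lineno}: invalid JSON ({exc})") from None
        if obj.get("v", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise LogIntegrityError(f"line {lineno}: unsupported schema version")
        cmds.append(Command.from_json(obj))
    return cmds
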