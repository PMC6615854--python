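"""Versioned plain-text snapshot/trajectory serialization and config files.

The snapshot format is line-oriented and human-diffable; floats are written
with ``repr`` so a write → read round trip is bit-exact. Unknown keys in the
meta block are preserved opaquely.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mechanics import BoundElement, Filament, NetworkState
from .params import ChemistryParams, MechanicalParams
from .protocol import SimulationConfig

FORMAT_VERSION = 1
_MAGIC = "#bundlesim-snapshot"


class SnapshotFormatError(ValueError):
    pass


@dataclass
class SnapshotRecord:
    time: float
    state: NetworkState
    seed: int = 0
    config_hash: str = ""
    free: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _f(x: float) -> str:
    return repr(float(x))


def dump_snapshot(rec: SnapshotRecord) -> str:
    meta = {"version": FORMAT_VERSION, "time": rec.time, "seed": rec.seed,
            "config_hash": rec.config_hash,
            "box": [float(b) for b in rec.state.box],
            "free": rec.free, **rec.extra}
    lines = [f"{_MAGIC} v{FORMAT_VERSION}", "meta " + json.dumps(meta)]
    for f in rec.state.filaments:
        lines.append(f"filament {f.n_beads}")
        lines.append("monomers " + " ".join(str(int(m)) for m in f.monomers))
        for b in f.beads:
            lines.append(f"bead {_f(b[0])} {_f(b[1])} {_f(b[2])}")
    for e in rec.state.bound:
        heads = "-" if e.n_heads is None else str(e.n_heads)
        lines.append("element {} {} {} {} {} {} {} {} {}".format(
            e.species, e.a[0], e.a[1], _f(e.a[2]), e.b[0], e.b[1], _f(e.b[2]),
            _f(e.rest_length), heads))
    lines.append("endsnapshot")
    return "\n".join(lines) + "\n"


def _parse_snapshot(lines: list[str], lineno0: int) -> SnapshotRecord:
    def err(i, msg):
        raise SnapshotFormatError(f"line {lineno0 + i + 1}: {msg}")

    if not lines or not lines[0].startswith(_MAGIC):
        err(0, "missing snapshot magic header")
    ver = lines[0].split("v")[-1]
    if int(ver) != FORMAT_VERSION:
        raise SnapshotFormatError(
            f"format version mismatch: file v{ver}, reader v{FORMAT_VERSION}")
    if len(lines) < 2 or not lines[1].startswith("meta "):
        err(1, "missing meta block")
    meta = json.loads(lines[1][5:])
    known = {"version", "time", "seed", "config_hash", "box", "free"}
    extra = {k: v for k, v in meta.items() if k not in known}
    fils: list[Filament] = []
    bound: list[BoundElement] = []
    i = 2
    ended = False
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "filament":
            n = int(tok[1])
            if i + 1 >= len(lines) or not lines[i + 1].startswith("monomers"):
                err(i + 1, "filament block missing monomers line")
            monomers = np.array([int(x) for x in lines[i + 1].split()[1:]])
            beads = []
            for k in range(n):
                j = i + 2 + k
                if j >= len(lines) or not lines[j].startswith("bead "):
                    err(min(j, len(lines) - 1), "truncated filament bead block")
                beads.append([float(x) for x in lines[j].split()[1:4]])
            fils.append(Filament(np.array(beads), monomers))
            i += 2 + n
        elif tok[0] == "element":
            if len(tok) != 10:
                err(i, "malformed element line")
            heads = None if tok[9] == "-" else int(tok[9])
            bound.append(BoundElement(
                tok[1], (int(tok[2]), int(tok[3]), float(tok[4])),
                (int(tok[5]), int(tok[6]), float(tok[7])), float(tok[8]), heads))
            i += 1
        elif tok[0] == "endsnapshot":
            ended = True
            i += 1
            break
        else:
            err(i, f"unknown block {tok[0]!r}")
    if not ended:
        raise SnapshotFormatError(
            f"line {lineno0 + len(lines)}: truncated snapshot (no endsnapshot)")
    state = NetworkState(fils, bound, np.array(meta["box"]))
    return SnapshotRecord(float(meta["time"]), state, int(meta.get("seed", 0)),
                          meta.get("config_hash", ""), meta.get("free", {}), extra)


def write_snapshot(rec: SnapshotRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(dump_snapshot(rec))
    return path


def read_snapshot(path: str | Path) -> SnapshotRecord:
    recs = read_archive(path)
    if len(recs) != 1:
        raise SnapshotFormatError(f"{path}: expected exactly one snapshot")
    return recs[0]


def write_archive(records: list[SnapshotRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(dump_snapshot(rec))
    return path


def read_archive(path: str | Path) -> list[SnapshotRecord]:
    text = Path(path).read_text()
    lines = text.splitlines()
    records = []
    start = None
    for i, ln in enumerate(lines):
        if ln.startswith(_MAGIC):
            if start is not None:
                records.append(_parse_snapshot(lines[start:i], start))
            start = i
    if start is not None:
        records.append(_parse_snapshot(lines[start:], start))
    if not records:
        raise SnapshotFormatError(f"{path}: no snapshots found")
    return records


# ---------------------------------------------------------------------------
# configuration

_TOP_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)} - {"mech", "chem"}
_MECH_KEYS = {f.name for f in dataclasses.fields(MechanicalParams)}
_CHEM_KEYS = {f.name for f in dataclasses.fields(ChemistryParams)}


def config_hash(config: SimulationConfig) -> str:
    d = dataclasses.asdict(config)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def config_from_dict(data: dict) -> SimulationConfig:
    """Build and validate a config, reporting all violations at once."""
    errors = []
    kw = {}
    for key, val in data.items():
        if key == "mech":
            bad = set(val) - _MECH_KEYS
            if bad:
                errors.append(f"unknown mech keys: {sorted(bad)}")
            else:
                try:
                    kw["mech"] = MechanicalParams(**val)
                except ValueError as exc:
                    errors.append(f"mech: {exc}")
        elif key == "chem":
            bad = set(val) - _CHEM_KEYS
            if bad:
                errors.append(f"unknown chem keys: {sorted(bad)}")
            else:
                try:
                    val = dict(val)
                    for band in ("linker_band", "motor_band"):
                        if band in val:
                            val[band] = tuple(val[band])
                    kw["chem"] = ChemistryParams(**val)
                except ValueError as exc:
                    errors.append(f"chem: {exc}")
        elif key in _TOP_KEYS:
            if key == "box":
                val = tuple(val)
            kw[key] = val
        else:
            errors.append(f"unknown key: {key}")
    cfg = None
    if not errors:
        try:
            cfg = SimulationConfig(**kw)
        except (ValueError, TypeError) as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def trajectory_records(traj, config: SimulationConfig | None = None
                       ) -> list[SnapshotRecord]:
    cfg = config or traj.config
    h = config_hash(cfg)
    return [SnapshotRecord(t, s, cfg.seed, h, free)
            for t, s, free in zip(traj.times, traj.snapshots, traj.free_totals)]
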