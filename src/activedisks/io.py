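"""Snapshot persistence, configuration parsing, and observable tables.

Snapshots use an extended-XYZ dialect: line 1 is the particle count, line 2 a
flat key=value properties string (format version, time, box, full parameter
echo, seed, column schema), then one row per particle in schema order.
Floats are written with `repr` (shortest round-trip decimal), so
read(write(state)) reproduces every value bit-exactly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .model import Box, ParticleState, SimParams

__all__ = [
    "SnapshotError",
    "SnapshotTruncatedError",
    "SnapshotSchemaError",
    "SnapshotVersionError",
    "write_snapshot",
    "read_snapshot",
    "parse_config",
    "read_config",
    "params_from_config",
    "write_table",
    "file_sha256",
]

FORMAT_VERSION = "activedisks-xyz-1"
COLUMNS = "id:x:y:vx:vy:theta:omega"


class SnapshotError(Exception):
    """Base error for snapshot parsing."""


class SnapshotTruncatedError(SnapshotError):
    pass


class SnapshotSchemaError(SnapshotError):
    pass


class SnapshotVersionError(SnapshotError):
    pass


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return repr(float(x))  # shortest round-trip decimal
    return str(x)


def write_snapshot(
    path: str | Path,
    state: ParticleState,
    box: Box,
    params: SimParams,
) -> None:
    """Write one snapshot in the extended-XYZ dialect (bit-exact floats)."""
    path = Path(path)
    n = state.n
    props = {
        "format": FORMAT_VERSION,
        "time": float(state.t),
        "Lx": float(box.Lx),
        "Ly": float(box.Ly),
        **params.as_dict(),
        "columns": COLUMNS,
    }
    header = " ".join(f"{k}={_fmt(v)}" for k, v in props.items())
    with path.open("w") as fh:
        fh.write(f"{n}\n{header}\n")
        for i in range(n):
            row = (state.pos[i, 0], state.pos[i, 1], state.vel[i, 0],
                   state.vel[i, 1], state.theta[i], state.omega[i])
            fh.write(f"{i} " + " ".join(repr(float(x)) for x in row) + "\n")


def _parse_props(line: str, path: Path) -> dict:
    props = {}
    for tok in line.split():
        if "=" not in tok:
            raise SnapshotSchemaError(
                f"{path}:2: malformed property token {tok!r}"
            )
        k, v = tok.split("=", 1)
        props[k] = v
    return props


def read_snapshot(path: str | Path) -> tuple[ParticleState, Box, SimParams]:
    """Read a snapshot; raises distinct errors for truncation, schema and
    version mismatches, each naming the offending line."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise SnapshotTruncatedError(f"{path}:1: missing header lines")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise SnapshotSchemaError(
            f"{path}:1: first line must be the particle count"
        ) from exc
    props = _parse_props(lines[1], path)
    version = props.get("format")
    if version != FORMAT_VERSION:
        raise SnapshotVersionError(
            f"{path}:2: format version {version!r}, expected "
            f"{FORMAT_VERSION!r}"
        )
    if props.get("columns") != COLUMNS:
        raise SnapshotSchemaError(
            f"{path}:2: column schema {props.get('columns')!r}, expected "
            f"{COLUMNS!r} (no silent defaults)"
        )
    missing = [k for k in ("time", "Lx", "Ly", *SimParams.FIELD_NAMES)
               if k not in props]
    if missing:
        raise SnapshotSchemaError(
            f"{path}:2: missing header keys: {', '.join(missing)}"
        )
    body = lines[2:]
    if len(body) < n:
        raise SnapshotTruncatedError(
            f"{path}:{2 + len(body) + 1}: expected {n} particle rows, "
            f"found {len(body)}"
        )
    pos = np.empty((n, 2))
    vel = np.empty((n, 2))
    theta = np.empty(n)
    omega = np.empty(n)
    for i in range(n):
        toks = body[i].split()
        if len(toks) != 7:
            raise SnapshotSchemaError(
                f"{path}:{3 + i}: expected 7 columns, found {len(toks)}"
            )
        pos[i] = (float(toks[1]), float(toks[2]))
        vel[i] = (float(toks[3]), float(toks[4]))
        theta[i] = float(toks[5])
        omega[i] = float(toks[6])
    params = params_from_config(
        {k: props[k] for k in SimParams.FIELD_NAMES}
    )
    box = Box(Lx=float(props["Lx"]), Ly=float(props["Ly"]))
    state = ParticleState(
        t=float(props["time"]), pos=pos, vel=vel, theta=theta, omega=omega
    )
    return state, box, params


# ------------------------------------------------------------------ config

def parse_config(text: str) -> dict[str, str]:
    """Flat key=value configuration dialect ('#' comments, blank lines ok)."""
    out: dict[str, str] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {ln}: expected key=value, got {raw!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_config(path: str | Path) -> dict[str, str]:
    return parse_config(Path(path).read_text())


_INT_FIELDS = {"N", "seed"}


def params_from_config(
    cfg: dict, overrides: dict | None = None
) -> SimParams:
    """Build SimParams from a flat config, collecting *all* problems into a
    single error (missing keys, unparseable values, invariant violations)."""
    merged = dict(cfg)
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})
    problems = []
    values = {}
    for name in SimParams.FIELD_NAMES:
        if name not in merged:
            problems.append(f"missing parameter {name}")
            continue
        raw = merged[name]
        try:
            values[name] = (
                int(raw) if name in _INT_FIELDS else float(raw)
            )
        except (TypeError, ValueError):
            problems.append(f"cannot parse {name}={raw!r}")
    unknown = set(merged) - set(SimParams.FIELD_NAMES)
    if unknown:
        problems.append(f"unknown parameters: {', '.join(sorted(unknown))}")
    if not problems:
        try:
            return SimParams(**values)
        except ValueError as exc:
            problems.append(str(exc))
    raise ValueError("invalid configuration: " + "; ".join(problems))


# ------------------------------------------------------------------ tables

def write_table(
    path: str | Path,
    columns: dict[str, np.ndarray],
    params: SimParams | None = None,
    extra_header: dict | None = None,
) -> None:
    """RFC-4180-style CSV with '#' comment lines echoing parameters/seed."""
    path = Path(path)
    with path.open("w") as fh:
        if params is not None:
            echo = " ".join(
                f"{k}={_fmt(v)}" for k, v in params.as_dict().items()
            )
            fh.write(f"# params: {echo}\n")
        for k, v in (extra_header or {}).items():
            fh.write(f"# {k}: {v}\n")
        names = list(columns)
        fh.write(",".join(names) + "\n")
        rows = len(next(iter(columns.values())))
        for i in range(rows):
            fh.write(",".join(_fmt(columns[k][i]) for k in names) + "\n")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
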