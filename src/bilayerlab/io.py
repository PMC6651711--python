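"""Readers and writers for the formats the pipeline touches.

Structures (GRO, PDB) and binary trajectories (XTC, DCD) are read through
MDAnalysis; tabular series come in as Grace-dialect XVG or CSV.  A plain-text
multi-frame trajectory format is provided so synthetic fixtures stay
human-readable.  All coordinates are converted to nm at the boundary.
"""
from __future__ import annotations

import json
import os
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import FrameEnsemble, ForceWindow, ParseError

_TEXT_TRAJ_MAGIC = "# bilayerlab-traj 1"


def _box_from_mda(universe) -> np.ndarray:
    dims = universe.dimensions
    if dims is None or np.all(np.asarray(dims[:3]) == 0):
        raise ParseError("no box record found (missing GRO box line / PDB CRYST1)")
    return np.asarray(dims[:3], dtype=float) / 10.0  # Angstrom -> nm


def read_structure(path, format: Optional[str] = None) -> Tuple[FrameEnsemble, pd.DataFrame]:
    """Read a single-frame structure (GRO or PDB) into a FrameEnsemble.

    Returns the ensemble (coordinates in nm) and a per-atom metadata table
    (name, resid, resname).
    """
    import MDAnalysis as mda

    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    fmt = (format or os.path.splitext(str(path))[1].lstrip(".")).upper()
    if fmt not in {"GRO", "PDB"}:
        raise ParseError(f"unsupported structure format: {fmt}")
    try:
        u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    box = _box_from_mda(u)
    coords = u.atoms.positions.astype(float) / 10.0
    meta = pd.DataFrame({
        "name": u.atoms.names if hasattr(u.atoms, "names") else [""] * len(u.atoms),
        "resid": u.atoms.resids,
        "resname": u.atoms.resnames if hasattr(u.atoms, "resnames") else [""] * len(u.atoms),
    })
    ens = FrameEnsemble(
        coordinates=coords[None, :, :],
        box=box[None, :],
        time=np.zeros(1),
        metadata={"source": str(path), "format": fmt},
    )
    return ens, meta


def read_trajectory(path, format: Optional[str] = None, topology=None,
                    stride: int = 1, n_atoms: Optional[int] = None) -> FrameEnsemble:
    """Read a multi-frame trajectory (XTC, DCD via MDAnalysis, or plain text).

    ``topology`` is a structure file path for binary formats; ``n_atoms``
    (or the topology's atom count) is checked against every frame.
    """
    fmt = (format or os.path.splitext(str(path))[1].lstrip(".")).upper()
    if fmt in {"TXT", "TRAJ"}:
        ens = read_text_trajectory(path, stride=stride)
        if n_atoms is not None and ens.n_atoms != n_atoms:
            raise ParseError(
                f"atom-count mismatch: trajectory has {ens.n_atoms}, expected {n_atoms}")
        return ens
    if fmt not in {"XTC", "DCD"}:
        raise ParseError(f"unsupported trajectory format: {fmt}")
    import MDAnalysis as mda

    if topology is None:
        raise ParseError("binary trajectories require a structure/topology file")
    u = mda.Universe(str(topology), str(path))
    if n_atoms is not None and len(u.atoms) != n_atoms:
        raise ParseError(
            f"atom-count mismatch: trajectory has {len(u.atoms)}, expected {n_atoms}")
    coords, boxes, times = [], [], []
    for ts in u.trajectory[::stride]:
        coords.append(u.atoms.positions.astype(float) / 10.0)
        boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
        times.append(float(ts.time))
    return FrameEnsemble(np.array(coords), np.array(boxes), np.array(times),
                         metadata={"source": str(path), "format": fmt})


def write_text_trajectory(path, ensemble: FrameEnsemble) -> None:
    """Write the plain-text multi-frame format (one coordinate row per atom)."""
    with open(path, "w") as fh:
        fh.write(_TEXT_TRAJ_MAGIC + "\n")
        for i in range(ensemble.n_frames):
            bx, by, bz = ensemble.box[i]
            fh.write(f"FRAME t={ensemble.time[i]:.6f} box={bx:.6f} {by:.6f} {bz:.6f} "
                     f"natoms={ensemble.n_atoms}\n")
            np.savetxt(fh, ensemble.coordinates[i], fmt="%.6f")


def read_text_trajectory(path, stride: int = 1) -> FrameEnsemble:
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    coords, boxes, times = [], [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _TEXT_TRAJ_MAGIC:
            raise ParseError(f"{path}: not a bilayerlab text trajectory")
        frame_no = 0
        while True:
            line = fh.readline()
            if not line:
                break
            line = line.strip()
            if not line:
                continue
            if not line.startswith("FRAME"):
                raise ParseError(f"{path}: expected FRAME header, got {line!r}")
            try:
                t_val = float(line.split("t=")[1].split()[0])
                box = np.array([float(v) for v in
                                line.split("box=")[1].split("natoms=")[0].split()])
                natoms = int(line.split("natoms=")[1].split()[0])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: malformed FRAME header {line!r}") from exc
            rows = []
            for _ in range(natoms):
                row = fh.readline()
                if not row:
                    raise ParseError(
                        f"{path}: truncated file; last complete frame is {frame_no - 1}")
                vals = row.split()
                if len(vals) != 3:
                    raise ParseError(f"{path}: malformed coordinate row {row!r}")
                rows.append([float(v) for v in vals])
            coords.append(rows)
            boxes.append(box)
            times.append(t_val)
            frame_no += 1
    if not coords:
        raise ParseError(f"{path}: no frames")
    ens = FrameEnsemble(np.array(coords), np.array(boxes), np.array(times),
                        metadata={"source": str(path), "format": "TXT"})
    if stride > 1:
        ens = FrameEnsemble(ens.coordinates[::stride], ens.box[::stride],
                            ens.time[::stride], ens.metadata)
    return ens


def write_gro(path, ensemble: FrameEnsemble, names=None, resnames=None,
              resids=None, frame: int = 0) -> None:
    """Write one frame as a GRO file (fixed-width GROMACS format, nm)."""
    n = ensemble.n_atoms
    names = names if names is not None else [f"A{i % 99999}" for i in range(n)]
    resnames = resnames if resnames is not None else ["MOL"] * n
    resids = resids if resids is not None else [1] * n
    with open(path, "w") as fh:
        fh.write("bilayerlab frame\n")
        fh.write(f"{n:5d}\n")
        for i in range(n):
            x, y, z = ensemble.coordinates[frame, i]
            fh.write(f"{int(resids[i]) % 100000:5d}{resnames[i]:<5.5s}"
                     f"{names[i]:>5.5s}{(i + 1) % 100000:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
        bx, by, bz = ensemble.box[frame]
        fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def read_timeseries(path) -> Tuple[pd.DataFrame, dict]:
    """Read an XVG (Grace dialect: @/# comments) or CSV time-series file.

    Returns a DataFrame (named columns for CSV with header, c0..cN for XVG)
    and a metadata dict with the skipped comment lines.
    """
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty file")
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".xvg":
        comments, rows = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                s = line.strip()
                if not s:
                    continue
                if s.startswith("@") or s.startswith("#"):
                    comments.append(s)
                    continue
                vals = s.split()
                rows.append((lineno, vals))
        if not rows:
            raise ParseError(f"{path}: no data rows")
        width = len(rows[0][1])
        for lineno, vals in rows:
            if len(vals) != width:
                raise ParseError(f"{path}:{lineno}: ragged row ({len(vals)} != {width})")
        data = np.array([[float(v) for v in vals] for _, vals in rows])
        df = pd.DataFrame(data, columns=[f"c{i}" for i in range(width)])
        return df, {"comments": comments}
    # CSV with header
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    if df.isna().any().any():
        raise ParseError(f"{path}: ragged or non-numeric rows")
    return df, {}


def write_profile_csv(path, z, value, se=None, z_name: str = "z_nm",
                      value_name: str = "value") -> None:
    cols = {z_name: np.asarray(z), value_name: np.asarray(value)}
    if se is not None:
        cols["stderr"] = np.asarray(se)
    pd.DataFrame(cols).to_csv(path, index=False)


def write_force_window_csv(path, window: ForceWindow) -> None:
    t = np.arange(window.forces.size) * window.dt
    pd.DataFrame({"t_ps": t, "force_kJ_mol_nm": window.forces}).to_csv(path, index=False)


def load_force_windows(manifest_path) -> list:
    """Load constraint-force windows from a YAML manifest.

    Manifest schema::

        temperature: 298.0
        dt: 0.01            # ps, default for all windows
        windows:
          - {file: win_z0.0_r0.csv, z: 0.0, replicate: 0}
          - ...

    File paths are resolved relative to the manifest location.
    """
    import yaml

    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(manifest_path))
    temperature = float(manifest.get("temperature", 298.0))
    default_dt = manifest.get("dt")
    windows = []
    for entry in manifest["windows"]:
        fpath = entry["file"]
        if not os.path.isabs(fpath):
            fpath = os.path.join(base, fpath)
        df, _ = read_timeseries(fpath)
        force_col = "force_kJ_mol_nm" if "force_kJ_mol_nm" in df.columns else df.columns[-1]
        dt = float(entry.get("dt", default_dt)) if (entry.get("dt") or default_dt) else None
        if dt is None:
            tcol = df.columns[0]
            dt = float(np.diff(df[tcol].to_numpy()[:2])[0])
        windows.append(ForceWindow(z=float(entry["z"]), forces=df[force_col].to_numpy(),
                                   dt=dt, temperature=temperature,
                                   replicate=int(entry.get("replicate", 0))))
    return windows


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
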