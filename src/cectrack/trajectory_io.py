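"""Trajectory and structure I/O, plus the end-to-end pipeline driver.

Coordinates are Angstrom, times femtoseconds throughout the package. Only
orthorhombic boxes are supported; all inter-atomic distances honour the
minimum-image convention when a box is present.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, TrajectoryParseError

__all__ = [
    "Frame",
    "FrameSeries",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_pdb_frame",
    "write_cec_outputs",
    "run_pipeline",
]


@dataclass
class Frame:
    """One snapshot: element symbols plus Cartesian positions in Angstrom.

    ``box`` holds orthorhombic cell lengths (Angstrom) or ``None`` for a
    non-periodic (gas-phase) frame. ``time`` is in femtoseconds.
    """

    elements: list[str]
    positions: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0
    index: int = 0
    comment: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.elements) != len(self.positions):
            raise ValueError(
                f"{len(self.elements)} elements but {len(self.positions)} positions"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.elements = [e.capitalize() for e in self.elements]
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ValueError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def atoms_of(self, element: str) -> np.ndarray:
        """Indices of all atoms of the given element symbol."""
        sym = element.capitalize()
        return np.array([i for i, e in enumerate(self.elements) if e == sym], dtype=int)

    def displacement(self, i: int, j: int) -> np.ndarray:
        """Minimum-image vector from atom ``i`` to atom ``j``."""
        return minimum_image(self.positions[j] - self.positions[i], self.box)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.displacement(i, j)))


def minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vector(s)."""
    vec = np.asarray(vec, dtype=float)
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


@dataclass
class FrameSeries:
    """An ordered trajectory with constant inter-frame spacing ``dt`` (fs)."""

    frames: list[Frame]
    dt: float = 0.5

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.frames:
            ref = self.frames[0].elements
            for k, fr in enumerate(self.frames):
                if fr.elements != ref:
                    raise TrajectoryParseError(
                        "inconsistent atom identity across frames", frame=k
                    )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k):
        return self.frames[k]


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"', re.IGNORECASE)
_TIME_RE = re.compile(r"Time=([-0-9.eE+]+)", re.IGNORECASE)


def _parse_comment(comment: str, frame_idx: int, line_no: int):
    """Extract (box, time) from an extended-XYZ comment line, if present."""
    box = None
    time = None
    m = _LATTICE_RE.search(comment)
    if m:
        vals = np.array([float(x) for x in m.group(1).split()])
        if vals.size != 9:
            raise TrajectoryParseError(
                "Lattice must have 9 components", frame=frame_idx, line=line_no
            )
        cell = vals.reshape(3, 3)
        off = cell - np.diag(np.diag(cell))
        if np.any(np.abs(off) > 1e-8):
            raise TrajectoryParseError(
                "only orthorhombic lattices are supported", frame=frame_idx, line=line_no
            )
        box = np.diag(cell).copy()
    m = _TIME_RE.search(comment)
    if m:
        time = float(m.group(1))
    return box, time


def read_xyz_trajectory(path: str | Path, dt: float | None = None) -> FrameSeries:
    """Read a (possibly multi-frame, extended) XYZ file into a FrameSeries.

    Parse errors cite the 1-based frame and line of the offending record.

    Box lengths and time stamps are recovered from ``Lattice="..."`` and
    ``Time=`` tokens on comment lines when present. ``dt`` overrides the
    spacing inferred from time stamps (default 0.5 fs when neither is given).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    n_ref = None
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        fidx = len(frames)
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"malformed atom-count line {lines[pos]!r}", frame=fidx + 1, line=pos + 1
            ) from None
        if n_ref is None:
            n_ref = n
        elif n != n_ref:
            raise TrajectoryParseError(
                f"frame has {n} atoms, expected {n_ref}", frame=fidx + 1, line=pos + 1
            )
        if pos + 1 + n >= len(lines) + 1 and pos + 2 + n > len(lines):
            raise TrajectoryParseError("truncated frame", frame=fidx + 1, line=pos + 1)
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        box, time = _parse_comment(comment, fidx + 1, pos + 2)
        elements, coords = [], []
        for k in range(n):
            lno = pos + 2 + k
            if lno >= len(lines):
                raise TrajectoryParseError("truncated frame", frame=fidx + 1, line=lno + 1)
            parts = lines[lno].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"atom line has {len(parts)} fields, expected >= 4",
                    frame=fidx + 1,
                    line=lno + 1,
                )
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise TrajectoryParseError(
                    f"non-numeric coordinate in {lines[lno]!r}", frame=fidx + 1, line=lno + 1
                ) from None
            elements.append(parts[0])
        frames.append(
            Frame(
                elements=elements,
                positions=np.array(coords),
                box=box,
                time=time if time is not None else float(fidx),
                index=fidx,
                comment=comment,
            )
        )
        pos += 2 + n
    if not frames:
        raise TrajectoryParseError("no frames found in file")
    if dt is None:
        if len(frames) >= 2 and frames[1].time > frames[0].time:
            dt = frames[1].time - frames[0].time
        else:
            dt = 0.5
    return FrameSeries(frames=frames, dt=dt)


def write_xyz_trajectory(series: FrameSeries | list[Frame], path: str | Path) -> None:
    """Write frames as extended XYZ (Lattice/Time metadata on comment lines)."""
    frames = series.frames if isinstance(series, FrameSeries) else series
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            tokens = []
            if fr.box is not None:
                a, b, c = fr.box
                tokens.append(
                    f'Lattice="{a:.10g} 0 0 0 {b:.10g} 0 0 0 {c:.10g}"'
                )
            tokens.append("Properties=species:S:1:pos:R:3")
            tokens.append(f"Time={fr.time:.10g}")
            if fr.comment and "Lattice" not in fr.comment:
                tokens.append(fr.comment.strip())
            fh.write(" ".join(tokens) + "\n")
            for el, (x, y, z) in zip(fr.elements, fr.positions):
                fh.write(f"{el:<2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


_ELEMENT_FALLBACK = {"HO", "HN", "HC", "HA", "HB", "HG", "HD", "HE", "HZ", "HH"}


def _element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name (common biomolecular set)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise TrajectoryParseError(f"cannot infer element from atom name {name!r}")
    two = stripped[:2].capitalize()
    if two in ("Cl", "Na", "Mg", "Fe", "Zn", "Ca", "Br") and stripped[:2].upper() != "CA":
        return two
    return stripped[0].upper()


def read_pdb_frame(path: str | Path) -> Frame:
    """Read a single-model PDB file into a Frame (via MDAnalysis).

    Elements come from the element column when populated, otherwise they are
    inferred from atom names. Only orthorhombic (90/90/90) CRYST1 cells are
    accepted; any other angles raise :class:`TrajectoryParseError`.
    """
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="PDB")
    atoms = u.atoms
    elements: list[str] = []
    raw = None
    if hasattr(atoms, "elements"):
        raw = list(atoms.elements)
    for i, atom in enumerate(atoms):
        sym = (raw[i] if raw is not None else "").strip()
        if not sym:
            sym = _element_from_name(atom.name)
        elements.append(sym.capitalize())
    box = None
    dims = u.dimensions
    if dims is not None and np.any(np.asarray(dims)[:3] > 0):
        angles = np.asarray(dims)[3:]
        if not np.allclose(angles, 90.0, atol=1e-6):
            raise TrajectoryParseError(
                f"non-orthorhombic CRYST1 angles {tuple(angles)} are not supported"
            )
        box = np.asarray(dims)[:3].astype(float)
    coords = atoms.positions.astype(float)
    if not np.all(np.isfinite(coords)):
        raise TrajectoryParseError("missing or non-finite coordinates in PDB")
    return Frame(elements=elements, positions=coords, box=box)


def write_cec_outputs(series: FrameSeries, results: list, prefix: str | Path) -> dict:
    """Write the CEC track for a trajectory.

    Produces ``<prefix>.xyz`` (trajectory with a pseudo-atom ``X`` appended at
    the CEC of each frame), ``<prefix>_track.csv`` and ``<prefix>_manifest.json``.
    Returns the mapping of product name to written path.
    """
    import pandas as pd

    if not results:
        raise ConfigurationError("no CEC results to write")
    if len(results) != len(series):
        raise ConfigurationError(
            f"{len(results)} results for {len(series)} frames"
        )
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    aug = []
    for fr, res in zip(series, results):
        aug.append(
            Frame(
                elements=fr.elements + ["X"],
                positions=np.vstack([fr.positions, res.cec[None, :]]),
                box=fr.box,
                time=fr.time,
                index=fr.index,
            )
        )
    xyz_path = prefix.with_suffix(".xyz")
    write_xyz_trajectory(aug, xyz_path)

    rows = []
    for fr, res in zip(series, results):
        row = {
            "frame": fr.index,
            "time_fs": fr.time,
            "cec_x": res.cec[0],
            "cec_y": res.cec[1],
            "cec_z": res.cec[2],
            "n_states": res.n_states,
            "c1_sq": res.weights[0],
        }
        if getattr(res, "xi", None) is not None:
            row["xi"] = res.xi
        rows.append(row)
    table_path = Path(str(prefix) + "_track.csv")
    pd.DataFrame(rows).to_csv(table_path, index=False, float_format="%.10g")

    manifest_path = Path(str(prefix) + "_manifest.json")
    from . import __version__

    manifest = {
        "tool": "cectrack",
        "version": __version__,
        "n_frames": len(series),
        "dt_fs": series.dt,
        "products": {"xyz": xyz_path.name, "track": table_path.name},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"xyz": xyz_path, "track": table_path, "manifest": manifest_path}


# --------------------------------------------------------------------------
# pipeline driver

_KNOWN_STAGES = ("fixtures", "cec", "spectrum", "xi", "fit", "grid", "metad-demo")


def run_pipeline(config: dict, out_prefix: str | Path | None = None) -> dict:
    """Execute the staged analysis pipeline described by a config document.

    The config is a plain mapping (typically loaded from YAML) with a
    ``stages`` list and one sub-mapping per requested stage; see the README
    for the schema. All stages are validated before any computation runs, and
    every run is deterministic for a fixed ``seed``.
    """
    from . import pipeline as _pipeline

    stages = config.get("stages")
    if not stages:
        raise ConfigurationError("config must list at least one stage in 'stages'")
    for st in stages:
        if st not in _KNOWN_STAGES:
            raise ConfigurationError(
                f"unknown stage {st!r}; expected one of {_KNOWN_STAGES}"
            )
    return _pipeline.execute(config, stages, out_prefix=out_prefix)
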