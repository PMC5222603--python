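"""Trajectory and table I/O.

Readers accept the two plain-text trajectory formats in common use for
coarse-grained chains — multi-frame XYZ and multi-model (MODEL/ENDMDL) PDB —
and hand back the package's :class:`~dcbg.trajectory.Trajectory` container.
File coordinates are interpreted in Angstroms and converted to nm with the
bit-exact factor 0.1.  Parsing is delegated to MDAnalysis.

For multi-bead PDB inputs one bead per residue is selected as the
side-chain proxy (the contact criterion is defined between side-chain
beads): atom name ``CB`` is preferred, then ``SC1``, then ``CA``, else the
residue's first atom.  XYZ input is assumed to carry one bead per residue
already.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import ContactMap, Trajectory, radius_of_gyration_series

__all__ = [
    "read_xyz_trajectory",
    "read_pdb_trajectory",
    "write_xyz_trajectory",
    "write_contact_map_csv",
    "write_rg_series_csv",
]

ANGSTROM_TO_NM = 0.1
_SIDE_CHAIN_PRIORITY = ("CB", "SC1", "CA")


def _universe(path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        # topology-less text formats trigger mass/element guessing chatter
        warnings.simplefilter("ignore")
        return mda.Universe(str(path))


def read_xyz_trajectory(path, frame_interval_ps: float = 100.0) -> Trajectory:
    """Read a multi-frame XYZ trajectory (Angstrom in file, nm in memory)."""
    u = _universe(path)
    frames = [u.atoms.positions.astype(float) * ANGSTROM_TO_NM for _ in u.trajectory]
    return Trajectory(coords=np.array(frames), frame_interval_ps=frame_interval_ps)


def read_pdb_trajectory(
    path, frame_interval_ps: float = 100.0, bead_name: str | None = None
) -> Trajectory:
    """Read a multi-model PDB trajectory, one side-chain bead per residue.

    ``bead_name`` overrides the CB > SC1 > CA selection rule.
    """
    u = _universe(path)
    indices = []
    for res in u.residues:
        names = list(res.atoms.names)
        chosen = None
        priority = (bead_name,) if bead_name else _SIDE_CHAIN_PRIORITY
        for name in priority:
            if name in names:
                chosen = res.atoms[names.index(name)]
                break
        if chosen is None:
            if bead_name:
                raise ValueError(f"residue {res.resid} has no atom named {bead_name!r}")
            chosen = res.atoms[0]
        indices.append(chosen.ix)
    group = u.atoms[indices]
    frames = [group.positions.astype(float) * ANGSTROM_TO_NM for _ in u.trajectory]
    return Trajectory(coords=np.array(frames), frame_interval_ps=frame_interval_ps)


def write_xyz_trajectory(traj: Trajectory, path, element: str = "C") -> Path:
    """Write a Trajectory as standard multi-frame XYZ (coordinates in Angstrom)."""
    path = Path(path)
    n = traj.chain_length
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for f, frame in enumerate(traj.coords):
            fh.write(f"{n}\n")
            fh.write(f"frame {f} t={f * traj.frame_interval_ps:g} ps\n")
            for x, y, z in frame / ANGSTROM_TO_NM:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")
    return path


def _header_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k} = {v}\n" for k, v in metadata.items())


def write_contact_map_csv(cmap: ContactMap, path, metadata: dict | None = None) -> Path:
    """Contact map as CSV with 1-based residue indices as header row/column."""
    path = Path(path)
    idx = np.arange(1, cmap.chain_length + 1)
    df = pd.DataFrame(cmap.P, index=idx, columns=idx)
    meta = {"cutoff_nm": cmap.cutoff, "n_frames": cmap.n_frames, **(metadata or {})}
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, float_format="%.8g", lineterminator="\n")
    return path


def write_rg_series_csv(traj: Trajectory, path, metadata: dict | None = None) -> Path:
    """Per-frame radius of gyration as a two-column CSV (frame, Rg_nm)."""
    path = Path(path)
    series = radius_of_gyration_series(traj)
    df = pd.DataFrame({"frame": np.arange(traj.n_frames), "Rg_nm": series})
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header_lines(metadata))
        df.to_csv(fh, index=False, float_format="%.8g", lineterminator="\n")
    return path
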