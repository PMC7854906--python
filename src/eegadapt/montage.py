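"""Electrode montages and the sphere-to-plane (azimuthal equidistant) projection.

Scalp electrodes live on (approximately) a unit sphere centered in the head,
with +z through the vertex and +y through the nasion.  To rasterise per-channel
values as images while keeping neighbourhood relations, positions are mapped to
the plane with the azimuthal equidistant ("polar") projection about the vertex:
a point at polar angle theta and azimuth phi goes to plane radius theta at the
same azimuth, so arc length along meridians is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["Montage", "load_montage", "packaged_montage", "azimuthal_project"]

#: Name of the montage file shipped with the package (62-channel 10-20 layout).
PACKAGED_MONTAGE = "standard_1020_62.tsv"

#: Default reference channel, excluded from the effective set when requested.
DEFAULT_REFERENCE = "Fz"


@dataclass
class Montage:
    """Channel names with unit-sphere 3D positions and optional 2D projection."""

    names: list[str]
    pos3d: np.ndarray                  # [n_channels, 3], unit norm
    pos2d: np.ndarray | None = None    # [n_channels, 2], set by azimuthal_project

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.pos3d = np.asarray(self.pos3d, dtype=float)
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate channel names in montage: {dupes}")
        if self.pos3d.shape != (len(self.names), 3):
            raise ValueError("pos3d must be [n_channels, 3]")
        norms = np.linalg.norm(self.pos3d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("pos3d rows must be unit vectors (normalize on load)")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def subset(self, names: list[str]) -> "Montage":
        """Montage restricted to `names`, in the given order."""
        index = {n.lower(): i for i, n in enumerate(self.names)}
        missing = [n for n in names if n.lower() not in index]
        if missing:
            raise KeyError(f"channels not in montage: {missing}")
        idx = [index[n.lower()] for n in names]
        return Montage(
            names=[self.names[i] for i in idx],
            pos3d=self.pos3d[idx],
            pos2d=None if self.pos2d is None else self.pos2d[idx],
        )


def load_montage(path, exclude_reference: str | None = None) -> Montage:
    """Read a `name<TAB>x<TAB>y<TAB>z` montage file (header row optional).

    Positions are normalized to the unit sphere, so files in any consistent
    length unit (m, mm, arbitrary head radius) load identically.  When
    `exclude_reference` names a channel it is dropped (e.g. the Fz reference,
    leaving 61 effective channels from the packaged 62-channel layout).
    """
    names: list[str] = []
    rows: list[list[float]] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'name x y z', got {line!r}")
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError:
            if lineno == 1:     # header row
                continue
            raise ValueError(f"{path}:{lineno}: non-numeric coordinates in {line!r}")
        names.append(parts[0])
        rows.append(xyz)
    if not names:
        raise ValueError(f"{path}: no electrode rows found")
    pos = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(pos)):
        bad = [names[i] for i in np.nonzero(~np.isfinite(pos).all(axis=1))[0]]
        raise ValueError(f"non-finite coordinates for channels: {bad}")
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        bad = [names[i] for i in np.nonzero(norms == 0)[0]]
        raise ValueError(f"zero-length position vectors for channels: {bad}")
    pos = pos / norms[:, None]
    if exclude_reference is not None:
        keep = [i for i, n in enumerate(names) if n.lower() != exclude_reference.lower()]
        if len(keep) == len(names):
            raise KeyError(f"reference channel {exclude_reference!r} not found in montage")
        names = [names[i] for i in keep]
        pos = pos[keep]
    return Montage(names=names, pos3d=pos)


def packaged_montage(exclude_reference: str | None = DEFAULT_REFERENCE) -> Montage:
    """The shipped 62-channel 10-20 montage; by default the Fz reference is
    dropped, giving the 61 effective channels."""
    ref = resources.files("eegadapt.data") / PACKAGED_MONTAGE
    with resources.as_file(ref) as path:
        return load_montage(path, exclude_reference=exclude_reference)


def azimuthal_project(montage: Montage) -> Montage:
    """Attach plane coordinates via the azimuthal equidistant projection.

    The vertex (0, 0, 1) maps to the origin; a point at polar angle theta maps
    to plane radius theta (radians) at its original azimuth.  The projection is
    singular at the antipode (theta = pi), which cannot occur for scalp
    electrodes.
    """
    z = np.clip(montage.pos3d[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    if np.any(theta > np.pi - 1e-9):
        bad = [montage.names[i] for i in np.nonzero(theta > np.pi - 1e-9)[0]]
        raise ValueError(f"projection singular at the antipode for channels: {bad}")
    phi = np.arctan2(montage.pos3d[:, 1], montage.pos3d[:, 0])
    pos2d = np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
    return Montage(names=list(montage.names), pos3d=montage.pos3d.copy(), pos2d=pos2d)
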