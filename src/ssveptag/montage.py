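"""Sensor-net geometry: 2-D electrode layout and nearest-neighbor relations.

The packaged default is the 128-channel geodesic sensor net layout bundled
with :mod:`mne` ("GSN-HydroCel-128"), projected to the plane with an
azimuthal-equidistant projection.  Only relative distances matter downstream
(topography falloff in the generator, nearest-neighbor interpolation in
preprocessing), so the units of the planar coordinates are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _azimuthal_projection(pos3d: np.ndarray) -> np.ndarray:
    """Project head-surface 3-D points to the plane, preserving arc distance
    from the vertex."""
    x, y, z = pos3d.T
    r = np.linalg.norm(pos3d, axis=1)
    r = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(z / r, -1.0, 1.0))  # polar angle from vertex
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


@dataclass
class Montage:
    channel_labels: list
    positions_2d: np.ndarray
    n_neighbors: int = 6

    def __post_init__(self):
        self.positions_2d = np.asarray(self.positions_2d, dtype=float)
        if self.positions_2d.shape != (len(self.channel_labels), 2):
            raise ValueError("positions_2d must be (n_channels, 2)")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        uniq = {tuple(p) for p in np.round(self.positions_2d, 12)}
        if len(uniq) != len(self.channel_labels):
            raise ValueError("channel positions must be unique")
        self._index = {c: i for i, c in enumerate(self.channel_labels)}

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index(self, label) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(c) for c in labels], dtype=int)

    def neighbors(self, label, k: int | None = None) -> list:
        """The ``k`` nearest distinct channels by planar distance."""
        k = self.n_neighbors if k is None else k
        i = self.index(label)
        d = np.linalg.norm(self.positions_2d - self.positions_2d[i], axis=1)
        d[i] = np.inf
        order = np.argsort(d, kind="stable")[:k]
        return [self.channel_labels[j] for j in order]

    def adjacency(self) -> dict:
        return {c: self.neighbors(c) for c in self.channel_labels}


def gsn128(n_neighbors: int = 6) -> Montage:
    """The 128-channel geodesic net layout shipped with mne, in 2-D."""
    import mne

    std = mne.channels.make_standard_montage("GSN-HydroCel-128")
    ch_pos = std.get_positions()["ch_pos"]
    labels = [f"E{i}" for i in range(1, 129)]
    pos3d = np.array([ch_pos[c] for c in labels])
    return Montage(labels, _azimuthal_projection(pos3d), n_neighbors=n_neighbors)
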