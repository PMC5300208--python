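"""Conformational ensembles and frame/atom selection.

The :class:`ConformerEnsemble` is the universal container of the toolkit:
``(n_frames, n_atoms, 3)`` coordinates in Å with per-frame times in ps and
a :class:`~gagmimic.topology.Topology`.  Frame times default to 0, 1, 2, …
ps, matching trajectories saved every picosecond.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyWindowError, GagmimicError, StrideError
from .topology import SelectionLike, Topology, select_atom_indices


@dataclass(frozen=True)
class FrameWindow:
    """Half-open time window ``(start_time, end_time]`` in ps with a stride.

    The half-open convention means a 20 ns trajectory saved every 1 ps,
    windowed over (10 ns, 20 ns] at a 10 ps stride, yields exactly 1000
    frames — the standard snapshot count for endpoint free-energy averages.
    """

    start_time: float
    end_time: float
    stride: float = 1.0

    def __post_init__(self):
        if not self.start_time < self.end_time:
            raise GagmimicError(
                f"start_time {self.start_time} must be < end_time {self.end_time}"
            )
        if self.stride <= 0:
            raise GagmimicError(f"stride must be positive, got {self.stride}")


@dataclass
class ConformerEnsemble:
    """Frames × atoms × 3 coordinate array (Å) with topology and times (ps)."""

    topology: Topology
    coordinates: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise GagmimicError(
                f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise GagmimicError(
                f"coordinate array has {self.coordinates.shape[1]} atoms but "
                f"topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise GagmimicError("coordinates contain non-finite values")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise GagmimicError(
                    f"times length {self.times.shape} does not match "
                    f"{self.n_frames} frames"
                )
            if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
                raise GagmimicError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, index: int) -> np.ndarray:
        """Coordinates of one frame, ``(n_atoms, 3)``."""
        return self.coordinates[index]

    @property
    def frame_spacing(self) -> float:
        """Median inter-frame spacing in ps (requires >= 2 frames)."""
        if self.n_frames < 2:
            raise GagmimicError("frame spacing undefined for < 2 frames")
        return float(np.median(np.diff(self.times)))

    def select_frames(self, window: FrameWindow) -> "ConformerEnsemble":
        """Frames with time in ``(start, end]`` at the window's stride.

        The stride must be an integer multiple of the frame spacing; strided
        frames are anchored at the first in-window frame.
        """
        mask = (self.times > window.start_time) & (self.times <= window.end_time)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise EmptyWindowError(
                f"window ({window.start_time}, {window.end_time}] ps selects no "
                f"frames of a trajectory spanning "
                f"[{self.times[0]}, {self.times[-1]}] ps"
            )
        if idx.size > 1:
            spacing = self.frame_spacing
            ratio = window.stride / spacing
            k = int(round(ratio))
            if k < 1 or abs(ratio - k) > 1e-9 * max(1.0, ratio):
                raise StrideError(
                    f"stride {window.stride} ps is not an integer multiple of "
                    f"the frame spacing {spacing} ps"
                )
            idx = idx[::k]
        return ConformerEnsemble(
            topology=self.topology,
            coordinates=self.coordinates[idx].copy(),
            times=self.times[idx].copy(),
        )

    def select_atoms(self, expr: SelectionLike) -> "ConformerEnsemble":
        """Ensemble restricted to atoms matching ``expr`` (original order).

        ``expr`` is a selection string (see
        :func:`gagmimic.topology.compile_selection`) or a predicate on
        :class:`~gagmimic.topology.AtomRecord`.  Matching nothing raises an
        explicit empty-selection error.
        """
        indices = select_atom_indices(self.topology, expr)
        return ConformerEnsemble(
            topology=self.topology.subset(indices),
            coordinates=self.coordinates[:, indices].copy(),
            times=self.times.copy(),
        )

    def atom_indices(self, expr: SelectionLike) -> list[int]:
        """Indices (into this ensemble's topology) matching ``expr``."""
        return select_atom_indices(self.topology, expr)


def select_frames(ensemble: ConformerEnsemble, window: FrameWindow) -> ConformerEnsemble:
    """Functional alias for :meth:`ConformerEnsemble.select_frames`."""
    return ensemble.select_frames(window)


def select_atoms(ensemble: ConformerEnsemble, expr: SelectionLike) -> ConformerEnsemble:
    """Functional alias for :meth:`ConformerEnsemble.select_atoms`."""
    return ensemble.select_atoms(expr)
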