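"""Core in-memory containers shared across the pipeline.

The raw unit of analysis is a multi-channel voxel grid (:class:`ImageStack`)
with named channel roles, from which binary regions (:class:`RegionMask`) are
built and per-nucleus quantities measured.  Time-lapse data are represented as
:class:`CellTrack` objects: one labelled frame sequence per cell at a fixed
frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "RegionMask", "CellTrack", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when generator or analysis parameters are inconsistent."""


@dataclass
class ImageStack:
    """Multi-channel voxel grid with channel-role labels.

    Parameters
    ----------
    channels
        Mapping from channel role (``"DAPI"``, ``"PCNA"``, ``"EdU"``, ``"EU"``,
        ``"PTM:<mark>"``, ``"marker:<protein>"``) to a ``(Z, Y, X)`` array.
        Roles are unique by construction of the mapping.
    spacing_um
        Voxel spacing ``(z, y, x)``.  Stored as opaque metadata; no analysis
        step computes with physical units.
    """

    channels: dict[str, np.ndarray]
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ConfigurationError(f"channel shapes differ: {shapes}")
        for role, ch in self.channels.items():
            if np.any(ch < 0):
                raise ConfigurationError(f"negative intensities in channel {role!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def roles(self) -> list[str]:
        return list(self.channels)

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(f"no channel with role {role!r}; have {self.roles}") from None


@dataclass
class RegionMask:
    """Binary region with provenance of how it was built.

    ``kind`` is one of ``nucleus``, ``block_Xstar``, ``block_X``, ``exclusion``.
    ``threshold_trace`` records every successive threshold applied during mask
    construction (empty for ground-truth masks).
    """

    mask: np.ndarray
    kind: str
    source: str = ""
    threshold_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def __and__(self, other: "RegionMask") -> np.ndarray:
        return self.mask & other.mask


# Label grammar for a complete S-phase traversal: nonS* early+ mid+ late+ nonS*
PATTERN_LABELS = ("nonS", "early", "mid", "late")


@dataclass
class CellTrack:
    """Time-ordered frame sequence for one cell at a fixed frame interval.

    ``labels`` holds one S-phase pattern label per frame; ``xstar_flags`` /
    ``x_flags`` mark frames during which the facultative (X*) or constitutive
    (X) heterochromatic block is replicating.
    """

    cell_id: str
    condition: str
    times_min: np.ndarray
    labels: list[str]
    xstar_flags: np.ndarray
    x_flags: np.ndarray
    interval_min: float = 20.0
    censored: bool = False

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.xstar_flags = np.asarray(self.xstar_flags, dtype=bool)
        self.x_flags = np.asarray(self.x_flags, dtype=bool)
        n = len(self.times_min)
        if not (len(self.labels) == len(self.xstar_flags) == len(self.x_flags) == n):
            raise ConfigurationError("track fields have mismatched lengths")
        if n >= 2:
            steps = np.diff(self.times_min)
            if np.any(steps <= 0) or not np.allclose(steps, self.interval_min):
                raise ConfigurationError("frame times must increase by the frame interval")
        bad = set(self.labels) - set(PATTERN_LABELS)
        if bad:
            raise ConfigurationError(f"unknown pattern labels: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def count(self, label: str) -> int:
        return sum(lab == label for lab in self.labels)
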