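"""Antenna-ring geometry and multistatic channel bookkeeping.

The acquisition setup is a planar (coronal-slice) ring of ``n`` antennas
equally spaced around the breast.  Every unordered transmit–receive pair,
monostatic pairs included, is one *channel*; a ring of 12 antennas therefore
yields ``12 * 13 / 2 = 78`` channels.  The angular separation between the two
antennas of a channel (the *channel angle* Z) drives the EA/MA/EAC model
architectures, and channels can be ranked by the physical two-leg path length
Tx -> tumour -> Rx for the ranked antenna-grouping vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = [
    "RingArray",
    "Channel",
    "ChannelRanking",
    "build_ring",
    "enumerate_channels",
    "channel_angle",
    "distinct_angles",
    "rank_channels_by_proximity",
]


@dataclass(frozen=True)
class RingArray:
    """Circular antenna array: antenna ``i`` sits at polar angle ``i * 360/n`` deg.

    Positions are in millimetres, counter-clockwise, antenna 0 on the
    positive x-axis relative to ``centre``.
    """

    n_antennas: int
    radius: float
    centre: tuple[float, float]
    positions: np.ndarray = field(repr=False)

    @property
    def adjacent_spacing(self) -> float:
        """Angular spacing between adjacent antennas, degrees."""
        return 360.0 / self.n_antennas


@dataclass(frozen=True, order=True)
class Channel:
    """One unordered transmit–receive pair, canonicalised so ``tx <= rx``."""

    tx: int
    rx: int
    angle_z: float = field(compare=False)

    def __post_init__(self) -> None:
        if self.tx > self.rx:
            raise GeometryError(f"channel pair must be canonicalised tx<=rx, got ({self.tx},{self.rx})")


@dataclass
class ChannelRanking:
    """Channels ordered by ascending two-leg path length to a tumour."""

    channels: list[Channel]
    metric: np.ndarray
    w_max: int

    def closest(self, w: int) -> list[Channel]:
        return self.channels[:w]


def build_ring(n: int, radius: float, centre: tuple[float, float] = (0.0, 0.0)) -> RingArray:
    """Place ``n`` antennas uniformly on a circle of ``radius`` mm around ``centre``."""
    if n < 1:
        raise GeometryError(f"need at least one antenna, got n={n}")
    if radius <= 0:
        raise GeometryError(f"ring radius must be positive, got {radius}")
    angles = 2.0 * np.pi * np.arange(n) / n
    positions = np.column_stack(
        [centre[0] + radius * np.cos(angles), centre[1] + radius * np.sin(angles)]
    )
    return RingArray(n_antennas=n, radius=float(radius), centre=(float(centre[0]), float(centre[1])),
                     positions=positions)


def channel_angle(tx: int, rx: int, array: RingArray) -> float:
    """Angular separation of a pair on the ring, in [0, 180] degrees for even n."""
    n = array.n_antennas
    for idx in (tx, rx):
        if not 0 <= idx < n:
            raise GeometryError(f"antenna index {idx} out of range [0,{n})")
    k = abs(tx - rx)
    k = min(k, n - k)
    return k * 360.0 / n


def enumerate_channels(array: RingArray) -> list[Channel]:
    """All unordered pairs including monostatic ones: ``n(n+1)/2`` channels."""
    return [
        Channel(i, j, channel_angle(i, j, array))
        for i in range(array.n_antennas)
        for j in range(i, array.n_antennas)
    ]


def distinct_angles(array: RingArray) -> list[float]:
    """Sorted distinct channel angles; {0, s, 2s, ..., 180} for even n with s=360/n."""
    return sorted({ch.angle_z for ch in enumerate_channels(array)})


def path_length(channel: Channel, point: np.ndarray, array: RingArray) -> float:
    """Two-leg Euclidean path Tx -> point -> Rx in mm."""
    p = np.asarray(point, dtype=float)
    leg_tx = float(np.hypot(*(array.positions[channel.tx] - p)))
    leg_rx = float(np.hypot(*(p - array.positions[channel.rx])))
    return leg_tx + leg_rx


def rank_channels_by_proximity(
    channels: list[Channel], tumour_position, array: RingArray
) -> ChannelRanking:
    """Order channels by ascending Tx->tumour->Rx path, ties broken by (tx, rx).

    The two-leg Euclidean path is the physical signal path and reduces to
    twice the antenna–tumour distance for monostatic channels.  A tumour
    outside the ring is suspicious but the ranking is still well defined,
    so only a warning is raised.
    """
    p = np.asarray(tumour_position, dtype=float)
    if np.hypot(p[0] - array.centre[0], p[1] - array.centre[1]) > array.radius:
        warnings.warn("tumour position lies outside the antenna ring", stacklevel=2)
    metric = np.array([path_length(ch, p, array) for ch in channels])
    order = sorted(range(len(channels)), key=lambda i: (metric[i], channels[i].tx, channels[i].rx))
    return ChannelRanking(
        channels=[channels[i] for i in order],
        metric=metric[order],
        w_max=len(channels),
    )
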