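"""Stage-2 tumour windowing: artefact removal, delay prediction, alignment.

A backscattered signal is dominated by antenna coupling and the skin
reflection; the tumour response is a short transient buried after them.  The
windowing stage (i) subtracts the antenna-only reference, (ii) predicts the
round-trip delay of the tumour echo from the known tumour position and an
average three-media propagation model (immersion medium, skin shell, breast
interior), (iii) cuts a window of 2.5 pulse widths around the predicted
arrival, (iv) time-aligns each channel on its peak and (v) downsamples from
600 GHz to 30 GHz, producing a 60-sample tumour signature per channel.

Units: positions/lengths in mm, times in ns, sampling rates in GHz,
relative permittivities dimensionless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError, GeometryError
from .geometry import Channel, RingArray

logger = logging.getLogger(__name__)

#: speed of light in mm/ns
C_MM_PER_NS = 299.792458

#: fixed alignment index of the 60-sample signature (0-based); the aligned
#: peak is pinned here so that the dominant time sample sits at the same
#: position for every channel and scan.
ALIGNMENT_INDEX = 33

__all__ = [
    "C_MM_PER_NS",
    "ALIGNMENT_INDEX",
    "MediaModel",
    "TumourSignature",
    "remove_artifact",
    "roundtrip_delay",
    "window_tumour",
    "align_signature",
    "align_and_downsample",
    "tumour_signature",
]


@dataclass(frozen=True)
class MediaModel:
    """Average propagation model through immersion medium, skin and interior.

    The breast is a disc of ``breast_radius`` with a skin shell of
    ``skin_thickness``; everything outside is immersion medium.  The speed in
    each medium is ``c / sqrt(eps)``.
    """

    eps_immersion: float
    eps_skin: float
    eps_interior: float
    skin_thickness: float
    breast_radius: float
    breast_centre: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("eps_immersion", "eps_skin", "eps_interior"):
            if getattr(self, name) < 1.0:
                raise GeometryError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 < self.skin_thickness < self.breast_radius:
            raise GeometryError("skin thickness must lie in (0, breast_radius)")

    @property
    def interior_radius(self) -> float:
        return self.breast_radius - self.skin_thickness


@dataclass
class TumourSignature:
    """Windowed, peak-aligned, 30 GHz tumour response of one channel."""

    samples: np.ndarray
    fs_out: float
    alignment_index: int
    channel: Channel | None = None
    scan_id: str | None = None
    low_quality: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise DataError("signature must be one-dimensional")


def remove_artifact(signal: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Subtract the antenna-only reference from a backscattered signal."""
    signal = np.asarray(signal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if signal.shape != reference.shape:
        raise DataError(
            f"signal/reference length mismatch: {signal.shape} vs {reference.shape}"
        )
    return signal - reference


def _length_inside_circle(a: np.ndarray, b: np.ndarray, centre: np.ndarray, r: float) -> float:
    """Length of the segment a->b lying inside the circle (centre, r)."""
    d = b - a
    f = a - centre
    dd = float(d @ d)
    if dd == 0.0:
        return 0.0
    # |a + t d - centre|^2 = r^2
    disc = (f @ d) ** 2 - dd * (f @ f - r * r)
    if disc <= 0.0:
        return 0.0
    sq = np.sqrt(disc)
    t1 = (-(f @ d) - sq) / dd
    t2 = (-(f @ d) + sq) / dd
    t1, t2 = max(t1, 0.0), min(t2, 1.0)
    if t2 <= t1:
        return 0.0
    return (t2 - t1) * float(np.sqrt(dd))


def _leg_delay(a: np.ndarray, p: np.ndarray, media: MediaModel) -> float:
    """One-way delay (ns) from antenna position ``a`` to interior point ``p``."""
    centre = np.asarray(media.breast_centre, dtype=float)
    total = float(np.hypot(*(p - a)))
    inside_outer = _length_inside_circle(a, p, centre, media.breast_radius)
    inside_inner = _length_inside_circle(a, p, centre, media.interior_radius)
    len_skin = inside_outer - inside_inner
    len_imm = total - inside_outer
    slowness = (
        len_imm * np.sqrt(media.eps_immersion)
        + len_skin * np.sqrt(media.eps_skin)
        + inside_inner * np.sqrt(media.eps_interior)
    )
    return slowness / C_MM_PER_NS


def roundtrip_delay(
    tumour_position, channel: Channel, array: RingArray, media: MediaModel
) -> float:
    """Round-trip delay (ns) Tx -> tumour -> Rx through the three-media model.

    Each leg is a straight ray whose immersion/skin/interior segment lengths
    are obtained from the two circle intersections, then divided by the
    per-medium speed ``c/sqrt(eps)``.
    """
    p = np.asarray(tumour_position, dtype=float)
    centre = np.asarray(media.breast_centre, dtype=float)
    if float(np.hypot(*(p - centre))) >= media.interior_radius:
        raise GeometryError("tumour position must lie strictly inside the breast interior")
    tx = array.positions[channel.tx]
    rx = array.positions[channel.rx]
    return _leg_delay(tx, p, media) + _leg_delay(rx, p, media)


def window_tumour(signal: np.ndarray, delay: float, pulse, fs: float) -> np.ndarray:
    """Cut a 2.5-pulse-width window around the predicted tumour arrival.

    The window starts 0.75 pulse widths before ``delay`` (asymmetric, leaving
    more room after the arrival for trailing spicule sub-echoes).  Portions
    falling outside the record are zero-padded with a logged warning.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[0]
    n_win = round(2.5 * pulse.width_tp * fs)
    if delay * fs >= n:
        raise DataError(f"predicted delay {delay:.3f} ns falls beyond the record end")
    start = round((delay - 0.75 * pulse.width_tp) * fs)
    out = np.zeros(n_win)
    lo = max(start, 0)
    hi = min(start + n_win, n)
    if lo > start or hi < start + n_win:
        logger.warning(
            "tumour window [%d,%d) overruns the record of %d samples; zero-padding",
            start, start + n_win, n,
        )
    if hi > lo:
        out[lo - start : hi - start] = signal[lo:hi]
    return out


def align_signature(x: np.ndarray, alignment_index: int) -> np.ndarray:
    """Circularly shift ``x`` so its maximum-|amplitude| sample lands at ``alignment_index``.

    Near-ties (within 1e-9 relative) resolve to the earliest sample so that
    the two equal-magnitude lobes of a clean differentiated-Gaussian echo
    cannot flip the alignment on floating-point noise.
    """
    x = np.asarray(x, dtype=float)
    a = np.abs(x)
    peak = int(np.flatnonzero(a >= a.max() * (1.0 - 1e-9))[0])
    return np.roll(x, alignment_index - peak)


def align_and_downsample(
    raw_window: np.ndarray,
    fs_in: float = 600.0,
    fs_out: float = 30.0,
    n_out: int = 60,
    alignment_index: int = ALIGNMENT_INDEX,
    channel: Channel | None = None,
    scan_id: str | None = None,
) -> TumourSignature:
    """Peak-align the raw window and decimate it to a fixed-length signature.

    Peak energy is read as the sample of maximum absolute amplitude.  The
    window is circularly shifted so that the peak maps to the alignment
    index, low-pass filtered at the output Nyquist (15 GHz for 30 GHz output)
    with a zero-phase FIR, and decimated.  A final output-rate shift pins the
    signature's |peak| exactly at ``alignment_index``, which makes the
    alignment idempotent.
    """
    raw = np.asarray(raw_window, dtype=float)
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9:
        raise DataError(f"fs_in/fs_out must be an integer decimation factor, got {q}")
    q = int(round(q))
    if raw.shape[0] < n_out * q:
        raise DataError(f"raw window of {raw.shape[0]} samples is too short for {n_out}x{q}")
    raw = raw[: n_out * q]
    if not np.any(raw):
        logger.warning("all-zero tumour window for scan=%s; low-quality signature", scan_id)
        return TumourSignature(
            samples=np.zeros(n_out), fs_out=fs_out, alignment_index=n_out // 2,
            channel=channel, scan_id=scan_id, low_quality=True,
        )
    shifted = align_signature(raw, alignment_index * q)
    if q > 1:
        down = sps.decimate(shifted, q, ftype="fir", zero_phase=True)
    else:
        down = shifted
    down = align_signature(down[:n_out], alignment_index)
    return TumourSignature(
        samples=down, fs_out=fs_out, alignment_index=alignment_index,
        channel=channel, scan_id=scan_id, low_quality=False,
    )


def tumour_signature(
    signal: np.ndarray,
    reference: np.ndarray,
    tumour_position,
    channel: Channel,
    array: RingArray,
    media: MediaModel,
    pulse,
    fs: float = 600.0,
    fs_out: float = 30.0,
    scan_id: str | None = None,
) -> TumourSignature:
    """Full per-channel chain: artefact removal -> delay -> window -> align+downsample."""
    cleaned = remove_artifact(signal, reference)
    delay = roundtrip_delay(tumour_position, channel, array, media)
    raw = window_tumour(cleaned, delay, pulse, fs)
    return align_and_downsample(raw, fs_in=fs, fs_out=fs_out, channel=channel, scan_id=scan_id)
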