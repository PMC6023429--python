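"""Synthetic multistatic breast-scan generator.

Full-wave electromagnetic simulation is replaced by a geometric echo model
that reproduces the statistical structure the diagnosis pipeline consumes:

* an antenna-coupling *reference* per channel (direct Tx->Rx pulse through
  the immersion medium, self-coupling at zero delay for monostatic pairs);
* a *skin reflection* at the skin round-trip delay, an order of magnitude
  stronger than the tumour echo;
* a *principal tumour echo*: a delayed copy of the interrogating pulse at the
  three-media round-trip delay, amplitude decaying as 1/path-length;
* *spicule sub-echoes* emulating the waveform distortion caused by a
  spiculated (malignant) margin — ``Poisson(round(10 s))`` extra copies with
  random delay offsets within one pulse width and amplitudes 0.2–0.8 of the
  principal echo, where ``s`` in [0,1] is the spiculation parameter
  (benign 0 <= s <= 0.25, malignant 0.50 <= s <= 0.90);
* *glandular clutter*: ``Poisson(20 gf)`` echoes from random interior
  scatterers, where ``gf`` is the glandular fraction (presets 1%, 5%, 27%);
* additive white Gaussian noise scaled to the principal-echo amplitude.

The interrogating pulse is a differentiated Gaussian with 6 GHz centre
frequency sampled at 600 GHz.  The default dataset design mirrors a
3-breast x 72-tumour x 5-position study: 1080 scans of 78 channels each,
84,240 signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError, GeometryError
from .geometry import Channel, RingArray, build_ring, enumerate_channels, path_length
from .windowing import C_MM_PER_NS, MediaModel, roundtrip_delay

__all__ = [
    "Pulse",
    "BreastSpec",
    "TumourSpec",
    "Scan",
    "ScanSet",
    "DesignSpec",
    "pulse_waveform",
    "simulate_reference",
    "simulate_channel_signal",
    "sample_tumour",
    "canonical_positions",
    "generate_dataset",
    "GLANDULAR_PRESETS",
]

#: glandular-fraction presets for the three breast models (1%, 5%, 27%)
GLANDULAR_PRESETS = (0.01, 0.05, 0.27)


@dataclass(frozen=True)
class Pulse:
    """Differentiated Gaussian interrogating pulse.

    ``centre_frequency`` (GHz) fixes the Gaussian scale via
    ``sigma = 1 / (2 pi f_c)`` — the spectral magnitude of a differentiated
    Gaussian peaks exactly there.  ``width_tp`` (ns) is the nominal pulse
    width used as the windowing time unit: 0.8 ns makes the 2.5-pulse-width
    window exactly 60 samples after downsampling to 30 GHz.
    """

    centre_frequency: float = 6.0
    width_tp: float = 0.8
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width_tp <= 0:
            raise DataError(f"pulse width must be positive, got {self.width_tp}")

    @property
    def sigma(self) -> float:
        """Gaussian time scale in ns."""
        return 1.0 / (2.0 * np.pi * self.centre_frequency)


def pulse_waveform(t, pulse: Pulse, t0: float = 0.0) -> np.ndarray:
    """First derivative of a Gaussian centred at ``t0`` (ns), peak |value| = amplitude."""
    x = (np.asarray(t, dtype=float) - t0) / pulse.sigma
    # normalise so max|w| = amplitude: |x e^{-x^2/2}| peaks at x=1 with e^{-1/2}
    return -pulse.amplitude * np.exp(0.5) * x * np.exp(-0.5 * x * x)


@dataclass(frozen=True)
class BreastSpec:
    """Simplified breast: adipose disc, thin skin shell, glandular clutter level."""

    radius: float = 55.0
    skin_thickness: float = 2.0
    glandular_fraction: float = 0.05
    eps_immersion: float = 9.0
    eps_skin: float = 36.0
    eps_interior: float = 9.0

    def __post_init__(self) -> None:
        if not 0.0 < self.skin_thickness < self.radius:
            raise GeometryError("skin thickness must lie in (0, radius)")
        if not 0.0 <= self.glandular_fraction <= 1.0:
            raise DataError("glandular fraction must be in [0,1]")
        for name in ("eps_immersion", "eps_skin", "eps_interior"):
            if getattr(self, name) < 1.0:
                raise GeometryError(f"{name} must be >= 1")

    @property
    def interior_radius(self) -> float:
        return self.radius - self.skin_thickness

    def media(self, centre: tuple[float, float] = (0.0, 0.0)) -> MediaModel:
        return MediaModel(
            eps_immersion=self.eps_immersion,
            eps_skin=self.eps_skin,
            eps_interior=self.eps_interior,
            skin_thickness=self.skin_thickness,
            breast_radius=self.radius,
            breast_centre=centre,
        )


@dataclass(frozen=True)
class TumourSpec:
    """Tumour diameter (mm), margin spiculation s in [0,1], position and class label.

    The benign/malignant class bands on s (defaults [0,0.25] and
    [0.50,0.90]) are enforced by :func:`sample_tumour`, which knows the
    configured bands; robustness sweeps may legitimately narrow the gap.
    """

    diameter: float
    spiculation_s: float
    position: tuple[float, float]
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("benign", "malignant"):
            raise DataError(f"label must be benign/malignant, got {self.label!r}")
        if not 0.0 <= self.spiculation_s <= 1.0:
            raise DataError(f"spiculation must lie in [0,1], got {self.spiculation_s}")


def canonical_positions(breast: BreastSpec) -> dict[str, tuple[float, float]]:
    """Five canonical tumour sites: centre plus the four quadrants.

    Quadrant sites sit at half the interior radius along the +-45 degree
    diagonals, a plausible reading of "four quadrants and the central
    portion" in the absence of stated coordinates.
    """
    r = 0.5 * breast.interior_radius
    d = r / np.sqrt(2.0)
    return {
        "centre": (0.0, 0.0),
        "q1": (d, d),
        "q2": (-d, d),
        "q3": (-d, -d),
        "q4": (d, -d),
    }


def sample_tumour(
    label: str,
    position: tuple[float, float],
    diameter_range: tuple[float, float] = (6.0, 20.0),
    rng: np.random.Generator | None = None,
    s_benign: tuple[float, float] = (0.0, 0.25),
    s_malignant: tuple[float, float] = (0.50, 0.90),
) -> TumourSpec:
    """Draw a tumour: s uniform in its class band, diameter uniform in 6–20 mm."""
    if label not in ("benign", "malignant"):
        raise DataError(f"label must be benign/malignant, got {label!r}")
    rng = np.random.default_rng() if rng is None else rng
    band = s_benign if label == "benign" else s_malignant
    if not 0.0 <= band[0] <= band[1] <= 1.0:
        raise DataError(f"spiculation band {band} must be ordered within [0,1]")
    s = float(rng.uniform(*band))
    diameter = float(rng.uniform(*diameter_range))
    return TumourSpec(diameter=diameter, spiculation_s=s, position=tuple(position), label=label)


def _echo_sum(t: np.ndarray, delays: np.ndarray, amps: np.ndarray, pulse: Pulse) -> np.ndarray:
    """Superposition of pulse copies at the given delays/amplitudes."""
    if len(delays) == 0:
        return np.zeros_like(t)
    x = (t[None, :] - np.asarray(delays, dtype=float)[:, None]) / pulse.sigma
    return np.einsum("e,et->t", np.asarray(amps, dtype=float),
                     -np.exp(0.5) * x * np.exp(-0.5 * x * x))


def simulate_reference(
    channel: Channel,
    array: RingArray,
    pulse: Pulse,
    fs: float = 600.0,
    n_samples: int = 4096,
    eps_immersion: float = 9.0,
    coupling_amplitude: float = 20.0,
) -> np.ndarray:
    """Antenna-only reference: direct Tx->Rx pulse through the immersion medium.

    For monostatic channels the Tx–Rx distance is zero, so the reference is
    the self-coupling echo at zero delay.  Channels with equal Tx–Rx distance
    (equal channel angle on the ring) get identical references; the chord is
    computed from the channel angle so the equality is exact in floats.
    """
    d = 2.0 * array.radius * np.sin(np.radians(channel.angle_z) / 2.0)
    delay = d * np.sqrt(eps_immersion) / C_MM_PER_NS
    amp = coupling_amplitude / (1.0 + d)
    t = np.arange(n_samples) / fs
    return amp * pulse_waveform(t, pulse, delay)


def _skin_echo_delay_amp(
    breast: BreastSpec, channel: Channel, array: RingArray,
    principal_amp: float, skin_amplitude_ratio: float,
) -> tuple[float, float]:
    """Stylised skin artefact: the early entry-point reflection.

    Modelled as each antenna's reflection off its nearest skin point, so its
    arrival (gap-crossing time for both antennas) always precedes the tumour
    window — the breast interior adds at least the tumour's depth to any
    tumour path.
    """
    centre = np.asarray(array.centre, dtype=float)
    gap_tx = float(np.hypot(*(array.positions[channel.tx] - centre))) - breast.radius
    gap_rx = float(np.hypot(*(array.positions[channel.rx] - centre))) - breast.radius
    delay = (gap_tx + gap_rx) * np.sqrt(breast.eps_immersion) / C_MM_PER_NS
    return delay, skin_amplitude_ratio * principal_amp


def simulate_channel_signal(
    breast: BreastSpec,
    tumour: TumourSpec,
    channel: Channel,
    array: RingArray,
    pulse: Pulse,
    noise_sigma: float,
    rng: np.random.Generator,
    fs: float = 600.0,
    n_samples: int = 4096,
    echo_gain: float = 100.0,
    skin_amplitude_ratio: float = 12.0,
    clutter_rate: float = 20.0,
    spicule_rate: float = 10.0,
    coupling_amplitude: float = 20.0,
    include_reference: bool = True,
) -> np.ndarray:
    """Synthesise one channel's backscattered record at ``fs`` GHz.

    signal = reference coupling + skin echo + tumour response + clutter
    + noise.  The tumour response is the principal delayed pulse plus
    ``Poisson(round(spicule_rate * s))`` sub-echoes; clutter echoes come from
    ``Poisson(clutter_rate * glandular_fraction)`` random interior points.
    Amplitudes decay as ``echo_gain / path_length_mm``.
    """
    centre = np.asarray(array.centre, dtype=float)
    if breast.radius >= array.radius:
        raise GeometryError("breast must fit inside the antenna ring")
    p = np.asarray(tumour.position, dtype=float)
    if float(np.hypot(*(p - centre))) >= breast.interior_radius:
        raise GeometryError("tumour must lie inside the breast interior")

    media = breast.media(centre=tuple(centre))
    t = np.arange(n_samples) / fs

    principal_delay = roundtrip_delay(p, channel, array, media)
    principal_amp = echo_gain / path_length(channel, p, array)

    delays = [principal_delay]
    amps = [principal_amp]

    skin_delay, skin_amp = _skin_echo_delay_amp(
        breast, channel, array, principal_amp, skin_amplitude_ratio
    )
    delays.append(skin_delay)
    amps.append(skin_amp)

    # spicule sub-echoes: waveform distortion grows with margin spiculation
    k_spicule = rng.poisson(round(spicule_rate * tumour.spiculation_s))
    for _ in range(k_spicule):
        delays.append(principal_delay + rng.uniform(-pulse.width_tp, pulse.width_tp))
        amps.append(rng.uniform(0.2, 0.8) * principal_amp)

    # glandular clutter from random interior scatterers
    n_clutter = rng.poisson(clutter_rate * breast.glandular_fraction)
    for _ in range(n_clutter):
        r = breast.interior_radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        q = centre + r * np.array([np.cos(theta), np.sin(theta)])
        delays.append(roundtrip_delay(q, channel, array, media))
        amps.append(rng.uniform(0.05, 0.5) * principal_amp)

    out = _echo_sum(t, np.array(delays), np.array(amps), pulse)
    if include_reference:
        out += simulate_reference(
            channel, array, pulse, fs=fs, n_samples=n_samples,
            eps_immersion=breast.eps_immersion, coupling_amplitude=coupling_amplitude,
        )
    if noise_sigma > 0:
        out += rng.normal(0.0, noise_sigma * principal_amp, n_samples)
    return out


@dataclass
class Scan:
    """One multistatic breast scan: one signal row per enumerated channel."""

    scan_id: str
    signals: np.ndarray  # (n_channels, n_samples)
    breast: BreastSpec
    tumour: TumourSpec
    position_site: str
    breast_index: int
    seed: int

    @property
    def label(self) -> str:
        return self.tumour.label


@dataclass
class DesignSpec:
    """Dataset design: breasts x tumours x positions, classes balanced."""

    n_breasts: int = 3
    n_tumours: int = 72
    n_positions: int = 5

    @property
    def n_scans(self) -> int:
        return self.n_breasts * self.n_tumours * self.n_positions


@dataclass
class ScanSet:
    """A generated dataset plus the shared geometry, pulse and references."""

    scans: list[Scan]
    array: RingArray
    channels: list[Channel]
    references: np.ndarray  # (n_channels, n_samples)
    pulse: Pulse
    fs: float
    design: DesignSpec
    params: dict = field(default_factory=dict)

    @property
    def n_signals(self) -> int:
        return len(self.scans) * len(self.channels)

    @property
    def scan_ids(self) -> list[str]:
        return [s.scan_id for s in self.scans]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.scans]


def generate_dataset(
    design: DesignSpec | None = None,
    glandular_fractions: tuple[float, ...] = GLANDULAR_PRESETS,
    seed: int = 0,
    n_antennas: int = 12,
    ring_radius: float = 70.0,
    n_samples: int = 4096,
    fs: float = 600.0,
    pulse: Pulse | None = None,
    noise_sigma: float = 0.05,
    s_benign: tuple[float, float] = (0.0, 0.25),
    s_malignant: tuple[float, float] = (0.50, 0.90),
    **channel_kwargs,
) -> ScanSet:
    """Generate the full scan dataset: one scan per (breast, tumour, position).

    Tumour shapes (s, diameter) are sampled once and reused across every
    breast and position, mirroring a fixed bank of tumour models.  Classes
    are balanced (``n_tumours`` must be even).  The result is bit-reproducible
    under ``seed``.
    """
    design = DesignSpec() if design is None else design
    if design.n_tumours % 2 != 0:
        raise DataError("n_tumours must be even so classes can be balanced")
    if len(glandular_fractions) < design.n_breasts:
        raise DataError("need one glandular fraction per breast model")

    pulse = Pulse() if pulse is None else pulse
    array = build_ring(n_antennas, ring_radius)
    channels = enumerate_channels(array)

    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])

    half = design.n_tumours // 2
    tumour_bank = [
        sample_tumour("benign" if i < half else "malignant", (0.0, 0.0),
                      rng=master, s_benign=s_benign, s_malignant=s_malignant)
        for i in range(design.n_tumours)
    ]

    references = np.stack([
        simulate_reference(
            ch, array, pulse, fs=fs, n_samples=n_samples,
            eps_immersion=channel_kwargs.get("eps_immersion", 9.0),
            coupling_amplitude=channel_kwargs.get("coupling_amplitude", 20.0),
        )
        for ch in channels
    ])

    scan_seeds = ss.spawn(design.n_scans)
    scans: list[Scan] = []
    idx = 0
    for bi in range(design.n_breasts):
        breast = BreastSpec(glandular_fraction=glandular_fractions[bi])
        sites = list(canonical_positions(breast).items())[: design.n_positions]
        for ti, base in enumerate(tumour_bank):
            for site_name, site_pos in sites:
                child = scan_seeds[idx]
                idx += 1
                rng = np.random.default_rng(child)
                tumour = replace(base, position=site_pos)
                signals = np.stack([
                    simulate_channel_signal(
                        breast, tumour, ch, array, pulse, noise_sigma, rng,
                        fs=fs, n_samples=n_samples,
                        **{k: v for k, v in channel_kwargs.items() if k != "eps_immersion"},
                    )
                    for ch in channels
                ])
                scans.append(Scan(
                    scan_id=f"b{bi}t{ti:02d}{site_name}",
                    signals=signals, breast=breast, tumour=tumour,
                    position_site=site_name, breast_index=bi,
                    seed=int(child.generate_state(1, np.uint32)[0]),
                ))
    return ScanSet(
        scans=scans, array=array, channels=channels, references=references,
        pulse=pulse, fs=fs, design=design,
        params={
            "seed": seed, "noise_sigma": noise_sigma, "n_samples": n_samples,
            "glandular_fractions": tuple(glandular_fractions[: design.n_breasts]),
            "s_benign": s_benign, "s_malignant": s_malignant,
            "ring_radius": ring_radius, "n_antennas": n_antennas,
            **channel_kwargs,
        },
    )
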