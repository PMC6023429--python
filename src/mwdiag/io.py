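"""Container formats: HDF5 scan sets, CSV feature/prediction tables.

The HDF5 layout stores one group per scan (``/scans/<id>/signals`` with the
class label, spiculation, diameter, position and glandular fraction as
attributes), the antenna geometry under ``/geometry`` and the per-channel
antenna-only references under ``/references``.  CSV tables carry the run's
config hash in a leading ``#`` comment line and round-trip bit-exactly
through pandas.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import pandas as pd

from .geometry import RingArray, enumerate_channels
from .simulate import BreastSpec, DesignSpec, Pulse, Scan, ScanSet, TumourSpec

__all__ = [
    "config_hash",
    "save_scanset",
    "load_scanset",
    "write_table",
    "read_table",
]


def config_hash(config) -> str:
    """Short stable hash of a (dataclass or dict) configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_scanset(path, scanset: ScanSet) -> None:
    """Write a ScanSet to an HDF5 container."""
    with h5py.File(path, "w") as f:
        geo = f.create_group("geometry")
        geo.create_dataset("positions", data=scanset.array.positions)
        geo.attrs["radius"] = scanset.array.radius
        geo.attrs["centre"] = scanset.array.centre
        geo.attrs["n_antennas"] = scanset.array.n_antennas
        f.create_dataset("references", data=scanset.references)
        f.attrs["fs"] = scanset.fs
        f.attrs["pulse_centre_frequency"] = scanset.pulse.centre_frequency
        f.attrs["pulse_width_tp"] = scanset.pulse.width_tp
        f.attrs["pulse_amplitude"] = scanset.pulse.amplitude
        f.attrs["design"] = json.dumps(dataclasses.asdict(scanset.design))
        f.attrs["params"] = json.dumps(scanset.params, default=str)
        grp = f.create_group("scans")
        for scan in scanset.scans:
            g = grp.create_group(scan.scan_id)
            g.create_dataset("signals", data=scan.signals)
            g.attrs["label"] = scan.tumour.label
            g.attrs["s"] = scan.tumour.spiculation_s
            g.attrs["diameter"] = scan.tumour.diameter
            g.attrs["position"] = scan.tumour.position
            g.attrs["position_site"] = scan.position_site
            g.attrs["glandular_fraction"] = scan.breast.glandular_fraction
            g.attrs["breast_radius"] = scan.breast.radius
            g.attrs["skin_thickness"] = scan.breast.skin_thickness
            g.attrs["eps_immersion"] = scan.breast.eps_immersion
            g.attrs["eps_skin"] = scan.breast.eps_skin
            g.attrs["eps_interior"] = scan.breast.eps_interior
            g.attrs["breast_index"] = scan.breast_index
            g.attrs["seed"] = scan.seed


def load_scanset(path) -> ScanSet:
    """Read a ScanSet back from an HDF5 container."""
    with h5py.File(path, "r") as f:
        geo = f["geometry"]
        array = RingArray(
            n_antennas=int(geo.attrs["n_antennas"]),
            radius=float(geo.attrs["radius"]),
            centre=tuple(geo.attrs["centre"]),
            positions=geo["positions"][...],
        )
        pulse = Pulse(
            centre_frequency=float(f.attrs["pulse_centre_frequency"]),
            width_tp=float(f.attrs["pulse_width_tp"]),
            amplitude=float(f.attrs["pulse_amplitude"]),
        )
        design = DesignSpec(**json.loads(f.attrs["design"]))
        scans = []
        for scan_id in sorted(f["scans"]):
            g = f["scans"][scan_id]
            breast = BreastSpec(
                radius=float(g.attrs["breast_radius"]),
                skin_thickness=float(g.attrs["skin_thickness"]),
                glandular_fraction=float(g.attrs["glandular_fraction"]),
                eps_immersion=float(g.attrs["eps_immersion"]),
                eps_skin=float(g.attrs["eps_skin"]),
                eps_interior=float(g.attrs["eps_interior"]),
            )
            tumour = TumourSpec(
                diameter=float(g.attrs["diameter"]),
                spiculation_s=float(g.attrs["s"]),
                position=tuple(g.attrs["position"]),
                label=str(g.attrs["label"]),
            )
            scans.append(Scan(
                scan_id=scan_id, signals=g["signals"][...], breast=breast,
                tumour=tumour, position_site=str(g.attrs["position_site"]),
                breast_index=int(g.attrs["breast_index"]), seed=int(g.attrs["seed"]),
            ))
        return ScanSet(
            scans=scans, array=array, channels=enumerate_channels(array),
            references=f["references"][...], pulse=pulse,
            fs=float(f.attrs["fs"]), design=design,
            params=json.loads(f.attrs["params"]),
        )


def write_table(path, table: pd.DataFrame, cfg_hash: str = "") -> None:
    """Write a CSV with the run's config hash on a leading comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        # %.17g round-trips IEEE doubles exactly
        table.to_csv(fh, index=False, float_format="%.17g")


def read_table(path) -> tuple[pd.DataFrame, str]:
    """Read a CSV written by :func:`write_table`; returns (table, config hash)."""
    with open(path) as fh:
        first = fh.readline().strip()
        cfg_hash = first.split("=", 1)[1] if first.startswith("# config_hash=") else ""
        table = pd.read_csv(fh, float_precision="round_trip")
    return table, cfg_hash
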