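"""Generate the demonstration multistatic scan dataset.

Produces a reduced-design dataset (one 5%-glandular breast, 24 tumours x 5
positions = 120 scans of 78 channels) with the generator defaults, stores
the HDF5 container under scratch/ (binary, not part of the deliverable) and
a small JSON summary under results/.
"""

import json
from pathlib import Path

import mwdiag as m

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scanset = m.generate_dataset(
        m.DesignSpec(n_breasts=1, n_tumours=24, n_positions=5),
        glandular_fractions=(0.05,),
        seed=1,
        n_samples=2560,
        noise_sigma=0.05,
    )
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    m.io.save_scanset(scratch / "demo_scans.h5", scanset)

    labels = scanset.labels
    s_values = [s.tumour.spiculation_s for s in scanset.scans]
    summary = {
        "n_scans": len(scanset.scans),
        "n_channels": len(scanset.channels),
        "n_signals": scanset.n_signals,
        "n_benign": labels.count("benign"),
        "n_malignant": labels.count("malignant"),
        "spiculation_range_benign": [
            min(s for s, l in zip(s_values, labels) if l == "benign"),
            max(s for s, l in zip(s_values, labels) if l == "benign"),
        ],
        "spiculation_range_malignant": [
            min(s for s, l in zip(s_values, labels) if l == "malignant"),
            max(s for s, l in zip(s_values, labels) if l == "malignant"),
        ],
        "record_samples": int(scanset.scans[0].signals.shape[1]),
        "fs_GHz": scanset.fs,
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "dataset_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print("dataset:", json.dumps(summary, indent=2))
    print(f"container -> {scratch / 'demo_scans.h5'}")


if __name__ == "__main__":
    main()
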