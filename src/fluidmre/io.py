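"""Array-container persistence for wave-field sets and parameter maps.

Fields and maps are stored as a single ``.npz`` archive next to a JSON
manifest recording frequencies, pixel spacing and density.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .inversion import ParameterMaps, WaveFieldSet

__all__ = [
    "save_wavefields",
    "load_wavefields",
    "save_maps",
    "load_maps",
]


def _manifest_path(path) -> Path:
    return Path(path).with_suffix(".json")


def save_wavefields(w: WaveFieldSet, path, rho: float = 1000.0) -> None:
    arrays = {}
    for f, u in zip(w.frequencies, w.fields):
        arrays[f"re_{f:g}"] = u.real
        arrays[f"im_{f:g}"] = u.imag
    np.savez_compressed(path, **arrays)
    with open(_manifest_path(path), "w") as fh:
        json.dump(
            {
                "freqs_hz": list(map(float, w.frequencies)),
                "spacing_m": w.spacing,
                "rho": rho,
            },
            fh,
        )


def load_wavefields(path) -> WaveFieldSet:
    with open(_manifest_path(path)) as fh:
        manifest = json.load(fh)
    npz = np.load(Path(path).with_suffix(".npz"))
    fields = [
        npz[f"re_{f:g}"] + 1j * npz[f"im_{f:g}"]
        for f in manifest["freqs_hz"]
    ]
    return WaveFieldSet(
        frequencies=np.asarray(manifest["freqs_hz"]),
        fields=fields,
        spacing=manifest["spacing_m"],
    )


def save_maps(m: ParameterMaps, path) -> None:
    arrays = {
        "magnitude": m.magnitude,
        "phase": m.phase,
        "fluidity": m.fluidity,
        "speed": m.speed,
        "valid": m.valid.astype(np.uint8),
    }
    for name, mask in m.masks.items():
        if isinstance(mask, np.ndarray):
            arrays[f"mask_{name}"] = np.asarray(mask, dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    with open(_manifest_path(path), "w") as fh:
        json.dump({"spacing_m": m.spacing, "rho": m.density}, fh)


def load_maps(path) -> ParameterMaps:
    with open(_manifest_path(path)) as fh:
        manifest = json.load(fh)
    npz = np.load(Path(path).with_suffix(".npz"))
    masks = {
        key[5:]: npz[key].astype(bool)
        for key in npz.files
        if key.startswith("mask_")
    }
    return ParameterMaps(
        magnitude=npz["magnitude"],
        phase=npz["phase"],
        fluidity=npz["fluidity"],
        speed=npz["speed"],
        spacing=manifest["spacing_m"],
        valid=npz["valid"].astype(bool),
        density=manifest["rho"],
        masks=masks,
    )
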