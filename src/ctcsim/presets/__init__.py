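"""Shipped scenario presets (YAML) and the calibrated material constants."""

from importlib import resources

import yaml

__all__ = ["list_presets", "load_preset_dict", "CTC_MATERIAL"]

#: Membrane constants calibrated so the 8 um, 642-vertex tumor-cell mesh
#: reaches Taylor ratio 0.31 at 2000 pN in the quasi-static stretch test.
CTC_MATERIAL = {
    "k_link": 166.0,
    "k_bend": 8.0,
    "k_area_local": 20.0,
    "k_area_global": 20.0,
    "k_volume": 300.0,
    "strain_max": 2.0,
}


def list_presets() -> list[str]:
    out = []
    for entry in resources.files(__package__).iterdir():
        if entry.name.endswith(".yaml"):
            out.append(entry.name[:-5])
    return sorted(out)


def load_preset_dict(name: str) -> dict:
    ref = resources.files(__package__) / f"{name}.yaml"
    if not ref.is_file():
        raise FileNotFoundError(f"no preset named {name!r}; available: {list_presets()}")
    with ref.open() as fh:
        return yaml.safe_load(fh)
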