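"""Locus presets shipped with the package (see ``data/locus_presets.yaml``)."""

from __future__ import annotations

from importlib import resources

import yaml

from .coords import AnchoredInterval
from .synthetic import Element, LocusSpec

__all__ = ["load_presets", "preset"]


def _spec_from_dict(name: str, d: dict) -> LocusSpec:
    elements = tuple(
        Element(
            label=e["label"],
            interval=AnchoredInterval(int(e["start"]), int(e["end"])),
            consensus=e["consensus"],
            rf_effect=float(e.get("rf_effect", 0.0)),
            pf_effect=float(e.get("pf_effect", 0.0)),
        )
        for e in d.get("elements", [])
    )
    return LocusSpec(
        name=name,
        length=int(d["length"]),
        upstream=int(d["upstream"]),
        orc_site=d.get("orc_site", LocusSpec.orc_site),
        orc_rf_effect=float(d.get("orc_rf_effect", 0.0)),
        orc_pf_effect=float(d.get("orc_pf_effect", 0.0)),
        elements=elements,
        rf_base=float(d.get("rf_base", 0.0)),
        pf_base=float(d.get("pf_base", 0.0)),
    )


def load_presets(path: str | None = None) -> dict[str, LocusSpec]:
    """Parse a preset file (default: the packaged collection) into LocusSpecs."""
    if path is None:
        text = resources.files("miniars").joinpath("data/locus_presets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: _spec_from_dict(name, d) for name, d in raw.items()}


def preset(name: str) -> LocusSpec:
    presets = load_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
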