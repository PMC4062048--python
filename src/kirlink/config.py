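"""One place for every operational threshold, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import yaml

from . import cnv, linkage, quant


@dataclass(frozen=True)
class Config:
    """Analysis thresholds with documented defaults.

    droplet_volume_nl
        Droplet volume in nanoliters (nominal 1 nL reactors; 0.85 is the
        common instrument convention). Ratio statistics (%L, copy number)
        are volume-independent.
    min_droplets
        Wells with fewer accepted droplets are flagged, not dropped.
    normalization
        Default %L denominator; ``max_channel`` respects copy-number
        ceilings such as a two-vs-one-copy sample maxing out at %L = 50.
    presence_threshold / abrogation_fraction / weak_threshold
        Motif-calling knobs; a motif is present when undigested %L exceeds
        the threshold and digestion cuts it to at most the given fraction.
    posterior_floor
        Mixture calls below this posterior are flagged for review.
    """

    droplet_volume_nl: float = quant.DEFAULT_DROPLET_VOLUME_NL
    min_droplets: int = quant.DEFAULT_MIN_DROPLETS
    normalization: str = "max_channel"
    presence_threshold: float = linkage.DEFAULT_PRESENCE_THRESHOLD
    abrogation_fraction: float = linkage.DEFAULT_ABROGATION_FRACTION
    weak_threshold: float = linkage.DEFAULT_WEAK_THRESHOLD
    posterior_floor: float = cnv.DEFAULT_POSTERIOR_FLOOR
    n_boot: int = 2000


def load_config(path=None, **overrides) -> Config:
    """Defaults, then YAML file values, then keyword overrides."""
    cfg = Config()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in fields(Config)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = replace(cfg, **data)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
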