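"""Run configuration: YAML loading, validation, hashing, seed fan-out."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bold import BandSpec
from .features import ExtractionConfig

DEFAULTS = {
    "seed": 0,
    "output_dir": "parcelstack_run",
    "extraction": {
        "band": [0.01, 0.08],
        "smoothing_fwhm_mm": 4.0,
        "reho_neighborhood": 27,
        "power_mode": "amplitude",
        "precision_regularization": "cv",
    },
    "evaluation": {
        "k": 10,
        "repeats": 5,
        "confound_scope": "train",
        "selection": "pca",
        "r": None,
        "inner_folds": 10,
        "inner_repeats": 5,
        "stack_cv": False,
        "permutations": 0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Validated run configuration with a content hash for provenance."""

    raw: dict
    path: Path | None = None
    _hash: str = field(default="", repr=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user, path=Path(path))

    @classmethod
    def from_dict(cls, user: dict, path=None) -> "RunConfig":
        raw = _merge(DEFAULTS, user)
        band = raw["extraction"]["band"]
        BandSpec(band[0], band[1])  # validates ordering
        if raw["evaluation"]["confound_scope"] not in ("train", "all", "none"):
            raise ValueError("confound_scope must be train/all/none")
        return cls(raw=raw, path=path)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    def extraction_config(self) -> ExtractionConfig:
        e = self.raw["extraction"]
        return ExtractionConfig(
            band=BandSpec(*e["band"]),
            smoothing_fwhm_mm=e["smoothing_fwhm_mm"],
            reho_neighborhood=e["reho_neighborhood"],
            power_mode=e["power_mode"],
            precision_regularization=e["precision_regularization"],
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: (seed + crc32(stage)) mod 2^31."""
        return (self.seed + zlib.crc32(stage.encode())) % (2**31 - 1)

    def config_hash(self) -> str:
        if not self._hash:
            blob = json.dumps(self.raw, sort_keys=True).encode()
            self._hash = hashlib.sha256(blob).hexdigest()[:12]
        return self._hash
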