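"""Per-machine configuration: geometry, jaw policy, Canny settings per view.

Stored as a small YAML file so clinics can keep one config per linac; the
Canny threshold/sigma defaults were tuned on synthetic images and are
expected to be re-optimised once per machine, after which they stay fixed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .edge_detection import CannyConfig
from .measurement import PhantomModel, vendor_jaw_policy


@dataclass
class MachineConfig:
    name: str = "default"
    vendor: str = "varian"
    sad_mm: float = 1000.0
    sid_mm: float = 1460.0
    pixel_spacing_mm: float = 0.4
    field_size_mm: float = 100.0
    couch_signs: tuple[int, int, int] = (1, 1, 1)
    jaws: tuple[str, ...] | None = None  # None -> vendor policy
    canny: dict[str, CannyConfig] = field(default_factory=dict)
    phantom: PhantomModel = field(default_factory=PhantomModel)

    def __post_init__(self) -> None:
        for view in ("AP", "lateral"):
            self.canny.setdefault(view, CannyConfig(view=view))
        if self.jaws is None:
            self.jaws = vendor_jaw_policy(self.vendor)
        self.couch_signs = tuple(int(s) for s in self.couch_signs)

    def canny_for(self, view: str) -> CannyConfig:
        return self.canny[view]

    def digest(self) -> str:
        """Stable hash of the configuration, recorded with every run."""
        payload = asdict(self)
        payload["canny"] = {k: asdict(v) for k, v in self.canny.items()}
        payload["phantom"] = asdict(self.phantom)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "name": self.name,
            "vendor": self.vendor,
            "sad_mm": self.sad_mm,
            "sid_mm": self.sid_mm,
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "field_size_mm": self.field_size_mm,
            "couch_signs": list(self.couch_signs),
            "jaws": list(self.jaws),
            "canny": {k: asdict(v) for k, v in self.canny.items()},
            "phantom": asdict(self.phantom),
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MachineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        canny = {
            k: CannyConfig(**v) for k, v in (payload.pop("canny", None) or {}).items()
        }
        phantom = PhantomModel(**(payload.pop("phantom", None) or {}))
        jaws = payload.pop("jaws", None)
        cfg = cls(
            canny=canny,
            phantom=phantom,
            jaws=tuple(jaws) if jaws else None,
            couch_signs=tuple(payload.pop("couch_signs", (1, 1, 1))),
            **payload,
        )
        return cfg
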