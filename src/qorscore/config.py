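"""Run configuration: anchors, bin orientation, filament set, seeds.

Defaults reproduce the faithful pipeline (inverted bins, calibrated
anchors, the standard filament set); configurations round-trip losslessly
through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .scoring import DeficitAnchors
from .vonfrey import DEFAULT_FILAMENTS

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Options steering the scoring + comparison pipeline."""

    anchors: DeficitAnchors = field(default_factory=DeficitAnchors)
    bin_orientation: str = "inverted"
    filament_set: tuple[float, ...] = DEFAULT_FILAMENTS
    posthoc: str = "holm"
    reference_group: str = "naive"
    seed: int = 0
    outdir: str = "qor_out"

    def __post_init__(self) -> None:
        object.__setattr__(self, "filament_set",
                           tuple(float(f) for f in self.filament_set))
        if self.bin_orientation not in ("inverted", "literal"):
            raise ValueError(f"unknown bin orientation {self.bin_orientation!r}")

    def to_dict(self) -> dict:
        return {
            "anchors": self.anchors.as_dict(),
            "bin_orientation": self.bin_orientation,
            "filament_set": list(self.filament_set),
            "posthoc": self.posthoc,
            "reference_group": self.reference_group,
            "seed": self.seed,
            "outdir": self.outdir,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        anchors = DeficitAnchors(**data.pop("anchors", {}))
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(anchors=anchors, **data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text) or {})

    def digest(self) -> str:
        """Stable content hash of the configuration (for run manifests)."""
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
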