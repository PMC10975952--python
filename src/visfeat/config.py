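"""Pipeline configuration: nested parameter sections with lossless YAML
round-tripping.  Every stage default is recorded here."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from visfeat.detect import DetectParams
from visfeat.frangi import FrangiParams
from visfeat.fusion import FusionParams
from visfeat.hessian import ScaleGrid
from visfeat.match import MatchParams
from visfeat.mfat import MfatParams
from visfeat.preprocess import AdaptiveMaskParams, HighlightParams, InpaintParams, PreprocessConfig
from visfeat.synth import VesselTreeSpec


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scales: ScaleGrid = field(default_factory=ScaleGrid)
    frangi: FrangiParams = field(default_factory=FrangiParams)
    mfat: MfatParams = field(default_factory=MfatParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    detect: DetectParams = field(default_factory=DetectParams)
    match: MatchParams = field(default_factory=MatchParams)
    synth: VesselTreeSpec = field(default_factory=VesselTreeSpec)
    direction_source: str = "stronger"  # 'frangi' | 'stronger'
    polarity: str = "dark"

    def __post_init__(self) -> None:
        if self.direction_source not in ("frangi", "stronger"):
            raise ValueError("direction_source must be 'frangi' or 'stronger'")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")
        # the scale grid and polarity are shared by both branches
        self.frangi.scales = self.scales
        self.mfat.scales = self.scales
        self.frangi.polarity = self.polarity
        self.mfat.polarity = self.polarity

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(tp, payload):
            if payload is None:
                return tp()
            kwargs = {}
            for f in dataclasses.fields(tp):
                if f.name not in payload:
                    continue
                val = payload[f.name]
                if dataclasses.is_dataclass(f.type) or f.name in _NESTED:
                    val = build(_NESTED[f.name], val)
                elif isinstance(val, list):
                    val = tuple(val)
                kwargs[f.name] = val
            return tp(**kwargs)

        _NESTED = {
            "preprocess": PreprocessConfig,
            "adaptive": AdaptiveMaskParams,
            "highlight": HighlightParams,
            "inpaint": InpaintParams,
            "scales": ScaleGrid,
            "frangi": FrangiParams,
            "mfat": MfatParams,
            "fusion": FusionParams,
            "detect": DetectParams,
            "match": MatchParams,
            "synth": VesselTreeSpec,
        }
        return build(cls, data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
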