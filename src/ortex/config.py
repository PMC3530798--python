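"""Engine configuration, optionally loaded from a YAML file.

Example::

    ort:
      density_homogeneity: true
      attribution: [I, S, L, O]
    relations:
      max_chain: 8
      omit_disjoint: true
    density_text_map:
      profuse: "3"
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import FormatError
from .io import DEFAULT_DENSITY_TEXT_MAP
from .model import DensityCode, RelationCode
from .ort import OrtConfig

__all__ = ["EngineConfig", "load_config"]


@dataclass(frozen=True)
class EngineConfig:
    ort: OrtConfig = field(default_factory=OrtConfig)
    max_chain: int = 8
    omit_disjoint: bool = True
    density_text_map: dict = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_TEXT_MAP)
    )


def load_config(path: str | Path | None) -> EngineConfig:
    """Build an :class:`EngineConfig`, overlaying YAML settings if given."""
    cfg = EngineConfig()
    if path is None:
        return cfg
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: invalid YAML ({exc})") from None
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: config must be a mapping")

    ort_doc = doc.get("ort", {})
    ort = OrtConfig(
        density_homogeneity=bool(
            ort_doc.get("density_homogeneity", cfg.ort.density_homogeneity)
        ),
        attribution_relations=frozenset(
            RelationCode(tok) for tok in ort_doc.get("attribution", ["I", "S", "L", "O"])
        ),
    )
    rel_doc = doc.get("relations", {})
    text_map = dict(DEFAULT_DENSITY_TEXT_MAP)
    for word, tok in (doc.get("density_text_map") or {}).items():
        text_map[str(word).lower()] = DensityCode(str(tok))
    return replace(
        cfg,
        ort=ort,
        max_chain=int(rel_doc.get("max_chain", cfg.max_chain)),
        omit_disjoint=bool(rel_doc.get("omit_disjoint", cfg.omit_disjoint)),
        density_text_map=text_map,
    )
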