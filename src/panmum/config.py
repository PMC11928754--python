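"""Pipeline configuration shared by the CLI, the pipeline and gap filling."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the aligner.

    Parse-level parameters: ``modulus``/``window`` control the expected
    phrase length of the prefix-free parse (backbone); ``gap_modulus`` is
    the smaller modulus used when re-parsing inside large gaps (shorter
    phrases find anchors in less conserved regions).

    ``small_gap_threshold`` is the largest per-sequence gap (bases) handed
    to the small-gap aligner directly; gaps at least ``parse_gap_factor``
    times larger search anchors on the parse level, in between on the base
    level.  ``extension_min_match`` is the minimum exact-match run required
    to cross a mismatching column during anchor extension.
    """

    modulus: int = 100
    window: int = 10
    gap_modulus: int = 20
    small_gap_threshold: int = 10_000
    parse_gap_factor: int = 10
    extension_min_match: int = 10
    min_base_anchor: int = 20  # minimum base-level anchor length in gaps
    mapq_min: int = 30
    removal_min_anchor: int = 500  # unalignable-sequence removal rule
    dp_max_fragments: int = 2000  # exact chaining above this uses the heuristic
    max_depth: int = 10
    seed: int = 0
    threads: int = 1  # accepted for interface parity; execution is serial
    external_aligner: Optional[Any] = None  # smallgap.ExternalAligner
    external_mapper: Optional[Any] = None  # gapfill.ExternalMapper

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
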