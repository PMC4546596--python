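"""YAML configuration for pipeline runs.

A single file can override the tunables of every stage: bootstrap
thresholds, negation/future marker lists, temporal vocabularies, the
assembly threshold and directional prefixes, the candidate stoplist and
the random seed. Omitted keys keep their defaults.

Example::

    seed: 7
    bootstrap: {pst: 3, ppt: 0.5, tft: 1}
    filter:
      negation_prefixes: [无, 拒绝, 否认, 未见]
      future_markers: [拟, 建议]
    temporal:
      idioms: [昨夜, 昨晚, 今夜, 今晚, 今早, 今晨]
    assembly: {threshold: 0.01, directional: [左, 右, 双]}
    stoplist: [入院, 出院, 住院, 就诊, 治疗]
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .assembly import PrefixConfig
from .bootstrap import BootstrapConfig
from .linker import DEFAULT_STOPLIST
from .tagger import FilterConfig
from .temporal import TemporalVocab

__all__ = ["RunConfig", "load_config"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    bootstrap: BootstrapConfig = dataclasses.field(default_factory=BootstrapConfig)
    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    temporal: TemporalVocab = dataclasses.field(default_factory=TemporalVocab)
    prefix: PrefixConfig = dataclasses.field(default_factory=PrefixConfig)
    assembly_threshold: float = 0.01
    stoplist: frozenset[str] = DEFAULT_STOPLIST


def _build(cls, raw: dict, tuple_fields: tuple[str, ...] = (), set_fields: tuple[str, ...] = ()):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        value = raw[f.name]
        if f.name in tuple_fields:
            value = tuple(value)
        elif f.name in set_fields:
            value = frozenset(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration; unknown top-level keys are an error."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {"seed", "bootstrap", "filter", "temporal", "assembly", "stoplist"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    assembly = raw.get("assembly", {})
    filter_raw = dict(raw.get("filter", {}))
    if "filtered_categories" in filter_raw:
        from .lexicon import Category

        filter_raw["filtered_categories"] = frozenset(
            Category(c) for c in filter_raw["filtered_categories"]
        )
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        bootstrap=_build(BootstrapConfig, raw.get("bootstrap", {})),
        filter=_build(
            FilterConfig,
            filter_raw,
            set_fields=("negation_prefixes", "future_markers"),
        ),
        temporal=_build(
            TemporalVocab,
            raw.get("temporal", {}),
            tuple_fields=(
                "pre_aw", "post_aw", "units", "temporal_units",
                "prepositions", "days", "periods", "idioms",
            ),
        ),
        prefix=_build(PrefixConfig, assembly, tuple_fields=("directional",)),
        assembly_threshold=float(assembly.get("threshold", 0.01)),
        stoplist=frozenset(raw["stoplist"]) if "stoplist" in raw else DEFAULT_STOPLIST,
    )
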