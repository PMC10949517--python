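"""Build simulator and model configurations from plain dictionaries.

Used by the CLI to load YAML run configurations; the dictionaries map
one-to-one onto the dataclasses in :mod:`plasenrich.simulate` and
:mod:`plasenrich.model`.
"""

from __future__ import annotations

from typing import Any, Mapping

from .model import ModelParams
from .simulate import (
    LATENCY_PRESETS,
    ChannelLifetime,
    FlowCellConfig,
    LatencySpec,
    LengthSpec,
    SampleMix,
    SampleSpec,
)


def latency_from_dict(data: Mapping[str, Any] | str) -> LatencySpec:
    """Either a preset name ('minknow', 'readbouncer') or an explicit spec."""
    if isinstance(data, str):
        try:
            return LATENCY_PRESETS[data]
        except KeyError:
            raise ValueError(
                f"unknown latency preset {data!r}; "
                f"known: {sorted(LATENCY_PRESETS)}"
            ) from None
    return LatencySpec(**data)


def lifetime_from_dict(data: Mapping[str, Any] | str) -> ChannelLifetime:
    if isinstance(data, str):
        return ChannelLifetime(family=data)
    return ChannelLifetime(**data)


def flowcell_from_dict(data: Mapping[str, Any]) -> FlowCellConfig:
    kwargs = dict(data)
    if "decision_latency" in kwargs:
        kwargs["decision_latency"] = latency_from_dict(kwargs["decision_latency"])
    if "channel_lifetime" in kwargs:
        kwargs["channel_lifetime"] = lifetime_from_dict(kwargs["channel_lifetime"])
    return FlowCellConfig(**kwargs)


def sample_from_dict(data: Mapping[str, Any]) -> SampleSpec:
    kwargs = dict(data)
    for key in ("length_plasmid", "length_chromosome"):
        if key in kwargs:
            kwargs[key] = LengthSpec(**kwargs[key])
    if "plasmid_lengths" in kwargs:
        kwargs["plasmid_lengths"] = tuple(kwargs["plasmid_lengths"])
    if "shared_region_span" in kwargs and kwargs["shared_region_span"] is not None:
        kwargs["shared_region_span"] = tuple(kwargs["shared_region_span"])
    return SampleSpec(**kwargs)


def mix_from_dict(samples: list[Mapping[str, Any]]) -> SampleMix:
    return SampleMix(samples=tuple(sample_from_dict(s) for s in samples))


def model_params_from_dict(data: Mapping[str, Any]) -> ModelParams:
    return ModelParams(**data)
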