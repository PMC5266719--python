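"""Channel design: mapping isobaric reporter tags to condition and timepoint.

The workflow runs a 6-plex control/treatment time course in a single MS run:
three timepoints (5, 30, 120 min), each with one control and one treated
channel, in both the iodoTMT (Cys redox) and iTRAQ (protein abundance)
reporter spaces.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, TextIO, Union

import yaml

IODO_LABELS = ("126", "127", "128", "129", "130", "131")
ITRAQ_LABELS = ("113", "114", "115", "116", "117", "118")

CONTROL = "control"
TREATED = "treated"


class DesignError(ValueError):
    """Channel design violates the paired 6-plex layout."""


@dataclass(frozen=True)
class ChannelDesign:
    """Reporter label -> (condition, timepoint) for both label spaces.

    The default layout labels controls at 5/30/120 min with iodoTMT 126/128/130
    and treatments with 127/129/131; iTRAQ controls are 113/115/117 and
    treatments 114/116/118.
    """

    iodo_map: Mapping[str, tuple[str, int]]
    itraq_map: Mapping[str, tuple[str, int]]
    replicates: tuple[str, ...] = ("rep1", "rep2", "rep3")

    def __post_init__(self) -> None:
        _validate_map("iodo", self.iodo_map, IODO_LABELS)
        _validate_map("itraq", self.itraq_map, ITRAQ_LABELS)
        if self.timepoints != _timepoints(self.itraq_map):
            raise DesignError("iodoTMT and iTRAQ maps cover different timepoints")
        if not self.replicates:
            raise DesignError("at least one replicate required")

    @property
    def timepoints(self) -> tuple[int, ...]:
        return _timepoints(self.iodo_map)

    def pair(self, space: str, timepoint: int) -> tuple[str, str]:
        """(control label, treated label) for one timepoint in one space."""
        mapping = self.iodo_map if space == "iodo" else self.itraq_map
        control = treated = None
        for label, (cond, tp) in mapping.items():
            if tp == timepoint:
                if cond == CONTROL:
                    control = label
                else:
                    treated = label
        if control is None or treated is None:
            raise DesignError(f"timepoint {timepoint} not paired in {space} map")
        return control, treated

    @classmethod
    def default(cls, replicates: tuple[str, ...] = ("rep1", "rep2", "rep3")) -> "ChannelDesign":
        tps = (5, 30, 120)
        iodo = {}
        itraq = {}
        for i, tp in enumerate(tps):
            iodo[IODO_LABELS[2 * i]] = (CONTROL, tp)
            iodo[IODO_LABELS[2 * i + 1]] = (TREATED, tp)
            itraq[ITRAQ_LABELS[2 * i]] = (CONTROL, tp)
            itraq[ITRAQ_LABELS[2 * i + 1]] = (TREATED, tp)
        return cls(iodo_map=iodo, itraq_map=itraq, replicates=tuple(replicates))


def _timepoints(mapping: Mapping[str, tuple[str, int]]) -> tuple[int, ...]:
    return tuple(sorted({tp for _, tp in mapping.values()}))


def _validate_map(
    name: str, mapping: Mapping[str, tuple[str, int]], labels: tuple[str, ...]
) -> None:
    if set(mapping) != set(labels):
        raise DesignError(
            f"{name} map must use exactly the labels {labels}, got {sorted(mapping)}"
        )
    for label, (cond, tp) in mapping.items():
        if cond not in (CONTROL, TREATED):
            raise DesignError(f"{name} label {label}: condition {cond!r} invalid")
    for tp in _timepoints(mapping):
        conds = sorted(cond for cond, t in mapping.values() if t == tp)
        if conds != [CONTROL, TREATED]:
            raise DesignError(
                f"{name} map: timepoint {tp} needs exactly one control and one "
                f"treated label, got {conds}"
            )


def read_design(source: Union[str, TextIO]) -> ChannelDesign:
    """Read a channel design from YAML.

    Expected layout::

        replicates: [rep1, rep2, rep3]
        iodo:
          "126": control,5
          "127": treated,5
          ...
        itraq:
          "113": control,5
          ...

    Values may also be two-element lists ``[control, 5]``.
    """
    if isinstance(source, str):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, dict) or "iodo" not in doc or "itraq" not in doc:
        raise DesignError("design config needs 'iodo' and 'itraq' sections")

    def parse_section(section: Mapping) -> dict[str, tuple[str, int]]:
        out = {}
        for label, value in section.items():
            if isinstance(value, str):
                cond, tp = (part.strip() for part in value.split(","))
            else:
                cond, tp = value
            out[str(label)] = (str(cond), int(tp))
        return out

    replicates = tuple(str(r) for r in doc.get("replicates", ("rep1", "rep2", "rep3")))
    return ChannelDesign(
        iodo_map=parse_section(doc["iodo"]),
        itraq_map=parse_section(doc["itraq"]),
        replicates=replicates,
    )


def write_design(design: ChannelDesign, target: Union[str, TextIO]) -> None:
    doc = {
        "replicates": list(design.replicates),
        "iodo": {lab: f"{cond},{tp}" for lab, (cond, tp) in sorted(design.iodo_map.items())},
        "itraq": {lab: f"{cond},{tp}" for lab, (cond, tp) in sorted(design.itraq_map.items())},
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if isinstance(target, str):
        with open(target, "w") as fh:
            fh.write(text)
    else:
        target.write(text)
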