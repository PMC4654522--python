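"""Experimental design: samples, iTRAQ channel groups, and the control channel.

The study layout this package targets is a two-tissue (pericarp, endosperm),
three-stage (10, 20, 33 days after pollination) kernel development experiment
quantified with 8-plex isobaric labelling.  Six biological samples N1..N6 are
split into two labelling groups by tissue; within each group the three stages
are labelled with reporter channels 114/115/116 and channel 113 carries the
common control sample, so that all quantitation is expressed as ratios to one
reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

TISSUES = ("pericarp", "endosperm")
STAGES_DAP = (10, 20, 33)
CONTROL_CHANNEL = "113"
REPORTER_CHANNELS = ("114", "115", "116")
ALL_CHANNELS = (CONTROL_CHANNEL,) + REPORTER_CHANNELS


class DesignError(ValueError):
    """A sample design violates its structural invariants."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    tissue: str
    stage_dap: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise DesignError(
                f"sample {self.sample_id}: unknown tissue {self.tissue!r} "
                f"(expected one of {TISSUES})"
            )
        if self.stage_dap not in STAGES_DAP:
            raise DesignError(
                f"sample {self.sample_id}: unknown stage {self.stage_dap!r} "
                f"(expected one of {STAGES_DAP})"
            )


@dataclass(frozen=True)
class ChannelGroup:
    """One isobaric labelling run: a map from channel label to sample id."""

    group_id: int
    channels: Mapping[str, str]

    def reporter_samples(self) -> tuple[str, ...]:
        return tuple(self.channels[c] for c in REPORTER_CHANNELS)


@dataclass
class SampleDesign:
    samples: list[Sample]
    groups: list[ChannelGroup]
    control_channel: str = CONTROL_CHANNEL
    control_sample: str = "N1"

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ #
    # validation

    def validate(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise DesignError("duplicate sample ids in design")
        if self.control_sample not in sample_ids:
            raise DesignError(
                f"control sample {self.control_sample!r} is not a declared sample"
            )
        pairs = [(s.tissue, s.stage_dap) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise DesignError("(tissue, stage) pairs must be unique across samples")

        seen_reporter: dict[str, int] = {}
        group_ids = set()
        for g in self.groups:
            if g.group_id in group_ids:
                raise DesignError(f"duplicate group id {g.group_id}")
            group_ids.add(g.group_id)
            missing = [c for c in ALL_CHANNELS if c not in g.channels]
            if missing:
                raise DesignError(
                    f"group {g.group_id}: missing channel(s) {', '.join(missing)}"
                )
            extra = [c for c in g.channels if c not in ALL_CHANNELS]
            if extra:
                raise DesignError(
                    f"group {g.group_id}: unknown channel(s) {', '.join(extra)}"
                )
            if g.channels[self.control_channel] != self.control_sample:
                raise DesignError(
                    f"group {g.group_id}: channel {self.control_channel} must carry "
                    f"the control sample {self.control_sample!r}"
                )
            reporters = g.reporter_samples()
            if len(set(reporters)) != len(reporters):
                raise DesignError(
                    f"group {g.group_id}: reporter channels must carry distinct samples"
                )
            for sid in reporters:
                if sid not in sample_ids:
                    raise DesignError(
                        f"group {g.group_id}: unknown sample {sid!r} in channel map"
                    )
                if sid in seen_reporter:
                    raise DesignError(
                        f"sample {sid} assigned to reporter channels of both "
                        f"group {seen_reporter[sid]} and group {g.group_id}"
                    )
                seen_reporter[sid] = g.group_id
        unassigned = [sid for sid in sample_ids if sid not in seen_reporter]
        if unassigned:
            raise DesignError(
                f"sample(s) {', '.join(unassigned)} not assigned to any reporter channel"
            )

    # ------------------------------------------------------------------ #
    # lookups

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group(self, group_id: int) -> ChannelGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def group_ids(self) -> list[int]:
        return [g.group_id for g in self.groups]

    def sample_channel(self, sample_id: str) -> tuple[int, str]:
        """(group_id, reporter channel) where this sample was labelled."""
        for g in self.groups:
            for c in REPORTER_CHANNELS:
                if g.channels[c] == sample_id:
                    return g.group_id, c
        raise KeyError(sample_id)

    def samples_by_tissue(self, tissue: str) -> list[Sample]:
        if tissue not in TISSUES:
            raise DesignError(f"unknown tissue {tissue!r}")
        out = [s for s in self.samples if s.tissue == tissue]
        return sorted(out, key=lambda s: s.stage_dap)

    def tissue_of(self, sample_id: str) -> str:
        return self.sample(sample_id).tissue

    def stage_of(self, sample_id: str) -> int:
        return self.sample(sample_id).stage_dap

    # ------------------------------------------------------------------ #
    # serialization

    def to_dict(self) -> dict:
        return {
            "control_channel": self.control_channel,
            "control_sample": self.control_sample,
            "samples": [
                {"id": s.sample_id, "tissue": s.tissue, "stage_dap": s.stage_dap}
                for s in self.samples
            ],
            "groups": [
                {"id": g.group_id, "channels": dict(g.channels)} for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleDesign":
        try:
            samples = [
                Sample(str(s["id"]), str(s["tissue"]), int(s["stage_dap"]))
                for s in d["samples"]
            ]
            groups = [
                ChannelGroup(int(g["id"]), {str(k): str(v) for k, v in g["channels"].items()})
                for g in d["groups"]
            ]
        except KeyError as e:
            raise DesignError(f"design document missing required field: {e}") from e
        return cls(
            samples=samples,
            groups=groups,
            control_channel=str(d.get("control_channel", CONTROL_CHANNEL)),
            control_sample=str(d.get("control_sample", "N1")),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def read_design(path: str | Path) -> SampleDesign:
    """Read a YAML/JSON design document and validate it."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise DesignError(f"{path}: design document is not a mapping")
    return SampleDesign.from_dict(doc)


def default_study_design() -> SampleDesign:
    """The two-group kernel development layout.

    N1–N3 pericarp and N4–N6 endosperm at 10/20/33 DAP on reporter channels
    114/115/116; N1 doubles as the 113 control in both groups, which is the
    only reading under which cross-tissue ratios are well defined.
    """
    samples = [
        Sample("N1", "pericarp", 10),
        Sample("N2", "pericarp", 20),
        Sample("N3", "pericarp", 33),
        Sample("N4", "endosperm", 10),
        Sample("N5", "endosperm", 20),
        Sample("N6", "endosperm", 33),
    ]
    groups = [
        ChannelGroup(1, {"113": "N1", "114": "N1", "115": "N2", "116": "N3"}),
        ChannelGroup(2, {"113": "N1", "114": "N4", "115": "N5", "116": "N6"}),
    ]
    return SampleDesign(samples=samples, groups=groups)
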