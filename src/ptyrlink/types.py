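"""Core containers shared across the pipeline.

The pipeline moves through a fixed sequence of matrix stages:

``raw_intensity`` (peptide x channel, one 10-plex run)
-> ``loading_normalized`` (channel loading correction applied)
-> ``bridged`` (peptide x (line, timepoint, replicate), runs joined via the
   bridge channel)
-> ``log2fc`` (log2 fold change over each line/replicate's own 0 s sample)
-> ``replicate_mean`` (peptide x (line, timepoint), averaged over replicates)

A :class:`PhosphoMatrix` carries its stage tag so downstream operations can
refuse inputs taken from the wrong point in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

N_CHANNELS = 10

#: Sentinel sample label for the per-run bridge ("batch") channel.
BRIDGE = "BRIDGE"

#: (cell line, timepoint in seconds, replicate index)
SampleKey = tuple[str, int, int]

STAGES = (
    "raw_intensity",
    "loading_normalized",
    "bridged",
    "log2fc",
    "replicate_mean",
)

RUN_STAGES = ("raw_intensity", "loading_normalized")
SAMPLE_STAGES = ("bridged", "log2fc")


class PtyrlinkError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(PtyrlinkError):
    """An invalid configuration value; the message names the field."""


class StageError(PtyrlinkError):
    """A matrix was supplied at the wrong processing stage."""


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with its quality metrics.

    ``reporter_intensity`` holds the ten isobaric reporter-ion intensities in
    channel order; missing channels are NaN.  ``peptide_id`` is the sequence
    plus the ordered phosphosite annotation, so singly and doubly
    phosphorylated forms of the same sequence are distinct peptides.
    """

    peptide_id: str
    run_id: str
    search_rank: int
    ion_score: float
    isolation_interference_pct: float
    reporter_intensity: tuple[float, ...]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if len(self.reporter_intensity) != N_CHANNELS:
            raise ValueError(
                f"reporter_intensity must have {N_CHANNELS} entries, "
                f"got {len(self.reporter_intensity)}"
            )
        if not (0.0 <= self.isolation_interference_pct <= 100.0):
            raise ValueError(
                "isolation_interference_pct must lie in [0, 100], got "
                f"{self.isolation_interference_pct}"
            )
        for v in self.reporter_intensity:
            if not math.isnan(v) and v < 0:
                raise ValueError(f"negative reporter intensity {v}")
        if self.search_rank < 1:
            raise ValueError(f"search_rank must be >= 1, got {self.search_rank}")

    @property
    def mean_signal(self) -> float:
        """Arithmetic mean reporter intensity over non-missing channels."""
        vals = np.asarray(self.reporter_intensity, dtype=float)
        if np.isnan(vals).all():
            return float("nan")
        return float(np.nanmean(vals))

    @property
    def n_missing_channels(self) -> int:
        return int(np.isnan(np.asarray(self.reporter_intensity, float)).sum())


@dataclass(frozen=True)
class PlexDesign:
    """Channel assignment for one 10-plex run.

    ``channel_map`` maps channel index (0-9) to either a
    ``(line, timepoint_s, replicate)`` triple or the :data:`BRIDGE` sentinel.
    Structural validity (10 channels, unique sample labels) is enforced here;
    bridge-count and design-completeness checks live in
    :func:`ptyrlink.io.validate_design`, which reports rather than raises.
    """

    run_id: str
    channel_map: Mapping[int, Union[str, SampleKey]]

    def __post_init__(self) -> None:
        channels = sorted(self.channel_map)
        if channels != list(range(N_CHANNELS)):
            raise ValueError(
                f"run {self.run_id}: channel_map must cover channels "
                f"0..{N_CHANNELS - 1}, got {channels}"
            )
        samples = [v for v in self.channel_map.values() if v != BRIDGE]
        if len(samples) != len(set(samples)):
            raise ValueError(f"run {self.run_id}: duplicate sample labels")

    @property
    def bridge_channels(self) -> list[int]:
        return [c for c, v in self.channel_map.items() if v == BRIDGE]

    @property
    def bridge_channel(self) -> int:
        bcs = self.bridge_channels
        if len(bcs) != 1:
            raise ValueError(
                f"run {self.run_id}: expected exactly one bridge channel, "
                f"found {len(bcs)}"
            )
        return bcs[0]

    def sample_channels(self) -> dict[int, SampleKey]:
        return {c: v for c, v in self.channel_map.items() if v != BRIDGE}


@dataclass
class PhosphoMatrix:
    """Peptide x sample matrix with a processing-stage tag.

    Run-level stages (``raw_intensity``, ``loading_normalized``) use integer
    channel columns; sample-level stages use a ``(line, timepoint_s,
    replicate)`` MultiIndex; ``replicate_mean`` uses ``(line, timepoint_s)``.
    """

    values: pd.DataFrame
    stage: str
    run_id: str | None = None
    replicate_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate peptide ids in matrix index")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample columns in matrix")

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"matrix is at stage {self.stage!r}; expected {' or '.join(stages)}"
            )

    @property
    def peptides(self) -> pd.Index:
        return self.values.index

    @property
    def lines(self) -> list[str]:
        self.require_stage(*SAMPLE_STAGES, "replicate_mean")
        return list(pd.unique(self.values.columns.get_level_values("line")))

    @property
    def timepoints_s(self) -> list[int]:
        self.require_stage(*SAMPLE_STAGES, "replicate_mean")
        return sorted(
            int(t)
            for t in pd.unique(self.values.columns.get_level_values("timepoint_s"))
        )

    @property
    def replicates(self) -> list[int]:
        self.require_stage(*SAMPLE_STAGES)
        return sorted(
            int(r) for r in pd.unique(self.values.columns.get_level_values("replicate"))
        )

    def copy(self) -> "PhosphoMatrix":
        return PhosphoMatrix(
            values=self.values.copy(),
            stage=self.stage,
            run_id=self.run_id,
            replicate_counts=None
            if self.replicate_counts is None
            else self.replicate_counts.copy(),
        )


def sample_columns(keys: Sequence[SampleKey]) -> pd.MultiIndex:
    """Build the canonical sample-level column index."""
    return pd.MultiIndex.from_tuples(
        [(line, int(t), int(r)) for line, t, r in keys],
        names=["line", "timepoint_s", "replicate"],
    )


def condition_columns(keys: Sequence[tuple[str, int]]) -> pd.MultiIndex:
    """Column index for replicate-mean matrices: (line, timepoint_s)."""
    return pd.MultiIndex.from_tuples(
        [(line, int(t)) for line, t in keys], names=["line", "timepoint_s"]
    )
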