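"""PSM filtering, peptide rollup, and multi-level TMT normalization.

The quality filter mirrors the standard quantitative pTyr workflow: keep a
PSM only if it is the top-ranked match for its spectrum, its search engine
ion score exceeds 15, the co-isolation interference is below 40%, and the
average reporter-ion signal exceeds 1,000; PSMs with any missing reporter
channel are dropped.  All thresholds are strict inequalities.

Normalization is three-level:

1. *loading*: each channel is divided by its crude-lysate median relative to
   the geometric mean of the run's medians, removing per-channel loading
   differences (only channel ratios matter; the geometric-mean centering
   cancels in the later fold-change step);
2. *bridge*: within each run every peptide is divided by its value in the
   bridge ("batch") channel, making peptide values comparable across runs;
3. *basal*: each (line, replicate) trajectory is expressed as log2 fold
   change over that line/replicate's own unstimulated (0 s) sample.

Missingness propagates throughout; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .types import (
    BRIDGE,
    N_CHANNELS,
    PhosphoMatrix,
    PlexDesign,
    PsmRecord,
    PtyrlinkError,
    sample_columns,
)

FILTER_RULES = ("rank", "score", "interference", "low_signal", "missing_channel")


@dataclass(frozen=True)
class FilterThresholds:
    """PSM quality gates.  Score, interference and signal bounds are strict."""

    max_rank: int = 1
    min_ion_score: float = 15.0
    max_interference_pct: float = 40.0
    min_mean_signal: float = 1000.0
    drop_any_missing_channel: bool = True

    def __post_init__(self) -> None:
        for name in ("min_ion_score", "max_interference_pct", "min_mean_signal"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")

    def violations(self, psm: PsmRecord) -> list[str]:
        """Names of every rule the record fails (possibly several)."""
        v = []
        if psm.search_rank > self.max_rank:
            v.append("rank")
        if not psm.ion_score > self.min_ion_score:
            v.append("score")
        if not psm.isolation_interference_pct < self.max_interference_pct:
            v.append("interference")
        mean = psm.mean_signal
        if not mean > self.min_mean_signal:  # NaN mean also fails
            v.append("low_signal")
        if self.drop_any_missing_channel and psm.n_missing_channels > 0:
            v.append("missing_channel")
        return v


@dataclass
class FilterAudit:
    n_input: int = 0
    n_kept: int = 0
    rejections: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in FILTER_RULES}
    )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "rejections": dict(self.rejections),
        }


@dataclass(frozen=True)
class PresenceRule:
    """Condition-coverage requirement applied to the log2FC matrix.

    A peptide is retained when every (line, timepoint) condition carries at
    least ``min_replicates_per_condition`` quantified replicates.  With
    ``require_all_conditions=False`` the check applies only to conditions in
    which the peptide was observed at all.
    """

    min_replicates_per_condition: int = 2
    require_all_conditions: bool = True

    def __post_init__(self) -> None:
        if self.min_replicates_per_condition < 1:
            raise ValueError("min_replicates_per_condition must be >= 1")


def filter_psms(
    psms: Iterable[PsmRecord], thresholds: FilterThresholds | None = None
) -> tuple[list[PsmRecord], FilterAudit]:
    """Apply the quality gates; a rejected record may increment several
    per-rule counters."""
    thresholds = thresholds or FilterThresholds()
    audit = FilterAudit()
    kept: list[PsmRecord] = []
    for psm in psms:
        audit.n_input += 1
        violations = thresholds.violations(psm)
        if violations:
            for rule in violations:
                audit.rejections[rule] += 1
        else:
            kept.append(psm)
    audit.n_kept = len(kept)
    return kept, audit


def rollup_peptides(
    psms: Sequence[PsmRecord], design: PlexDesign, key: str = "peptide_id"
) -> PhosphoMatrix:
    """Sum reporter intensities over PSMs of each unique phosphopeptide.

    With ``key="protein_id"`` the same contract yields the convenience
    protein-level rollup (sum over all unique peptides of a protein).
    """
    if key not in ("peptide_id", "protein_id"):
        raise ValueError("key must be 'peptide_id' or 'protein_id'")
    mismatched = sorted({p.run_id for p in psms} - {design.run_id})
    if mismatched:
        raise PtyrlinkError(
            f"PSMs from run(s) {mismatched} do not match design run "
            f"{design.run_id!r}"
        )
    if not psms:
        return PhosphoMatrix(
            values=pd.DataFrame(columns=range(N_CHANNELS), dtype=float),
            stage="raw_intensity",
            run_id=design.run_id,
        )
    data = pd.DataFrame(
        [p.reporter_intensity for p in psms],
        index=[getattr(p, key) for p in psms],
        columns=range(N_CHANNELS),
        dtype=float,
    )
    summed = data.groupby(level=0, sort=True).sum(min_count=1)
    return PhosphoMatrix(values=summed, stage="raw_intensity", run_id=design.run_id)


def loading_normalize(
    matrix: PhosphoMatrix, crude_medians: np.ndarray
) -> PhosphoMatrix:
    """Divide each channel by its crude-lysate median relative to the run's
    geometric-mean median."""
    matrix.require_stage("raw_intensity")
    med = np.asarray(crude_medians, dtype=float)
    if med.shape != (N_CHANNELS,):
        raise ValueError(f"expected {N_CHANNELS} crude medians, got {med.shape}")
    if not (med > 0).all():
        raise PtyrlinkError("crude medians must all be strictly positive")
    factors = med / gmean(med)
    values = matrix.values / factors
    return PhosphoMatrix(
        values=values, stage="loading_normalized", run_id=matrix.run_id
    )


def bridge_ratio(
    matrix: PhosphoMatrix, design: PlexDesign, method: str = "per_peptide"
) -> PhosphoMatrix:
    """Express one run's channels relative to its bridge channel.

    ``per_peptide`` (default) divides each peptide's channels by that
    peptide's own bridge value (internal-reference scaling); a peptide with
    no positive bridge value becomes missing for the whole run.
    ``global_factor`` instead divides the run by the median bridge intensity,
    a single run-level factor.
    """
    matrix.require_stage("loading_normalized", "raw_intensity")
    bc = design.bridge_channel
    values = matrix.values.where(matrix.values > 0)
    bridge = values[bc]
    if method == "per_peptide":
        ratio = values.div(bridge, axis=0)
    elif method == "global_factor":
        scale = float(np.nanmedian(bridge.to_numpy()))
        if not np.isfinite(scale) or scale <= 0:
            raise PtyrlinkError(
                f"run {design.run_id}: no usable bridge intensities"
            )
        ratio = values / scale
    else:
        raise ValueError(f"unknown bridge method {method!r}")
    return PhosphoMatrix(values=ratio, stage="loading_normalized",
                         run_id=matrix.run_id)


def bridge_normalize(
    runs: Mapping[str, PhosphoMatrix],
    designs: Mapping[str, PlexDesign],
    method: str = "per_peptide",
) -> PhosphoMatrix:
    """Bridge-normalize every run and join them into one sample-level matrix.

    Peptides absent (or without a bridge value) in a run are missing for that
    run's samples and retained wherever they were observed.
    """
    pieces = []
    for run_id in sorted(runs):
        if run_id not in designs:
            raise PtyrlinkError(f"no design for run {run_id}")
        design = designs[run_id]
        ratio = bridge_ratio(runs[run_id], design, method=method)
        chans = design.sample_channels()
        ordered = sorted(chans)
        block = ratio.values[ordered]
        block.columns = sample_columns([chans[c] for c in ordered])
        pieces.append(block)
    combined = pd.concat(pieces, axis=1, join="outer").sort_index()
    combined = combined.sort_index(axis=1)
    return PhosphoMatrix(values=combined, stage="bridged")


def basal_log2fc(matrix: PhosphoMatrix) -> PhosphoMatrix:
    """log2 fold change of each sample over its line/replicate 0 s sample.

    0 s columns become exactly 0 and are retained.  A (line, replicate)
    trajectory whose basal value is missing becomes missing throughout.
    """
    matrix.require_stage("bridged")
    values = matrix.values.where(matrix.values > 0)
    out = pd.DataFrame(
        np.nan, index=values.index, columns=values.columns, dtype=float
    )
    cols = values.columns
    for line, rep in sorted({(c[0], c[2]) for c in cols}):
        group = [c for c in cols if c[0] == line and c[2] == rep]
        basal_key = (line, 0, rep)
        if basal_key not in values.columns:
            continue  # trajectory set stays missing
        basal = values[basal_key]
        for c in group:
            out[c] = np.log2(values[c] / basal)
    return PhosphoMatrix(values=out, stage="log2fc")


def replicate_mean(matrix: PhosphoMatrix) -> PhosphoMatrix:
    """Mean log2FC over available replicates, with contributing counts."""
    matrix.require_stage("log2fc")
    grouped = matrix.values.T.groupby(level=["line", "timepoint_s"], sort=True)
    means = grouped.mean().T
    counts = grouped.count().T
    means = means.where(counts > 0)
    return PhosphoMatrix(
        values=means, stage="replicate_mean", replicate_counts=counts
    )


def presence_filter(matrix: PhosphoMatrix, rule: PresenceRule) -> PhosphoMatrix:
    """Retain peptides meeting the per-condition replicate coverage rule."""
    matrix.require_stage("log2fc")
    notna = matrix.values.notna()
    counts = notna.T.groupby(level=["line", "timepoint_s"], sort=True).sum().T
    if rule.require_all_conditions:
        keep = (counts >= rule.min_replicates_per_condition).all(axis=1)
    else:
        observed = counts > 0
        ok = (counts >= rule.min_replicates_per_condition) | ~observed
        keep = ok.all(axis=1) & observed.any(axis=1)
    filtered = matrix.values.loc[keep[keep].index]
    return PhosphoMatrix(values=filtered, stage="log2fc")
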