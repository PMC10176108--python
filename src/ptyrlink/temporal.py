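"""Time-course feature extraction and per-timepoint responsiveness calls.

The headline scalar summary of a peptide's response in one cell line is the
area under its log2FC-vs-time curve (trapezoid rule on the measured
timepoints, log2FC*seconds; negative excursions contribute negatively).
Per-timepoint log2FC values are available as an alternative or additional
feature mode for downstream regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import PhosphoMatrix, PtyrlinkError

FEATURE_MODES = ("auc", "per_timepoint", "combined")


@dataclass
class FeatureMatrix:
    """Cell line x feature matrix ready for regression.

    ``feature_meta`` has one row per column with the peptide id and feature
    kind (``auc`` or ``log2fc@<t>``).  Features not quantified in every line
    are dropped, so ``values`` has no missing cells.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in FEATURE_MODES:
            raise ValueError(f"unknown feature mode {self.mode!r}")
        if len(self.feature_meta) != self.values.shape[1]:
            raise ValueError("feature_meta length must equal column count")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing cells")


def auc_feature(
    trajectory: Mapping[int, float] | pd.Series, timepoints_s: Sequence[int]
) -> float:
    """Trapezoidal area under log2FC over the time course.

    Returns NaN when any requested timepoint is missing.
    """
    ts = list(timepoints_s)
    if ts != sorted(ts) or len(set(ts)) != len(ts):
        raise ValueError("timepoints must be strictly increasing")
    traj = pd.Series(dict(trajectory)) if not isinstance(trajectory, pd.Series) \
        else trajectory
    try:
        y = np.asarray([float(traj[t]) for t in ts])
    except KeyError:
        return float("nan")
    if np.isnan(y).any():
        return float("nan")
    return float(np.trapezoid(y, x=np.asarray(ts, dtype=float)))


def line_trajectories(matrix: PhosphoMatrix, line: str) -> pd.DataFrame:
    """Peptide x timepoint table of replicate-mean log2FC for one line."""
    matrix.require_stage("replicate_mean")
    block = matrix.values.xs(line, axis=1, level="line")
    block.columns = [int(t) for t in block.columns]
    return block.sort_index(axis=1)


def auc_matrix(matrix: PhosphoMatrix) -> pd.DataFrame:
    """Line x peptide matrix of AUC features (NaN where incomplete)."""
    matrix.require_stage("replicate_mean")
    ts = matrix.timepoints_s
    rows = {}
    for line in matrix.lines:
        traj = line_trajectories(matrix, line)
        y = traj[ts].to_numpy(dtype=float)
        auc = np.trapezoid(y, x=np.asarray(ts, dtype=float), axis=1)
        auc[np.isnan(y).any(axis=1)] = np.nan
        rows[line] = pd.Series(auc, index=traj.index)
    return pd.DataFrame(rows).T


def feature_matrix(matrix: PhosphoMatrix, mode: str = "auc") -> FeatureMatrix:
    """Assemble the observation (line) x feature matrix for modeling.

    ``per_timepoint`` uses the stimulated timepoints only (0 s is identically
    zero after basal normalization); ``combined`` concatenates AUC and
    per-timepoint features.
    """
    matrix.require_stage("replicate_mean")
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}")
    blocks: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    if mode in ("auc", "combined"):
        auc = auc_matrix(matrix)
        auc.columns = [f"{p}::auc" for p in auc.columns]
        meta_rows += [
            {"feature": c, "peptide_id": c.rsplit("::", 1)[0], "kind": "auc"}
            for c in auc.columns
        ]
        blocks.append(auc)
    if mode in ("per_timepoint", "combined"):
        stim = [t for t in matrix.timepoints_s if t != 0]
        wide = {}
        for line in matrix.lines:
            traj = line_trajectories(matrix, line)[stim]
            flat = traj.stack(future_stack=True)
            flat.index = [f"{p}::log2fc@{t}" for p, t in flat.index]
            wide[line] = flat
        tp = pd.DataFrame(wide).T
        meta_rows += [
            {
                "feature": c,
                "peptide_id": c.rsplit("::", 1)[0],
                "kind": c.rsplit("::", 1)[1],
            }
            for c in tp.columns
        ]
        blocks.append(tp)
    values = pd.concat(blocks, axis=1)
    complete = values.columns[values.notna().all(axis=0)]
    values = values[complete]
    meta = pd.DataFrame(meta_rows).set_index("feature").loc[complete].reset_index()
    return FeatureMatrix(values=values, feature_meta=meta, mode=mode)


def network_sum(matrix: PhosphoMatrix) -> pd.DataFrame:
    """Line x timepoint summed (and mean) log2FC over the common peptide set.

    Expects a presence-filtered replicate-mean matrix; raises on an empty or
    incomplete peptide set rather than summing over missing cells.
    """
    matrix.require_stage("replicate_mean")
    if matrix.values.shape[0] == 0:
        raise PtyrlinkError("network_sum: empty peptide set")
    if matrix.values.isna().any().any():
        raise PtyrlinkError(
            "network_sum requires a complete matrix; apply presence_filter first"
        )
    sums = matrix.values.sum(axis=0)
    means = matrix.values.mean(axis=0)
    out = pd.DataFrame({"sum_log2fc": sums, "mean_log2fc": means})
    out.index.names = ["line", "timepoint_s"]
    return out.reset_index()


@dataclass
class ResponsiveResult:
    pvalues: pd.DataFrame  # peptide x stimulated timepoint
    responsive: pd.Series  # bool per tested peptide
    fraction: float
    n_tested: int
    n_responsive: int


def responsive_sites(
    matrix: PhosphoMatrix,
    alpha: float = 0.05,
    line: str | None = None,
    correction: str | None = None,
) -> ResponsiveResult:
    """Two-sided one-sample t tests of replicate log2FC against 0.

    Basal normalization turns the stimulated-vs-unstimulated contrast into a
    one-sample test per (peptide, stimulated timepoint).  A peptide is called
    responsive when any stimulated timepoint is significant at ``alpha``.
    Cells with fewer than 2 replicates (or zero variance) are untestable;
    peptides with no testable cell are excluded from the denominator.
    ``correction="bh"`` applies Benjamini-Hochberg across all tests (off by
    default).
    """
    matrix.require_stage("log2fc")
    values = matrix.values
    if line is not None:
        mask = values.columns.get_level_values("line") == line
        values = values.loc[:, mask]
    stim = sorted(
        t for t in set(values.columns.get_level_values("timepoint_s")) if t != 0
    )
    pvals = pd.DataFrame(np.nan, index=values.index, columns=stim, dtype=float)
    for t in stim:
        block = values.xs(t, axis=1, level="timepoint_s")
        arr = block.to_numpy(dtype=float)
        n = (~np.isnan(arr)).sum(axis=1)
        sd = np.nanstd(arr, axis=1, ddof=1)
        import warnings as _warnings

        with np.errstate(invalid="ignore", divide="ignore"), \
                _warnings.catch_warnings():
            # degenerate cells (n < 2, zero variance) are masked below
            _warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_1samp(arr, 0.0, axis=1, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
        p[(n < 2) | ~(sd > 0)] = np.nan
        pvals[t] = p
    if correction == "bh":
        flat = pvals.to_numpy().ravel()
        ok = ~np.isnan(flat)
        if ok.any():
            from statsmodels.stats.multitest import multipletests

            adj = flat.copy()
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
            pvals = pd.DataFrame(
                adj.reshape(pvals.shape), index=pvals.index, columns=pvals.columns
            )
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    testable = pvals.notna().any(axis=1)
    responsive = (pvals < alpha).any(axis=1)[testable]
    n_tested = int(testable.sum())
    n_resp = int(responsive.sum())
    fraction = n_resp / n_tested if n_tested else float("nan")
    return ResponsiveResult(
        pvalues=pvals,
        responsive=responsive,
        fraction=fraction,
        n_tested=n_tested,
        n_responsive=n_resp,
    )
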