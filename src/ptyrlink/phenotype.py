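"""Scalar phenotype responses from raw time series.

Three phenotypes enter the regression stage:

* proliferation: slope of ln(confluency) vs time (exponential growth rate,
  1/h) over a configurable window, reported as the EGF minus no-EGF delta;
* migration: wound-closure rate (negative least-squares slope of wound width
  vs time, width units/h, restricted to the pre-closure window), again as an
  EGF delta;
* receptor internalization: mean pHrodo fluorescence over the untransfected
  control mean, a dimensionless index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as pio
from .types import PtyrlinkError

PHENOTYPES = ("proliferation", "migration", "internalization")


def proliferation_rate(
    times_h: Sequence[float],
    confluency_pct: Sequence[float],
    window_h: tuple[float, float] = (0.0, 24.0),
) -> float:
    """Exponential growth rate (1/h): slope of ln(confluency) vs time."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(confluency_pct, dtype=float)
    if (c <= 0).any():
        raise PtyrlinkError("confluency values must be strictly positive")
    lo, hi = window_h
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise PtyrlinkError(
            f"proliferation window [{lo}, {hi}] h covers fewer than 3 points"
        )
    res = stats.linregress(t[mask], np.log(c[mask]))
    return float(res.slope)


def migration_rate(
    times_h: Sequence[float], wound_width: Sequence[float]
) -> float:
    """Wound-closure rate (width units/h) on the pre-closure window."""
    t = np.asarray(times_h, dtype=float)
    w = np.asarray(wound_width, dtype=float)
    if (w < 0).any():
        raise PtyrlinkError("wound widths must be nonnegative")
    if len(t) < 3:
        raise PtyrlinkError("migration series needs at least 3 points")
    if w[0] <= 0:
        raise PtyrlinkError("wound is already closed at the first timepoint")
    open_mask = w > 0
    # pre-closure window: points up to (excluding) the first fully closed one
    if (~open_mask).any():
        first_closed = int(np.argmax(~open_mask))
        open_mask = np.zeros_like(open_mask)
        open_mask[:first_closed] = True
    if open_mask.sum() < 2:
        raise PtyrlinkError("fewer than 2 pre-closure points")
    res = stats.linregress(t[open_mask], w[open_mask])
    return float(-res.slope)


def internalization_index(
    sample_fluor: Sequence[float], control_fluor: Sequence[float]
) -> float:
    """Mean sample fluorescence normalized to the untransfected control."""
    s = np.asarray(sample_fluor, dtype=float)
    c = np.asarray(control_fluor, dtype=float)
    if len(s) == 0 or len(c) == 0:
        raise PtyrlinkError("internalization requires sample and control values")
    cm = float(np.mean(c))
    if cm <= 0:
        raise PtyrlinkError("control fluorescence mean must be positive")
    return float(np.mean(s)) / cm


@dataclass
class PhenotypeTable:
    """Per-line scalar phenotypes (means) plus per-replicate values."""

    summary: pd.DataFrame  # line x phenotype
    replicates: pd.DataFrame  # long: line, phenotype, replicate, value

    def target(self, phenotype: str) -> pd.Series:
        if phenotype not in self.summary.columns:
            raise KeyError(phenotype)
        return self.summary[phenotype]


def build_phenotype_table(
    confluency: pd.DataFrame,
    wound: pd.DataFrame,
    internalization: pd.DataFrame,
    window_h: tuple[float, float] = (0.0, 24.0),
) -> PhenotypeTable:
    """Reduce the three raw assay tables to per-line scalar responses.

    Proliferation and migration are EGF-minus-control delta rates computed
    per replicate; internalization is the control-normalized index per
    replicate (control = the :data:`ptyrlink.io.CONTROL_LINE` rows).
    """
    records = []

    for (line, rep), grp in confluency.groupby(["line", "replicate"]):
        rates = {}
        for egf, sub in grp.groupby("egf"):
            sub = sub.sort_values("time_h")
            rates[int(egf)] = proliferation_rate(
                sub["time_h"], sub["confluency_pct"], window_h=window_h
            )
        if 0 in rates and 1 in rates:
            records.append(
                dict(line=line, phenotype="proliferation", replicate=rep,
                     value=rates[1] - rates[0])
            )

    for (line, rep), grp in wound.groupby(["line", "replicate"]):
        rates = {}
        for egf, sub in grp.groupby("egf"):
            sub = sub.sort_values("time_h")
            rates[int(egf)] = migration_rate(sub["time_h"], sub["wound_width_um"])
        if 0 in rates and 1 in rates:
            records.append(
                dict(line=line, phenotype="migration", replicate=rep,
                     value=rates[1] - rates[0])
            )

    controls = internalization[internalization["line"] == pio.CONTROL_LINE]
    if controls.empty:
        raise PtyrlinkError(
            f"internalization table has no {pio.CONTROL_LINE!r} rows"
        )
    samples = internalization[internalization["line"] != pio.CONTROL_LINE]
    control_by_rep = controls.set_index("replicate")["fluorescence"]
    for (line, rep), grp in samples.groupby(["line", "replicate"]):
        if rep in control_by_rep.index:
            ctrl = [float(control_by_rep.loc[rep])]
        else:  # fall back to the pooled control mean
            ctrl = controls["fluorescence"].tolist()
        records.append(
            dict(line=line, phenotype="internalization", replicate=rep,
                 value=internalization_index(grp["fluorescence"], ctrl))
        )

    reps = pd.DataFrame(records)
    summary = (
        reps.pivot_table(index="line", columns="phenotype", values="value",
                         aggfunc="mean")
        .reindex(columns=list(PHENOTYPES))
    )
    if (summary["internalization"].dropna() <= 0).any():
        raise PtyrlinkError("internalization index must be positive")
    return PhenotypeTable(summary=summary, replicates=reps)


def phenotype_correlations(table: PhenotypeTable) -> pd.DataFrame:
    """Pairwise Pearson r across cell lines for the three phenotypes."""
    summary = table.summary.dropna()
    if len(summary) < 3:
        raise PtyrlinkError(
            "phenotype correlations need at least 3 complete lines"
        )
    sd = summary.std(ddof=1)
    if not (sd > 0).all():
        bad = sd.index[~(sd > 0)][0]
        raise PtyrlinkError(f"phenotype {bad!r} has zero variance")
    return summary.corr(method="pearson")
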