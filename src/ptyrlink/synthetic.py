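"""Ground-truth-bearing synthetic study generator.

Emulates the statistical structure of a 9-line x 5-timepoint x 3-replicate
EGF stimulation study multiplexed by timepoint in TMT 10-plexes (9 cell-line
channels plus one bridge channel carrying the WT 2-min sample), so every
downstream stage can be tested against a known truth without any deposited
data.

Responsive peptides follow smooth saturating/peaked latent trajectories

    log2FC(t) = a * (1 - exp(-t/tau)) * exp(-t/kappa)

shared per latent axis and scaled per (peptide, line); the two-parameter
family covers both sustained and transient responses.  Reporter intensities
are drawn lognormally around base abundance x fold change x per-channel
loading factor.  A configurable fraction of junk PSMs each violate at least
one quality filter, with the violation type recorded so the filter stage can
be audited exactly.  Phenotypes are noisy linear functions of planted true
AUC features, rendered as the raw assay time series the phenotype module
consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .types import (
    BRIDGE,
    ConfigError,
    N_CHANNELS,
    PhosphoMatrix,
    PlexDesign,
    PsmRecord,
    condition_columns,
)

DEFAULT_LINES = (
    "WT",
    "Y845F",
    "Y992F",
    "Y1045F",
    "Y1068F",
    "Y1148F",
    "Y1173F",
    "DY5",
    "DY6",
)

#: The bridge channel carries this (line, timepoint) sample in every plex.
BRIDGE_SAMPLE = ("WT", 120)

JUNK_KINDS = ("rank", "score", "interference", "low_signal", "missing_channel")

# Raw-assay rendering constants (see docs/methods.md for rationale).
_PROLIF_BASE = 0.020  # 1/h, unstimulated exponential growth rate
_PROLIF_DELTA = (0.008, 0.012)  # EGF delta rate: offset + scale * z
_MIG_BASE = 15.0  # um/h, unstimulated closure rate
_MIG_DELTA = (8.0, 6.0)
_WOUND_W0 = 800.0  # um
_INT_LOG = (0.4, 0.35)  # log internalization index: offset + scale * z
_CONTROL_FLUOR = 1200.0
_ASSAY_TIMES_H = np.arange(0.0, 24.1, 3.0)
_CONFLUENCY_0 = 5.0  # percent seeded


@dataclass(frozen=True)
class SyntheticStudyConfig:
    n_peptides: int = 300
    lines: tuple[str, ...] = DEFAULT_LINES
    timepoints_s: tuple[int, ...] = (0, 30, 60, 120, 300)
    n_replicates: int = 3
    n_latent_axes: int = 4
    responsive_fraction: float = 0.6
    noise_sd_log2: float = 0.15
    loading_bias_range: tuple[float, float] = (0.7, 1.4)
    n_planted_per_phenotype: int = 5
    planted_phenotype_features: Mapping[str, Sequence[tuple[str, float]]] | None = None
    phenotype_noise_sd: float = 0.1
    junk_psm_fraction: float = 0.1
    psm_duplicate_prob: float = 0.3
    # per-channel missing-at-random dropout; with the missing-channel filter
    # on, this is what makes peptides drop out of individual runs and gives
    # the presence filter real attrition to act on
    dropout_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ConfigError("n_peptides must be >= 1")
        if len(self.lines) < 2 or len(set(self.lines)) != len(self.lines):
            raise ConfigError("lines must be >= 2 unique names")
        if len(self.lines) > N_CHANNELS - 1:
            raise ConfigError(
                f"lines: at most {N_CHANNELS - 1} lines fit one plex beside "
                "the bridge channel"
            )
        ts = list(self.timepoints_s)
        if ts != sorted(set(ts)) or 0 not in ts:
            raise ConfigError(
                "timepoints_s must be strictly increasing and include 0"
            )
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.n_latent_axes < 1:
            raise ConfigError("n_latent_axes must be >= 1")
        for name in ("responsive_fraction", "junk_psm_fraction",
                     "psm_duplicate_prob", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.junk_psm_fraction >= 1.0:
            raise ConfigError("junk_psm_fraction must be < 1")
        for name in ("noise_sd_log2", "phenotype_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        lo, hi = self.loading_bias_range
        if not (0 < lo <= hi):
            raise ConfigError(
                "loading_bias_range must be a positive interval (lo <= hi)"
            )
        if self.n_planted_per_phenotype < 0:
            raise ConfigError("n_planted_per_phenotype must be >= 0")
        if BRIDGE_SAMPLE[1] not in ts:
            raise ConfigError(
                f"timepoints_s must include the bridge timepoint "
                f"{BRIDGE_SAMPLE[1]} s"
            )
        if BRIDGE_SAMPLE[0] not in self.lines:
            raise ConfigError(f"lines must include {BRIDGE_SAMPLE[0]!r}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticStudyConfig":
        data = dict(data)
        for key in ("lines", "timepoints_s", "loading_bias_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["planted_phenotype_features"] is not None:
            d["planted_phenotype_features"] = {
                k: [[p, float(c)] for p, c in v]
                for k, v in d["planted_phenotype_features"].items()
            }
        return d


@dataclass
class GroundTruth:
    """Everything needed to verify downstream recovery."""

    true_log2fc: pd.DataFrame  # peptide x (line, timepoint_s)
    cluster_labels: pd.Series  # peptide -> latent axis id (-1 = flat)
    true_loading_factors: dict[str, np.ndarray]  # run -> per-channel factor
    planted_features: dict[str, list[tuple[str, float]]]
    planted_phenotype_values: pd.DataFrame  # line x phenotype (noise-free z)
    psm_audit: pd.DataFrame  # run_id, psm_index, peptide_id, survive, violation

    def true_auc(self, timepoints_s: Sequence[int]) -> pd.DataFrame:
        """Line x peptide true AUC features from the noise-free log2FC."""
        ts = np.asarray(sorted(timepoints_s), dtype=float)
        out = {}
        for line in self.true_log2fc.columns.get_level_values("line").unique():
            block = self.true_log2fc.xs(line, axis=1, level="line")
            y = block[[int(t) for t in ts]].to_numpy(dtype=float)
            out[line] = pd.Series(
                np.trapezoid(y, x=ts, axis=1), index=block.index
            )
        return pd.DataFrame(out).T


@dataclass
class PhenotypeRawTables:
    confluency: pd.DataFrame
    wound: pd.DataFrame
    internalization: pd.DataFrame


@dataclass
class SyntheticStudy:
    config: SyntheticStudyConfig
    truth: GroundTruth
    psm_tables: dict[str, list[PsmRecord]]
    designs: dict[str, PlexDesign]
    crude_medians: dict[str, np.ndarray]
    phenotypes: PhenotypeRawTables

    def run_ids(self) -> list[str]:
        return sorted(self.psm_tables)


def _trajectory_shapes(
    config: SyntheticStudyConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-axis unit-peak response shapes over the stimulated time course."""
    ts = np.asarray(config.timepoints_s, dtype=float)
    shapes = np.zeros((config.n_latent_axes, len(ts)))
    fine = np.linspace(0.0, ts[-1], 601)
    for k in range(config.n_latent_axes):
        tau = rng.uniform(20.0, 120.0)
        kappa = rng.uniform(150.0, 2500.0)
        f = lambda t: (1.0 - np.exp(-t / tau)) * np.exp(-t / kappa)
        peak = f(fine).max()
        shapes[k] = f(ts) / peak
    return shapes


def _make_truth(
    config: SyntheticStudyConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    peptides = [f"pep{i:04d}_Y{rng.integers(10, 1500)}" for i in
                range(config.n_peptides)]
    # peptide ids must be unique; suffix duplicates deterministically
    seen: dict[str, int] = {}
    uniq = []
    for p in peptides:
        if p in seen:
            seen[p] += 1
            uniq.append(f"{p}.{seen[p]}")
        else:
            seen[p] = 0
            uniq.append(p)
    peptides = uniq

    shapes = _trajectory_shapes(config, rng)
    n_resp = int(round(config.n_peptides * config.responsive_fraction))
    resp_idx = rng.choice(config.n_peptides, size=n_resp, replace=False)
    labels = np.full(config.n_peptides, -1, dtype=int)
    labels[resp_idx] = rng.integers(0, config.n_latent_axes, size=n_resp)

    sign = rng.choice([1.0, -1.0], size=config.n_peptides, p=[0.9, 0.1])
    amp = sign * rng.uniform(0.5, 2.5, size=config.n_peptides)
    line_mod = rng.uniform(
        0.3, 1.3, size=(config.n_latent_axes, config.n_lines)
    )

    ts = list(config.timepoints_s)
    cols = condition_columns(
        [(line, t) for line in config.lines for t in ts]
    )
    fc = np.zeros((config.n_peptides, len(cols)))
    for j, (line, t) in enumerate(cols):
        li = config.lines.index(line)
        ti = ts.index(t)
        responsive = labels >= 0
        fc[responsive, j] = (
            amp[responsive]
            * line_mod[labels[responsive], li]
            * shapes[labels[responsive], ti]
        )
    true_log2fc = pd.DataFrame(fc, index=peptides, columns=cols)
    cluster_labels = pd.Series(labels, index=peptides, name="latent_axis")
    basal_offset = rng.normal(0.0, 0.3, size=(config.n_peptides, config.n_lines))
    return true_log2fc, cluster_labels, basal_offset


def _plant_phenotypes(
    config: SyntheticStudyConfig,
    truth_fc: pd.DataFrame,
    cluster_labels: pd.Series,
    rng: np.random.Generator,
) -> tuple[dict[str, list[tuple[str, float]]], pd.DataFrame]:
    from .phenotype import PHENOTYPES

    if config.planted_phenotype_features is not None:
        planted = {
            phen: [(str(p), float(c)) for p, c in feats]
            for phen, feats in config.planted_phenotype_features.items()
        }
    else:
        responsive = list(cluster_labels.index[cluster_labels >= 0])
        k = config.n_planted_per_phenotype
        need = k * len(PHENOTYPES)
        if need > len(responsive):
            raise ConfigError(
                "n_planted_per_phenotype: not enough responsive peptides "
                f"({len(responsive)}) to plant {need} features"
            )
        chosen = rng.choice(len(responsive), size=need, replace=False)
        planted = {}
        for i, phen in enumerate(PHENOTYPES):
            idx = chosen[i * k:(i + 1) * k]
            planted[phen] = [
                (responsive[j], float(rng.choice([1.0, -1.0])
                                      * rng.uniform(0.8, 1.2)))
                for j in idx
            ]

    ts = sorted({t for _, t in truth_fc.columns})
    auc = GroundTruth(
        true_log2fc=truth_fc,
        cluster_labels=cluster_labels,
        true_loading_factors={},
        planted_features={},
        planted_phenotype_values=pd.DataFrame(),
        psm_audit=pd.DataFrame(),
    ).true_auc(ts)

    values = {}
    for phen, feats in planted.items():
        total = pd.Series(0.0, index=auc.index)
        for pep, coef in feats:
            col = auc[pep]
            sd = col.std(ddof=0)
            z = (col - col.mean()) / sd if sd > 0 else col * 0.0
            total = total + coef * z
        sd = total.std(ddof=0)
        values[phen] = total / sd if sd > 0 else total
    return planted, pd.DataFrame(values)


def _render_phenotypes(
    config: SyntheticStudyConfig,
    planted_values: pd.DataFrame,
    rng: np.random.Generator,
) -> PhenotypeRawTables:
    """Raw assay tables whose fitted delta rates/index track the planted
    standardized phenotype values."""
    pn = config.phenotype_noise_sd
    conf_rows, wound_rows, int_rows = [], [], []
    t_h = _ASSAY_TIMES_H
    for line in config.lines:
        z = {
            phen: float(planted_values.loc[line, phen])
            + rng.normal(0.0, pn)
            for phen in planted_values.columns
        }
        for rep in range(1, config.n_replicates + 1):
            r_ctrl = _PROLIF_BASE + rng.normal(0.0, pn * _PROLIF_DELTA[1])
            delta_r = (_PROLIF_DELTA[0]
                       + _PROLIF_DELTA[1] * z["proliferation"]
                       + rng.normal(0.0, pn * _PROLIF_DELTA[1]))
            for egf, rate in ((0, r_ctrl), (1, r_ctrl + delta_r)):
                conf = _CONFLUENCY_0 * np.exp(rate * t_h)
                for t, c in zip(t_h, conf):
                    conf_rows.append(
                        dict(line=line, egf=egf, replicate=rep, time_h=t,
                             confluency_pct=c)
                    )
            m_ctrl = _MIG_BASE + rng.normal(0.0, pn * _MIG_DELTA[1])
            delta_m = (_MIG_DELTA[0] + _MIG_DELTA[1] * z["migration"]
                       + rng.normal(0.0, pn * _MIG_DELTA[1]))
            for egf, slope in ((0, m_ctrl), (1, m_ctrl + delta_m)):
                width = np.maximum(0.0, _WOUND_W0 - slope * t_h)
                for t, w in zip(t_h, width):
                    wound_rows.append(
                        dict(line=line, egf=egf, replicate=rep, time_h=t,
                             wound_width_um=w)
                    )
            idx = np.exp(
                _INT_LOG[0] + _INT_LOG[1] * z["internalization"]
                + rng.normal(0.0, pn * _INT_LOG[1])
            )
            int_rows.append(
                dict(line=line, replicate=rep,
                     fluorescence=idx * _CONTROL_FLUOR)
            )
    for rep in range(1, config.n_replicates + 1):
        int_rows.append(
            dict(line=pio.CONTROL_LINE, replicate=rep,
                 fluorescence=_CONTROL_FLUOR)
        )
    return PhenotypeRawTables(
        confluency=pd.DataFrame(conf_rows, columns=list(pio.CONFLUENCY_COLUMNS)),
        wound=pd.DataFrame(wound_rows, columns=list(pio.WOUND_COLUMNS)),
        internalization=pd.DataFrame(
            int_rows, columns=list(pio.INTERNALIZATION_COLUMNS)
        ),
    )


def _corrupt(
    kind: str,
    intensities: np.ndarray,
    rank: int,
    score: float,
    interference: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, float, float]:
    if kind == "rank":
        rank = int(rng.integers(2, 5))
    elif kind == "score":
        score = float(rng.uniform(0.0, 15.0))
    elif kind == "interference":
        interference = float(rng.uniform(40.0, 95.0))
    elif kind == "low_signal":
        target = rng.uniform(50.0, 900.0)
        intensities = intensities * (target / np.nanmean(intensities))
    elif kind == "missing_channel":
        k = int(rng.integers(1, 4))
        drop = rng.choice(N_CHANNELS, size=k, replace=False)
        intensities = intensities.copy()
        intensities[drop] = np.nan
    else:  # pragma: no cover
        raise ValueError(kind)
    return intensities, rank, score, interference


def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate the full synthetic study (deterministic under the seed)."""
    rng = np.random.default_rng(config.seed)
    true_log2fc, cluster_labels, basal_offset = _make_truth(config, rng)
    peptides = list(true_log2fc.index)
    base = 10.0 ** rng.uniform(3.5, 7.0, size=config.n_peptides)
    planted, planted_values = _plant_phenotypes(
        config, true_log2fc, cluster_labels, rng
    )

    ln2 = np.log(2.0)
    min_signal = 1000.0
    designs: dict[str, PlexDesign] = {}
    crude: dict[str, np.ndarray] = {}
    loading: dict[str, np.ndarray] = {}
    psm_tables: dict[str, list[PsmRecord]] = {}
    audit_rows: list[dict] = []
    bline, btime = BRIDGE_SAMPLE

    fc_arr = true_log2fc.to_numpy()
    col_pos = {key: j for j, key in enumerate(true_log2fc.columns)}

    for t in config.timepoints_s:
        for rep in range(1, config.n_replicates + 1):
            run_id = f"plex_t{t:03d}_r{rep}"
            # channel scramble: fresh channel assignment per run
            perm = rng.permutation(N_CHANNELS)
            slots = [(line, t, rep) for line in config.lines] + [BRIDGE]
            cmap = {int(perm[i]): slots[i] for i in range(len(slots))}
            designs[run_id] = PlexDesign(run_id=run_id, channel_map=cmap)

            load = rng.uniform(*config.loading_bias_range, size=N_CHANNELS)
            loading[run_id] = load
            crude[run_id] = load * 10.0 ** rng.uniform(4.0, 5.0)

            records: list[PsmRecord] = []
            for pi, pep in enumerate(peptides):
                n_psm = 1 + int(rng.random() < config.psm_duplicate_prob)
                for _ in range(n_psm):
                    base_psm = base[pi] * rng.uniform(0.3, 1.0)
                    intens = np.empty(N_CHANNELS)
                    for ch, label in cmap.items():
                        if label == BRIDGE:
                            line, tp = bline, btime
                        else:
                            line, tp = label[0], label[1]
                        li = config.lines.index(line)
                        logfc = (
                            fc_arr[pi, col_pos[(line, tp)]]
                            + basal_offset[pi, li]
                        )
                        noise = rng.normal(0.0, config.noise_sd_log2 * ln2)
                        intens[ch] = (
                            base_psm * 2.0 ** logfc * load[ch] * np.exp(noise)
                        )
                    mean = float(np.nanmean(intens))
                    if mean <= min_signal:
                        # keep clean records above the signal gate; uniform
                        # scaling preserves all channel ratios
                        intens *= (min_signal * 1.25) / mean
                    if config.dropout_rate > 0:
                        drop = rng.random(N_CHANNELS) < config.dropout_rate
                        intens[drop] = np.nan
                    missing = bool(np.isnan(intens).any())
                    records.append(
                        PsmRecord(
                            peptide_id=pep,
                            run_id=run_id,
                            search_rank=1,
                            ion_score=float(rng.uniform(20.0, 100.0)),
                            isolation_interference_pct=float(
                                rng.uniform(0.0, 35.0)
                            ),
                            reporter_intensity=tuple(intens),
                            protein_id=pep.split("_")[0],
                        )
                    )
                    audit_rows.append(
                        dict(
                            run_id=run_id,
                            peptide_id=pep,
                            survive_filter=not missing,
                            violation="missing_channel" if missing else "",
                        )
                    )

            n_clean = len(records)
            n_junk = int(round(
                config.junk_psm_fraction * n_clean
                / (1.0 - config.junk_psm_fraction)
            ))
            for _ in range(n_junk):
                pi = int(rng.integers(0, config.n_peptides))
                kind = str(rng.choice(JUNK_KINDS))
                base_psm = base[pi] * rng.uniform(0.3, 1.0)
                profile = np.full(N_CHANNELS, base_psm)
                profile *= np.exp(
                    rng.normal(0.0, 0.3, size=N_CHANNELS)
                )
                if np.nanmean(profile) <= min_signal:
                    profile *= (min_signal * 1.25) / np.nanmean(profile)
                intens, rank, score, interf = _corrupt(
                    kind,
                    profile,
                    1,
                    float(rng.uniform(20.0, 100.0)),
                    float(rng.uniform(0.0, 35.0)),
                    rng,
                )
                records.append(
                    PsmRecord(
                        peptide_id=peptides[pi],
                        run_id=run_id,
                        search_rank=rank,
                        ion_score=score,
                        isolation_interference_pct=interf,
                        reporter_intensity=tuple(intens),
                        protein_id=peptides[pi].split("_")[0],
                    )
                )
                audit_rows.append(
                    dict(
                        run_id=run_id,
                        peptide_id=peptides[pi],
                        survive_filter=False,
                        violation=kind,
                    )
                )
            # shuffle row order so junk is interleaved like a real export
            order = rng.permutation(len(records))
            psm_tables[run_id] = [records[i] for i in order]
            run_audit = [audit_rows[len(audit_rows) - len(records) + i]
                         for i in order]
            del audit_rows[len(audit_rows) - len(records):]
            for j, row in enumerate(run_audit):
                row["psm_index"] = j
            audit_rows.extend(run_audit)

    phenos = _render_phenotypes(config, planted_values, rng)
    audit = pd.DataFrame(
        audit_rows,
        columns=["run_id", "psm_index", "peptide_id", "survive_filter",
                 "violation"],
    )
    truth = GroundTruth(
        true_log2fc=true_log2fc,
        cluster_labels=cluster_labels,
        true_loading_factors=loading,
        planted_features=planted,
        planted_phenotype_values=planted_values,
        psm_audit=audit,
    )
    return SyntheticStudy(
        config=config,
        truth=truth,
        psm_tables=psm_tables,
        designs=designs,
        crude_medians=crude,
        phenotypes=phenos,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, str]:
    """Persist all study inputs in the dialects the ingest module reads.

    Returns a name -> path manifest; the seed is recorded in metadata.json.
    """
    out = Path(out_dir)
    (out / "psm").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    manifest: dict[str, str] = {}
    for run_id, records in sorted(study.psm_tables.items()):
        path = out / "psm" / f"{run_id}.tsv"
        pio.write_psm_table(records, path)
        manifest[f"psm/{run_id}"] = str(path)
    pio.write_designs(study.designs, out / "designs.tsv")
    pio.write_crude_medians(study.crude_medians, out / "crude_medians.tsv")
    pio.write_table(study.phenotypes.confluency, out / "confluency.tsv")
    pio.write_table(study.phenotypes.wound, out / "wound.tsv")
    pio.write_table(study.phenotypes.internalization,
                    out / "internalization.tsv")
    truth_fc = PhosphoMatrix(
        values=study.truth.true_log2fc, stage="replicate_mean"
    )
    pio.write_matrix(truth_fc, out / "truth" / "true_log2fc.tsv")
    pio.write_table(
        study.truth.psm_audit, out / "truth" / "psm_audit.tsv"
    )
    pio.write_table(
        study.truth.planted_phenotype_values.reset_index(names="line"),
        out / "truth" / "planted_phenotypes.tsv",
    )
    meta = {
        "seed": study.config.seed,
        "config": study.config.to_dict(),
        "n_runs": len(study.psm_tables),
    }
    with open(out / "metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    manifest.update(
        designs=str(out / "designs.tsv"),
        crude_medians=str(out / "crude_medians.tsv"),
        confluency=str(out / "confluency.tsv"),
        wound=str(out / "wound.tsv"),
        internalization=str(out / "internalization.tsv"),
        metadata=str(out / "metadata.json"),
    )
    return manifest


def make_planted_regression(
    n_obs: int = 9,
    n_features: int = 200,
    n_planted: int = 5,
    noise_sd_ratio: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Latent-structured regression problem with known informative features.

    Emulates the correlation structure of AUC features in a co-regulated
    signaling network: every feature loads on two shared latent response
    axes (loading scale 0.8) plus unit idiosyncratic variation, the planted
    features track the first axis tightly (idiosyncratic SD 0.1, so each
    carries a standardized effect of ~1 on the response), and the response
    is the planted features' sum plus noise.  Returns (X, y, planted ids).
    """
    rng = np.random.default_rng(seed)
    t = rng.normal(size=(n_obs, 2))
    X = np.empty((n_obs, n_features))
    n_null = n_features - n_planted
    gam = rng.normal(size=(n_null, 2))
    X[:, :n_null] = 0.8 * (t @ gam.T) + rng.normal(size=(n_obs, n_null))
    u = rng.normal(size=(n_obs, n_planted))
    X[:, n_null:] = t[:, [0]] + 0.1 * u
    y_signal = X[:, n_null:].sum(axis=1)
    noise = rng.normal(size=n_obs)
    y = y_signal + noise_sd_ratio * y_signal.std(ddof=0) * (
        noise / max(noise.std(ddof=0), 1e-12)
    )
    names = [f"f{i:03d}" for i in range(n_features)]
    order = rng.permutation(n_features)
    X = X[:, order]
    names_shuffled = [names[i] for i in order]
    planted = [names[i] for i in range(n_null, n_features)]
    lines = [f"line{i}" for i in range(n_obs)]
    Xdf = pd.DataFrame(X, index=lines, columns=names_shuffled)
    return Xdf, pd.Series(y, index=lines, name="phenotype"), planted


def make_null_regression(
    n_obs: int = 9, n_features: int = 200, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Regression problem with no feature-phenotype association at all.

    Both the features and the phenotype are idiosyncratic noise, the null
    against which cross-validated predictivity must not register.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_obs, n_features))
    y = rng.normal(size=n_obs)
    lines = [f"line{i}" for i in range(n_obs)]
    return (
        pd.DataFrame(X, index=lines,
                     columns=[f"f{i:03d}" for i in range(n_features)]),
        pd.Series(y, index=lines, name="phenotype"),
    )
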