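"""End-to-end orchestration: synthesize/ingest -> preprocess -> features ->
multivariate -> SOM consensus -> phenotypes -> PLSR -> report.

A single seed in the config fans out deterministically to per-stage seeds.
Every run writes a ``manifest.json`` recording the config hash, per-stage
input hashes and artifact checksums; rerunning with an unchanged config
skips stages whose inputs and outputs are intact (content-hash based), and
rerunning from scratch with the same seed reproduces every artifact
bit-identically.  Stage logs record the record/peptide counts surviving each
filter, so the "PSMs -> quantified peptides -> presence-filtered peptides"
funnel is a first-class output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import multivariate, phenotype, plsr, preprocess, som, synthetic, temporal
from .types import ConfigError, PhosphoMatrix, PtyrlinkError

logger = logging.getLogger("ptyrlink")

STAGE_ORDER = (
    "synthesize",
    "ingest",
    "preprocess",
    "temporal",
    "multivariate",
    "som",
    "phenotype",
    "plsr",
)


@dataclass
class PipelineConfig:
    """Everything a run needs, loadable from one YAML file."""

    seed: int = 0
    mode: str = "synthetic"  # or "files"
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # paths for mode="files"
    thresholds: dict = field(default_factory=dict)
    presence: dict = field(
        default_factory=lambda: {
            "min_replicates_per_condition": 2,
            "require_all_conditions": True,
        }
    )
    feature_mode: str = "auc"
    alpha: float = 0.05
    som: dict = field(
        default_factory=lambda: {
            "lines": ["WT", "Y992F"],
            "n_restarts": 200,
            "epochs": 50,
            "n_clusters": 4,
        }
    )
    plsr: dict = field(
        default_factory=lambda: {
            "n_components": 3,
            "scale": True,
            "vip_threshold": 1.5,
            "robustness_drop": ["Y845F", "Y1045F"],
        }
    )
    phenotype_window_h: tuple[float, float] = (0.0, 24.0)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"mode: unknown value {self.mode!r}")
        if self.feature_mode not in temporal.FEATURE_MODES:
            raise ConfigError(f"feature_mode: unknown value {self.feature_mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        # fail fast on impossible presence rules in synthetic mode
        rule = self.presence_rule()
        if self.mode == "synthetic":
            n_rep = self.synthetic_config().n_replicates
            if rule.min_replicates_per_condition > n_rep:
                raise ConfigError(
                    "presence.min_replicates_per_condition exceeds the "
                    f"design's {n_rep} replicates"
                )
        if self.mode == "files":
            missing = [
                k for k in ("psm_dir", "designs", "crude_medians")
                if k not in self.inputs
            ]
            if missing:
                raise ConfigError(f"inputs: missing path(s) {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "phenotype_window_h" in data:
            data["phenotype_window_h"] = tuple(data["phenotype_window_h"])
        return cls(**data)

    def synthetic_config(self) -> synthetic.SyntheticStudyConfig:
        params = dict(self.synthetic)
        params.setdefault("seed", _stage_seed(self.seed, "synthesize"))
        return synthetic.SyntheticStudyConfig.from_dict(params)

    def thresholds_obj(self) -> preprocess.FilterThresholds:
        return preprocess.FilterThresholds(**self.thresholds)

    def presence_rule(self) -> preprocess.PresenceRule:
        return preprocess.PresenceRule(**self.presence)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mode": self.mode,
            "synthetic": dict(self.synthetic),
            "inputs": dict(self.inputs),
            "thresholds": dict(self.thresholds),
            "presence": dict(self.presence),
            "feature_mode": self.feature_mode,
            "alpha": self.alpha,
            "som": dict(self.som),
            "plsr": dict(self.plsr),
            "phenotype_window_h": list(self.phenotype_window_h),
            "log_level": self.log_level,
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (kept below 2**31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunReport:
    out_dir: Path
    config_hash: str
    stages: dict = field(default_factory=dict)  # stage -> summary dict
    manifest: dict = field(default_factory=dict)  # relpath -> sha256
    timings_s: dict = field(default_factory=dict)
    funnel: dict = field(default_factory=dict)

    def write(self) -> None:
        with open(self.out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "stages": self.stages,
                    "artifacts": self.manifest,
                    "funnel": self.funnel,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        # timings vary between runs; kept out of the hashed manifest
        with open(self.out_dir / "timings.json", "w", encoding="utf-8") as fh:
            json.dump(self.timings_s, fh, indent=2, sort_keys=True)


class _Stager:
    """Content-hash based skip/run bookkeeping for pipeline stages."""

    def __init__(self, out_dir: Path, config_hash: str):
        self.out_dir = out_dir
        self.config_hash = config_hash
        self.previous = {}
        manifest_path = out_dir / "manifest.json"
        if manifest_path.exists():
            try:
                with open(manifest_path, encoding="utf-8") as fh:
                    old = json.load(fh)
                if old.get("config_hash") == config_hash:
                    self.previous = old
            except (json.JSONDecodeError, OSError):
                pass

    def intact_artifacts(self, stage: str, prefix: str) -> dict[str, str] | None:
        """Previous artifact hashes for a stage if every file is intact.

        Returns None (stage must rerun) when the stage was never completed,
        produced no artifacts under ``prefix``, or any file changed on disk.
        """
        stages = self.previous.get("stages", {})
        artifacts = self.previous.get("artifacts", {})
        if stage not in stages:
            return None
        hits = {rel: h for rel, h in artifacts.items()
                if rel.startswith(prefix)}
        if not hits:
            return None
        for rel, h in hits.items():
            p = self.out_dir / rel
            if not p.exists() or _sha256(p) != h:
                return None
        return hits

    def stage_summary(self, stage: str) -> dict:
        return self.previous.get("stages", {}).get(stage, {})


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute all stages in order, persisting intermediate artifacts."""
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=out, config_hash=config.content_hash())
    stager = _Stager(out, report.config_hash)

    def _register(*paths: Path) -> None:
        for p in paths:
            report.manifest[str(p.relative_to(out))] = _sha256(p)

    def _timed(stage: str, fn: Callable) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise PtyrlinkError(f"stage {stage!r} failed: {exc}") from exc
        report.timings_s[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, report.timings_s[stage])

    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    _register(out / "config.yaml")

    state: dict = {}

    # -- synthesize / locate inputs -------------------------------------
    def stage_synthesize():
        if config.mode == "synthetic":
            cached = stager.intact_artifacts("synthesize", "inputs/")
            if cached is not None:
                state["input_dir"] = out / "inputs"
                report.manifest.update(cached)
                report.stages["synthesize"] = stager.stage_summary("synthesize")
                logger.info("stage synthesize skipped (inputs unchanged)")
                return
            study = synthetic.generate_study(config.synthetic_config())
            manifest = synthetic.write_study(study, out / "inputs")
            state["input_dir"] = out / "inputs"
            state["study"] = study
            _register(*[Path(p) for p in manifest.values()])
            report.stages["synthesize"] = {
                "n_runs": len(study.psm_tables),
                "n_peptides": study.config.n_peptides,
                "seed": study.config.seed,
            }
        else:
            state["input_dir"] = None
            report.stages["synthesize"] = {"skipped": "files mode"}

    _timed("synthesize", stage_synthesize)

    # -- ingest + validate ------------------------------------------------
    def stage_ingest():
        if config.mode == "synthetic":
            base = state["input_dir"]
            psm_dir = base / "psm"
            designs = pio.read_designs(base / "designs.tsv")
            crude = pio.read_crude_medians(base / "crude_medians.tsv")
            pheno_paths = {
                "confluency": base / "confluency.tsv",
                "wound": base / "wound.tsv",
                "internalization": base / "internalization.tsv",
            }
        else:
            psm_dir = Path(config.inputs["psm_dir"])
            designs = pio.read_designs(Path(config.inputs["designs"]))
            crude = pio.read_crude_medians(Path(config.inputs["crude_medians"]))
            pheno_paths = {
                k: Path(config.inputs[k])
                for k in ("confluency", "wound", "internalization")
                if k in config.inputs
            }
        psms = {}
        n_row_errors = 0
        for run_id in sorted(designs):
            path = psm_dir / f"{run_id}.tsv"
            parsed = pio.read_psm_table(path, run_id)
            n_row_errors += len(parsed.errors)
            psms[run_id] = parsed.records
        lines = sorted(
            {
                key[0]
                for d in designs.values()
                for key in d.sample_channels().values()
            }
        )
        tps = sorted(
            {
                key[1]
                for d in designs.values()
                for key in d.sample_channels().values()
            }
        )
        reps = sorted(
            {
                key[2]
                for d in designs.values()
                for key in d.sample_channels().values()
            }
        )
        validation = pio.validate_design(designs, lines, tps, len(reps))
        validation.write_json(out / "design_validation.json")
        _register(out / "design_validation.json")
        if not validation.passed:
            raise PtyrlinkError(
                "design validation failed:\n" + validation.to_text()
            )
        state.update(
            psms=psms, designs=designs, crude=crude, pheno_paths=pheno_paths,
            lines=lines, timepoints=tps, replicates=reps,
        )
        report.stages["ingest"] = {
            "n_runs": len(designs),
            "n_psms": sum(len(v) for v in psms.values()),
            "n_row_errors": n_row_errors,
            "design_valid": validation.passed,
        }

    _timed("ingest", stage_ingest)

    # -- preprocess -------------------------------------------------------
    pre_dir = out / "preprocess"

    def stage_preprocess():
        pre_dir.mkdir(exist_ok=True)
        thresholds = config.thresholds_obj()
        total_in = 0
        total_kept = 0
        rejections: dict[str, int] = {}
        runs = {}
        for run_id, records in state["psms"].items():
            kept, audit = preprocess.filter_psms(records, thresholds)
            total_in += audit.n_input
            total_kept += audit.n_kept
            for rule, n in audit.rejections.items():
                rejections[rule] = rejections.get(rule, 0) + n
            matrix = preprocess.rollup_peptides(kept, state["designs"][run_id])
            runs[run_id] = preprocess.loading_normalize(
                matrix, state["crude"][run_id]
            )
        bridged = preprocess.bridge_normalize(runs, state["designs"])
        log2fc = preprocess.basal_log2fc(bridged)
        rule = config.presence_rule()
        filtered = preprocess.presence_filter(log2fc, rule)
        strict = preprocess.presence_filter(
            log2fc,
            preprocess.PresenceRule(
                min_replicates_per_condition=len(state["replicates"]),
                require_all_conditions=True,
            ),
        )
        means = preprocess.replicate_mean(filtered)
        pio.write_matrix(log2fc, pre_dir / "log2fc_all.tsv")
        pio.write_matrix(filtered, pre_dir / "log2fc_filtered.tsv")
        pio.write_matrix(means, pre_dir / "replicate_mean.tsv")
        funnel = {
            "psms_total": total_in,
            "psms_kept": total_kept,
            "psm_rejections": rejections,
            "peptides_quantified": int(log2fc.values.shape[0]),
            "peptides_presence_filtered": int(filtered.values.shape[0]),
            "peptides_all_replicates": int(strict.values.shape[0]),
        }
        with open(pre_dir / "funnel.json", "w", encoding="utf-8") as fh:
            json.dump(funnel, fh, indent=2, sort_keys=True)
        _register(
            pre_dir / "log2fc_all.tsv",
            pre_dir / "log2fc_filtered.tsv",
            pre_dir / "replicate_mean.tsv",
            pre_dir / "funnel.json",
        )
        report.funnel = funnel
        report.stages["preprocess"] = funnel
        state.update(log2fc=filtered, means=means)

    _timed("preprocess", stage_preprocess)

    # -- temporal features ------------------------------------------------
    tmp_dir = out / "temporal"

    def stage_temporal():
        tmp_dir.mkdir(exist_ok=True)
        features = temporal.feature_matrix(state["means"],
                                           mode=config.feature_mode)
        resp = temporal.responsive_sites(
            state["log2fc"], alpha=config.alpha, line="WT"
            if "WT" in state["lines"] else None
        )
        sums = temporal.network_sum(state["means"])
        features.values.to_csv(tmp_dir / "features.tsv", sep="\t",
                               index_label="line", float_format="%.12g")
        resp.pvalues.to_csv(tmp_dir / "responsive_pvalues.tsv", sep="\t",
                            index_label="peptide_id", float_format="%.12g")
        pio.write_table(sums, tmp_dir / "network_sum.tsv")
        _register(
            tmp_dir / "features.tsv",
            tmp_dir / "responsive_pvalues.tsv",
            tmp_dir / "network_sum.tsv",
        )
        report.stages["temporal"] = {
            "n_features": int(features.values.shape[1]),
            "feature_mode": config.feature_mode,
            "responsive_fraction": resp.fraction,
            "n_responsive": resp.n_responsive,
            "n_tested": resp.n_tested,
        }
        state.update(features=features, responsive=resp)

    _timed("temporal", stage_temporal)

    # -- multivariate -----------------------------------------------------
    mv_dir = out / "multivariate"

    def stage_multivariate():
        mv_dir.mkdir(exist_ok=True)
        # observations = (line, timepoint) conditions, features = peptides
        cond = state["means"].values.T.dropna(axis=1)
        cond.index = [f"{line}@{t}" for line, t in cond.index]
        pca_res = multivariate.pca(cond, center=True, scale=False)
        pca_res.scores.to_csv(mv_dir / "pca_scores.tsv", sep="\t",
                              index_label="condition", float_format="%.12g")
        pca_res.variance_explained_pct.rename("variance_pct").to_csv(
            mv_dir / "pca_variance.tsv", sep="\t", index_label="component"
        )
        auc = temporal.auc_matrix(state["means"]).dropna(axis=1)
        line_tree = multivariate.hcluster(
            multivariate.pearson_distance(auc, axis="rows")
        )
        with open(mv_dir / "line_dendrogram.nwk", "w", encoding="utf-8") as fh:
            fh.write(line_tree.to_newick() + "\n")
        cmap = multivariate.correlation_map(auc, axis="rows")
        cmap.r.to_csv(mv_dir / "line_correlations.tsv", sep="\t",
                      index_label="line", float_format="%.12g")
        _register(
            mv_dir / "pca_scores.tsv",
            mv_dir / "pca_variance.tsv",
            mv_dir / "line_dendrogram.nwk",
            mv_dir / "line_correlations.tsv",
        )
        report.stages["multivariate"] = {
            "pc1_pct": float(pca_res.variance_explained_pct.iloc[0]),
            "pc2_pct": float(pca_res.variance_explained_pct.iloc[1])
            if pca_res.n_components > 1 else float("nan"),
        }
        state["auc"] = auc

    _timed("multivariate", stage_multivariate)

    # -- SOM consensus ----------------------------------------------------
    som_dir = out / "som"

    def stage_som():
        som_dir.mkdir(exist_ok=True)
        cached = stager.intact_artifacts("som", "som/")
        if cached is not None:
            report.manifest.update(cached)
            report.stages["som"] = stager.stage_summary("som")
            logger.info("stage som skipped (artifacts unchanged)")
            return
        som_cfg_params = dict(config.som)
        pair = som_cfg_params.pop("lines", None)
        n_clusters = som_cfg_params.pop("n_clusters", 4)
        som_cfg_params.setdefault("seed", _stage_seed(config.seed, "som"))
        som_cfg = som.SomConfig(**som_cfg_params)
        if pair and len(pair) == 2 and all(l in state["lines"] for l in pair):
            data, dropped = som.differential_som_input(
                pair[0], pair[1], state["means"]
            )
        else:
            # all-line concatenated stimulated trajectories
            blocks = []
            for line in state["lines"]:
                traj = temporal.line_trajectories(state["means"], line)
                traj = traj[[t for t in traj.columns if t != 0]]
                traj.columns = [f"{line}@{t}" for t in traj.columns]
                blocks.append(traj)
            data = pd.concat(blocks, axis=1).dropna()
            dropped = []
        cmap = som.cocluster(data, som_cfg)
        labels = som.cut_cocluster(cmap, n_clusters=n_clusters)
        cmap.freq.to_csv(som_dir / "cocluster.tsv", sep="\t",
                         index_label="peptide_id", float_format="%.12g")
        labels.rename("cluster").to_csv(som_dir / "clusters.tsv", sep="\t",
                                        index_label="peptide_id")
        band_paths = []
        largest = labels.value_counts().idxmax()
        members = list(labels.index[labels == largest])
        for line in (pair if pair else state["lines"][:2]):
            band = som.cluster_band(members, state["means"], line)
            path = som_dir / f"band_{line}.tsv"
            pio.write_table(band, path)
            band_paths.append(path)
        _register(som_dir / "cocluster.tsv", som_dir / "clusters.tsv",
                  *band_paths)
        report.stages["som"] = {
            "n_peptides": int(data.shape[0]),
            "n_dropped": len(dropped),
            "n_restarts": som_cfg.n_restarts,
            "n_clusters": int(labels.nunique()),
            "largest_cluster": int(len(members)),
        }
        state["som_labels"] = labels

    _timed("som", stage_som)

    # -- phenotypes -------------------------------------------------------
    ph_dir = out / "phenotype"

    def stage_phenotype():
        ph_dir.mkdir(exist_ok=True)
        paths = state["pheno_paths"]
        table = phenotype.build_phenotype_table(
            pio.read_confluency(paths["confluency"]),
            pio.read_wound(paths["wound"]),
            pio.read_internalization(paths["internalization"]),
            window_h=config.phenotype_window_h,
        )
        corr = phenotype.phenotype_correlations(table)
        pio.write_table(table.summary.reset_index(), ph_dir / "phenotypes.tsv")
        pio.write_table(table.replicates, ph_dir / "phenotype_replicates.tsv")
        corr.to_csv(ph_dir / "phenotype_correlations.tsv", sep="\t",
                    index_label="phenotype", float_format="%.12g")
        _register(
            ph_dir / "phenotypes.tsv",
            ph_dir / "phenotype_replicates.tsv",
            ph_dir / "phenotype_correlations.tsv",
        )
        report.stages["phenotype"] = {
            "n_lines": int(table.summary.shape[0]),
            "correlations": {
                f"{a}~{b}": float(corr.loc[a, b])
                for i, a in enumerate(corr.index)
                for b in corr.index[i + 1:]
            },
        }
        state["phenotypes"] = table

    _timed("phenotype", stage_phenotype)

    # -- PLSR -------------------------------------------------------------
    pl_dir = out / "plsr"

    def stage_plsr():
        pl_dir.mkdir(exist_ok=True)
        params = dict(config.plsr)
        n_comp = params.get("n_components", 3)
        scale = params.get("scale", True)
        vip_threshold = params.get("vip_threshold", 1.5)
        drop = params.get("robustness_drop", [])
        X_full = state["features"].values
        table = state["phenotypes"]
        summary = {}
        models = {}
        for phen in phenotype.PHENOTYPES:
            y = table.target(phen).reindex(X_full.index)
            if y.isna().any():
                raise PtyrlinkError(
                    f"phenotype {phen!r} missing for some modeled lines"
                )
            a = min(n_comp, len(X_full) - 2, X_full.shape[1])
            cv = plsr.loocv(X_full, y, max_components=a, scale=scale)
            model = plsr.fit_plsr(X_full, y, n_components=a, scale=scale)
            models[phen] = model
            entry = {
                "r2": model.r2,
                "q2": cv.q2,
                "q2_by_components": {
                    int(k): float(v) for k, v in cv.q2_by_components.items()
                },
                "selected_n_components": cv.selected_n_components,
                "n_components_used": model.n_components,
            }
            if drop:
                rob = plsr.robustness_refit(
                    X_full, y, drop, n_components=a, scale=scale
                )
                entry["robustness"] = {
                    "dropped": rob.dropped,
                    "reduced_r2": rob.reduced["r2"],
                    "reduced_q2": rob.reduced["q2"],
                    "vip_spearman": rob.vip_spearman,
                }
            summary[phen] = entry
        vips = plsr.cumulative_vip(models, threshold=vip_threshold)
        vips.to_csv(pl_dir / "vip.tsv", sep="\t", index_label="feature",
                    float_format="%.12g")
        with open(pl_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _register(pl_dir / "vip.tsv", pl_dir / "summary.json")
        report.stages["plsr"] = {
            phen: {"r2": summary[phen]["r2"], "q2": summary[phen]["q2"]}
            for phen in summary
        }

    _timed("plsr", stage_plsr)

    report.write()
    return report


# ---------------------------------------------------------------------------
# Report rendering (from persisted artifacts only)
# ---------------------------------------------------------------------------

REPORT_ARTIFACTS = {
    "heatmap": "preprocess/replicate_mean.tsv",
    "pca": "multivariate/pca_scores.tsv",
    "dendrogram": "multivariate/line_dendrogram.nwk",
    "cocluster": "som/cocluster.tsv",
    "vip": "plsr/vip.tsv",
    "phenotype_correlations": "phenotype/phenotype_correlations.tsv",
}


@dataclass
class ReportResult:
    summary_path: Path | None
    figures: dict[str, Path]
    missing: list[str]


def render_report(run_dir: str | Path) -> ReportResult:
    """Render figures and a markdown summary from a completed run.

    Operates on persisted artifacts only, so it is re-renderable without
    recomputing; missing artifacts are listed rather than fatal.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    missing = [
        f"{name}: {rel}"
        for name, rel in REPORT_ARTIFACTS.items()
        if not (run / rel).exists()
    ]
    fig_dir = run / "figures"
    fig_dir.mkdir(exist_ok=True)
    figures: dict[str, Path] = {}

    def _save(name: str, fig) -> None:
        path = fig_dir / f"{name}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        figures[name] = path

    if (run / REPORT_ARTIFACTS["heatmap"]).exists():
        mat = pio.read_matrix(run / REPORT_ARTIFACTS["heatmap"])
        fig, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(mat.values.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-2, vmax=2)
        ax.set_xlabel("condition (line x timepoint)")
        ax.set_ylabel("peptide")
        ax.set_title("Replicate-mean log2FC over basal")
        fig.colorbar(im, ax=ax, label="log2FC")
        _save("heatmap", fig)

    if (run / REPORT_ARTIFACTS["pca"]).exists():
        scores = pd.read_csv(run / REPORT_ARTIFACTS["pca"], sep="\t",
                             index_col="condition")
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(scores["PC1"], scores.get("PC2", scores["PC1"] * 0), s=18)
        for name, row in scores.iterrows():
            ax.annotate(str(name), (row["PC1"], row.get("PC2", 0.0)),
                        fontsize=5)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title("Condition PCA (basal-normalized)")
        _save("pca", fig)

    if (run / REPORT_ARTIFACTS["dendrogram"]).exists():
        corr_path = run / "multivariate/line_correlations.tsv"
        if corr_path.exists():
            from scipy.cluster import hierarchy as sph
            from scipy.spatial.distance import squareform

            r = pd.read_csv(corr_path, sep="\t", index_col="line")
            d = np.clip(1.0 - r.to_numpy(), 0, 2)
            np.fill_diagonal(d, 0.0)
            Z = sph.linkage(squareform(d, checks=False), method="average")
            fig, ax = plt.subplots(figsize=(6, 4))
            sph.dendrogram(Z, labels=list(r.index), ax=ax)
            ax.set_ylabel("Pearson distance")
            ax.set_title("Cell-line similarity (AUC features)")
            _save("dendrogram", fig)

    if (run / REPORT_ARTIFACTS["cocluster"]).exists():
        freq = pd.read_csv(run / REPORT_ARTIFACTS["cocluster"], sep="\t",
                           index_col="peptide_id")
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(freq.to_numpy(), cmap="viridis", vmin=0, vmax=1)
        ax.set_title("SOM co-clustering frequency")
        fig.colorbar(im, ax=ax, label="co-assignment frequency")
        _save("cocluster", fig)

    if (run / REPORT_ARTIFACTS["vip"]).exists():
        vips = pd.read_csv(run / REPORT_ARTIFACTS["vip"], sep="\t",
                           index_col="feature")
        top = vips.sort_values("cumulative_vip", ascending=False).head(20)
        fig, ax = plt.subplots(figsize=(7, 5))
        ax.barh(range(len(top)), top["cumulative_vip"][::-1])
        ax.set_yticks(range(len(top)))
        ax.set_yticklabels(list(top.index)[::-1], fontsize=6)
        ax.set_xlabel("cumulative VIP across phenotype models")
        ax.set_title("Top features by cumulative VIP")
        _save("vip", fig)

    if (run / REPORT_ARTIFACTS["phenotype_correlations"]).exists():
        corr = pd.read_csv(run / REPORT_ARTIFACTS["phenotype_correlations"],
                           sep="\t", index_col="phenotype")
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(corr.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(len(corr)))
        ax.set_xticklabels(corr.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(corr)))
        ax.set_yticklabels(corr.index)
        for i in range(len(corr)):
            for j in range(len(corr)):
                ax.text(j, i, f"{corr.iloc[i, j]:.2f}", ha="center",
                        va="center", fontsize=8)
        ax.set_title("Phenotype Pearson correlations")
        fig.colorbar(im, ax=ax)
        _save("phenotype_correlations", fig)

    summary_path = None
    manifest_path = run / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
        lines = ["# Run summary", ""]
        funnel = manifest.get("funnel", {})
        if funnel:
            lines += [
                "## Peptide funnel",
                "",
                f"- PSMs parsed: {funnel.get('psms_total')}",
                f"- PSMs passing quality filters: {funnel.get('psms_kept')}",
                f"- quantified peptides: {funnel.get('peptides_quantified')}",
                "- presence-filtered peptides: "
                f"{funnel.get('peptides_presence_filtered')}",
                "- peptides in all replicates: "
                f"{funnel.get('peptides_all_replicates')}",
                "",
            ]
        stages = manifest.get("stages", {})
        if "plsr" in stages:
            lines += ["## PLSR models", ""]
            for phen, vals in sorted(stages["plsr"].items()):
                if isinstance(vals, dict) and "r2" in vals:
                    lines.append(
                        f"- {phen}: R2={vals['r2']:.3f} Q2={vals['q2']:.3f}"
                    )
            lines.append("")
        if missing:
            lines += ["## Missing artifacts", ""]
            lines += [f"- {m}" for m in missing]
            lines.append("")
        lines += ["## Figures", ""]
        lines += [f"- figures/{name}.png" for name in sorted(figures)]
        summary_path = run / "report.md"
        with open(summary_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    return ReportResult(summary_path=summary_path, figures=figures,
                        missing=missing)
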