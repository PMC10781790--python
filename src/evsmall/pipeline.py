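"""End-to-end orchestration: quant -> DE -> classify -> trajectory -> survival.

A single YAML config drives every stage; each stage can also start from prior
outputs (e.g. a counts table with quantification disabled). Every produced
file is checksummed into a run manifest, and a human-readable report plus a
machine-readable JSON twin summarize the run.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import de as de_mod
from . import quant as quant_mod
from . import survival as surv_mod
from . import trajectory as traj_mod
from .reference import ReferenceBundle

DEFAULT_CONTRASTS = (("PD", "healthy"), ("iRBD", "healthy"), ("PD", "iRBD"))

_KNOWN_KEYS = {
    "seed",
    "output_dir",
    "counts",
    "metadata",
    "reads_dir",
    "references",
    "adapter",
    "stages",
    "de",
    "classify",
    "trajectory",
    "survival",
}
_KNOWN_STAGE_KEYS = {"quant", "de", "classify", "trajectory", "survival"}
_KNOWN_DE_KEYS = {"contrasts", "use_adjusted", "log_offset"}
_KNOWN_CLASSIFY_KEYS = {"contrast", "boruta_runs", "n_estimators", "folds", "kernel"}
_KNOWN_TRAJ_KEYS = {"k", "m", "alpha"}
_KNOWN_SURV_KEYS = {"table", "features", "max_features", "alpha", "minprop"}
_KNOWN_REF_KEYS = {"fasta", "offsets"}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: Path
    counts: Path | None = None
    metadata: Path | None = None
    reads_dir: Path | None = None
    references_fasta: Path | None = None
    references_offsets: Path | None = None
    adapter: str | None = None
    stages: dict = field(
        default_factory=lambda: {s: True for s in _KNOWN_STAGE_KEYS}
    )
    de: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)


def _reject_unknown(block: dict, known: set, where: str) -> None:
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config; unknown keys are rejected by name and
    relative paths resolved against the config file's directory."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _reject_unknown(raw, _KNOWN_KEYS, "config")
    base = path.parent

    def resolve(p):
        return None if p is None else (base / p).resolve()

    stages = {s: True for s in _KNOWN_STAGE_KEYS}
    if "stages" in raw:
        _reject_unknown(raw["stages"], _KNOWN_STAGE_KEYS, "stages")
        stages.update(raw["stages"])
    for block, known in (
        ("de", _KNOWN_DE_KEYS),
        ("classify", _KNOWN_CLASSIFY_KEYS),
        ("trajectory", _KNOWN_TRAJ_KEYS),
        ("survival", _KNOWN_SURV_KEYS),
    ):
        if block in raw and raw[block]:
            _reject_unknown(raw[block], known, block)
    refs = raw.get("references") or {}
    if refs:
        _reject_unknown(refs, _KNOWN_REF_KEYS, "references")
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    cfg = PipelineConfig(
        seed=int(raw["seed"]),
        output_dir=resolve(raw.get("output_dir", "evsmall_out")),
        counts=resolve(raw.get("counts")),
        metadata=resolve(raw.get("metadata")),
        reads_dir=resolve(raw.get("reads_dir")),
        references_fasta=resolve(refs.get("fasta")),
        references_offsets=resolve(refs.get("offsets")),
        adapter=raw.get("adapter"),
        stages=stages,
        de=raw.get("de") or {},
        classify=raw.get("classify") or {},
        trajectory=raw.get("trajectory") or {},
        survival=raw.get("survival") or {},
    )
    surv_table = cfg.survival.get("table")
    if surv_table:
        cfg.survival["table"] = str(resolve(surv_table))
    for p in (cfg.counts, cfg.metadata, cfg.reads_dir, cfg.references_fasta,
              cfg.references_offsets):
        if p is not None and not Path(p).exists():
            raise ValueError(f"configured path does not exist: {p}")
    return cfg


# --------------------------------------------------------------------------
# Manifest
# --------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)  # stage -> {outputs, seconds}
    warnings: list = field(default_factory=list)
    completed: list = field(default_factory=list)

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
        }
        self.completed.append(stage)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "feature") -> Path:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")
    return path


def _contrast_name(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}:{contrast[1]}"


def _de_covariates(contrast: tuple[str, str], metadata: pd.DataFrame) -> tuple[str, ...]:
    """Sex is corrected only for PD-involving contrasts; batch always, when
    present with >1 level."""
    covs = []
    if "PD" in contrast and "sex" in metadata.columns:
        covs.append("sex")
    if "batch" in metadata.columns and metadata["batch"].nunique() > 1:
        covs.append("batch")
    return tuple(covs)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages; returns the run manifest.

    Stage outputs land under ``config.output_dir``; the manifest (with
    checksums of every produced file) and report are written at the end.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_payload = json.dumps(
        {k: str(v) for k, v in asdict(config).items()}, sort_keys=True
    )
    manifest = RunManifest(config_hash=hashlib.sha256(cfg_payload.encode()).hexdigest())
    summary: dict = {"contrasts": []}

    metadata = None
    if config.metadata is not None:
        metadata = pd.read_csv(config.metadata, sep="\t", index_col=0)

    normalized = None
    raw = None

    # ---------------------------------------------------------------- quant
    if config.stages.get("quant") and config.reads_dir is not None:
        t0 = _time.perf_counter()
        bundle = ReferenceBundle.from_fasta(
            config.references_fasta, config.references_offsets
        )
        sample_reads = {}
        for fq in sorted(Path(config.reads_dir).glob("*.fastq")):
            sample_reads[fq.stem] = quant_mod.read_fastq_sequences(fq)
        cm, logs = quant_mod.quantify_samples(
            sample_reads, bundle, adapter=config.adapter
        )
        raw, normalized = cm.raw, cm.normalized
        outputs = [
            _write_tsv(cm.raw, out / "counts_raw.tsv"),
            _write_tsv(cm.normalized, out / "counts_normalized.tsv"),
            _write_tsv(
                cm.size_factors.to_frame(), out / "size_factors.tsv", "sample"
            ),
            _write_tsv(cm.class_composition, out / "class_composition.tsv", "class"),
        ]
        log_path = out / "quant_log.json"
        with open(log_path, "w") as fh:
            json.dump(
                {s: vars(l) for s, l in logs.items()}, fh, indent=2, sort_keys=True
            )
            fh.write("\n")
        outputs.append(log_path)
        manifest.record("quant", outputs, _time.perf_counter() - t0)
        summary["quant"] = {
            "n_samples": len(sample_reads),
            "n_features": int((cm.raw.sum(axis=1) > 0).sum()),
        }

    if normalized is None:
        if config.counts is None:
            if any(
                config.stages.get(s) for s in ("de", "classify", "trajectory")
            ):
                raise ValueError("no counts available: provide counts or reads")
        else:
            raw = pd.read_csv(config.counts, sep="\t", index_col=0)
            sf = quant_mod.compute_size_factors(raw)
            normalized = quant_mod.normalize_counts(raw, sf)

    expressed = None
    if normalized is not None:
        expressed = quant_mod.filter_expressed(normalized)
        if expressed.empty:
            expressed = normalized

    # ------------------------------------------------------------------- de
    de_tables: dict[str, pd.DataFrame] = {}
    if config.stages.get("de") and expressed is not None:
        t0 = _time.perf_counter()
        contrast_spec = config.de.get("contrasts")
        contrasts = (
            [tuple(c.split(":")) for c in contrast_spec]
            if contrast_spec
            else list(DEFAULT_CONTRASTS)
        )
        outputs = []
        for contrast in contrasts:
            covs = _de_covariates(contrast, metadata)
            table = de_mod.differential_expression(
                expressed,
                metadata,
                contrast,
                covariates=covs,
                log_offset=float(config.de.get("log_offset", 1.0)),
                use_adjusted=bool(config.de.get("use_adjusted", False)),
            )
            name = _contrast_name(contrast)
            de_tables[name] = table
            outputs.append(
                _write_tsv(table, out / f"de_{name.replace(':', '_vs_')}.tsv")
            )
            summary["contrasts"].append(
                {
                    "contrast": name,
                    "n_up": int((table["call"] == "up").sum()),
                    "n_down": int((table["call"] == "down").sum()),
                    "covariates": list(covs),
                }
            )
        manifest.record("de", outputs, _time.perf_counter() - t0)

    # ------------------------------------------------------------- classify
    if config.stages.get("classify") and expressed is not None and de_tables:
        t0 = _time.perf_counter()
        contrast = tuple(
            config.classify.get("contrast", "PD:healthy").split(":")
        )
        name = _contrast_name(contrast)
        de_table = de_tables.get(name)
        if de_table is None:
            raise ValueError(f"classify contrast {name} has no DE table")
        de_feats = list(de_table.index[de_table["call"] != "ns"])
        if len(de_feats) < 2:
            manifest.warnings.append(
                f"classify skipped: <2 DE features for {name}"
            )
        else:
            expr = de_mod.log_transform(expressed)
            ev = clf.evaluate_biomarker_panel(
                expr,
                metadata,
                contrast,
                de_feats,
                seed=config.seed,
                boruta_runs=int(config.classify.get("boruta_runs", 100)),
                n_estimators=int(config.classify.get("n_estimators", 500)),
                folds=int(config.classify.get("folds", 5)),
                kernel=config.classify.get("kernel", "linear"),
            )
            outputs = [
                _write_tsv(
                    pd.DataFrame({"feature": ev.selected_features}),
                    out / "selected_features.tsv",
                    "rank",
                ),
                _write_tsv(ev.roc_points, out / "roc_validation.tsv", "idx"),
            ]
            metrics = {
                "contrast": name,
                "selected_features": ev.selected_features,
                "selection_fallback": ev.selection_fallback,
                "cv_accuracy": ev.cv_accuracy,
                "train": vars(ev.train_metrics),
                "validation": vars(ev.validation_metrics),
                "train_auc": ev.train_auc,
                "validation_auc": ev.validation_auc,
                "validation_auc_ci": list(ev.validation_auc_ci),
            }
            mpath = out / "classifier_metrics.json"
            with open(mpath, "w") as fh:
                json.dump(metrics, fh, indent=2, sort_keys=True)
                fh.write("\n")
            outputs.append(mpath)
            manifest.record("classify", outputs, _time.perf_counter() - t0)
            summary["classifier"] = metrics

    # ----------------------------------------------------------- trajectory
    if config.stages.get("trajectory") and expressed is not None:
        t0 = _time.perf_counter()
        k = int(config.trajectory.get("k", 8))
        screen, model, table = traj_mod.trajectory_analysis(
            expressed,
            metadata["group"],
            k=k,
            m=float(config.trajectory.get("m", 2.0)),
            alpha=float(config.trajectory.get("alpha", 0.05)),
            seed=config.seed,
        )
        centers = pd.DataFrame(
            model.centers,
            index=[f"cluster{j + 1}" for j in range(model.k)],
            columns=[f"mean_{g}" for g in traj_mod.GROUP_ORDER],
        )
        outputs = [
            _write_tsv(screen, out / "kw_screen.tsv"),
            _write_tsv(table, out / "clusters.tsv"),
            _write_tsv(centers, out / "cluster_centers.tsv", "cluster"),
        ]
        manifest.record("trajectory", outputs, _time.perf_counter() - t0)
        patterns = table["pattern"].value_counts().to_dict()
        summary["trajectory"] = {
            "n_screened": int(screen["significant"].sum()),
            "k": model.k,
            "pattern_counts": {k2: int(v) for k2, v in patterns.items()},
        }

    # ------------------------------------------------------------- survival
    if config.stages.get("survival"):
        t0 = _time.perf_counter()
        surv_table_path = config.survival.get("table")
        records = None
        features = config.survival.get("features")
        if surv_table_path:
            records = pd.read_csv(surv_table_path, sep="\t", index_col=0)
            if features is None:
                reserved = {"time", "event", "age", "sex", "group"}
                features = [c for c in records.columns if c not in reserved]
        elif (
            metadata is not None
            and {"time", "event"} <= set(metadata.columns)
            and normalized is not None
        ):
            irbd = metadata[
                (metadata["group"] == "iRBD") & metadata["time"].notna()
            ]
            records = irbd[["time", "event", "age", "sex"]].copy()
            expr = de_mod.log_transform(normalized[irbd.index])
            if features is None:
                max_feats = int(config.survival.get("max_features", 50))
                features = list(
                    expr.var(axis=1).sort_values(ascending=False).index[:max_feats]
                )
            for feat in features:
                records[feat] = expr.loc[feat]
        if records is None:
            manifest.warnings.append("survival skipped: no survival input")
        else:
            features = [f for f in features if records[f].std(ddof=1) > 0]
            cox_table, candidates, km_results = surv_mod.conversion_analysis(
                records,
                features,
                alpha=float(config.survival.get("alpha", 0.05)),
                minprop=float(config.survival.get("minprop", 0.1)),
            )
            outputs = [_write_tsv(cox_table, out / "cox_screen.tsv")]
            cut_rows, km_rows = [], []
            for feat, (cp, curves) in km_results.items():
                cut_rows.append(
                    {
                        "feature": feat,
                        "cutpoint": cp.cutpoint,
                        "statistic": cp.statistic,
                        "n_high": cp.n_high,
                        "n_low": cp.n_low,
                        "logrank_p": cp.logrank_p,
                    }
                )
                for level, curve in curves.items():
                    curve = curve.assign(feature=feat, level=level)
                    km_rows.append(curve)
            if cut_rows:
                outputs.append(
                    _write_tsv(
                        pd.DataFrame(cut_rows).set_index("feature"),
                        out / "cutpoints.tsv",
                    )
                )
            if km_rows:
                outputs.append(
                    _write_tsv(
                        pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv", "idx"
                    )
                )
            manifest.record("survival", outputs, _time.perf_counter() - t0)
            summary["survival"] = {
                "n_screened": len(features),
                "n_events": int(records["event"].sum()),
                "candidates": candidates,
            }

    write_report(manifest, summary, out)
    manifest.write(out / "manifest.json")
    return manifest


def write_report(manifest: RunManifest, summary: dict, out_dir: Path) -> tuple[Path, Path]:
    """Markdown report + machine-readable JSON twin of the stage summaries."""
    out_dir = Path(out_dir)
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = ["# evsmall run report", ""]
    if summary.get("contrasts"):
        lines += ["## Differential expression", "",
                  "| contrast | up | down | covariates |", "|---|---|---|---|"]
        for c in summary["contrasts"]:
            lines.append(
                f"| {c['contrast']} | {c['n_up']} | {c['n_down']} | "
                f"{','.join(c['covariates']) or '-'} |"
            )
        lines.append("")
    if "classifier" in summary:
        cs = summary["classifier"]
        lines += [
            "## Biomarker classifier",
            "",
            f"- contrast: {cs['contrast']}",
            f"- selected features ({len(cs['selected_features'])}): "
            + ", ".join(cs["selected_features"]),
            f"- CV accuracy: {cs['cv_accuracy']:.4f}",
            f"- validation AUC: {cs['validation_auc']:.4f} "
            f"(95% CI {cs['validation_auc_ci'][0]:.3f}-{cs['validation_auc_ci'][1]:.3f})",
            "",
        ]
    if "trajectory" in summary:
        ts = summary["trajectory"]
        lines += [
            "## Trajectory clustering",
            "",
            f"- features passing Kruskal-Wallis screen: {ts['n_screened']}",
            f"- clusters: {ts['k']}; pattern counts: {ts['pattern_counts']}",
            "",
        ]
    if "survival" in summary:
        ss = summary["survival"]
        lines += [
            "## Conversion survival",
            "",
            f"- miRNAs screened: {ss['n_screened']}; events: {ss['n_events']}",
            f"- Cox candidates (p<0.05): {', '.join(ss['candidates']) or 'none'}",
            "",
        ]
    if manifest.warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in manifest.warnings] + [""]
    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(lines))
    return md_path, json_path
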