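"""End-to-end pipeline: simulate -> analyze -> features -> classify -> report.

A run is fully determined by its configuration and root seed; the
:class:`RunManifest` records both (plus per-stage output paths), so a
manifest replay reproduces every output bit-for-bit.  The JSON report
deliberately carries no timestamps — it must be byte-identical across
replays — while the manifest records the wall-clock time of the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, analysis, synthetic
from .classification import evaluate, split_dataset, train_rbf_svm
from .io import PipelineConfig, write_trace_csv

logger = logging.getLogger("nanowpt")


@dataclass
class RunManifest:
    """Everything needed to replay a pipeline run exactly."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(config=data["config"], seed=data["seed"],
                   version=data.get("version", __version__),
                   outputs=data.get("outputs", {}),
                   timestamp=data.get("timestamp", ""))


def _round6(x: float) -> float:
    """Round to 6 significant digits (keeps tiny p-values meaningful)."""
    return float(f"{x:.6g}")


def run_pipeline(config: PipelineConfig, seed: int, outdir: str | Path,
                 write_traces: bool = False) -> RunManifest:
    """Execute the full simulate/analyze/classify pipeline.

    Generates the labelled dataset at ``seed``, computes per-condition
    gradual/instantaneous summaries and the protein-vs-NC one-way ANOVA,
    trains the fine-Gaussian SVM on a stratified 70/30 split and
    evaluates it, then writes ``report.json``, ``features.csv`` and
    ``manifest.json`` (plus per-trace CSVs when ``write_traces``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        spec = synthetic.DatasetSpec(
            n_experiments=config.dataset.n_experiments,
            protein_fraction=config.dataset.protein_fraction,
            seed=seed,
        )
        traces, dataset = synthetic.generate_dataset(
            spec, noise_sd=config.noise.white_noise_sd,
            sampling_rate=config.lockin.sampling_rate,
        )
        logger.info("simulate: %d traces (seed %d)", len(traces), seed)

        stage = "analyze"
        per_condition: dict[str, dict[str, list[float]]] = {}
        for trace, cond in zip(traces, dataset.conditions):
            st = analysis.step_stats(trace, step_record_start=0.0,
                                     addition_time=trace.annotations[0][0])
            entry = per_condition.setdefault(cond, {"instantaneous": [], "gradual": []})
            entry["instantaneous"].append(st.instantaneous_change_pct)
            entry["gradual"].append(st.gradual_change_pct)
        summaries = {
            cond: {
                kind: {
                    "mean_pct": _round6(float(np.mean(vals))),
                    "sd_pct": _round6(float(np.std(vals, ddof=1))),
                    "n": len(vals),
                }
                for kind, vals in entries.items()
            }
            for cond, entries in sorted(per_condition.items())
        }
        by_class = list(_gradual_by_class(traces, dataset))
        protein_gradual = [g for label, g in by_class if label == "protein"]
        nc_gradual = [g for label, g in by_class if label == "negative_control"]
        f_stat, p_value = analysis.anova_oneway([nc_gradual, protein_gradual])
        logger.info("analyze: ANOVA protein vs NC F=%.3f p=%.3g", f_stat, p_value)

        stage = "features"
        features_path = outdir / "features.csv"
        dataset.to_frame().to_csv(features_path, index=False)

        stage = "classify"
        train, test = split_dataset(dataset, train_fraction=0.7)
        clf = train_rbf_svm(train)
        report_cls = evaluate(clf, test)
        logger.info("classify: accuracy %.1f%% AUC %.3f",
                    report_cls.accuracy_pct, report_cls.auc)

        stage = "report"
        report = {
            "dataset": {
                "n_experiments": spec.n_experiments,
                "class_counts": dataset.class_counts(),
                "train_size": len(train),
                "test_size": len(test),
            },
            "group_summaries": summaries,
            "anova_protein_vs_nc": {"F": _round6(f_stat), "p": _round6(p_value)},
            "classification": report_cls.to_dict(),
        }
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

        outputs = {"report": str(report_path), "features": str(features_path)}
        if write_traces:
            tdir = outdir / "traces"
            tdir.mkdir(exist_ok=True)
            for i, trace in enumerate(traces):
                write_trace_csv(trace, tdir / f"trace_{i:03d}.csv")
            outputs["traces"] = str(tdir)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = RunManifest(config=config.raw, seed=seed, outputs=outputs,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _gradual_by_class(traces, dataset):
    for trace, label in zip(traces, dataset.labels):
        g = analysis.gradual_change_pct(trace, 0.0, trace.annotations[0][0])
        yield label, g
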