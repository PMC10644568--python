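"""Serialization of analysis results to a report directory.

A report is a directory of small CSV tables (one per analysis artifact)
plus a JSON manifest recording the software version, seeds and which
artifacts were produced, so every number in the report is traceable to a
stage and an input.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .stats import ComparisonMatrix, IndependenceMap


def write_report(results: dict, path) -> Path:
    """Write analysis artifacts to ``path`` (created if needed).

    Recognized keys in ``results`` (all optional): ``summaries``,
    ``normality``, ``comparison`` (:class:`ComparisonMatrix`),
    ``independence`` (:class:`IndependenceMap`), ``classifier_reports``
    (list of ClassifierReport), ``rmse_table``, ``circuit_summary``,
    ``cohort``, ``seed``, ``mode``, ``notes``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []

    def save(frame, name):
        frame.to_csv(path / name, index=False)
        written.append(name)

    if "cohort" in results:
        results["cohort"].write_csv(path / "cohort.csv")
        written.append("cohort.csv")
    if "summaries" in results:
        save(results["summaries"], "group_summaries.csv")
    if "normality" in results:
        save(results["normality"], "normality_gate.csv")
    if "comparison" in results:
        cm: ComparisonMatrix = results["comparison"]
        save(cm.to_frame(), "comparison_matrix.csv")
    if "independence" in results:
        im: IndependenceMap = results["independence"]
        save(im.to_frame(), "independence_map.csv")
    if "rmse_table" in results:
        frame = results["rmse_table"].copy()
        frame.insert(0, "kernel", frame.index)
        save(frame, "gp_rmse.csv")
    if "classifier_reports" in results:
        import pandas as pd

        frames = []
        for rep in results["classifier_reports"]:
            f = rep.per_sample.copy()
            f.insert(0, "kernel", rep.kernel)
            f.insert(1, "features", "+".join(rep.feature_subset))
            f["rmse"] = rep.rmse
            frames.append(f)
        if frames:
            save(pd.concat(frames, ignore_index=True), "gp_predictions.csv")
    if "circuit_summary" in results:
        save(results["circuit_summary"], "circuit_parameter_summary.csv")

    manifest = {
        "software": "etmpheno",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "mode": results.get("mode"),
        "seed": results.get("seed"),
        "notes": results.get("notes", ""),
        "artifacts": written,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path
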