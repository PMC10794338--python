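"""Analysis report assembly: exclusion counts, cell means, Bayes factors."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayesfactor import BayesFactorResult

__all__ = ["analysis_report", "report_to_markdown", "write_report"]


def _cell_table(summaries: pd.DataFrame) -> list[dict]:
    rows = []
    for (cond, it), sub in summaries.groupby(["condition", "item_type"]):
        rows.append(
            {
                "condition": cond,
                "item_type": it,
                "n_participants": int(len(sub)),
                "mean_rt_ms": _r(sub["mean_rt_ms"].mean()),
                "sd_rt_ms": _r(sub["mean_rt_ms"].std(ddof=1)),
                "mean_prop_partial": _r(sub["prop_partial"].mean(), 5),
                "sd_prop_partial": _r(sub["prop_partial"].std(ddof=1), 5),
            }
        )
    return rows


def _r(x, nd: int = 2):
    return None if x is None or (isinstance(x, float) and not np.isfinite(x)) else round(float(x), nd)


def _bf_block(res: BayesFactorResult) -> dict:
    return {
        "prior_scale": res.prior_scale,
        "seed": res.seed,
        "log_bf": {f"{a},{b}": _r(v, 4) for (a, b), v in res.log_bf.items()},
        "bf": {f"{a},{b}": float(np.exp(v)) for (a, b), v in res.log_bf.items()},
        "mc_error": {f"{a},{b}": _r(v, 5) for (a, b), v in res.mc_error.items()},
        "extras": {k: v for k, v in res.extras.items() if np.isscalar(v)},
    }


def analysis_report(
    task: str,
    exclusion_counts: Mapping[str, int],
    n_total: int,
    summaries: pd.DataFrame,
    bf_results: Mapping[str, BayesFactorResult],
    exgauss: Mapping[str, Mapping[str, float]] | None = None,
    config: Mapping | None = None,
) -> dict:
    """Assemble the JSON-serializable analysis report."""
    n_excluded = int(sum(exclusion_counts.values()))
    return {
        "task": task,
        "n_trials_total": int(n_total),
        "n_trials_excluded": n_excluded,
        "exclusion_fraction": _r(n_excluded / n_total if n_total else 0.0, 4),
        "exclusion_counts": {k: int(v) for k, v in exclusion_counts.items()},
        "cells": _cell_table(summaries),
        "bayes_factors": {name: _bf_block(res) for name, res in bf_results.items()},
        "exgaussian": exgauss or {},
        "config": dict(config or {}),
    }


def report_to_markdown(report: dict) -> str:
    lines = [f"# Analysis report — {report['task']}", ""]
    lines.append(
        f"Trials: {report['n_trials_total']} total, "
        f"{report['n_trials_excluded']} excluded "
        f"({100 * report['exclusion_fraction']:.2f}%)."
    )
    lines.append("")
    lines.append("| reason | n |")
    lines.append("|---|---|")
    for reason, n in report["exclusion_counts"].items():
        lines.append(f"| {reason} | {n} |")
    lines.append("")
    lines.append("## Cell means")
    lines.append("")
    lines.append(
        "| condition | item type | n | mean RT (ms) | SD | partial % |"
    )
    lines.append("|---|---|---|---|---|---|")
    for c in report["cells"]:
        pp = c["mean_prop_partial"]
        lines.append(
            f"| {c['condition']} | {c['item_type']} | {c['n_participants']} "
            f"| {c['mean_rt_ms']} | {c['sd_rt_ms']} "
            f"| {100 * pp:.2f} |" if pp is not None else
            f"| {c['condition']} | {c['item_type']} | {c['n_participants']} "
            f"| {c['mean_rt_ms']} | {c['sd_rt_ms']} | — |"
        )
    lines.append("")
    lines.append("## Bayes factors")
    lines.append("")
    for name, block in report["bayes_factors"].items():
        lines.append(f"### {name} (Cauchy scale {block['prior_scale']})")
        lines.append("")
        for pair, logbf in block["log_bf"].items():
            bf = block["bf"][pair]
            err = block["mc_error"].get(pair)
            lines.append(f"- BF_{pair} = {bf:.4g} (log {logbf}, mc err {err})")
        lines.append("")
    if report.get("exgaussian"):
        lines.append("## Ex-Gaussian estimates")
        lines.append("")
        for cell, params in report["exgaussian"].items():
            lines.append(f"- {cell}: {params}")
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, out_dir: str | Path, stem: str = "report") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"json": out_dir / f"{stem}.json", "markdown": out_dir / f"{stem}.md"}
    paths["json"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    paths["markdown"].write_text(report_to_markdown(report) + "\n")
    return paths
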