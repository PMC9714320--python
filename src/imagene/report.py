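"""HTML report rendering and the plots it embeds.

The report is one self-contained HTML file with five section groups, in
pipeline order: (1) input summary, (2) clustered correlation heat maps,
(3) surviving features and train/test parameters, (4) model interpretation
(MSE/RMSE/CV tables, the RMSE:STDEV bar plot, true-vs-predicted scatter for
labels with v ≤ 1, AUC vs dt), and (5) permutation ("validation permuts")
summaries.  Images are written next to the report inside the job directory
and referenced by relative path, so the job directory travels as a unit.

The correlation heat map is rendered as three views of the same coefficient
matrix: the raw pairwise matrix, a row-clustered profile view, and the
fully biclustered view.
"""

from __future__ import annotations

import html
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .correlation import CorrelationResult, cluster_order
from .evaluation import LabelEvaluation

_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Radiogenomic analysis report</title>
<style>
body {{ font-family: sans-serif; margin: 2em auto; max-width: 70em; }}
h1 {{ border-bottom: 2px solid #444; }}
h2 {{ border-bottom: 1px solid #aaa; margin-top: 2em; }}
h3 {{ color: #333; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
td, th {{ border: 1px solid #999; padding: 0.3em 0.6em; text-align: right; }}
th {{ background: #eee; }}
td:first-child, th:first-child {{ text-align: left; }}
img {{ max-width: 100%; }}
.empty {{ color: #a00; font-style: italic; }}
</style>
</head>
<body>
<h1>Radiogenomic analysis report</h1>
{body}
</body>
</html>
"""


def _esc(x) -> str:
    return html.escape(str(x))


def _table(df: pd.DataFrame, float_fmt: str = "{:.4g}") -> str:
    if df.empty:
        return '<p class="empty">No rows.</p>'
    head = "".join(f"<th>{_esc(c)}</th>" for c in df.columns)
    rows = []
    for _, row in df.iterrows():
        cells = []
        for v in row:
            if isinstance(v, (float, np.floating)):
                cells.append(f"<td>{'' if np.isnan(v) else float_fmt.format(v)}</td>")
            else:
                cells.append(f"<td>{_esc(v)}</td>")
        rows.append("<tr>" + "".join(cells) + "</tr>")
    return f"<table><tr>{head}</tr>{''.join(rows)}</table>"


def _img(path: Path, job_dir: Path, alt: str) -> str:
    rel = path.relative_to(job_dir).as_posix()
    return f'<img src="{_esc(rel)}" alt="{_esc(alt)}">'


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def correlation_heatmaps(
    corr: CorrelationResult, out_dir: Path
) -> list[Path]:
    """Three views of the coefficient matrix; returns the written paths."""
    out_dir.mkdir(parents=True, exist_ok=True)
    m = corr.r
    row_order, col_order, _ = cluster_order(m)
    views = [
        ("heatmap_pairwise.png", m, "Pairwise correlation matrix"),
        (
            "heatmap_profiles.png",
            m[row_order, :],
            "Row-clustered correlation profiles",
        ),
        (
            "heatmap_biclustered.png",
            m[np.ix_(row_order, col_order)],
            "Biclustered correlation matrix",
        ),
    ]
    paths = []
    for fname, mat, title in views:
        fig, ax = plt.subplots(
            figsize=(min(12, 2 + 0.2 * mat.shape[1]), min(10, 2 + 0.2 * mat.shape[0]))
        )
        sns.heatmap(
            mat, ax=ax, cmap="vlag", center=0, vmin=-1, vmax=1,
            xticklabels=False, yticklabels=False,
        )
        ax.set_title(title)
        ax.set_xlabel(f"omics features (n={mat.shape[1]})")
        ax.set_ylabel(f"imaging features (n={mat.shape[0]})")
        p = out_dir / fname
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths


def v_bar_plot(evals: list[LabelEvaluation], path: Path) -> Path:
    labels = [e.label_name for e in evals]
    vs = [e.v for e in evals]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(labels)), 4))
    ax.bar(labels, vs, color="#4878a8")
    ax.axhline(1.0, color="#a04040", linestyle="--", linewidth=1)
    ax.set_ylabel("RMSE : STDEV (v)")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def scatter_plot(
    evals: list[LabelEvaluation],
    Y_obs: np.ndarray,
    Y_pred: np.ndarray,
    label_names: list[str],
    path: Path,
) -> Path | None:
    """True vs predicted, only for labels with v ≤ 1; None if none qualify."""
    keep = [e.label_name for e in evals if e.defined and e.v <= 1.0]
    if not keep:
        return None
    fig, ax = plt.subplots(figsize=(5, 5))
    for name in keep:
        j = label_names.index(name)
        ax.scatter(Y_obs[:, j], Y_pred[:, j], s=12, alpha=0.6, label=name)
    lims = ax.get_xlim()
    ax.plot(lims, lims, color="#888", linewidth=1)
    ax.set_xlabel("observed")
    ax.set_ylabel("predicted")
    ax.set_title("True vs predicted (labels with v ≤ 1)")
    if len(keep) <= 12:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def auc_dt_plot(evals: list[LabelEvaluation], path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for e in evals:
        dts = [dt for dt, _ in e.auc_curve]
        aucs = [a for _, a in e.auc_curve]
        ax.plot(dts, aucs, marker="o", markersize=3, label=e.label_name)
    ax.set_xlabel("decision threshold (dt)")
    ax.set_ylabel("AUC")
    ax.set_ylim(-0.05, 1.05)
    ax.axhline(0.9, color="#a04040", linestyle="--", linewidth=1)
    if len(evals) <= 12:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def render_report(
    job_dir: Path,
    input_summary: dict,
    scenario_sections: list[dict],
) -> Path:
    """Write report.html into ``job_dir``.

    ``scenario_sections`` holds one dict per scenario with keys:
    title, empty (bool), correlation_images, surviving, parameters (df),
    metrics (df), cv_scores, images (dict name→Path|None),
    permutation_summary (df).
    """
    parts: list[str] = []

    parts.append("<h2>1. Input data</h2>")
    rows = pd.DataFrame(
        [{"property": k, "value": v} for k, v in input_summary.items()]
    )
    parts.append(_table(rows))

    parts.append("<h2>2. Correlation heat maps</h2>")
    any_corr = False
    for sec in scenario_sections:
        imgs = sec.get("correlation_images") or []
        if imgs:
            any_corr = True
            parts.append(f"<h3>{_esc(sec['title'])}</h3>")
            for p in imgs:
                parts.append(_img(p, job_dir, p.stem))
    if not any_corr:
        parts.append(
            '<p class="empty">No correlation stage was run '
            "(model-selected-features scenario bypasses it).</p>"
        )

    parts.append("<h2>3. Surviving features and train/test parameters</h2>")
    for sec in scenario_sections:
        parts.append(f"<h3>{_esc(sec['title'])}</h3>")
        if sec["empty"]:
            parts.append(
                '<p class="empty">Scenario produced no usable feature set.</p>'
            )
            continue
        surv = sec.get("surviving")
        if surv is not None:
            parts.append(
                f"<p>Data features ({len(surv['features'])}): "
                f"{_esc(', '.join(surv['features']))}</p>"
            )
            parts.append(
                f"<p>Labels ({len(surv['labels'])}): "
                f"{_esc(', '.join(surv['labels']))}</p>"
            )
        parts.append(_table(sec["parameters"]))

    parts.append("<h2>4. Model interpretation</h2>")
    for sec in scenario_sections:
        parts.append(f"<h3>{_esc(sec['title'])}</h3>")
        if sec["empty"]:
            parts.append('<p class="empty">Scenario is empty.</p>')
            continue
        parts.append("<p>K-fold cross-validation scores (negative MSE): "
                     f"{_esc(', '.join(f'{s:.4g}' for s in sec['cv_scores']))}</p>")
        parts.append(_table(sec["metrics"]))
        for alt, p in (sec.get("images") or {}).items():
            if p is not None:
                parts.append(_img(p, job_dir, alt))

    parts.append("<h2>5. Permutation tests (validation permuts)</h2>")
    for sec in scenario_sections:
        parts.append(f"<h3>{_esc(sec['title'])}</h3>")
        if sec["empty"]:
            parts.append('<p class="empty">Scenario is empty.</p>')
            continue
        summ = sec.get("permutation_summary")
        if summ is None or summ.empty:
            parts.append(
                '<p class="empty">No label cleared the AUC &gt; 0.9 and '
                "R² &gt; 0.25 gate.</p>"
            )
        else:
            parts.append(_table(summ))

    out = job_dir / "report.html"
    out.write_text(_PAGE.format(body="\n".join(parts)), encoding="utf-8")
    return out
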