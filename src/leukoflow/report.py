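"""Phase-5 report generation: plots and the assembled HTML case report.

HTML is the primary render (it is parseable, hence testable); printing it
to PDF is left to the viewer.  Every figure is deterministic given the
pipeline seed, and the report carries the QC indicators, warnings and
provenance needed to re-run the case identically.
"""

from __future__ import annotations

import base64
import hashlib
import html
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.manifold import TSNE

from .errors import ConfigurationError
from .mdpc import CellCluster, ExpressionLevel
from .pipeline import CaseResult
from .qc import fit_singlet_separator

__all__ = [
    "render_scatter_grid",
    "render_heatmap",
    "render_embedding",
    "assemble_report",
    "MANDATORY_SECTIONS",
]

MANDATORY_SECTIONS = [
    "diagnosis",
    "abnormal-fraction",
    "qc-indicators",
    "warnings",
    "cluster-table",
    "scatter-plots",
    "heatmap",
    "embedding",
    "provenance",
]

_CMAP = plt.get_cmap("tab10")


def _cluster_colors(clusters: list[CellCluster]) -> dict[str, tuple]:
    return {cl.cluster_id: _CMAP(i % 10) for i, cl in enumerate(clusters)}


def render_scatter_grid(result: CaseResult, out_dir) -> list[Path]:
    """Per tube: FSC-A/FSC-H singlet gate, FSC-A/SSC-A debris view,
    CD45/SSC-A by category, and the first marker pair by cluster."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tube_id, tr in result.tubes.items():
        tbl = tr.retained
        colors = _cluster_colors(tr.clusters)
        fig, axes = plt.subplots(2, 2, figsize=(9, 8))
        fig.suptitle(f"{tube_id}: QC and population structure")

        a, h_, s = tbl.column("FSC-A"), tbl.column("FSC-H"), tbl.column("SSC-A")
        ax = axes[0, 0]
        ax.scatter(a, h_, s=2, c="steelblue", alpha=0.4, rasterized=True)
        try:
            sep = fit_singlet_separator(tbl)
            xs = np.linspace(a.min(), a.max(), 50)
            ax.plot(xs, sep.slope * xs + sep.intercept - sep.margin, "r--", lw=1,
                    label="singlet gate")
            ax.legend(fontsize=7)
        except Exception:
            pass
        ax.set_xlabel("FSC-A"), ax.set_ylabel("FSC-H")

        ax = axes[0, 1]
        ax.scatter(a, s, s=2, c="steelblue", alpha=0.4, rasterized=True)
        ax.axvspan(0, np.percentile(a, 1), color="salmon", alpha=0.3,
                   label="debris region")
        ax.set_xlabel("FSC-A"), ax.set_ylabel("SSC-A")
        ax.legend(fontsize=7)

        ax = axes[1, 0]
        if tbl.has_channel("CD45"):
            cd45 = tbl.column("CD45")
            for cl in tr.clusters:
                cat = tr.labels[cl.cluster_id][0]
                ax.scatter(cd45[cl.member_indices], s[cl.member_indices], s=2,
                           color=colors[cl.cluster_id], alpha=0.5,
                           label=f"{cl.cluster_id} {cat}", rasterized=True)
            ax.set_xlabel("CD45 (transformed)"), ax.set_ylabel("SSC-A")
            ax.legend(fontsize=6, markerscale=3)

        ax = axes[1, 1]
        markers = tbl.markers
        pair = [m for m in markers if m != "CD45"][:2]
        if len(pair) == 2:
            x, y = tbl.column(pair[0]), tbl.column(pair[1])
            for cl in tr.clusters:
                ax.scatter(x[cl.member_indices], y[cl.member_indices], s=2,
                           color=colors[cl.cluster_id], alpha=0.5,
                           label=cl.cluster_id, rasterized=True)
            ax.set_xlabel(pair[0]), ax.set_ylabel(pair[1])
            ax.legend(fontsize=6, markerscale=3)

        fig.tight_layout()
        path = out_dir / f"scatter_{tube_id}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths


def render_heatmap(clusters: list[CellCluster], out_path) -> Path:
    """Cluster x marker grid colored by expression-level rank (5 steps),
    rows ordered by cluster fraction, descending."""
    if not clusters:
        raise ConfigurationError("no clusters to draw")
    ordered = sorted(clusters, key=lambda c: -c.fraction)
    markers = list(ordered[0].signature)
    grid = np.array([[int(cl.signature[m]) for m in markers] for cl in ordered])
    fig, ax = plt.subplots(figsize=(0.6 * len(markers) + 2, 0.45 * len(ordered) + 1.5))
    im = ax.imshow(grid, cmap="viridis", vmin=0, vmax=4, aspect="auto")
    ax.set_xticks(range(len(markers)), markers, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(len(ordered)),
                  [f"{c.cluster_id} ({c.fraction:.1%})" for c in ordered], fontsize=8)
    cbar = fig.colorbar(im, ticks=range(5))
    cbar.ax.set_yticklabels([lv.name for lv in ExpressionLevel])
    ax.set_title("Five-level expression signature")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def render_embedding(
    table,
    clusters: list[CellCluster],
    out_path,
    seed: int = 0,
    max_events: int = 20000,
) -> tuple[Path, np.ndarray, np.ndarray]:
    """Seeded t-SNE of (a uniform per-cluster sample of) the events,
    colored by cluster.  Returns (path, coordinates, sampled indices)."""
    if not clusters:
        raise ConfigurationError("no clusters to embed")
    n = table.n_events
    rng = np.random.default_rng(seed)
    take: list[np.ndarray] = []
    if n > max_events:
        frac = max_events / n
        for cl in clusters:
            m = max(int(round(frac * cl.size)), 1)
            take.append(rng.choice(cl.member_indices, size=m, replace=False))
    else:
        take = [np.asarray(cl.member_indices) for cl in clusters]
    idx = np.sort(np.concatenate(take))
    cols = [table.channel_index(m) for m in table.markers]
    X = table.values[np.ix_(idx, cols)]
    perplexity = min(30.0, max(5.0, (len(idx) - 1) / 4))
    coords = TSNE(n_components=2, random_state=seed, init="pca",
                  perplexity=perplexity).fit_transform(X)
    member_of = {}
    for cl in clusters:
        for i in cl.member_indices:
            member_of[int(i)] = cl.cluster_id
    colors = _cluster_colors(clusters)
    fig, ax = plt.subplots(figsize=(6, 5))
    for cl in clusters:
        sel = np.array([member_of[int(i)] == cl.cluster_id for i in idx])
        ax.scatter(coords[sel, 0], coords[sel, 1], s=3,
                   color=colors[cl.cluster_id], label=cl.cluster_id, rasterized=True)
    ax.legend(fontsize=7, markerscale=3)
    ax.set_title("t-SNE embedding by population")
    ax.set_xticks([]), ax.set_yticks([])
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path, coords, idx


def _img_tag(path: Path) -> str:
    data = base64.b64encode(Path(path).read_bytes()).decode()
    return f'<img src="data:image/png;base64,{data}" style="max-width:100%"/>'


def assemble_report(
    result: CaseResult,
    out_dir,
    case_id: str = "case",
    embed_seed: int = 0,
) -> Path:
    """Render all parts and assemble the single-file HTML case report.

    Raises if any mandatory section cannot be produced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scatter_paths = render_scatter_grid(result, out_dir / "figures")
    first_tube = next(iter(result.tubes.values()))
    heat_path = render_heatmap(first_tube.clusters, out_dir / "figures" / "heatmap.png")
    emb_path, _, _ = render_embedding(
        first_tube.retained, first_tube.clusters,
        out_dir / "figures" / "embedding.png", seed=embed_seed)

    dx = result.diagnosis
    qc_rows = "".join(
        f"<tr><td>{t}</td><td>{r.qc.total_events}</td><td>{r.qc.unstable_events}</td>"
        f"<td>{r.qc.doublet_events}</td><td>{r.qc.debris_events}</td>"
        f"<td>{r.qc.retained_events}</td></tr>"
        for t, r in result.tubes.items())
    warn_items = "".join(f"<li>{html.escape(w)}</li>" for w in dx.warnings) or \
        "<li>none</li>"
    alert = ("<div class='alert'>Quality-control or diagnostic warnings are "
             "present; manual review of the flagged items is advised.</div>"
             if dx.warnings else "")
    cluster_html = result.cluster_table().to_html(index=False)
    provenance = {
        "case_id": case_id,
        "seed": result.config.seed,
        "transform": result.config.transform_method,
        "cofactor": result.config.cofactor,
        "blast_threshold": result.config.diagnosis.blast_threshold,
        "config_hash": hashlib.sha256(
            json.dumps({
                "transform": result.config.transform_method,
                "cofactor": result.config.cofactor,
                "min_fraction": result.config.mdpc.min_fraction,
                "blast_threshold": result.config.diagnosis.blast_threshold,
            }, sort_keys=True).encode()).hexdigest()[:16],
    }

    sections = {
        "diagnosis": f"<h2>Diagnosis</h2><p class='dx'>{dx.label}</p>",
        "abnormal-fraction":
            f"<h2>Abnormal cell fraction</h2><p>{dx.abnormal_fraction:.1f}% "
            "of nucleated events</p>",
        "qc-indicators":
            "<h2>QC indicators</h2>" + alert +
            "<table><tr><th>tube</th><th>total</th><th>unstable</th>"
            f"<th>doublets</th><th>debris</th><th>retained</th></tr>{qc_rows}</table>",
        "warnings": f"<h2>Warnings</h2><ul>{warn_items}</ul>",
        "cluster-table": f"<h2>Cluster table</h2>{cluster_html}",
        "scatter-plots": "<h2>Scatter plots</h2>" +
            "".join(_img_tag(p) for p in scatter_paths),
        "heatmap": f"<h2>Expression heat map</h2>{_img_tag(heat_path)}",
        "embedding": f"<h2>t-SNE embedding</h2>{_img_tag(emb_path)}",
        "provenance":
            "<h2>Provenance</h2><pre>" +
            html.escape(json.dumps(provenance, indent=2)) + "</pre>",
    }
    missing = [s for s in MANDATORY_SECTIONS if s not in sections]
    if missing:
        raise ConfigurationError(f"report assembly missing sections: {missing}")
    body = "".join(f"<section id='{sid}'>{content}</section>"
                   for sid, content in sections.items())
    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>MFC report {html.escape(case_id)}</title>"
        "<style>body{font-family:sans-serif;margin:2em} .dx{font-size:1.6em;"
        "font-weight:bold} .alert{background:#ffe0e0;border:1px solid #c00;"
        "padding:0.5em} table{border-collapse:collapse} td,th{border:1px solid "
        "#999;padding:2px 6px}</style></head><body>"
        f"<h1>Flow cytometry diagnosis report: {html.escape(case_id)}</h1>"
        f"{body}</body></html>"
    )
    path = out_dir / f"{case_id}.html"
    path.write_text(doc)
    return path
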