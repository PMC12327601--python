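"""Lightweight output rendering: pathway SVGs and cluster heatmaps."""

from __future__ import annotations

from xml.sax.saxutils import escape

import numpy as np

_BOX_W, _BOX_H, _GAP = 220, 56, 90


def render_pathway_svg(pathway, graph=None) -> str:
    """A left-to-right SVG of one predicted pathway: one box per mass
    signature, arrows annotated with rule id, enzyme support and edge
    support. Pure-text output; no plotting backend required."""
    n = len(pathway.nodes)
    width = n * _BOX_W + max(n - 1, 0) * _GAP + 40
    height = 180
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="monospace" font-size="11">'
    ]
    xs = []
    for i, node in enumerate(pathway.nodes):
        x = 20 + i * (_BOX_W + _GAP)
        xs.append(x)
        attrs = graph.nodes[node] if graph is not None and node in graph else {}
        kind = attrs.get("kind", "")
        fill = "#eef6ff" if kind != "ghost" else "#f5f5f5"
        parts.append(
            f'<rect x="{x}" y="40" width="{_BOX_W}" height="{_BOX_H}" fill="{fill}" '
            f'stroke="#333" rx="6"/>'
        )
        parts.append(f'<text x="{x + 8}" y="58">{escape(str(node))}</text>')
        mass = attrs.get("mass")
        if mass is not None:
            parts.append(f'<text x="{x + 8}" y="74">M = {mass:.4f} Da</text>')
        if kind:
            parts.append(f'<text x="{x + 8}" y="88">{escape(kind)}</text>')
    for i, (u, v, rule_id) in enumerate(pathway.edges):
        x0 = xs[i] + _BOX_W
        x1 = xs[i + 1]
        y = 40 + _BOX_H // 2
        parts.append(
            f'<line x1="{x0}" y1="{y}" x2="{x1 - 8}" y2="{y}" stroke="#333" '
            f'marker-end="url(#arrow)"/>'
        )
        label = escape(str(rule_id))
        parts.append(f'<text x="{x0 + 4}" y="{y - 8}">{label}</text>')
        if graph is not None and graph.has_edge(u, v, rule_id):
            data = graph.edges[u, v, rule_id]
            sup = data.get("edge_support")
            tr = data.get("support_transcripts", "")
            if sup is not None:
                parts.append(
                    f'<text x="{x0 + 4}" y="{y + 16}">w = {float(sup):.3f}</text>'
                )
            if tr:
                parts.append(f'<text x="{x0 + 4}" y="{y + 30}">{escape(tr)}</text>')
    parts.append(
        '<defs><marker id="arrow" markerWidth="8" markerHeight="8" refX="8" refY="4" '
        'orient="auto"><path d="M0,0 L8,4 L0,8 z" fill="#333"/></marker></defs>'
    )
    parts.append("</svg>")
    return "\n".join(parts)


def cluster_heatmap_frame(cluster, expression, features, annotations=None):
    """Member abundance matrix for one functional cluster, rows ordered
    transcripts (scaffold -> tailoring -> other) then features; values are
    row-max normalized. Returns a DataFrame ready for CSV export or any
    heatmap tool."""
    import pandas as pd

    cat = {}
    if annotations:
        cat = {a.transcript_id: a.category for a in annotations}
    order = {"scaffold": 0, "tailoring": 1, "other": 2}
    t_rows = sorted(
        (t for t in cluster.transcripts if t in expression.values.index),
        key=lambda t: (order.get(cat.get(t, "other"), 2), t),
    )
    f_rows = sorted(f for f in cluster.features if f in features.abundance.index)
    mat = pd.concat(
        [expression.values.loc[t_rows], features.abundance.loc[f_rows]], axis=0
    )
    peak = mat.abs().max(axis=1).replace(0, 1.0)
    return mat.div(peak, axis=0)


def save_cluster_heatmap(cluster, expression, features, path, annotations=None):
    """PNG/SVG heatmap of one cluster's members (extension decides format)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = cluster_heatmap_frame(cluster, expression, features, annotations)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.3 * frame.shape[1]), max(3.0, 0.25 * frame.shape[0]))
    )
    im = ax.imshow(frame.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(np.arange(len(frame.index)), labels=frame.index, fontsize=6)
    ax.set_xticks(np.arange(len(frame.columns)), labels=frame.columns, fontsize=6, rotation=90)
    fig.colorbar(im, ax=ax, shrink=0.7)
    ax.set_title(f"functional cluster {cluster.cluster_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
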