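"""Disk formats: slice stacks (PNG/TIFF), graphs (GraphML + CSV tables),
metric tables (CSV/JSON with explicit nulls), QC overlays, and plots.

Undefined metric values (NaN in memory) are written as JSON ``null`` and as
empty CSV cells — never as zeros.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .depth import DepthProfile, GroupComparison
from .graphx import Edge, NetworkGraph, Vertex
from .imageproc import SliceImage
from .morpho import MorphoRecord
from .netmetrics import MetricsRecord
from .phantom import GroundTruth

# ---------------------------------------------------------------------------
# images


def write_slice(img: SliceImage, path) -> None:
    """16-bit TIFF for .tif/.tiff paths, 8-bit PNG otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (img.pixels * 65535).round().astype(np.uint16))
    else:
        import imageio.v3 as iio
        iio.imwrite(path, (img.pixels * 255).round().astype(np.uint8))


def write_stack(stack, out_dir, fmt: str = "png") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for img, _ in stack:
        p = out_dir / f"slice_{img.depth_index:04d}.{fmt}"
        write_slice(img, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# graphs


def _path_str(path) -> str:
    return ";".join(f"{r}:{c}" for r, c in path)


def _parse_path(s: str):
    if not s:
        return ()
    return tuple(tuple(int(x) for x in p.split(":")) for p in s.split(";"))


def write_graph(g: NetworkGraph, base) -> dict[str, Path]:
    """GraphML + paired vertices.csv / edges.csv under the path stem ``base``."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    out = {}
    nxg = g.to_networkx()
    out["graphml"] = base.with_suffix(".graphml")
    nx.write_graphml(nxg, out["graphml"])
    vdf = pd.DataFrame(
        [{"id": v.id, "row": v.centroid[0], "col": v.centroid[1], "kind": v.kind}
         for v in g.vertices])
    edf = pd.DataFrame(
        [{"id": e.id, "vertex_a": e.vertex_a, "vertex_b": e.vertex_b,
          "length_um": e.length_um, "n_path_pixels": len(e.pixel_path),
          "pixel_path": _path_str(e.pixel_path)} for e in g.edges])
    out["vertices"] = base.parent / f"{base.name}_vertices.csv"
    out["edges"] = base.parent / f"{base.name}_edges.csv"
    vdf.to_csv(out["vertices"], index=False)
    edf.to_csv(out["edges"], index=False)
    return out


def read_graph(base, pixel_size_um: float) -> NetworkGraph:
    """Rebuild a NetworkGraph from its paired CSV tables."""
    base = Path(base)
    vdf = pd.read_csv(base.parent / f"{base.name}_vertices.csv")
    edf = pd.read_csv(base.parent / f"{base.name}_edges.csv",
                      keep_default_na=False, dtype={"pixel_path": str})
    vertices = tuple(
        Vertex(int(r.id), (float(r.row), float(r.col)), str(r.kind), ())
        for r in vdf.itertuples())
    edges = tuple(
        Edge(int(r.id), int(r.vertex_a), int(r.vertex_b),
             _parse_path(r.pixel_path), float(r.length_um))
        for r in edf.itertuples())
    return NetworkGraph(vertices, edges, pixel_size_um)


def write_ground_truth(gt: GroundTruth, base) -> dict[str, Path]:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    out = {"graphml": base.with_suffix(".graphml")}
    nx.write_graphml(gt.to_networkx(), out["graphml"])
    vdf = pd.DataFrame([{"id": i, "row": r, "col": c}
                        for i, (r, c) in enumerate(gt.vertices)])
    edf = pd.DataFrame([{"id": i, "vertex_a": a, "vertex_b": b,
                         "pixel_path": _path_str(poly)}
                        for i, (a, b, poly) in enumerate(gt.edges)])
    out["vertices"] = base.parent / f"{base.name}_vertices.csv"
    out["edges"] = base.parent / f"{base.name}_edges.csv"
    vdf.to_csv(out["vertices"], index=False)
    edf.to_csv(out["edges"], index=False)
    return out


def overlay_png(img: SliceImage, g: NetworkGraph, path) -> None:
    """QC overlay: edges red, junctions yellow, endpoints/anchors green."""
    rgb = np.repeat(img.pixels[..., None], 3, axis=2)
    for e in g.edges:
        for r, c in e.pixel_path:
            rgb[r, c] = (1.0, 0.0, 0.0)
    for v in g.vertices:
        r, c = int(round(v.centroid[0])), int(round(v.centroid[1]))
        color = (1.0, 1.0, 0.0) if v.kind == "junction" else (0.0, 1.0, 0.0)
        rgb[max(0, r - 1):r + 2, max(0, c - 1):c + 2] = color
    import imageio.v3 as iio
    iio.imwrite(Path(path), (rgb * 255).round().astype(np.uint8))


# ---------------------------------------------------------------------------
# metric tables


def _clean_value(v):
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def records_to_frame(metrics: list[MetricsRecord],
                     morpho: list[MorphoRecord] | None = None) -> pd.DataFrame:
    rows = []
    for i, m in enumerate(metrics):
        row = m.as_dict()
        if morpho is not None:
            extra = morpho[i].as_dict()
            extra.pop("depth_index", None)
            row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)


def write_metrics_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(Path(path), index=False, na_rep="")


def write_metrics_json(metrics: list[MetricsRecord], path) -> None:
    payload = [{k: _clean_value(v) for k, v in m.as_dict().items()} for m in metrics]
    Path(path).write_text(json.dumps(payload, indent=2))


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {"metric": c.metric_name, "region": c.region,
               "t_statistic": c.t_statistic, "p_value": c.p_value,
               "significant": c.significant}
        for g in sorted(c.group_means):
            row[f"mean_{g}"] = c.group_means[g]
            row[f"sd_{g}"] = c.group_sds[g]
            row[f"shapiro_p_{g}"] = c.normality_p[g]
            row[f"n_{g}"] = c.n_per_group[g]
        rows.append(row)
    return pd.DataFrame(rows)


def write_eval_report(report, path) -> None:
    Path(path).write_text(json.dumps(
        {k: _clean_value(v) for k, v in report.as_dict().items()}, indent=2))


def write_roc_csv(report, path) -> None:
    pts = report.roc_points or []
    pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# plots


def plot_group_bands(bands_per_metric: dict, path,
                     colors: dict | None = None) -> None:
    """One panel per metric: group mean line + SD band versus depth."""
    colors = colors or {"CTRL": "tab:blue", "HOA": "tab:red"}
    names = list(bands_per_metric)
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.2),
                             squeeze=False)
    for ax, name in zip(axes[0], names):
        for group, (grid, mean, sd) in bands_per_metric[name].items():
            color = colors.get(group)
            ax.plot(grid, mean, color=color, label=group)
            ax.fill_between(grid, mean - sd, mean + sd, color=color, alpha=0.25)
        ax.set_xlabel("depth (mm)")
        ax.set_title(name)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_roc(reports, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    for rep in reports:
        if rep.roc_points:
            pts = np.array(rep.roc_points)
            ax.plot(pts[:, 0], pts[:, 1], label=f"{rep.arm} (AUC={rep.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
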