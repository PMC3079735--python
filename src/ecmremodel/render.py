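"""Pseudo-colored rendering of per-layer projections and the run report.

Projections are rendered with a discrete 226-level colormap running
black/blue (low intensity) through red to white (high intensity), matching
the pseudo-coloring convention of the original figures, with the
cell-region outline overlaid.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, LinearSegmentedColormap

from .errors import DataError
from .layers import LAYERS, max_projection
from .scoring import RegionMask
from .stacks import SCALE_MAX

#: One discrete color per integer intensity level 0..225.
N_LEVELS = 226


def intensity_colormap():
    """226-level black/blue -> red -> white pseudo-color map with its norm."""
    cmap = LinearSegmentedColormap.from_list(
        "ecm_intensity",
        ["black", "#00004d", "blue", "#7a00b3", "red", "#ff8080", "white"],
        N=N_LEVELS,
    )
    norm = BoundaryNorm(np.arange(N_LEVELS + 1) - 0.5, N_LEVELS)
    return cmap, norm


def render_projection(
    projection: np.ndarray,
    path,
    region: RegionMask | None = None,
    title: str = "",
) -> str:
    """Write one pseudo-colored projection PNG with an optional mask outline."""
    cmap, norm = intensity_colormap()
    fig, ax = plt.subplots(figsize=(4.2, 4.2), dpi=120)
    im = ax.imshow(np.clip(projection, 0, SCALE_MAX), cmap=cmap, norm=norm)
    if region is not None:
        ax.contour(region.cell_mask, levels=[0.5], colors="yellow", linewidths=0.9)
    ax.set_axis_off()
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, fraction=0.045, ticks=[0, 90, 225])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)


def render_report(bundle: dict, region_by_field: dict | None = None) -> Path:
    """Render per-(layer, channel) projections and an HTML score report.

    ``bundle`` is the dict returned by :func:`ecmremodel.pipeline.run_pipeline`;
    projections are re-derived from the recorded partitions when the caller
    also passes the scaled stacks under ``bundle["stacks"]``.  The report
    table lists exactly the score values of the scores CSV.
    """
    out_dir = Path(bundle["out_dir"]) / "report"
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = bundle["scores"]
    if scores.empty:
        raise DataError("bundle contains no scores to report")

    images = []
    stacks = bundle.get("stacks", {})
    for field_id, scaled in stacks.items():
        part = bundle["partitions"][field_id]
        region = (region_by_field or {}).get(field_id)
        for layer in LAYERS:
            for ch in ("tmp", "fibronectin"):
                proj = max_projection(scaled, ch, part.planes(layer))
                png = out_dir / f"{field_id}_{layer}_{ch}.png"
                render_projection(
                    proj, png, region, title=f"{field_id} {layer} {ch}"
                )
                images.append(png.name)

    table_html = scores.to_html(index=False, float_format=lambda v: f"{v:.3f}")
    html = [
        "<html><head><title>ECM remodeling report</title></head><body>",
        f"<h1>ECM remodeling report</h1>",
        f"<p>config hash: {bundle['config_hash']}</p>",
        "<h2>Scores</h2>",
        table_html,
        "<h2>Pseudo-colored layer projections</h2>",
    ]
    html += [f'<div><img src="{name}" alt="{name}"/></div>' for name in images]
    html.append("</body></html>")
    report = out_dir / "report.html"
    report.write_text("\n".join(html))
    with open(out_dir / "report_scores.json", "w") as fh:
        json.dump(
            scores[["field", "layer", "channel", "score_percent"]].to_dict("records"),
            fh, indent=2,
        )
    return report
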