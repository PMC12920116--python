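"""Render figures and tables from a completed run directory.

Dot plots follow the forward-red / reverse-blue convention; the junction
profile is drawn over every vector position (zero-coverage included) and
self-link arcs are drawn as semicircles over the linearized plasmid map.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .dotplot import dotplot, plot_dotplot
from .errors import PipelineError
from .panel import ReferencePanel
from .pipeline import read_tsv

REQUIRED_ARTIFACTS = [
    "structure_calls.tsv", "category_summary.tsv", "junctions.tsv",
    "junction_profile.tsv", "self_link_arcs.tsv",
]


def render_report(
    run_dir,
    panel: ReferencePanel | None = None,
    reads: list[tuple[str, str]] | None = None,
    max_dotplots_per_category: int = 1,
) -> Path:
    """Write report tables and plots under ``<run_dir>/report``.

    Raises :class:`PipelineError` listing any missing stage artifacts.
    When ``panel`` and ``reads`` are provided, one representative dot plot
    per called category is rendered against the vector region.
    """
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise PipelineError("report", f"missing artifacts: {missing}")

    out = run_dir / "report"
    out.mkdir(exist_ok=True)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = read_tsv(run_dir / "category_summary.tsv")
    summary.to_csv(out / "category_summary.tsv", sep="\t", index=False)

    profile = read_tsv(run_dir / "junction_profile.tsv")
    counts = profile["count"].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(np.arange(len(counts)), counts, step="mid", color="darkred")
    ax.set_xlabel("vector plasmid position (bp)")
    ax.set_ylabel("junction endpoints")
    fig.tight_layout()
    fig.savefig(out / "junction_profile.png", dpi=120)
    plt.close(fig)

    arcs = read_tsv(run_dir / "self_link_arcs.tsv")
    fig, ax = plt.subplots(figsize=(8, 3))
    for row in arcs.itertuples(index=False):
        s, e = float(row.start), float(row.end)
        mid, rad = (s + e) / 2, (e - s) / 2
        theta = np.linspace(0, np.pi, 50)
        ax.plot(mid + rad * np.cos(theta), rad * np.sin(theta),
                color="steelblue", alpha=0.6, lw=0.5 + 0.5 * float(row.count))
    ax.set_xlabel("vector plasmid position (bp)")
    ax.set_yticks([])
    ax.set_title("vector self-links")
    fig.tight_layout()
    fig.savefig(out / "self_link_arcs.png", dpi=120)
    plt.close(fig)

    if panel is not None and reads is not None:
        calls = read_tsv(run_dir / "structure_calls.tsv")
        vec, v0, v1 = panel.vector_region()
        region = panel.sequences[vec][v0:v1]
        by_id = dict(reads)
        for category, sub in calls.groupby("category"):
            for rid in sub["read_id"].head(max_dotplots_per_category):
                if rid not in by_id:
                    continue
                m = dotplot(by_id[rid], region)
                plot_dotplot(m, out / f"dotplot_{category}_{rid}.png",
                             title=f"{rid} ({category})")
    return out
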