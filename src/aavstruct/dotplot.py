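"""Windowed alignment dot plots.

Both sequences are cut into consecutive non-overlapping windows (default
20 bp, matching the window size used for nanopore read inspection); cell
(i, j) is a forward hit when window i of A matches window j of B within a
small Hamming tolerance, and a reverse hit when window i of A matches the
reverse complement of window j of B.  The tolerance absorbs sequencing
error; exact matching is too brittle at ~5% error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import revcomp


@dataclass
class DotPlotMatrix:
    window: int
    n_rows: int  # windows of sequence A
    n_cols: int  # windows of sequence B
    forward_hits: set = field(default_factory=set)
    reverse_hits: set = field(default_factory=set)

    def transpose(self) -> "DotPlotMatrix":
        return DotPlotMatrix(
            window=self.window, n_rows=self.n_cols, n_cols=self.n_rows,
            forward_hits={(j, i) for i, j in self.forward_hits},
            reverse_hits={(j, i) for i, j in self.reverse_hits},
        )


def _window_codes(seq: str, w: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = (len(seq) // w) * w
    return arr[:n].reshape(-1, w)


def dotplot(seq_a: str, seq_b: str, window: int = 20, max_mismatch: int = 2) -> DotPlotMatrix:
    """Compute the windowed dot plot of two sequences.

    Raises on ``window < 4``; both sequences must be at least one window
    long.  ``max_mismatch`` is the per-window Hamming tolerance.
    """
    if window < 4:
        raise ValueError(f"window {window} < 4")
    if len(seq_a) < window or len(seq_b) < window:
        raise ValueError("sequences must be at least one window long")

    wa = _window_codes(seq_a, window)
    wb = _window_codes(seq_b, window)
    # reverse hits compare A windows to the revcomp of each B window
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGTacgt", b"TGCATGCA"):
        comp[x] = y
    rc_of_b_windows = comp[wb][:, ::-1]

    fwd = (wa[:, None, :] != wb[None, :, :]).sum(axis=2) <= max_mismatch
    rev = (wa[:, None, :] != rc_of_b_windows[None, :, :]).sum(axis=2) <= max_mismatch

    fi, fj = np.nonzero(fwd)
    ri, rj = np.nonzero(rev)
    return DotPlotMatrix(
        window=window, n_rows=wa.shape[0], n_cols=wb.shape[0],
        forward_hits={(int(i), int(j)) for i, j in zip(fi, fj)},
        reverse_hits={(int(i), int(j)) for i, j in zip(ri, rj)},
    )


def write_dotplot_tsv(matrix: DotPlotMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#row\tcol\tstrand\n")
        for i, j in sorted(matrix.forward_hits):
            fh.write(f"{i}\t{j}\t+\n")
        for i, j in sorted(matrix.reverse_hits):
            fh.write(f"{i}\t{j}\t-\n")


def plot_dotplot(matrix: DotPlotMatrix, path, title: str = "") -> None:
    """Render: forward hits red, reverse hits blue."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if matrix.forward_hits:
        xs, ys = zip(*[(i, j) for i, j in matrix.forward_hits])
        ax.scatter(xs, ys, s=2, c="red", label="forward")
    if matrix.reverse_hits:
        xs, ys = zip(*[(i, j) for i, j in matrix.reverse_hits])
        ax.scatter(xs, ys, s=2, c="blue", label="reverse")
    ax.set_xlabel(f"read windows ({matrix.window} bp)")
    ax.set_ylabel(f"reference windows ({matrix.window} bp)")
    ax.set_xlim(-1, matrix.n_rows)
    ax.set_ylim(-1, matrix.n_cols)
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", markerscale=4)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
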