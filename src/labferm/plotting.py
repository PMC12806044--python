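"""Plotting hooks for the four standard scan panels.

Panels: mu(S0), lag(S0), the growth-adaptation trade-off (mu vs 1/lag), and
the Pirt plane (1/Y vs 1/mu) with the regime split at Sc.  All functions take
a ScanResult from an S0 sweep and write PNG files; they are thin wrappers so
publication styling stays in the caller's hands.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .scans import ScanResult

__all__ = ["plot_scan_panels"]


def plot_scan_panels(scan: ScanResult, prefix: str | Path) -> list[Path]:
    """Write the four scan panels as ``<prefix>_<panel>.png``; returns paths."""
    if scan.axis != "S0":
        raise ValueError("scan panels are defined for S0 scans")
    df = scan.traits
    prefix = Path(prefix)
    written = []

    def _save(fig, name):
        path = prefix.parent / f"{prefix.name}_{name}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.plot(df.S0, df.mu_1_per_h, "-", color="tab:blue")
    if scan.Sc is not None:
        ax.axvline(scan.Sc, ls="--", color="grey", lw=0.8)
        ax.annotate(f"Sc = {scan.Sc:.1f}", (scan.Sc, df.mu_1_per_h.max()),
                    fontsize=8, ha="left")
    ax.set_xlabel("S0 (g/dm³)")
    ax.set_ylabel("μ (1/h)")
    _save(fig, "mu_vs_S0")

    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.plot(df.S0, df.lag_h, "-", color="tab:red")
    ax.set_xlabel("S0 (g/dm³)")
    ax.set_ylabel("lag λ (h)")
    _save(fig, "lag_vs_S0")

    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    below = df.S0 <= (scan.Sc if scan.Sc is not None else df.S0.max())
    ax.plot(1 / df.lag_h[below], df.mu_1_per_h[below], "o", ms=3,
            color="tab:blue", label="S0 < Sc")
    ax.plot(1 / df.lag_h[~below], df.mu_1_per_h[~below], "o", ms=3,
            color="tab:red", label="S0 > Sc")
    ax.set_xlabel("adaptation 1/λ (1/h)")
    ax.set_ylabel("μ (1/h)")
    ax.legend(fontsize=8)
    _save(fig, "tradeoff")

    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.plot(1 / df.mu_1_per_h[below], 1 / df.Y[below], "o", ms=3,
            color="tab:blue", label="S0 < Sc")
    ax.plot(1 / df.mu_1_per_h[~below], 1 / df.Y[~below], "o", ms=3,
            color="tab:red", label="S0 > Sc")
    ax.set_xlabel("1/μ (h)")
    ax.set_ylabel("1/Y (g substrate / g biomass)")
    ax.legend(fontsize=8)
    _save(fig, "pirt")

    return written
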