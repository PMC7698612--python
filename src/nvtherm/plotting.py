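"""Optional figures for the sweep-design scan and the paired comparison."""

from __future__ import annotations

from pathlib import Path
from typing import Union

from .sweep_optimizer import RangeComparison, RangeScanResult


def plot_scan(scan: RangeScanResult, path: Union[str, Path]) -> None:
    """Accuracy vs sweep half-width, one curve per noise level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scan.to_frame()
    fig, ax = plt.subplots(figsize=(5, 4))
    for level, sub in df.groupby("noise_level"):
        sub = sub.sort_values("half_width_mhz")
        ax.errorbar(
            2 * sub["half_width_mhz"],
            sub["accuracy_k_per_sqrthz"],
            yerr=sub["mc_se"],
            label=f"{level:.0%} noise",
        )
    ax.set_xlabel("sweep width (MHz)")
    ax.set_ylabel("accuracy (K/Hz$^{1/2}$)")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_comparison(cmp: RangeComparison, path: Union[str, Path]) -> None:
    """Paired per-trial accuracies with the equality diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(cmp.accuracy_b, cmp.accuracy_a, s=8, c="gray", alpha=0.6)
    lims = [
        min(cmp.accuracy_a.min(), cmp.accuracy_b.min()),
        max(cmp.accuracy_a.max(), cmp.accuracy_b.max()),
    ]
    ax.plot(lims, lims, "r-", lw=1)
    ax.set_xlabel(
        f"accuracy, {cmp.grid_b.f_start:.0f}-{cmp.grid_b.f_end:.0f} MHz (K/Hz$^{{1/2}}$)"
    )
    ax.set_ylabel(
        f"accuracy, {cmp.grid_a.f_start:.0f}-{cmp.grid_a.f_end:.0f} MHz (K/Hz$^{{1/2}}$)"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
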