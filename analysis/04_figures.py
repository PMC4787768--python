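"""Figures: example trace, bound-state FRET histograms with fitted
Gaussians, and dwell-time survival curves, written to results/figures/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from fretbind.scenarios import load_scenario
from fretbind.simulate import simulate_dataset
from fretbind.traces import compute_fret, detect_photobleach

RECORDS = Path("results/records")
FIG = Path("results/figures")


def example_trace() -> None:
    cfg = load_scenario("unmodified_binary", n_molecules=3, rng_seed=4)
    traces, _ = simulate_dataset(cfg)
    tr = traces[0]
    bf = detect_photobleach(tr)
    traj = compute_fret(tr, 50, 50, bleach_frame=bf)
    t = tr.times
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 4))
    ax1.plot(t, tr.donor, lw=0.6, color="tab:blue", label="Cy3 (donor)")
    ax1.plot(t, tr.acceptor, lw=0.6, color="tab:red", label="Cy5 (acceptor)")
    ax1.set_ylabel("intensity (counts)")
    ax1.legend(loc="upper right", fontsize=8)
    fret = np.where(traj.valid_mask, traj.fret, np.nan)
    ax2.plot(t, fret, lw=0.6, color="k")
    ax2.set_ylim(-0.1, 1.1)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("FRET")
    fig.tight_layout()
    fig.savefig(FIG / "example_trace.png", dpi=150)
    plt.close(fig)


def gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def histograms() -> None:
    records = sorted(RECORDS.glob("*.json"))
    if not records:
        print("no records found; run 02_analyze_conditions.py first")
        return
    fig, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
    for ax, path in zip(axes.ravel(), records):
        rec = json.loads(path.read_text())
        edges = np.array(rec["histogram_edges"])
        counts = np.array(rec["histogram_counts"])
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.bar(centers, counts, width=edges[1] - edges[0], color="0.8",
               edgecolor="0.5", lw=0.3)
        x = np.linspace(-0.1, 1.1, 400)
        total_area = counts.sum() * (edges[1] - edges[0])
        for comp, color in zip(rec["components"], ("tab:red", "tab:blue")):
            area = comp["area_fraction"] * total_area
            amp = area / (comp["width"] * np.sqrt(2 * np.pi))
            ax.plot(x, gauss(x, amp, comp["center"], comp["width"]),
                    color=color, lw=1.5,
                    label=f"{comp['center']:.2f}")
        ax.set_title(rec["scenario_label"], fontsize=9)
        ax.legend(fontsize=7)
        ax.set_xlim(0, 1.05)
    for ax in axes[-1]:
        ax.set_xlabel("FRET")
    for ax in axes[:, 0]:
        ax.set_ylabel("frames")
    fig.tight_layout()
    fig.savefig(FIG / "histograms.png", dpi=150)
    plt.close(fig)


def main() -> None:
    FIG.mkdir(parents=True, exist_ok=True)
    example_trace()
    histograms()
    print(f"wrote figures to {FIG}/")


if __name__ == "__main__":
    main()
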