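"""Diagnostic visuals and the plain-text run summary.

Four figures summarize a run:

* composition — stacked bars of each sample's species profile next to a
  "Theoretical" bar of the expected mix;
* rho — per-sample Spearman correlation with the theoretical mix;
* per-taxon — one panel per expected species, observed percent per
  sample with the theoretical percent as a reference line;
* unknown — per-sample percent of reads assigned to no expected member.

Plots are pure views of the compare-module outputs: every number drawn
here is taken verbatim from the profile/result objects, never
recomputed. SVG is the canonical format — with a fixed hash salt and the
date stripped, output bytes are reproducible, which tests exploit.
"""

from __future__ import annotations

import os
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.figure import Figure

from mockqc.compare import UNKNOWN_LABEL, ComparisonResult, SpeciesProfile
from mockqc.errors import ValidationError
from mockqc.reference import TheoreticalComposition

UNKNOWN_COLOR = "#8c8c8c"
_SVG_SALT = "mockqc"

PLOT_NAMES = ("composition", "rho", "per_taxon", "unknown")


def species_color_map(labels) -> dict[str, str]:
    """Stable categorical color per species, keyed by sorted label;
    Unknown is always the reserved grey."""
    palette = plt.get_cmap("tab20").colors
    ordered = sorted(l for l in labels if l != UNKNOWN_LABEL)
    colors = {
        label: matplotlib.colors.to_hex(palette[i % len(palette)])
        for i, label in enumerate(ordered)
    }
    colors[UNKNOWN_LABEL] = UNKNOWN_COLOR
    return colors


def _require_profiles(profiles) -> None:
    if not profiles:
        raise ValidationError("no profiles to plot")


def plot_composition(
    profiles: list[SpeciesProfile], tc: TheoreticalComposition
) -> Figure:
    """Stacked composition bars, one per sample plus one theoretical bar."""
    _require_profiles(profiles)
    labels = tc.species + [UNKNOWN_LABEL]
    colors = species_color_map(labels)
    bar_names = [p.sample_id for p in profiles] + ["Theoretical"]
    theoretical = {**tc.expected, UNKNOWN_LABEL: 0.0}
    stacks = [p.abundances for p in profiles] + [theoretical]

    fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(bar_names) + 2), 4.5))
    x = np.arange(len(bar_names))
    bottom = np.zeros(len(bar_names))
    for label in labels:
        heights = np.array([s.get(label, 0.0) for s in stacks])
        ax.bar(x, heights, bottom=bottom, label=label, color=colors[label], width=0.8)
        bottom += heights
    ax.set_xticks(x)
    ax.set_xticklabels(bar_names, rotation=45, ha="right")
    ax.set_ylabel("Relative abundance (%)")
    ax.set_ylim(0, 100)
    ax.set_title(f"Mock community composition ({tc.mock_name})")
    ax.legend(bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=8)
    fig.tight_layout()
    return fig


def plot_rho(results: list[ComparisonResult]) -> Figure:
    """Per-sample Spearman rho bars on a fixed [-1, 1] axis.

    A sample whose rho is undefined (all-tied ranks) gets no bar and an
    ``n/a`` annotation instead.
    """
    if not results:
        raise ValidationError("no comparison results to plot")
    fig, ax = plt.subplots(figsize=(max(6, 0.7 * len(results) + 2), 4))
    x = np.arange(len(results))
    for i, r in enumerate(results):
        if r.rho is None:
            ax.annotate("n/a", (i, 0.05), ha="center", fontsize=9)
        else:
            ax.bar(i, r.rho, color="#4878d0", width=0.7)
            ax.annotate(f"{r.rho:.2f}", (i, r.rho), ha="center",
                        va="bottom" if r.rho >= 0 else "top", fontsize=8)
    ax.set_xticks(x)
    ax.set_xticklabels([r.sample_id for r in results], rotation=45, ha="right")
    ax.set_ylim(-1, 1)
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_ylabel("Spearman rho vs theoretical")
    ax.set_title("Correlation with theoretical composition")
    fig.tight_layout()
    return fig


def plot_per_taxon(
    profiles: list[SpeciesProfile], tc: TheoreticalComposition
) -> Figure:
    """One panel per expected species: observed percent per sample as
    bars, theoretical percent as a horizontal reference line."""
    _require_profiles(profiles)
    species = tc.species
    colors = species_color_map(species + [UNKNOWN_LABEL])
    ncols = min(4, len(species))
    nrows = -(-len(species) // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False, sharex=True
    )
    x = np.arange(len(profiles))
    sample_ids = [p.sample_id for p in profiles]
    for idx, label in enumerate(species):
        ax = axes[idx // ncols][idx % ncols]
        observed = [p.abundances.get(label, 0.0) for p in profiles]
        ax.bar(x, observed, color=colors[label], width=0.7)
        ax.axhline(tc.expected[label], color="black", linestyle="--", linewidth=1)
        ax.set_title(label, fontsize=9)
        ax.set_xticks(x)
        ax.set_xticklabels(sample_ids, rotation=90, fontsize=7)
    for idx in range(len(species), nrows * ncols):
        axes[idx // ncols][idx % ncols].axis("off")
    fig.supylabel("Relative abundance (%)")
    fig.suptitle("Per-taxon abundance vs theoretical (dashed line)")
    fig.tight_layout()
    return fig


def plot_unknown(profiles: list[SpeciesProfile]) -> Figure:
    """Per-sample percent of reads not matching any expected member."""
    _require_profiles(profiles)
    fig, ax = plt.subplots(figsize=(max(6, 0.7 * len(profiles) + 2), 4))
    x = np.arange(len(profiles))
    values = [p.unknown_percent for p in profiles]
    ax.bar(x, values, color=UNKNOWN_COLOR, width=0.7)
    for i, v in enumerate(values):
        ax.annotate(f"{v:.2f}", (i, v), ha="center", va="bottom", fontsize=8)
    ax.set_xticks(x)
    ax.set_xticklabels([p.sample_id for p in profiles], rotation=45, ha="right")
    ax.set_ylim(0, 100)
    ax.set_ylabel("Unknown taxa (%)")
    ax.set_title("Reads not matching any expected taxon")
    fig.tight_layout()
    return fig


def summary_text(
    results: list[ComparisonResult],
    tc: TheoreticalComposition,
    params=None,
) -> str:
    lines = [
        f"mockqc run summary — mock: {tc.mock_name}",
        f"expected species: {len(tc.species)}",
    ]
    if params is not None:
        lines.append(
            f"classifier: k={params.k} bootstraps={params.n_bootstraps} "
            f"subsample={params.subsample_fraction} "
            f"threshold={params.confidence_threshold} seed={params.rng_seed}"
        )
    lines.append("")
    lines.append(f"{'sample':<12}{'rho':>10}{'unknown %':>12}")
    for r in results:
        rho = "n/a" if r.rho is None else f"{r.rho:.4f}"
        lines.append(f"{r.sample_id:<12}{rho:>10}{r.unknown_percent:>12.4f}")
    return "\n".join(lines) + "\n"


def save_figure(fig: Figure, path: str | os.PathLike) -> None:
    """Save with deterministic bytes for the SVG backend."""
    path = str(path)
    with matplotlib.rc_context({"svg.hashsalt": _SVG_SALT}):
        if path.endswith(".svg"):
            fig.savefig(path, metadata={"Date": None})
        else:
            fig.savefig(path)
    plt.close(fig)


def render_report(
    profiles: list[SpeciesProfile],
    results: list[ComparisonResult],
    tc: TheoreticalComposition,
    out_dir: str | os.PathLike,
    fmt: str = "svg",
    params=None,
) -> dict[str, Path]:
    """Write the four figures plus ``run_summary.txt`` into ``out_dir``."""
    if fmt not in ("svg", "png"):
        raise ValidationError(f"plot format must be 'svg' or 'png', got {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    figures = {
        "composition": plot_composition(profiles, tc),
        "rho": plot_rho(results),
        "per_taxon": plot_per_taxon(profiles, tc),
        "unknown": plot_unknown(profiles),
    }
    paths: dict[str, Path] = {}
    for name, fig in figures.items():
        p = out / f"{name}.{fmt}"
        save_figure(fig, p)
        paths[name] = p
    summary = summary_text(results, tc, params)
    summary_path = out / "run_summary.txt"
    summary_path.write_text(summary, encoding="utf-8")
    paths["summary"] = summary_path
    return paths
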