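"""Mode comparisons and summary figures.

Long-format tables comparing per-embryo calls across analysis modes
(posterior, category, error probability, linkage-site count, region span)
plus convenience plots: site-count boxplots per mode, a log-scale
error-probability strip chart, and per-embryo violins of the per-site
disease-origin evidence.  All quantitative checks run on the tables; the
figures are conveniences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .linkage_bayes import EmbryoCall

__all__ = ["ModeComparison", "compare_modes", "plot_summaries"]


@dataclass
class ModeComparison:
    """Per embryo x mode call table with its per-site audit rows."""

    table: pd.DataFrame    # embryo_id, mode, p_disease, category, error_probability, ...
    summary: pd.DataFrame  # per-mode medians / extremes
    audit: pd.DataFrame    # per-site evidence rows

    @property
    def n_category_changes(self) -> int:
        wide = self.table.pivot(index="embryo_id", columns="mode", values="category")
        return int((wide.nunique(axis=1) > 1).sum())


def compare_modes(calls_by_mode: dict[str, list[EmbryoCall]]) -> ModeComparison:
    """Build the long-format comparison table across analysis modes.

    All modes must cover the same embryo set.
    """
    if not calls_by_mode:
        raise ValueError("no calls supplied")
    embryo_sets = {
        mode: frozenset(c.embryo_id for c in calls)
        for mode, calls in calls_by_mode.items()
    }
    if len(set(embryo_sets.values())) != 1:
        raise ValueError(f"modes cover different embryo sets: {embryo_sets}")
    rows, audit_rows = [], []
    for mode, calls in calls_by_mode.items():
        for c in calls:
            rows.append({
                "embryo_id": c.embryo_id, "mode": mode, "p_disease": c.p_disease,
                "category": c.category, "error_probability": c.error_probability,
                "n_sites": c.n_sites_used, "span_bp": c.region_span_bp,
            })
            for r in c.site_audit:
                audit_rows.append({**r, "mode": mode})
    table = pd.DataFrame(rows)
    summary = table.groupby("mode").agg(
        n_embryos=("embryo_id", "nunique"),
        median_n_sites=("n_sites", "median"),
        min_error_probability=("error_probability", "min"),
        max_error_probability=("error_probability", "max"),
    ).reset_index()
    return ModeComparison(table, summary, pd.DataFrame(audit_rows))


def plot_summaries(comparison: ModeComparison, out_dir: str | Path) -> list[Path]:
    """Write the three summary figures; returns their paths."""
    if comparison.table.empty:
        raise ValueError("empty comparison")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    modes = sorted(comparison.table["mode"].unique())

    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(modes), 4))
    data = [comparison.table.loc[comparison.table["mode"] == m, "n_sites"] for m in modes]
    ax.boxplot(data, tick_labels=modes)
    ax.set_ylabel("linkage sites per embryo")
    p = out_dir / "site_counts.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(modes), 4))
    floor = 1e-12  # keep zero/sub-1e-12 posteriors on the log axis
    for i, m in enumerate(modes):
        vals = comparison.table.loc[comparison.table["mode"] == m, "error_probability"]
        x = np.full(len(vals), i + 1, dtype=float)
        x += np.linspace(-0.15, 0.15, len(vals))  # deterministic spread, no jitter
        ax.scatter(x, np.maximum(vals, floor), s=18)
    ax.set_yscale("log")
    ax.set_xticks(range(1, len(modes) + 1), modes)
    ax.set_ylabel("error probability")
    p = out_dir / "error_probabilities.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    if not comparison.audit.empty:
        link = comparison.audit[comparison.audit["side"] != "mutation"]
        embryos = sorted(link["embryo_id"].unique())
        data = [link.loc[link["embryo_id"] == e, "p_disease"] for e in embryos]
        data = [d if len(d) else pd.Series([0.5]) for d in data]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(embryos) + 1), embryos, rotation=45)
    ax.set_ylabel("per-site P(disease origin)")
    ax.set_ylim(-0.05, 1.05)
    p = out_dir / "site_evidence.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
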