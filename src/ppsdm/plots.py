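"""Figure rendering for experiment reports.

Every number a figure shows also lives in the report's CSV tables — the
images are presentation artifacts only.  Uses the non-interactive Agg
backend so rendering works headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402 - backend must be set first

from .derived_indices import IndexSeries, relative_series

__all__ = ["plot_index_series", "plot_logratio_map", "plot_report"]


def plot_index_series(series_by_label: dict[str, IndexSeries], component: str,
                      path: str | Path, relative: bool = False,
                      ylabel: str | None = None) -> Path:
    """Overlay per-scenario index series with their 95% bands."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, series in series_by_label.items():
        s = relative_series(series) if relative else series
        t = s.table[s.table["component"] == component]
        ax.errorbar(t["year"], t["estimate"],
                    yerr=[t["estimate"] - t["lwr"], t["upr"] - t["estimate"]],
                    marker="o", capsize=3, label=label, alpha=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel(ylabel or component)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_logratio_map(table, path: str | Path, isobath_m: float = 200.0) -> Path:
    """Map of fine-vs-coarse density log-ratios over the coarse blocks."""
    fig, ax = plt.subplots(figsize=(4, 8))
    lim = max(1e-3, float(abs(table["log_ratio"]).max()))
    sc = ax.scatter(table["easting_km"], table["northing_km"],
                    c=table["log_ratio"], cmap="RdBu_r", vmin=-lim, vmax=lim,
                    s=25, marker="s")
    brk = table[table["straddles_break"]]
    ax.scatter(brk["easting_km"], brk["northing_km"], facecolors="none",
               edgecolors="k", s=40, marker="s", linewidths=0.5,
               label=f"straddles {isobath_m:.0f} m")
    fig.colorbar(sc, ax=ax, label="log(fine / coarse)")
    ax.set_xlabel("Eastings (km)")
    ax.set_ylabel("Northings (km)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_report(report, outdir: str | Path) -> list[Path]:
    """Render the standard figures for one experiment report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    bios = {lb: sc["biomass"] for lb, sc in report.scenarios.items()
            if sc["biomass"] is not None}
    cogs = {lb: sc["cog"] for lb, sc in report.scenarios.items()
            if sc["cog"] is not None}
    if bios:
        comp = next(iter(bios.values())).table["component"].iloc[0]
        written.append(plot_index_series(
            bios, comp, outdir / f"{report.experiment}_biomass.png",
            relative=(comp == "biomass"), ylabel="relative biomass"))
    if cogs:
        for comp in ("north", "east"):
            written.append(plot_index_series(
                cogs, comp, outdir / f"{report.experiment}_cog_{comp}.png",
                ylabel=f"COG {comp} (km)"))
    for name, tab in report.tables.items():
        if name.startswith("logratio_") and len(tab):
            written.append(plot_logratio_map(
                tab, outdir / f"{report.experiment}_{name}_map.png"))
    return written
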