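"""Decision point 3: how coarse can the prediction grid be?

Takes one fitted model and predicts it to the native survey-resolution
grid and to 2x and 4x coarsened grids.  Reports (a) where fine and coarse
per-cell densities disagree (log-ratios, largest over blocks straddling
the shelf break, where averaging depth across the drop-off misplaces the
quadratic depth response), and (b) how little the aggregate biomass series
cares — the published Figs 6-8 pattern.  Output: results/resolution/.

Run:  python analysis/05_prediction_resolution.py [--seed 1]
"""

import argparse
from pathlib import Path

from ppsdm import (
    BathymetryProfile,
    default_params,
    make_domain,
    simulate_fields,
    simulate_survey,
)
from ppsdm.decision_experiments import resolution_experiment
from ppsdm.estimation import ModelSpec, fit

OUT = Path("results/resolution")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bath = BathymetryProfile(break_km=28.0, width_km=10.0)
    domain = make_domain(24, 60, (2.8, 3.7), bath)
    params = default_params(n_years=8, stations_per_year=180, seed=seed)
    fields = simulate_fields(domain, params, seed=seed)
    obs = simulate_survey(domain, fields, params, seed=seed)
    spec = ModelSpec(include_depth=True, st_mode="none", n_knots=40, n_starts=2)
    res = fit(spec, obs)
    report = resolution_experiment(res, domain.to_prediction_grid(),
                                   factors=(2, 4), seed=seed, n_draws=300)
    for factor in (2, 4):
        tab = report.tables[f"logratio_{factor}x"]
        brk = tab[tab["straddles_break"]]
        interior = tab[~tab["straddles_break"] & (tab["depth_coarse_m"] > 200)]
        print(f"{factor}x coarsening, final year: mean |log-ratio| "
              f"{brk['abs_log_ratio'].mean():.3f} over {len(brk)} shelf-break blocks vs "
              f"{interior['abs_log_ratio'].mean():.3f} over {len(interior)} slope-interior blocks")
    for label, sc in report.scenarios.items():
        bio = sc["biomass"].table
        rel = bio["estimate"] / bio["estimate"].max()
        print(f"  {label}: relative biomass range {rel.min():.3f}-1.000, "
              f"mean SE/est {float((bio['se'] / bio['estimate']).mean()):.3f}")
    report.write(OUT)
    from ppsdm.plots import plot_report

    plot_report(report, OUT)
    print(f"wrote {OUT}/resolution_*.csv/json")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
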