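"""Which climate variables correlate with leaf size, stem size, or the
allometry score itself?

Cleans the occurrence table, summarizes the bioclim variables per
species (mean, 5% and 95% quantiles), and runs the Bayes-factor
correlation grid for the three traits.  The full study grid is 3 traits
x 19 variables x 3 summaries (171 pairs, 342 model runs); this driver
runs a 3 x 4 x 1 sub-grid (the full grid is a flag away) so it finishes
in a few minutes, plus a PGLS of each trait on the bio15/bio19 axes.
"""

import warnings
from pathlib import Path

import pandas as pd

from leafstem import phylo_core as pc
from leafstem.bayes_correlation import correlation_grid, plan_grid
from leafstem.climate_summaries import clean_occurrences, summarize_climate
from leafstem.pgls_allometry import fit_pgls

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
VARIABLES = ["bio1", "bio12", "bio15", "bio19"]


def main() -> None:
    tree = pc.read_newick_file(ROOT / "data" / "tree.nwk")
    occ_raw = pd.read_csv(ROOT / "data" / "occurrences.csv")
    occ, report = clean_occurrences(occ_raw)
    print(f"cleaning: {report.as_dict()}")
    climate = summarize_climate(occ)
    climate.to_csv(ROOT / "climate_summaries.csv")

    truth = pd.read_csv(ROOT / "data" / "species_truth.csv").set_index("species")
    resid = pd.read_csv(ROOT / "residuals.csv", index_col=0)["residual"]
    traits = pd.DataFrame({
        "residual": resid,
        "log_leaf_area": truth["log_leaf_area"],
        "log_stem_area": truth["log_stem_area"],
    })

    full = plan_grid(list(traits.columns), [f"bio{i}" for i in range(1, 20)],
                     ["mean", "q05", "q95"])
    print(f"full study grid: {len(full) // 2} pairs, {len(full)} model runs; "
          f"running {len(traits.columns) * len(VARIABLES)} mean-summary pairs")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        grid = correlation_grid(
            tree, traits, climate, variables=VARIABLES, summaries=["mean"],
            stones=10, iters_per_stone=300, seed=SEED,
        )
    grid.to_csv(ROOT / "correlation_grid.csv", index=False)
    for _, row in grid.iterrows():
        print(f"  {row['trait']:>14} x {row['variable']:>5}: "
              f"logBF {row['logbf']:7.2f}  ({row['class']})")

    # PGLS of each trait on the two rainfall axes of interest
    rows = []
    for var in ("bio15", "bio19"):
        for trait in ("log_leaf_area", "log_stem_area"):
            tab = pd.DataFrame({
                "species": traits.index,
                trait: traits[trait].to_numpy(),
                var: climate[(var, "mean")].reindex(traits.index).to_numpy(),
            })
            f = fit_pgls(tree, tab, response=trait, predictor=var)
            rows.append({"trait": trait, "variable": var, "slope": f.slope,
                         "slope_p": f.p[1], "intercept": f.intercept,
                         "intercept_p": f.p[0]})
            print(f"  PGLS {trait} ~ {var}: slope {f.slope:.4f} "
                  f"(p = {f.p[1]:.2g})")
    pd.DataFrame(rows).to_csv(ROOT / "pgls_vs_climate.csv", index=False)


if __name__ == "__main__":
    main()
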