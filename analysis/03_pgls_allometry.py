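"""Leaf/stem scaling by PGLS under the OU error structure.

Fits the whole-clade regression of log stem cross-sectional area on log
leaf area, then per-group fits by mutualistic strategy and by plant
architecture, and writes the regression summary table plus the
per-species residuals (the allometry scores used by script 04).
"""

import warnings
from pathlib import Path

import pandas as pd

from leafstem import phylo_core as pc
from leafstem.pgls_allometry import (
    aggregate_species,
    fit_pgls,
    fit_pgls_by_group,
    pgls_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tree = pc.read_newick_file(ROOT / "data" / "tree.nwk")
    specimens = pd.read_csv(ROOT / "data" / "specimens.csv")
    species = aggregate_species(specimens)

    fit = fit_pgls(tree, species)
    print(
        f"whole clade (n={fit.n}): log stem area = "
        f"{fit.slope:.2f} * log leaf area {fit.intercept:+.2f}  "
        f"(slope F(1,{fit.df_resid}) = {fit.F[1]:.2f}, p = {fit.p[1]:.2g}; "
        f"OU alpha = {fit.alpha:.2f})"
    )

    tables = [pgls_table({"all": fit})]
    for grouping in ("strategy", "architecture"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fits = fit_pgls_by_group(tree, species, grouping)
        tab = pgls_table(fits)
        tab.insert(0, "grouping", grouping)
        tables.append(tab)
        for g, f in fits.items():
            if g != "_skipped":
                print(f"  {grouping}/{g}: slope {f.slope:.2f} "
                      f"(SE {f.se[1]:.2f}), intercept {f.intercept:.2f} "
                      f"(SE {f.se[0]:.2f}), n={f.n}")

    pd.concat(tables).to_csv(ROOT / "pgls_table.csv", index=False)
    fit.residuals.rename("residual").to_csv(ROOT / "residuals.csv")
    print(f"wrote {ROOT / 'pgls_table.csv'} and residuals.csv")


if __name__ == "__main__":
    main()
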