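"""Do allometry scores differ among mutualistic strategies, and where
did the OU optimum shift?

Takes the PGLS residuals from script 03 as species-specific allometry
scores, tests group differences with a simulation-based phylogenetic
ANOVA (10,000 BM simulations), searches for shifts in the OU selection
optimum along branches (up to 10, ranked S1.. by stepwise AIC), and
exports phenogram coordinates for plotting residuals against time.
"""

from pathlib import Path

import pandas as pd

from leafstem import phylo_core as pc
from leafstem.shift_inference import detect_ou_shifts, phenogram_coords, phylo_anova

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    tree = pc.read_newick_file(ROOT / "data" / "tree.nwk")
    resid = pd.read_csv(ROOT / "residuals.csv", index_col=0)["residual"]
    truth = pd.read_csv(ROOT / "data" / "species_truth.csv").set_index("species")

    groups = truth.loc[resid.index, "strategy"]
    an = phylo_anova(tree, resid, groups, nsim=10_000, seed=SEED)
    print(f"phylogenetic ANOVA: F = {an.F:.2f}, p = {an.p:.4f} "
          f"({an.n_sim} simulations)")
    an.posthoc_p.to_csv(ROOT / "anova_posthoc_p.csv")
    pd.DataFrame(
        [{"F": an.F, "p": an.p, "n_sim": an.n_sim}]
    ).to_csv(ROOT / "anova.csv", index=False)

    shifts = detect_ou_shifts(tree, resid, nmax=10, seed=SEED)
    print(f"OU shift search: {shifts.selected} shift(s) selected "
          f"(alpha = {shifts.alpha:.2f}); candidates ranked:")
    for i, (node, tips, aic) in enumerate(shifts.shifts[:5]):
        mark = "*" if i < shifts.selected else " "
        print(f" {mark}S{i + 1}: clade of {len(tips)} species, AIC {aic:.2f}")
    shifts.to_frame().to_csv(ROOT / "ou_shifts.csv", index=False)

    nodes, edges = phenogram_coords(tree, resid)
    nodes.to_csv(ROOT / "phenogram_nodes.csv", index=False)
    edges.to_csv(ROOT / "phenogram_edges.csv", index=False)
    print(f"wrote anova.csv, ou_shifts.csv and phenogram coordinates to {ROOT}")


if __name__ == "__main__":
    main()
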