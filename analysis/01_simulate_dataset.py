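"""Generate the synthetic study dataset.

Produces a 70-species dated tree (unit height), a specimen table
(~10 measured leaves and one stem diameter per specimen, 15% lognormal
measurement noise) whose species-level truth follows the allometric
line log(stem area) = 0.60 * log(leaf area) - 4.58 with OU residual
structure and a lowered intercept for specialized ant-plants, and an
occurrence table with 19 bioclim values per record in which bio15
(precipitation seasonality) is correlated with log leaf area.
"""

from pathlib import Path

import pandas as pd

from leafstem import phylo_core as pc
from leafstem import synthetic_data as sd

SEED = 1
N_SPECIES = 70
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tree = sd.sim_tree(N_SPECIES, seed=SEED)
    config = sd.GeneratorConfig(
        seed=SEED,
        n_species=N_SPECIES,
        group_intercepts={"specialized": -2.88},
    )
    specimens, truth = sd.sim_allometry_dataset(tree, config)

    # architecture and domatium growth evolve jointly: single stems gain
    # apical growth fast (and vice versa), a dependent Mk process
    Q = sd.pagel_rate_matrix([0.3, 0.3, 0.3, 3.0, 0.3, 3.0, 0.3, 0.3])
    arch01, dom01, _ = sd.sim_discrete(tree, Q, coupling="dependent",
                                       seed=SEED + 5, root_state=0)
    arch = pd.Series(arch01, index=tree.tip_labels).map(
        dict(enumerate(sd.ARCHITECTURES)))
    dom = pd.Series(dom01, index=tree.tip_labels).map(
        dict(enumerate(sd.DOMATIUM_GROWTH)))
    truth["architecture"] = arch.loc[truth["species"]].to_numpy()
    truth["domatium_growth"] = dom.loc[truth["species"]].to_numpy()
    specimens["architecture"] = arch.loc[specimens["species"]].to_numpy()
    specimens["domatium_growth"] = dom.loc[specimens["species"]].to_numpy()

    occurrences = sd.sim_occurrences(
        tree.tip_labels,
        seed=SEED,
        n_per_species=20,
        correlate_with=truth.set_index("species").loc[
            tree.tip_labels, "log_leaf_area"
        ].to_numpy(),
        rho=0.8,
        correlated_variable="bio15",
        n_duplicates=5,
        n_zero_coords=3,
    )
    (OUT / "tree.nwk").write_text(pc.write_newick(tree))
    specimens.to_csv(OUT / "specimens.csv", index=False)
    truth.to_csv(OUT / "species_truth.csv", index=False)
    occurrences.to_csv(OUT / "occurrences.csv", index=False)
    print(
        f"wrote {len(specimens)} specimen rows, {N_SPECIES} species truth rows "
        f"and {len(occurrences)} occurrences to {OUT}"
    )


if __name__ == "__main__":
    main()
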