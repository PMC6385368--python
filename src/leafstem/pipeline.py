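"""End-to-end orchestration of the comparative-allometry analysis.

Stages, in the order the results build on each other: aggregate
specimens to species -> continuous-trait model selection -> PGLS (whole
clade and per group) -> residual allometry scores -> phylogenetic ANOVA
-> OU optimum-shift search -> discrete-character fits, stochastic maps
and Pagel's test -> climate summaries -> trait-climate correlation grid
-> phenogram exports.  Every stage writes a CSV; a JSON manifest records
settings, seeds and per-stage wall time.  In synthetic mode the pipeline
generates its own inputs with known ground truth.
"""

from __future__ import annotations

import argparse
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .phylo_core import PhyloTree, prune_to_taxa, read_newick_file, write_newick
from . import synthetic_data as sdata
from .pgls_allometry import aggregate_species, fit_pgls, fit_pgls_by_group, pgls_table
from .trait_models import model_select
from .shift_inference import detect_ou_shifts, phenogram_coords, phylo_anova
from .discrete_evolution import fit_mk, pagel_test, simmap, summarize_histories
from .climate_summaries import clean_occurrences, summarize_climate
from .bayes_correlation import correlation_grid

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "main"]

log = logging.getLogger("leafstem")


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; ``synthetic=True`` generates all
    inputs, otherwise ``tree_path``/``specimen_path``/``occurrence_path``
    must exist."""

    output_dir: str = "results/pipeline"
    synthetic: bool = True
    tree_path: str | None = None
    specimen_path: str | None = None
    occurrence_path: str | None = None
    seed: int = 0
    n_species: int = 40
    log_base: float | None = None  # natural log
    error_model: str = "OU"
    anova_nsim: int = 1000
    shift_nmax: int = 4
    stones: int = 8
    iters_per_stone: int = 200
    grid_variables: tuple = ("bio1", "bio12", "bio15")
    grid_summaries: tuple = ("mean",)
    grouping: str = "strategy"

    def validate(self) -> list[str]:
        problems = []
        if not self.synthetic:
            for name in ("tree_path", "specimen_path", "occurrence_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    problems.append(f"{name}: missing file {p!r}")
        if self.anova_nsim < 100:
            problems.append("anova_nsim must be >= 100")
        if self.shift_nmax < 1:
            problems.append("shift_nmax must be >= 1")
        if self.stones < 2 or self.iters_per_stone < 100:
            problems.append("MCMC settings out of range")
        return problems


def validate_inputs(
    tree: PhyloTree, specimens: pd.DataFrame, occurrences: pd.DataFrame | None = None
) -> dict:
    """Report-only consistency check of tree vs tables: species dropped on
    either side, label vocabulary violations, non-positive measurements."""
    report: dict = {"dropped_not_in_tree": [], "tree_tips_without_data": [],
                    "bad_labels": {}, "nonpositive_rows": 0, "errors": []}
    sp_data = set(specimens["species"].unique())
    sp_tree = set(tree.tip_labels)
    report["dropped_not_in_tree"] = sorted(sp_data - sp_tree)
    report["tree_tips_without_data"] = sorted(sp_tree - sp_data)
    if not sp_data & sp_tree:
        report["errors"].append("empty tree/table species intersection")
    vocab = {
        "architecture": set(sdata.ARCHITECTURES),
        "domatium_growth": set(sdata.DOMATIUM_GROWTH),
        "strategy": set(sdata.STRATEGIES),
    }
    for col, allowed in vocab.items():
        if col in specimens.columns:
            bad = sorted(set(specimens[col].unique()) - allowed)
            if bad:
                report["bad_labels"][col] = bad
    num = specimens[["leaf_area_mm2", "stem_diameter_mm"]]
    report["nonpositive_rows"] = int((num <= 0).any(axis=1).sum())
    if occurrences is not None:
        report["occ_species_missing"] = sorted(
            sp_tree - set(occurrences["species"].unique())
        )
    return report


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = {
                "seconds": round(dt, 3),
                "ok": exc_type is None,
            }
            if exc_type is not None:
                manifest["failed_stage"] = name
                log.error("stage %s failed after %.2fs: %s", name, dt, exc)
            else:
                log.info("stage %s: done in %.2fs", name, dt)

    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON).

    Any stage failure halts the run with the stage name in the raised
    error and in the manifest.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "settings": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(config).items()},
        "stages": {},
        "outputs": [],
    }

    def save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, index=kw.pop("index", False), **kw)
        manifest["outputs"].append(name)

    try:
        with _stage(manifest, "inputs"):
            if config.synthetic:
                tree = sdata.sim_tree(config.n_species, seed=config.seed)
                gc = sdata.GeneratorConfig(
                    seed=config.seed, n_species=config.n_species,
                    group_intercepts={"specialized": -2.88},
                )
                specimens, truth = sdata.sim_allometry_dataset(tree, gc)
                occurrences = sdata.sim_occurrences(
                    tree.tip_labels, seed=config.seed, n_per_species=10
                )
                (out / "tree.nwk").write_text(write_newick(tree))
                save(specimens, "specimens.csv")
                save(truth, "species_truth.csv")
            else:
                tree = read_newick_file(config.tree_path)
                specimens = pd.read_csv(config.specimen_path)
                occurrences = pd.read_csv(config.occurrence_path)
            report = validate_inputs(tree, specimens, occurrences)
            (out / "validation.json").write_text(json.dumps(report, indent=2))
            if report["errors"]:
                raise ValueError(f"input validation failed: {report['errors']}")

        with _stage(manifest, "aggregate"):
            species = aggregate_species(specimens, log_base=config.log_base)
            keep = [s for s in species["species"] if s in set(tree.tip_labels)]
            species = species[species["species"].isin(keep)]
            tree = prune_to_taxa(tree, keep)
            save(species.sort_values("species"), "species_table.csv")

        with _stage(manifest, "model_selection"):
            import warnings

            tabs = {}
            idx = species.set_index("species")
            for trait in ("log_leaf_area", "log_stem_area"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    tabs[trait] = model_select(tree, idx[trait])
                tabs[trait].insert(0, "trait", trait)
            save(pd.concat(tabs.values()), "model_selection.csv")

        with _stage(manifest, "pgls"):
            fit_all = fit_pgls(tree, species, error_model=config.error_model)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fits = fit_pgls_by_group(
                    tree, species, config.grouping, error_model=config.error_model
                )
            table = pd.concat([pgls_table({"all": fit_all}), pgls_table(fits)])
            save(table, "pgls_table.csv")
            resid = fit_all.residuals.rename("residual").to_frame()
            save(resid.sort_index(), "residuals.csv", index=True)

        with _stage(manifest, "phylo_anova"):
            groups = species.set_index("species")[config.grouping]
            an = phylo_anova(
                tree, fit_all.residuals, groups, nsim=config.anova_nsim,
                seed=config.seed,
            )
            save(
                pd.DataFrame(
                    [{"F": an.F, "p": an.p, "n_sim": an.n_sim,
                      "groups": ";".join(an.groups)}]
                ),
                "anova.csv",
            )
            save(an.posthoc_p, "anova_posthoc_p.csv", index=True)

        with _stage(manifest, "ou_shifts"):
            shifts = detect_ou_shifts(
                tree, fit_all.residuals, nmax=config.shift_nmax, seed=config.seed
            )
            save(shifts.to_frame(), "ou_shifts.csv")

        with _stage(manifest, "discrete"):
            idx = species.set_index("species")
            arch = (idx["architecture"] == sdata.ARCHITECTURES[1]).astype(int)
            dom = (idx["domatium_growth"] == sdata.DOMATIUM_GROWTH[1]).astype(int)
            rows = []
            for name, states in (("architecture", arch), ("domatium_growth", dom)):
                for structure in ("ER", "ARD"):
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)
                        m, lnl, aic = fit_mk(tree, states, structure)
                    rows.append(
                        {"trait": name, "structure": structure, "q01": m.q01,
                         "q10": m.q10, "lnL": lnl, "AIC": aic}
                    )
            save(pd.DataFrame(rows), "mk_fits.csv")
            m, _, _ = fit_mk(tree, arch, "ER")
            hists = de_simmap_safe(tree, arch, m, nsim=200, seed=config.seed)
            summ = summarize_histories(tree, hists)
            save(
                pd.DataFrame(
                    summ["node_probabilities"],
                    columns=["p_state0", "p_state1"],
                ).assign(node=np.arange(tree.n_nodes)),
                "simmap_node_probs.csv",
            )
            pr = pagel_test(
                tree, arch, dom, stones=config.stones,
                iters_per_stone=config.iters_per_stone, seed=config.seed,
            )
            save(
                pd.DataFrame(
                    [{"ss_dependent": pr.ss_dependent,
                      "ss_independent": pr.ss_independent,
                      "logBF": pr.logbf, "class": pr.classification}]
                ),
                "pagel.csv",
            )

        with _stage(manifest, "climate"):
            occ, rep = clean_occurrences(occurrences)
            (out / "occurrence_cleaning.json").write_text(
                json.dumps(rep.as_dict(), indent=2)
            )
            climate = summarize_climate(occ)
            save(climate, "climate_summaries.csv", index=True)

        with _stage(manifest, "correlation_grid"):
            traits = pd.DataFrame(
                {
                    "residual": fit_all.residuals,
                    "log_leaf_area": species.set_index("species")["log_leaf_area"],
                    "log_stem_area": species.set_index("species")["log_stem_area"],
                }
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                grid = correlation_grid(
                    tree, traits, climate,
                    variables=list(config.grid_variables),
                    summaries=list(config.grid_summaries),
                    stones=config.stones,
                    iters_per_stone=config.iters_per_stone,
                    seed=config.seed,
                )
            save(grid, "correlation_grid.csv")

        with _stage(manifest, "phenograms"):
            nodes, edges = phenogram_coords(tree, fit_all.residuals)
            save(nodes, "phenogram_nodes.csv")
            save(edges, "phenogram_edges.csv")
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def de_simmap_safe(tree, states, model, nsim, seed):
    """simmap, falling back to a tiny positive rate for degenerate data."""
    from .discrete_evolution import MkModel, simmap as _simmap

    if model.q01 <= 0:
        model = MkModel(1e-6, 1e-6, "ER")
    return _simmap(tree, states, model, nsim=nsim, seed=seed)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _add_common(p: argparse.ArgumentParser) -> None:
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", default="results/pipeline")
    p.add_argument("--n-species", type=int, default=40)


def main(argv: list[str] | None = None) -> int:
    ap = argparse.ArgumentParser(
        prog="leafstem",
        description="Phylogenetic comparative analysis of leaf/stem allometry",
    )
    sub = ap.add_subparsers(dest="cmd", required=True)
    p_sim = sub.add_parser("simulate", help="generate a synthetic dataset")
    _add_common(p_sim)
    p_val = sub.add_parser("validate", help="validate input files")
    p_val.add_argument("--tree", required=True)
    p_val.add_argument("--specimens", required=True)
    p_val.add_argument("--occurrences")
    p_run = sub.add_parser("run", help="run the full pipeline")
    _add_common(p_run)
    p_run.add_argument("--tree")
    p_run.add_argument("--specimens")
    p_run.add_argument("--occurrences")
    p_run.add_argument("--anova-nsim", type=int, default=1000)
    p_run.add_argument("--shift-nmax", type=int, default=4)
    p_run.add_argument("--stones", type=int, default=8)
    p_run.add_argument("--iters-per-stone", type=int, default=200)
    args = ap.parse_args(argv)

    if args.cmd == "simulate":
        out = Path(args.out)
        out.mkdir(parents=True, exist_ok=True)
        tree = sdata.sim_tree(args.n_species, seed=args.seed)
        gc = sdata.GeneratorConfig(seed=args.seed, n_species=args.n_species)
        specimens, truth = sdata.sim_allometry_dataset(tree, gc)
        occ = sdata.sim_occurrences(tree.tip_labels, seed=args.seed)
        (out / "tree.nwk").write_text(write_newick(tree))
        specimens.to_csv(out / "specimens.csv", index=False)
        truth.to_csv(out / "species_truth.csv", index=False)
        occ.to_csv(out / "occurrences.csv", index=False)
        print(f"wrote synthetic dataset ({tree.n_tips} species) to {out}")
        return 0
    if args.cmd == "validate":
        tree = read_newick_file(args.tree)
        specimens = pd.read_csv(args.specimens)
        occ = pd.read_csv(args.occurrences) if args.occurrences else None
        report = validate_inputs(tree, specimens, occ)
        print(json.dumps(report, indent=2))
        return 1 if report["errors"] else 0
    if args.cmd == "run":
        cfg = PipelineConfig(
            output_dir=args.out,
            seed=args.seed,
            n_species=args.n_species,
            synthetic=args.tree is None,
            tree_path=args.tree,
            specimen_path=args.specimens,
            occurrence_path=args.occurrences,
            anova_nsim=args.anova_nsim,
            shift_nmax=args.shift_nmax,
            stones=args.stones,
            iters_per_stone=args.iters_per_stone,
        )
        manifest = run_pipeline(cfg)
        print(json.dumps({k: v for k, v in manifest.items() if k != "settings"},
                         indent=2))
        return 0
    return 2


if __name__ == "__main__":
    raise SystemExit(main())
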