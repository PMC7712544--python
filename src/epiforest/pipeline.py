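"""End-to-end pipeline: input -> GWAS baseline -> stage-1 forest screen ->
r2VIM -> forest-structure epistasis screen -> interaction GLM -> networks ->
per-network decision trees.

Every stage writes a TSV artifact and a line in the JSON run manifest
(seeds, thresholds, counts in/out).  One global seed fans out to per-stage
seed streams so stages are reproducible in isolation; manifests contain no
timestamps and are byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import epistasis, gwas, interaction, network, r2vim
from .forest import corrected_impurity, train_forest
from .io_genotype import GenotypeMatrix, PhenotypeTable, filter_variants, read_tped
from .sim_data import SimulationSpec, simulate, truth_set

logger = logging.getLogger(__name__)

SEX_FEATURE = "SEX"


@dataclass
class PipelineConfig:
    """Defaults reproduce the reference analysis settings; tests override
    tree counts with a desk-scale profile."""

    # input: either a simulation spec or a tped/tfam prefix
    simulation: SimulationSpec | None = None
    tped_prefix: str | None = None

    maf_min: float = 0.01
    autosomes_only: bool = True
    include_sex: bool = True

    stage1_n_trees: int = 1000
    stage1_mtry_fraction: float = 1 / 3
    stage1_min_node_fraction: float = 0.1
    stage1_p_threshold: float = 0.01
    # rank-based handoff for small desk feature counts, where the
    # mirrored-null empirical p-value is too coarse; None = p-threshold
    stage1_top_k: int | None = None

    r2vim_n_forests: int = 11
    r2vim_n_trees: int = 10_000
    r2vim_mtry_fraction: float = 1 / 3
    r2vim_min_node_fraction: float = 0.1
    r2vim_threshold: float = 1.0

    fdr_ensemble: float = 0.05
    fdr_interaction: float = 0.05
    min_cell: int = 10

    # dedicated screening forest grown on the r2VIM-selected features; None
    # falls back to the saved final r2VIM forest (the reference behaviour)
    screen_n_trees: int | None = None
    screen_min_node_fraction: float = 0.2
    screen_mtry_fraction: float = 0.15

    # which pairs seed the networks: 'interaction' = confirmed by the GLM
    # second FDR pass; 'screen' = all ensemble-retained pairs
    network_gate: str = "interaction"

    network_alpha: float = 0.05
    network_min_leaf: int = 20
    or_mode: str = "complement"

    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None and not isinstance(
                d["simulation"], SimulationSpec):
            sim = dict(d["simulation"])
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            sim["main_effects"] = [tuple(t) for t in sim.get("main_effects", [])]
            sim["interactions"] = [tuple(t) for t in sim.get("interactions", [])]
            sim["ld_blocks"] = [tuple(t) for t in sim.get("ld_blocks", [])]
            sim["maf_overrides"] = [tuple(t) for t in sim.get("maf_overrides", [])]
            d["simulation"] = SimulationSpec(**sim)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PipelineResult:
    manifest: dict
    gm: GenotypeMatrix
    pheno: PhenotypeTable
    gwas_result: gwas.GwasResult | None = None
    importance: object = None
    stage1_selected: np.ndarray | None = None
    r2vim_result: r2vim.R2vimResult | None = None
    screen: epistasis.PairScreenResult | None = None
    interactions: pd.DataFrame | None = None
    networks: list = field(default_factory=list)
    network_trees: list = field(default_factory=list)


def _stage_seeds(seed: int, n: int = 10) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    if config.network_gate not in ("interaction", "screen"):
        raise ValueError(f"bad network_gate {config.network_gate!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {"seed": config.seed, "config": _config_dict(config), "stages": []}

    def record(name, seed, n_in, n_out, **extra):
        entry = {"stage": name, "seed": seed, "n_in": n_in, "n_out": n_out}
        entry.update(extra)
        manifest["stages"].append(entry)
        logger.info("stage %-12s in=%s out=%s", name, n_in, n_out)

    def finish(result):
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return result

    # ---- stage 1: input ---------------------------------------------------
    if config.simulation is not None:
        spec = dataclasses.replace(config.simulation, seed=seeds[0])
        gm, pheno, truth = simulate(spec)
        truth.to_frame(gm.variant_ids()).to_csv(out / "truth.tsv", sep="\t",
                                                index=False)
    elif config.tped_prefix is not None:
        gm, pheno = read_tped(f"{config.tped_prefix}.tped",
                              f"{config.tped_prefix}.tfam")
    else:
        raise ValueError("config needs a simulation spec or a tped prefix")
    record("input", seeds[0], None, gm.n_variants,
           n_subjects=gm.n_subjects, n_cases=pheno.n_cases)

    # ---- stage 2: variant filters ----------------------------------------
    n_before = gm.n_variants
    gm = filter_variants(gm, maf_min=config.maf_min,
                         autosomes_only=config.autosomes_only)
    record("filter", None, n_before, gm.n_variants,
           maf_min=config.maf_min, autosomes_only=config.autosomes_only)

    result = PipelineResult(manifest=manifest, gm=gm, pheno=pheno)

    # modelling matrix: dosages plus optional sex column
    feature_names = gm.variant_ids()
    X = gm.dosages
    if config.include_sex and pheno.sex is not None:
        X = np.column_stack([X, pheno.sex.astype(np.int8)])
        feature_names = feature_names + [SEX_FEATURE]
    y = pheno.status

    # ---- stage 3: GWAS baseline ------------------------------------------
    gres = gwas.additive_scan(gm, pheno)
    gres.write_tsv(out / "gwas.tsv")
    result.gwas_result = gres
    record("gwas", None, gm.n_variants, len(gres))

    # ---- stage 4: stage-1 forest + corrected impurity screen -------------
    ctx = train_forest(X, y, n_trees=config.stage1_n_trees,
                       mtry_fraction=config.stage1_mtry_fraction,
                       min_node_fraction=config.stage1_min_node_fraction,
                       seed=seeds[1], shadow=True)
    imp = corrected_impurity(ctx)
    imp.to_frame(feature_names).to_csv(out / "stage1_importance.tsv",
                                       sep="\t", index=False)
    if config.stage1_top_k is not None:
        order = np.argsort(imp.corrected)[::-1]
        stage1_idx = np.sort(order[:config.stage1_top_k])
    else:
        stage1_idx = np.flatnonzero(imp.p_value < config.stage1_p_threshold)
    result.importance = imp
    result.stage1_selected = stage1_idx
    record("stage1_forest", seeds[1], X.shape[1], len(stage1_idx),
           n_trees=config.stage1_n_trees,
           p_threshold=config.stage1_p_threshold,
           top_k=config.stage1_top_k)

    if len(stage1_idx) < 2:
        record("r2vim", seeds[2], len(stage1_idx), 0, skipped=True)
        record("epistasis_screen", seeds[3], 0, 0, skipped=True)
        record("interaction", None, 0, 0, skipped=True)
        record("networks", None, 0, 0, skipped=True)
        return finish(result)

    # ---- stage 5: r2VIM ---------------------------------------------------
    sub_names = [feature_names[i] for i in stage1_idx]
    Xsub = np.ascontiguousarray(X[:, stage1_idx])
    rres = r2vim.run_r2vim(
        Xsub, y, n_forests=config.r2vim_n_forests,
        n_trees=config.r2vim_n_trees,
        mtry_fraction=config.r2vim_mtry_fraction,
        min_node_fraction=config.r2vim_min_node_fraction,
        threshold=config.r2vim_threshold, seed=seeds[2])
    rres.to_frame(sub_names).to_csv(out / "r2vim.tsv", sep="\t", index=False)
    rres.final_forest.to_json(out / "final_forest.json")
    sel_sub = rres.selected_indices()
    result.r2vim_result = rres
    record("r2vim", seeds[2], len(stage1_idx), len(sel_sub),
           n_forests=config.r2vim_n_forests, n_trees=config.r2vim_n_trees,
           threshold=config.r2vim_threshold)

    sel_names = [sub_names[i] for i in sel_sub]

    # ---- stage 6: forest-structure epistasis screen ----------------------
    if config.screen_n_trees is not None and len(sel_sub) >= 2:
        # scarce dedicated forest over the full stage-1 feature set (like
        # the saved final forest, but with many cheap small trees): features
        # must compete for a handful of nodes, which is what makes paired
        # selection frequency informative at desk scale
        sctx = train_forest(
            Xsub, y, n_trees=config.screen_n_trees,
            mtry_fraction=config.screen_mtry_fraction,
            min_node_fraction=config.screen_min_node_fraction,
            seed=seeds[3])
        screen_forest = sctx.forest
    else:
        screen_forest = rres.final_forest
    screen_features = sel_sub
    screen = epistasis.screen_pairs(screen_forest, screen_features,
                                    fdr_threshold=config.fdr_ensemble,
                                    feature_ids=sel_names)
    screen.write_tsv(out / "pair_screen.tsv")
    retained = screen.retained()
    result.screen = screen
    record("epistasis_screen", None, len(screen.table), len(retained),
           fdr=config.fdr_ensemble)

    # ---- stage 7: interaction GLM ----------------------------------------
    col_lookup = {name: X[:, k] for k, name in enumerate(feature_names)}
    glm_results = []
    for _, row in retained.iterrows():
        glm_results.append(interaction.min_interaction_p(
            col_lookup[row["feature_i"]], col_lookup[row["feature_j"]], y,
            min_cell=config.min_cell,
            feature_i=row["feature_i"], feature_j=row["feature_j"]))
    itable = interaction.fdr_pass(glm_results, threshold=config.fdr_interaction)
    itable.to_csv(out / "interactions.tsv", sep="\t", index=False)
    result.interactions = itable
    record("interaction", None, len(retained), len(itable),
           fdr=config.fdr_interaction, min_cell=config.min_cell)

    # ---- stage 8: networks + decision trees ------------------------------
    if config.network_gate == "interaction":
        seed_pairs = itable[itable["significant"]]
    elif config.network_gate == "screen":
        seed_pairs = itable
    else:
        raise ValueError(f"bad network_gate {config.network_gate!r}")
    pair_list = [(r["feature_i"], r["feature_j"], r["q_interaction"])
                 for _, r in seed_pairs.iterrows()]
    networks = network.condense_networks(pair_list)
    result.networks = networks
    with open(out / "networks.tsv", "w") as fh:
        fh.write("network_id\tmembers\n")
        for net in networks:
            fh.write(f"{net.network_id}\t{','.join(map(str, net.members))}\n")

    trees = []
    for net in networks:
        cols = {m: col_lookup[m] for m in net.members if m in col_lookup}
        ntree = network.fit_network_tree(net, cols, y,
                                         alpha=config.network_alpha,
                                         min_leaf=config.network_min_leaf)
        network.terminal_odds_ratios(ntree, y, mode=config.or_mode)
        trees.append(ntree)
        base = out / f"network_{net.network_id}"
        ntree.leaf_table().to_csv(f"{base}_leaves.tsv", sep="\t", index=False)
        with open(f"{base}.dot", "w") as fh:
            fh.write(ntree.to_dot())
        with open(f"{base}.txt", "w") as fh:
            fh.write(ntree.to_outline())
    result.network_trees = trees
    record("networks", None, len(itable), len(networks),
           alpha=config.network_alpha, or_mode=config.or_mode)

    return finish(result)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("simulation") is not None:
        sim = d["simulation"]
        sim["maf_range"] = list(sim["maf_range"])
        sim["main_effects"] = [list(t) for t in sim["main_effects"]]
        sim["interactions"] = [list(t) for t in sim["interactions"]]
        sim["ld_blocks"] = [list(t) for t in sim["ld_blocks"]]
        sim["maf_overrides"] = [list(t) for t in sim["maf_overrides"]]
    return d
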