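"""Recovery benchmarks on synthetic compendia with known ground truth.

These drive the acceptance checks: module/hub recovery on the default
compendium and leave-class-out specificity on a reduced one. Both return
per-seed records so callers can count successes across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import graph, perturb, preprocess
from .enrichment import GeneSetCollection
from .inference import InferenceParams, infer_weight_matrix, standardize_profiles, threshold_edges
from .simulate import SimConfig, generate_compendium

# At the synthetic scale (~80-node graphs) greedy modularity's resolution
# limit fragments planted 40-gene modules; see detect_modules docstring.
RECOVERY_TOP_DENSITY = 8.0
RECOVERY_RESOLUTION = 0.5


@dataclass
class RecoveryResult:
    seed: int
    ari: float
    hub_ranks: dict[str, int | None]  # hub gene -> degree rank within module

    @property
    def hubs_top5(self) -> bool:
        return all(r is not None and r <= 5 for r in self.hub_ranks.values())


def _adjusted_rand(labels_a: list, labels_b: list) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))


def module_hub_recovery(
    seed: int,
    n_trees: int = 200,
    sim_config: SimConfig | None = None,
    top_density: float = RECOVERY_TOP_DENSITY,
    resolution: float = RECOVERY_RESOLUTION,
    min_size: int = 12,
) -> RecoveryResult:
    """Run the full pipeline on one simulated compendium and score recovery.

    ARI compares detected module labels against planted membership over the
    genes assigned to any detected module; hub rank is the planted hub's
    position by degree (ties by gene id) within its detected module.
    """
    cfg = sim_config if sim_config is not None else SimConfig(seed=seed)
    if sim_config is not None and sim_config.seed != seed:
        raise ValueError("sim_config.seed must match seed")
    cm, sheet, truth = generate_compendium(cfg)
    det = preprocess.differential_expression(cm, sheet)
    genes = preprocess.filter_de_genes(det)
    fc = standardize_profiles(preprocess.build_fc_matrix(det, genes))
    wm = infer_weight_matrix(fc, InferenceParams(n_trees=n_trees, seed=seed + 100))
    el = threshold_edges(wm, top_density=top_density)
    net = graph.build_graph(el)
    part = graph.detect_modules(net, min_size=min_size, resolution=resolution)

    common = [g for g in part.membership if truth.module_membership.get(g) is not None]
    ari = (
        _adjusted_rand(
            [truth.module_membership[g] for g in common],
            [part.membership[g] for g in common],
        )
        if common
        else 0.0
    )

    ctab = graph.centrality(net, part)
    hub_ranks: dict[str, int | None] = {}
    for hub in sorted(truth.hub_genes):
        if hub not in part.membership:
            hub_ranks[hub] = None
            continue
        module_tab = ctab[ctab["module"] == part.membership[hub]].sort_values(
            ["degree", "gene"], ascending=[False, True], ignore_index=True
        )
        hub_ranks[hub] = int(module_tab.index[module_tab["gene"] == hub][0]) + 1
    return RecoveryResult(seed=seed, ari=ari, hub_ranks=hub_ranks)


@dataclass
class SpecificityResult:
    seed: int
    delta_own_removal: float  # planted class-A set delta under class-A removal
    rel_other_removal: float  # its relative delta under class-B removal
    rel_baseline_max: float  # max |relative delta| over random sets, class-B removal

    @property
    def direction_lower(self) -> bool:
        return self.delta_own_removal < 0

    @property
    def within_baseline(self) -> bool:
        return abs(self.rel_other_removal) <= self.rel_baseline_max


def reduced_perturbation_config(seed: int) -> SimConfig:
    """Reduced-scale compendium for the leave-class-out benchmark."""
    return SimConfig(
        seed=seed,
        n_genes=160,
        module_sizes=(30, 30),
        treatments_per_class=6,
        n_other_treatments=8,
        replicates_per_treatment=3,
        # strong, broadly responding modules: this benchmark measures
        # class-removal specificity, not hub-degree recovery
        gene_multiplier_range=(0.5, 1.0),
        response_spread=0.5,
    )


def perturbation_specificity(
    seed: int,
    n_trees: int = 100,
    iterations: int = 5,
    n_random_sets: int = 19,
) -> SpecificityResult:
    """Leave-class-out specificity on one reduced compendium.

    The planted class-A module set must lose co-expression (delta < 0) when
    class A's samples are removed; under class-B removal its *relative*
    delta (delta / random-average mean, a scale-free measure) must fall
    within the range spanned by random same-size gene sets.
    """
    cfg = reduced_perturbation_config(seed)
    cm, sheet, truth = generate_compendium(cfg)
    det = preprocess.differential_expression(cm, sheet)
    genes = preprocess.filter_de_genes(det)
    params = InferenceParams(n_trees=n_trees, seed=seed + 7)

    set_a = set(truth.module_genes(1)) & set(genes)
    class_a = truth.class_of_module[1]
    class_b = truth.class_of_module[2]
    rng = np.random.default_rng(seed)
    sets: dict[str, set] = {"planted_a": set_a}
    size = min(len(set_a), len(genes))
    for i in range(n_random_sets):
        sets[f"rand{i}"] = set(rng.choice(genes, size=size, replace=False))
    gsc = GeneSetCollection(sets=sets, universe=set(genes))

    res_a = perturb.leave_class_out(
        cm, sheet, class_a, genes, gsc, params, iterations=iterations, seed=seed + 11
    )
    res_b = perturb.leave_class_out(
        cm, sheet, class_b, genes, gsc, params, iterations=iterations, seed=seed + 13
    )
    a = res_a.set_index("set")
    b = res_b.set_index("set")
    rel_b = b["delta"] / b["mean_w_random_avg"]
    rand_rel = [abs(rel_b[f"rand{i}"]) for i in range(n_random_sets) if f"rand{i}" in rel_b]
    return SpecificityResult(
        seed=seed,
        delta_own_removal=float(a.loc["planted_a", "delta"]),
        rel_other_removal=float(rel_b["planted_a"]),
        rel_baseline_max=float(max(rand_rel)),
    )
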