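"""Directed co-expression inference by per-target tree-ensemble regression.

Each gene in turn is the regression target; every other gene is a candidate
predictor. A random forest is fit per target and each predictor is scored by
its total sample-weighted variance reduction averaged over trees and divided
by the number of observations — the importance scale on which the published
0.00858 edge cutoff is defined. Profiles are standardized first so
importances are comparable across targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor


@dataclass
class InferenceParams:
    n_trees: int = 1000
    k_rule: str = "sqrt"  # candidate predictors per split: "sqrt" or "all"
    seed: int = 0
    max_depth: int | None = None
    bootstrap: bool = True
    backend: str = "fast"  # "fast" (compiled) or "sklearn" (cross-check)

    def __post_init__(self) -> None:
        if self.k_rule not in ("sqrt", "all"):
            raise ValueError("k_rule must be 'sqrt' or 'all'")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.backend not in ("fast", "sklearn"):
            raise ValueError("backend must be 'fast' or 'sklearn'")


@dataclass
class WeightMatrix:
    """Regulator x target non-negative importance matrix, zero diagonal."""

    w: pd.DataFrame  # index = regulator, columns = target
    params: InferenceParams = field(default_factory=InferenceParams)

    def __post_init__(self) -> None:
        vals = self.w.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("weight matrix has non-finite entries")
        if (vals < 0).any():
            raise ValueError("weight matrix has negative entries")
        if list(self.w.index) != list(self.w.columns):
            raise ValueError("weight matrix index and columns must match")
        np.fill_diagonal(self.w.values, 0.0)

    @property
    def genes(self) -> list[str]:
        return list(self.w.index)

    @classmethod
    def from_tsv(cls, path) -> "WeightMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.w.to_csv(path, sep="\t")

    def to_sparse_tsv(self, path) -> None:
        """Sorted (descending weight) nonzero triplets."""
        w = self.w
        regs, tgts = np.nonzero(w.to_numpy())
        df = pd.DataFrame(
            {
                "regulator": w.index[regs],
                "target": w.columns[tgts],
                "weight": w.to_numpy()[regs, tgts],
            }
        ).sort_values(["weight", "regulator", "target"], ascending=[False, True, True])
        df.to_csv(path, sep="\t", index=False)


@dataclass
class EdgeList:
    edges: pd.DataFrame  # columns regulator, target, weight
    threshold: float

    def __post_init__(self) -> None:
        df = self.edges
        if (df["regulator"] == df["target"]).any():
            raise ValueError("edge list contains self-edges")
        if df.duplicated(subset=["regulator", "target"]).any():
            raise ValueError("duplicate edges")
        self.edges = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    @classmethod
    def from_tsv(cls, path) -> "EdgeList":
        df = pd.read_csv(path, sep="\t")
        thr = float(df["weight"].min()) if len(df) else 0.0
        return cls(df, threshold=thr)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_sif(self, path, relation: str = "coexp") -> None:
        with open(path, "w") as fh:
            for row in self.edges.itertuples(index=False):
                fh.write(f"{row.regulator}\t{relation}\t{row.target}\n")


def standardize_profiles(fc: pd.DataFrame) -> pd.DataFrame:
    """Center and scale every gene row to mean 0, variance 1.

    Zero-variance rows carry no co-expression information and are dropped
    with a warning.
    """
    if fc.shape[1] < 2:
        raise ValueError("need at least 2 treatments to standardize")
    X = fc.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant-profile genes", stacklevel=2
        )
    X = X[keep]
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(X, index=fc.index[keep], columns=fc.columns)


def target_importances(
    target_profile: np.ndarray,
    predictor_profiles: np.ndarray,
    n_trees: int = 1000,
    k_rule: str = "sqrt",
    seed: int = 0,
    max_depth: int | None = None,
    bootstrap: bool = True,
    backend: str = "fast",
) -> np.ndarray:
    """Per-predictor importance for one target gene.

    ``predictor_profiles`` is (n_predictors, n_observations). Importance of
    predictor j is the sum over tree nodes splitting on j of
    (node samples / n) * impurity decrease, averaged over trees — i.e. total
    variance reduction credited to j divided by the observation count.

    The default compiled backend and the sklearn backend implement the same
    estimator (CART variance-reduction splits, bootstrap rows, k random
    candidate features per node); their tie-breaking and RNG streams differ,
    so matrices agree in distribution, not bitwise.
    """
    y = np.asarray(target_profile, dtype=float)
    X = np.ascontiguousarray(np.asarray(predictor_profiles, dtype=float).T)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if X.shape[1] < 1:
        raise ValueError("need at least 1 predictor")
    p = X.shape[1]
    k = max(1, int(np.sqrt(p))) if k_rule == "sqrt" else p
    if backend == "fast":
        from ._forest import forest_importances

        imp = forest_importances(
            X,
            y,
            n_trees,
            k,
            -1 if max_depth is None else max_depth,
            bootstrap,
            seed % (2**32),
        )
    else:
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=k,
            max_depth=max_depth,
            bootstrap=bootstrap,
            min_samples_leaf=1,
            random_state=seed,
            n_jobs=1,
        )
        forest.fit(X, y)
        imp = np.mean(
            [
                t.tree_.compute_feature_importances(normalize=False)
                for t in forest.estimators_
            ],
            axis=0,
        )
    return np.maximum(imp, 0.0)


def infer_weight_matrix(fc: pd.DataFrame, params: InferenceParams) -> WeightMatrix:
    """Run per-target ensembles over a standardized log2FC matrix.

    ``w[j, i]`` is the importance of gene j for predicting target gene i.
    Per-target seeds are derived from ``params.seed`` so serial and
    by-target-parallel execution give identical results.
    """
    if fc.shape[1] < 3:
        raise ValueError("need at least 3 treatments/observations")
    genes = list(fc.index)
    n = len(genes)
    X = fc.to_numpy(dtype=float)
    w = np.zeros((n, n))
    seeds = np.random.SeedSequence(params.seed).generate_state(n)
    for i in range(n):
        predictors = np.delete(np.arange(n), i)
        imp = target_importances(
            X[i],
            X[predictors],
            n_trees=params.n_trees,
            k_rule=params.k_rule,
            seed=int(seeds[i] % (2**31 - 1)),
            max_depth=params.max_depth,
            bootstrap=params.bootstrap,
            backend=params.backend,
        )
        w[predictors, i] = imp
    return WeightMatrix(pd.DataFrame(w, index=genes, columns=genes), params=params)


def threshold_edges(
    w: WeightMatrix,
    min_weight: float | None = None,
    top_density: float | None = None,
) -> EdgeList:
    """Keep directed edges at or above a weight cutoff.

    Exactly one of ``min_weight`` (absolute cutoff, the published default is
    0.00858) or ``top_density`` (mean out-degree; keeps the strongest
    ``round(top_density * n_genes)`` edges) must be given.
    """
    if (min_weight is None) == (top_density is None):
        raise ValueError("give exactly one of min_weight / top_density")
    mat = w.w.to_numpy()
    regs, tgts = np.nonzero(~np.eye(len(mat), dtype=bool))
    weights = mat[regs, tgts]
    if top_density is not None:
        n_keep = int(round(top_density * len(mat)))
        if n_keep < 1:
            raise ValueError("top_density keeps no edges")
        order = np.argsort(weights, kind="stable")[::-1][:n_keep]
        cutoff = float(weights[order].min())
        keep = np.zeros(weights.size, dtype=bool)
        keep[order] = True
    else:
        cutoff = float(min_weight)
        keep = weights >= cutoff
    if not keep.any():
        warnings.warn("threshold produced an empty network", stacklevel=2)
    df = pd.DataFrame(
        {
            "regulator": w.w.index[regs[keep]],
            "target": w.w.columns[tgts[keep]],
            "weight": weights[keep],
        }
    ).sort_values(["weight", "regulator", "target"], ascending=[False, True, True])
    return EdgeList(df, threshold=cutoff)
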