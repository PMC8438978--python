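"""Count preprocessing: expression filters, per-treatment differential
expression against matched vehicle controls, and the log2FC matrix.

The internal DE test is a lightweight negative-binomial Wald stand-in for a
full empirical-Bayes GLM pipeline: median-of-ratios size factors, per-gene
method-of-moments dispersion, and a delta-method standard error on the log
fold change. Published DE output can be ingested verbatim instead via
``differential_expression(..., method="external_table")``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .data import CountMatrix, DataError, DETable, SampleSheet

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass
class ResponseCriteria:
    """Thresholds defining when a gene "responds" to a treatment."""

    alpha: float = 0.05
    min_abs_lfc: float = 0.0
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.min_abs_lfc < 0:
            raise ValueError("min_abs_lfc must be >= 0")


def filter_low_expression(
    cm: CountMatrix, max_zero_fraction: float = 0.25
) -> CountMatrix:
    """Drop genes with a zero count in at least ``ceil(frac * n_samples)`` samples."""
    if not 0 < max_zero_fraction <= 1:
        raise ValueError("max_zero_fraction must be in (0, 1]")
    n_samples = cm.shape[1]
    cutoff = math.ceil(max_zero_fraction * n_samples)
    zeros = (cm.counts == 0).sum(axis=1)
    keep = zeros < cutoff
    if not keep.any():
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return CountMatrix(cm.counts.loc[keep].copy())


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Uses genes with strictly positive counts in every sample as the
    reference set, as in the standard RNA-seq median-of-ratios scheme.
    """
    counts = cm.counts.to_numpy(dtype=float)
    expressed = (counts > 0).all(axis=1)
    if not expressed.any():
        raise DataError("no gene expressed in all samples; cannot compute size factors")
    ref = counts[expressed]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=cm.samples, name="size_factor")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _moments_dispersion(treated: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion alpha from pooled within-group moments.

    var = mu + alpha * mu^2  =>  alpha = (s2 - mu) / mu^2, floored.
    """
    mu = (treated.mean(axis=1) + control.mean(axis=1)) / 2.0
    s2 = (treated.var(axis=1, ddof=1) + control.var(axis=1, ddof=1)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / np.square(mu)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def differential_expression(
    cm: CountMatrix,
    sheet: SampleSheet,
    method: str = "internal_nb_wald",
    external_path=None,
) -> DETable:
    """Per-treatment DE versus the matched vehicle control.

    ``internal_nb_wald``: size-factor normalization, log2fc on pseudocounted
    group means, NB Wald test with method-of-moments dispersion, BH within
    each comparison.  ``external_table``: read a precomputed table with the
    same schema from ``external_path``.
    """
    if method == "external_table":
        if external_path is None:
            raise ValueError("external_table method requires external_path")
        return DETable.from_tsv(external_path)
    if method != "internal_nb_wald":
        raise ValueError(f"unknown DE method: {method}")

    factors = size_factors(cm)
    norm = cm.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    norm = pd.DataFrame(norm, index=cm.genes, columns=cm.samples)

    sample_pos = {s: i for i, s in enumerate(cm.samples)}
    frames = []
    for treatment in sheet.treatments():
        t_samples = sheet.samples_of(treatment)
        c_samples = sheet.samples_of(sheet.control_of(treatment))
        if len(t_samples) < 2 or len(c_samples) < 2:
            raise DataError(f"treatment {treatment} lacks >= 2 replicates per group")
        t_idx = [sample_pos[s] for s in t_samples]
        c_idx = [sample_pos[s] for s in c_samples]
        treated = norm.to_numpy()[:, t_idx]
        control = norm.to_numpy()[:, c_idx]

        mu_t = treated.mean(axis=1)
        mu_c = control.mean(axis=1)
        log2fc = np.log2((mu_t + PSEUDOCOUNT) / (mu_c + PSEUDOCOUNT))

        alpha = _moments_dispersion(treated, control)
        # Delta-method variance of log(mean) per group: (1/mu + alpha) / n.
        var_log = (1.0 / (mu_t + PSEUDOCOUNT) + alpha) / treated.shape[1] + (
            1.0 / (mu_c + PSEUDOCOUNT) + alpha
        ) / control.shape[1]
        se_log2 = np.sqrt(var_log) / math.log(2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = log2fc / se_log2
        z = np.where(np.isfinite(z), z, 0.0)
        df = treated.shape[1] + control.shape[1] - 2
        p = 2.0 * stats.t.sf(np.abs(z), df)
        padj = bh_adjust(p)

        frames.append(
            pd.DataFrame(
                {
                    "gene": cm.genes,
                    "treatment": treatment,
                    "log2fc": log2fc,
                    "p": p,
                    "padj": padj,
                }
            )
        )
    return DETable(pd.concat(frames, ignore_index=True))


def filter_de_genes(
    det: DETable, min_comparisons: int = 3, alpha: float = 0.05
) -> list[str]:
    """Genes with padj < alpha in at least ``min_comparisons`` treatments.

    Order-stable: result follows the gene order of the DE table.
    """
    if det.table.empty:
        raise DataError("empty DE table")
    hits = det.table[det.table["padj"] < alpha].groupby("gene").size()
    keep = set(hits[hits >= min_comparisons].index)
    return [g for g in det.genes if g in keep]


def build_fc_matrix(det: DETable, genes: list[str]) -> pd.DataFrame:
    """Genes x treatments matrix of log2 fold changes for the given genes."""
    missing = set(genes) - set(det.genes)
    if missing:
        raise DataError(f"genes absent from DE table: {sorted(missing)[:5]}")
    wide = det.table.pivot(index="gene", columns="treatment", values="log2fc")
    wide = wide.loc[genes, det.treatments]
    if wide.isna().any().any():
        raise DataError("missing (gene, treatment) cells in DE table")
    wide.columns.name = None
    wide.index.name = "gene"
    return wide


def ward_cluster_treatments(
    fc: pd.DataFrame, k: int = 6
) -> tuple[np.ndarray, pd.Series]:
    """Ward (D2) hierarchical clustering of treatment log2FC columns.

    Returns the scipy linkage matrix and a treatment -> cluster label map
    with labels 1..k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > fc.shape[1]:
        raise ValueError("k exceeds the number of treatments")
    X = fc.to_numpy().T  # treatments as observations
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=fc.columns, name="cluster")


def count_responsive_chemicals(
    det: DETable,
    gene: str,
    class_filter: list[str] | None,
    crit: ResponseCriteria,
    sheet: SampleSheet | None = None,
) -> int:
    """Number of treatments (optionally restricted to classes) a gene responds to."""
    sub = det.table[det.table["gene"] == gene]
    if sub.empty:
        raise DataError(f"unknown gene: {gene}")
    if class_filter is not None:
        if sheet is None:
            raise ValueError("class_filter requires a sample sheet")
        allowed = {
            t for c in class_filter for t in sheet.treatments_of_class(c)
        }
        sub = sub[sub["treatment"].isin(allowed)]
    pcol = "padj" if crit.use_adjusted else "p"
    hits = (sub[pcol] < crit.alpha) & (sub["log2fc"].abs() > crit.min_abs_lfc)
    return int(hits.sum())
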