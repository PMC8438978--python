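"""Synthetic multi-chemical count compendia with planted co-expression modules.

Counts are negative-binomial around a per-gene lognormal baseline. Each
chemical class owns one or more planted gene modules; every treatment of
that class induces its modules through a shared per-treatment latent factor,
so module genes co-vary across treatments — the level at which the network
is later inferred. Hub genes respond with the maximal, most consistent
multiplier, creating a recoverable degree gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CONTROL_CLASS, CountMatrix, SampleSheet

DEFAULT_CLASS_NAMES = ("FRC", "AHR2_Activator")


@dataclass
class SimConfig:
    n_genes: int = 300
    n_classes: int = 2
    treatments_per_class: int = 8
    n_other_treatments: int = 8
    replicates_per_treatment: int = 4
    module_sizes: tuple[int, ...] = (40, 40)
    hub_per_module: bool = True
    effect_size_log2: float = 2.0
    effect_sd_log2: float = 0.3
    dispersion: float = 0.05
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    noise_corr: float = 0.0
    gene_multiplier_range: tuple[float, float] = (0.2, 0.7)
    response_spread: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if self.replicates_per_treatment < 2:
            raise ValueError("replicates_per_treatment must be >= 2")
        if self.baseline_log_sd <= 0:
            raise ValueError("baseline_log_sd must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.noise_corr < 1:
            raise ValueError("noise_corr must be in [0, 1)")
        lo, hi = self.gene_multiplier_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("gene_multiplier_range must satisfy 0 < lo <= hi <= 1")
        if not 0 <= self.response_spread <= 1:
            raise ValueError("response_spread must be in [0, 1]")

    def class_names(self) -> list[str]:
        names = list(DEFAULT_CLASS_NAMES[: self.n_classes])
        names += [f"class{i + 1}" for i in range(len(names), self.n_classes)]
        return names

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a simulated compendium."""

    module_membership: dict[str, int | None]
    class_of_module: dict[int, str]
    hub_genes: set[str]
    planted_lfc: dict[str, dict[str, float]]  # gene -> treatment -> log2 effect
    control_pairing: dict[str, str]
    gene_multiplier: dict[str, float] = field(default_factory=dict)

    def module_genes(self, module_id: int) -> list[str]:
        return [g for g, m in self.module_membership.items() if m == module_id]

    def modules_of_class(self, cls: str) -> list[int]:
        return [m for m, c in self.class_of_module.items() if c == cls]

    def to_json(self, path) -> None:
        payload = {
            "module_membership": self.module_membership,
            "class_of_module": {str(k): v for k, v in self.class_of_module.items()},
            "hub_genes": sorted(self.hub_genes),
            "planted_lfc": self.planted_lfc,
            "control_pairing": self.control_pairing,
            "gene_multiplier": self.gene_multiplier,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            module_membership=payload["module_membership"],
            class_of_module={int(k): v for k, v in payload["class_of_module"].items()},
            hub_genes=set(payload["hub_genes"]),
            planted_lfc=payload["planted_lfc"],
            control_pairing=payload["control_pairing"],
            gene_multiplier=payload.get("gene_multiplier", {}),
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, var mu + alpha*mu^2); Poisson limit at alpha == 0."""
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_compendium(
    config: SimConfig,
) -> tuple[CountMatrix, SampleSheet, SimTruth]:
    """Simulate a count compendium with planted class-specific modules.

    Deterministic given ``config.seed``. Returns the counts, the sample
    sheet with matched vehicle-control groups, and the planted truth.
    """
    rng = np.random.default_rng(config.seed)
    class_names = config.class_names()

    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]

    # Planted modules occupy the leading genes, in contiguous blocks;
    # module m is owned by class (m-1) mod n_classes.
    module_membership: dict[str, int | None] = {g: None for g in genes}
    class_of_module: dict[int, str] = {}
    hub_genes: set[str] = set()
    cursor = 0
    for m, size in enumerate(config.module_sizes, start=1):
        block = genes[cursor : cursor + size]
        cursor += size
        for g in block:
            module_membership[g] = m
        class_of_module[m] = class_names[(m - 1) % config.n_classes]
        if config.hub_per_module and block:
            hub_genes.add(block[0])

    lo, hi = config.gene_multiplier_range
    multiplier = lo + (hi - lo) * rng.uniform(size=config.n_genes)
    for i, g in enumerate(genes):
        if g in hub_genes:
            multiplier[i] = 1.0
    gene_multiplier = {g: float(multiplier[i]) for i, g in enumerate(genes)}

    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    )

    # Treatment roster: per-class treatments, then unstructured "other" ones.
    treatments: list[tuple[str, str]] = []  # (treatment id, class label)
    for ci, cname in enumerate(class_names):
        for j in range(1, config.treatments_per_class + 1):
            treatments.append((f"{cname}_t{j:02d}", cname))
    for j in range(1, config.n_other_treatments + 1):
        treatments.append((f"other_t{j:02d}", "other"))

    control_pairing = {t: f"ctrl_{t}" for t, _ in treatments}

    # Response model. Each treatment of a class carries a shared latent
    # induction factor f_t (the co-expression source). A module gene's
    # log2 effect mixes the shared factor with an idiosyncratic
    # per-(gene, treatment) component by its multiplier, and the gene
    # responds to any given class treatment only with probability m_g:
    #
    #   beta_gt = r_gt * effect * (m_g * f_t + (1 - m_g) * eps_gt),
    #   r_gt ~ Bernoulli(1 - spread * (1 - m_g)),
    #   f_t, eps_gt ~ N(1, effect_sd^2).
    #
    # Hubs (m = 1) respond to every class treatment and track the shared
    # factor exactly — the broadest, most consistent responders — which is
    # what makes them recoverable as high-degree network nodes.
    latent = {
        t: float(rng.normal(1.0, config.effect_sd_log2)) for t, _ in treatments
    }
    idio = rng.normal(1.0, config.effect_sd_log2, (config.n_genes, len(treatments)))
    resp_prob = 1.0 - config.response_spread * (1.0 - multiplier)
    responds = rng.uniform(size=(config.n_genes, len(treatments))) < resp_prob[:, None]

    planted_lfc: dict[str, dict[str, float]] = {}
    beta = np.zeros((config.n_genes, len(treatments)))
    for ti, (t, cls) in enumerate(treatments):
        owned = {m for m, c in class_of_module.items() if c == cls}
        if not owned:
            continue
        for gi, g in enumerate(genes):
            if module_membership[g] in owned and responds[gi, ti]:
                m_g = multiplier[gi]
                b = config.effect_size_log2 * (
                    m_g * latent[t] + (1.0 - m_g) * idio[gi, ti]
                )
                beta[gi, ti] = b
                if b != 0.0:
                    planted_lfc.setdefault(g, {})[t] = float(b)

    # Assemble sample-level means, then draw counts in one vectorized pass.
    sample_ids: list[str] = []
    rows = []
    mean_cols = []
    for ti, (t, cls) in enumerate(treatments):
        ctrl = control_pairing[t]
        for grp, grp_cls, b in ((t, cls, beta[:, ti]), (ctrl, CONTROL_CLASS, 0.0)):
            for r in range(1, config.replicates_per_treatment + 1):
                sid = f"{grp}_r{r}"
                sample_ids.append(sid)
                rows.append(
                    {
                        "sample": sid,
                        "treatment": grp,
                        "control_for": ctrl if grp_cls != CONTROL_CLASS else "",
                        "class": grp_cls,
                        "replicate": r,
                    }
                )
                mean_cols.append(baseline * np.exp2(b))

    means = np.column_stack(mean_cols)
    if config.noise_corr > 0:
        # Sample-level nuisance factor shared by all genes: induces a
        # baseline correlation floor among unrelated genes.
        u = rng.normal(0.0, 1.0, means.shape[1])
        means = means * np.exp(config.noise_corr * u)[None, :]

    counts = _nb_draw(rng, means, config.dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids))
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = SimTruth(
        module_membership=module_membership,
        class_of_module=class_of_module,
        hub_genes=hub_genes,
        planted_lfc=planted_lfc,
        control_pairing=control_pairing,
        gene_multiplier=gene_multiplier,
    )
    return cm, sheet, truth


def write_compendium(outdir, cm: CountMatrix, sheet: SampleSheet, truth: SimTruth) -> dict:
    """Write counts/sheet/truth under ``outdir``; returns the path map."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    cm.to_tsv(paths["counts"])
    sheet.to_tsv(paths["samples"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
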