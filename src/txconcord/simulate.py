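"""Synthetic count data with planted differential expression and planted
convergent/divergent structure.

The generator emulates the shapes of the study the pipeline targets: a
reference disease cohort of 12 cases vs 12 controls, and a three-condition
in-vitro model cohort (NM n=3, NUntr n=3, NTr n=4).  Counts are negative
binomial with a shared dispersion ``alpha`` (variance ``mu + alpha*mu^2``),
log-normal baseline means and log-uniform library sizes.  A configurable
fraction of genes receives a reference log2 fold change; within those, each
model condition plants effects of matching (convergent) or opposite
(divergent) sign relative to the reference.  Every artifact is reproducible
from (config, seed) and the planted ground truth is returned alongside.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import CountMatrix, GeneSet, GeneSetCollection, SampleSheet

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "StudyData",
    "generate_reference",
    "generate_model_cohorts",
    "generate_genesets",
    "generate_id_map",
    "simulate_study",
    "preset",
]

REFERENCE_CONDITIONS = ("CTL", "ASD")
MODEL_BASELINE = "NM"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study; ``seed`` is mandatory.

    Defaults mirror the emulated study design: a 12-vs-12 reference cohort,
    model conditions NM=3, NUntr=3, NTr=4, NB dispersion 0.1, 10% DE genes
    with |log2FC| = 1 in the reference and |log2FC| = 2 planted in the model
    conditions, library sizes log-uniform on [0.5, 2] and log-normal baseline
    means (median 100).
    """

    seed: int
    n_genes: int = 2000
    reference_sizes: tuple = (12, 12)                # (CTL, ASD)
    model_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"NM": 3, "NUntr": 3, "NTr": 4}
    )
    libsize_range: tuple = (0.5, 2.0)
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    de_fraction: float = 0.1
    lfc_abs: float = 1.0
    model_lfc_abs: float = 2.0
    # per non-baseline model condition: fraction of reference DE genes planted
    # convergent / divergent (the rest get no model effect)
    concordance_plan: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "NTr": {"convergent": 0.4, "divergent": 0.3},
            "NUntr": {"convergent": 0.4, "divergent": 0.3},
        }
    )
    # gene-set collection plan
    n_background_sets: int = 15
    set_size: int = 30
    n_enriched_sets: int = 1
    enriched_overlap: float = 1.0
    enriched_source_condition: str = "NTr"
    enriched_source_label: str = "convergent"
    emit_source_ids: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if min(self.reference_sizes) < 2 or min(self.model_sizes.values()) < 2:
            raise ValidationError("all group sizes must be >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if MODEL_BASELINE not in self.model_sizes:
            raise ValidationError(f"model_sizes must include the baseline {MODEL_BASELINE!r}")
        for cond, plan in self.concordance_plan.items():
            if cond not in self.model_sizes or cond == MODEL_BASELINE:
                raise ValidationError(f"concordance plan names unknown condition {cond!r}")
            fc = plan.get("convergent", 0.0)
            fd = plan.get("divergent", 0.0)
            if fc < 0 or fd < 0 or fc + fd > 1.0 + 1e-12:
                raise ValidationError(
                    f"plan for {cond!r} incoherent: convergent+divergent must be <= 1"
                )
        if not 0.0 <= self.enriched_overlap <= 1.0:
            raise ValidationError("enriched_overlap must lie in [0, 1]")
        if self.set_size > self.n_genes:
            raise ValidationError("set_size exceeds n_genes")

    def gene_symbols(self) -> np.ndarray:
        return np.array([f"G{i:05d}" for i in range(self.n_genes)], dtype=object)

    def source_ids(self) -> np.ndarray:
        return np.array([f"ENSG{i:011d}" for i in range(self.n_genes)], dtype=object)


@dataclass
class TruthTable:
    """Planted ground truth: per-gene reference effect and per-condition
    model labels, plus per-gene-set enrichment flags."""

    genes: pd.DataFrame          # index symbol; ref_log2fc, ref_de, label_<cond>, model_log2fc_<cond>
    enriched_sets: tuple = ()    # names of planted-enriched gene sets

    def planted(self, condition: str, label: str) -> frozenset:
        col = f"label_{condition}"
        if col not in self.genes.columns:
            raise ValidationError(f"no planted labels for condition {condition!r}")
        return frozenset(self.genes.index[self.genes[col] == label])

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


@dataclass(frozen=True)
class StudyData:
    reference_counts: CountMatrix
    reference_sheet: SampleSheet
    model_counts: CountMatrix
    model_sheet: SampleSheet
    genesets: GeneSetCollection
    truth: TruthTable
    id_map: pd.DataFrame


def _rng_for(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, variance mu + alpha*mu^2); alpha=0 degenerates to Poisson."""
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _baseline_and_libsizes(cfg, rng, n_samples):
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    lo, hi = cfg.libsize_range
    libs = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples))
    return baseline, libs


def generate_reference(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Reference cohort counts (CTL vs ASD) with planted DE.

    Exactly ``round(de_fraction * n_genes)`` genes receive a log2FC of
    ``+/- lfc_abs`` (signs split evenly) applied to the ASD group.  Returns
    ``(CountMatrix, SampleSheet, TruthTable)``.
    """
    rng = rng if rng is not None else _rng_for(cfg, 0)
    n_de = round(cfg.de_fraction * cfg.n_genes)
    if cfg.de_fraction > 0 and n_de < 1:
        raise ValidationError(
            f"infeasible config: de_fraction {cfg.de_fraction} with {cfg.n_genes} genes plants no DE gene"
        )
    symbols = cfg.gene_symbols()
    n_ctl, n_asd = cfg.reference_sizes
    baseline, libs = _baseline_and_libsizes(cfg, rng, n_ctl + n_asd)

    lfc = np.zeros(cfg.n_genes)
    if n_de:
        de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
        signs = np.ones(n_de)
        signs[: n_de // 2] = -1.0
        rng.shuffle(signs)
        lfc[de_idx] = signs * cfg.lfc_abs

    group = np.array([0.0] * n_ctl + [1.0] * n_asd)
    mu = baseline[:, None] * libs[None, :] * np.exp2(lfc[:, None] * group[None, :])
    counts = _nb_counts(rng, mu, cfg.dispersion)

    sample_ids = [f"CTL_{i+1:02d}" for i in range(n_ctl)] + [
        f"ASD_{i+1:02d}" for i in range(n_asd)
    ]
    gene_index = cfg.source_ids() if cfg.emit_source_ids else symbols
    cm = CountMatrix(pd.DataFrame(counts, index=gene_index, columns=sample_ids))
    sheet = SampleSheet(
        pd.DataFrame(
            {"condition": ["CTL"] * n_ctl + ["ASD"] * n_asd},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = TruthTable(
        genes=pd.DataFrame(
            {"ref_log2fc": lfc, "ref_de": lfc != 0.0},
            index=pd.Index(symbols, name="gene"),
        )
    )
    return cm, sheet, truth


def generate_model_cohorts(
    cfg: SimulationConfig, truth: TruthTable, rng: np.random.Generator | None = None
):
    """Model cohort counts (NM baseline plus treated/untreated conditions).

    Each non-baseline condition plants, among the reference DE genes, effects
    of magnitude ``model_lfc_abs`` whose sign matches (convergent) or opposes
    (divergent) the reference sign, per the concordance plan fractions; the
    remaining genes carry no effect.  The truth table gains per-condition
    label and effect columns.  Returns ``(CountMatrix, SampleSheet, TruthTable)``.
    """
    rng = rng if rng is not None else _rng_for(cfg, 1)
    symbols = cfg.gene_symbols()
    if not truth.genes.index.equals(pd.Index(symbols, name="gene")):
        raise ValidationError("truth table does not match this config's gene namespace")
    ref_lfc = truth.genes["ref_log2fc"].to_numpy()
    de_idx = np.flatnonzero(truth.genes["ref_de"].to_numpy())
    conditions = list(cfg.model_sizes)
    n_samples = sum(cfg.model_sizes.values())
    baseline, libs = _baseline_and_libsizes(cfg, rng, n_samples)

    genes_frame = truth.genes.copy()
    delta = {}  # condition -> per-gene model log2fc (vs NM baseline)
    for cond in conditions:
        if cond == MODEL_BASELINE:
            continue
        plan = cfg.concordance_plan.get(cond, {})
        fc = plan.get("convergent", 0.0)
        fd = plan.get("divergent", 0.0)
        n_conv = round(fc * len(de_idx))
        n_div = round(fd * len(de_idx))
        if n_conv + n_div > len(de_idx):
            raise ValidationError(f"plan for {cond!r} exceeds the reference DE gene pool")
        perm = rng.permutation(de_idx)
        conv_idx, div_idx = perm[:n_conv], perm[n_conv:n_conv + n_div]
        d = np.zeros(cfg.n_genes)
        d[conv_idx] = np.sign(ref_lfc[conv_idx]) * cfg.model_lfc_abs
        d[div_idx] = -np.sign(ref_lfc[div_idx]) * cfg.model_lfc_abs
        delta[cond] = d
        labels = np.full(cfg.n_genes, "none", dtype=object)
        labels[de_idx] = "null"
        labels[conv_idx] = "convergent"
        labels[div_idx] = "divergent"
        genes_frame[f"label_{cond}"] = labels
        genes_frame[f"model_log2fc_{cond}"] = d

    cols, conds, mus = [], [], []
    col = 0
    for cond in conditions:
        k = cfg.model_sizes[cond]
        d = delta.get(cond, np.zeros(cfg.n_genes))
        for i in range(k):
            cols.append(f"{cond}_{i+1:02d}")
            conds.append(cond)
            mus.append(baseline * libs[col] * np.exp2(d))
            col += 1
    mu = np.column_stack(mus)
    counts = _nb_counts(rng, mu, cfg.dispersion)

    gene_index = cfg.source_ids() if cfg.emit_source_ids else symbols
    cm = CountMatrix(pd.DataFrame(counts, index=gene_index, columns=cols))
    sheet = SampleSheet(
        pd.DataFrame({"condition": conds}, index=pd.Index(cols, name="sample_id"))
    )
    new_truth = TruthTable(genes=genes_frame, enriched_sets=truth.enriched_sets)
    return cm, sheet, new_truth


def generate_genesets(
    cfg: SimulationConfig, truth: TruthTable, rng: np.random.Generator | None = None
):
    """Gene-set collection with planted-enriched and background sets.

    Enriched sets draw ``round(enriched_overlap * set_size)`` members from the
    genes planted with ``enriched_source_label`` in ``enriched_source_condition``
    and the rest uniformly from other genes; background sets are uniform.
    Returns ``(GeneSetCollection, TruthTable)`` with enrichment flags filled in.
    """
    rng = rng if rng is not None else _rng_for(cfg, 2)
    symbols = cfg.gene_symbols()
    coll = GeneSetCollection()
    enriched_names = []
    n_from_pool = round(cfg.enriched_overlap * cfg.set_size)
    if cfg.n_enriched_sets > 0 and n_from_pool > 0:
        pool = sorted(truth.planted(cfg.enriched_source_condition, cfg.enriched_source_label))
        if len(pool) < n_from_pool:
            raise ValidationError(
                f"planted pool ({len(pool)} genes) smaller than requested overlap "
                f"({n_from_pool}); increase the concordance plan or shrink set_size"
            )
    for i in range(cfg.n_enriched_sets):
        if n_from_pool > 0:
            members = list(rng.choice(pool, size=n_from_pool, replace=False))
        else:
            members = []
        others = np.setdiff1d(symbols, np.array(members, dtype=object))
        fill = cfg.set_size - len(members)
        members += list(rng.choice(others, size=fill, replace=False))
        name = f"SET_ENRICHED_{i+1:02d}"
        coll.add(GeneSet(name, "planted-enriched synthetic set", tuple(sorted(members))))
        enriched_names.append(name)
    for i in range(cfg.n_background_sets):
        members = rng.choice(symbols, size=cfg.set_size, replace=False)
        coll.add(
            GeneSet(f"SET_BG_{i+1:02d}", "background synthetic set", tuple(sorted(members)))
        )
    new_truth = TruthTable(genes=truth.genes, enriched_sets=tuple(enriched_names))
    return coll, new_truth


def generate_id_map(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic one-to-one source-id -> symbol table for this config."""
    return pd.DataFrame(
        {"source_id": cfg.source_ids(), "target_symbol": cfg.gene_symbols()}
    )


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Generate the full synthetic study (reference + model + gene sets)."""
    ref_cm, ref_sheet, truth = generate_reference(cfg)
    mod_cm, mod_sheet, truth = generate_model_cohorts(cfg, truth)
    coll, truth = generate_genesets(cfg, truth)
    return StudyData(
        reference_counts=ref_cm,
        reference_sheet=ref_sheet,
        model_counts=mod_cm,
        model_sheet=mod_sheet,
        genesets=coll,
        truth=truth,
        id_map=generate_id_map(cfg),
    )


PRESETS = {
    # small end-to-end demo: strong planted effects, quick on one CPU
    "demo": dict(
        n_genes=800,
        dispersion=0.05,
        de_fraction=0.15,
        lfc_abs=1.5,
        model_lfc_abs=2.0,
    ),
    # global null: no DE anywhere
    "null": dict(
        n_genes=2000,
        dispersion=0.1,
        de_fraction=0.0,
        concordance_plan={},
        n_enriched_sets=0,
        enriched_overlap=0.0,
    ),
    # the emulated study shape with strong planted concordance
    "planted_strong": dict(
        n_genes=800,
        dispersion=0.05,
        de_fraction=0.15,
        lfc_abs=1.5,
        model_lfc_abs=2.0,
        concordance_plan={
            "NTr": {"convergent": 0.4, "divergent": 0.3},
            "NUntr": {"convergent": 0.4, "divergent": 0.3},
        },
    ),
}


def preset(name: str, seed: int, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)
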