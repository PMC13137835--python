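"""Negative-binomial differential expression for two-group count contrasts.

The model follows the standard bulk RNA-seq NB regression recipe:

* per-sample size factors by the median-of-ratios scheme,
* per-gene NB dispersion ``alpha`` (variance ``mu + alpha*mu^2``) estimated by
  a within-condition method-of-moments, with shrinkage toward a fitted
  mean-dispersion trend ``a0 + a1/mu``,
* a per-gene log-linear NB GLM with a two-group design and log size factors
  as offsets, fitted by IRLS (vectorised across genes),
* a Wald test of the group coefficient against the standard normal, and
* Benjamini-Hochberg adjustment across tested genes.

The public surface is statsmodels-flavoured: :class:`NegativeBinomialDE` is
the model object built from a :class:`~txconcord.io.CountMatrix` and a
:class:`~txconcord.io.SampleSheet`; :meth:`NegativeBinomialDE.fit` returns a
:class:`ContrastResults` that carries the per-gene table, a ``summary()`` and
the DEG-selection step.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import CountMatrix, SampleSheet

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)
RESULT_COLUMNS = ["base_mean", "log2fc", "se", "stat", "pvalue", "padj"]

__all__ = [
    "estimate_size_factors",
    "estimate_dispersions",
    "bh_adjust",
    "select_degs",
    "NegativeBinomialDE",
    "ContrastResults",
    "DispersionEstimates",
    "DEGSet",
]


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def estimate_size_factors(m: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over reference genes of
    ``count / geometric mean of the gene across samples``.  Reference genes
    are those with strictly positive counts in every sample; with
    ``pseudo_reference=True`` the geometric mean is instead taken over the
    positive entries only (poscounts-style), rescuing data sets where no gene
    is everywhere positive.
    """
    counts = m.counts.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_positive = np.all(counts > 0, axis=1)
    if not pseudo_reference:
        if not all_positive.any():
            raise ValidationError(
                "no gene has all-positive counts; re-run with pseudo_reference=True"
            )
        geomean = np.exp(logc[all_positive].mean(axis=1))
        ratios = counts[all_positive] / geomean[:, None]
        factors = np.median(ratios, axis=0)
    else:
        n_pos = (counts > 0).sum(axis=1)
        usable = n_pos > 0
        log_geomean = np.where(
            usable,
            np.where(counts > 0, logc, 0.0).sum(axis=1) / counts.shape[1],
            np.nan,
        )
        geomean = np.exp(log_geomean)
        factors = np.empty(counts.shape[1])
        for j in range(counts.shape[1]):
            ok = usable & (counts[:, j] > 0)
            if not ok.any():
                raise ValidationError(f"sample {m.sample_ids[j]!r} has no usable gene")
            factors[j] = np.median(counts[ok, j] / geomean[ok])
    if not np.all(factors > 0):
        raise ValidationError("non-positive size factor estimated")
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


# ---------------------------------------------------------------------------
# Dispersions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionEstimates:
    """Per-gene raw, trend and final NB dispersions; all-zero genes excluded."""

    frame: pd.DataFrame            # columns raw, trend, final
    excluded_genes: tuple          # all-zero genes, reported not estimated
    trend_coef: tuple              # (a0, a1) of trend alpha ~ a0 + a1/mu

    @property
    def final(self) -> pd.Series:
        return self.frame["final"]


def _fit_dispersion_trend(mu: np.ndarray, raw: np.ndarray, floor: float) -> tuple:
    """Least-squares fit of raw ~ a0 + a1/mu with nonnegative coefficients,
    with one trimming pass against gross outliers."""
    use = (raw > 0) & (mu > 1e-3)
    if use.sum() < 10:
        a0 = max(float(np.median(raw[raw > 0])) if (raw > 0).any() else floor, floor)
        return a0, 0.0
    from scipy.optimize import nnls

    x, y = mu[use], raw[use]
    for _ in range(2):
        design = np.column_stack([np.ones_like(x), 1.0 / x])
        coef, _ = nnls(design, y)
        fitted = design @ coef
        fitted = np.maximum(fitted, floor)
        ratio = y / fitted
        keep = (ratio > 1e-4) & (ratio < 15.0)
        if keep.all() or keep.sum() < 10:
            break
        x, y = x[keep], y[keep]
    a0 = max(float(coef[0]), floor)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def estimate_dispersions(
    m: CountMatrix,
    sheet: SampleSheet,
    size_factors: pd.Series,
    conditions: Sequence[str] | None = None,
    shrink_weight: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> DispersionEstimates:
    """Method-of-moments dispersions with trend shrinkage.

    Raw per-gene estimate on size-factor-normalised counts, pooling moments
    within condition: ``alpha_hat = max(0, (s2 - xi*mu)/mu^2)`` where ``s2``
    is the pooled within-condition variance, ``mu`` the overall normalised
    mean and ``xi`` the mean reciprocal size factor (the Poisson part of the
    variance of a scaled count).  Final estimates shrink ``log alpha_hat``
    toward the fitted trend with weight ``shrink_weight``; zero raw estimates
    collapse to the trend.
    """
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValidationError("shrink_weight must be in [0, 1]")
    conditions = list(conditions) if conditions is not None else sheet.conditions
    groups = {c: sheet.samples_for(c) for c in conditions}
    for c, ss in groups.items():
        if len(ss) < 2:
            raise ValidationError(f"condition {c!r} needs >=2 samples for dispersion")
    samples = [s for c in conditions for s in groups[c]]
    sub = m.subset_samples(samples)
    sf = size_factors.loc[samples].to_numpy()
    norm = sub.counts / sf

    nonzero = norm.sum(axis=1) > 0
    excluded = tuple(np.asarray(sub.gene_ids)[~nonzero])
    if excluded:
        logger.info("estimate_dispersions: excluding %d all-zero genes", len(excluded))
    norm = norm[nonzero]
    genes = [g for g, keep in zip(sub.gene_ids, nonzero) if keep]
    if len(genes) == 0:
        raise ValidationError("all genes have zero counts in the analysed samples")

    ss_tot = np.zeros(norm.shape[0])
    dof = 0
    col = 0
    mu = norm.mean(axis=1)
    for c in conditions:
        k = len(groups[c])
        block = norm[:, col:col + k]
        col += k
        ss_tot += block.var(axis=1, ddof=1) * (k - 1)
        dof += k - 1
    s2 = ss_tot / dof
    xi = float(np.mean(1.0 / sf))
    raw = np.maximum(0.0, (s2 - xi * mu) / mu ** 2)

    a0, a1 = _fit_dispersion_trend(mu, raw, dispersion_floor)
    trend = np.maximum(a0 + a1 / mu, dispersion_floor)

    w = shrink_weight
    final = np.where(
        raw < dispersion_floor,
        trend,
        np.exp((1.0 - w) * np.log(np.maximum(raw, dispersion_floor)) + w * np.log(trend)),
    )
    final = np.maximum(final, dispersion_floor)

    frame = pd.DataFrame(
        {"raw": raw, "trend": trend, "final": final}, index=pd.Index(genes, name="gene_id")
    )
    return DispersionEstimates(frame=frame, excluded_genes=excluded, trend_coef=(a0, a1))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up; preserves input order; NaNs are excluded
    from the family and returned as NaN."""
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Vectorised NB IRLS
# ---------------------------------------------------------------------------

def _irls_two_group(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple:
    """Fit ``log mu = offset + b0 + b1*x`` per gene for NB counts.

    ``y`` is genes x samples, ``x`` the 0/1 group indicator, ``alpha`` the
    per-gene dispersion (treated as known).  Returns (b0, b1, se_b1,
    converged).  The 2x2 weighted normal equations are solved in closed form
    across all genes simultaneously.
    """
    G, S = y.shape
    sf = np.exp(offset)
    b0 = np.log(np.maximum((y / sf).mean(axis=1), 1e-8))
    b1 = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    a = alpha[:, None]
    a11 = a12 = a22 = det = None
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x + offset, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)
        z = (eta - offset) + (y - mu) / mu
        a11 = W.sum(axis=1)
        a12 = (W * x).sum(axis=1)
        a22 = (W * x * x).sum(axis=1)
        r1 = (W * z).sum(axis=1)
        r2 = (W * z * x).sum(axis=1)
        det = np.maximum(a11 * a22 - a12 ** 2, 1e-300)
        nb0 = (a22 * r1 - a12 * r2) / det
        nb1 = (a11 * r2 - a12 * r1) / det
        delta = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        converged |= delta < tol
        if converged.all():
            break
    se_b1 = np.sqrt(a11 / det)
    return b0, b1, se_b1, converged


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEGSet:
    """Differentially expressed genes of one contrast with their fold-change signs."""

    name: str
    p_adj_max: float
    abs_log2fc_min: float
    signs: pd.Series  # index gene, values +1/-1
    direction_label: str | None = None

    @property
    def genes(self) -> list:
        return list(self.signs.index)

    def __len__(self):
        return len(self.signs)

    def __contains__(self, gene):
        return gene in self.signs.index


def select_degs(
    result: "ContrastResults",
    p_adj_max: float = 0.05,
    abs_log2fc_min: float = 0.2,
) -> DEGSet:
    """Genes with ``padj < p_adj_max`` and ``|log2fc| >= abs_log2fc_min``."""
    if p_adj_max <= 0 or abs_log2fc_min <= 0:
        raise ValidationError("selection thresholds must be > 0")
    df = result.frame
    mask = (df["padj"] < p_adj_max) & (df["log2fc"].abs() >= abs_log2fc_min)
    mask &= df["padj"].notna()
    signs = np.sign(df.loc[mask, "log2fc"]).astype(np.int8)
    if len(signs) == 0:
        logger.info("select_degs: empty DEG set for contrast %s", result.name)
    return DEGSet(
        name=result.name,
        p_adj_max=p_adj_max,
        abs_log2fc_min=abs_log2fc_min,
        signs=signs,
        direction_label=result.direction_label,
    )


@dataclass(frozen=True)
class ContrastResults:
    """Per-gene DE summary of one two-condition comparison.

    ``log2fc`` is oriented ``cond_b`` over ``cond_a`` (the orientation stamp
    ``contrast=(cond_a, cond_b)`` records this); ``direction_label`` is an
    optional semantic tag (e.g. ``"case_vs_control"``) that downstream
    concordance logic uses to align signs across data sets.
    """

    frame: pd.DataFrame  # index gene_id; columns RESULT_COLUMNS (+ converged)
    contrast: tuple      # (cond_a, cond_b)
    direction_label: str | None = None
    excluded_genes: tuple = ()
    n_unconverged: int = 0

    @property
    def name(self) -> str:
        return f"{self.contrast[1]}_vs_{self.contrast[0]}"

    @property
    def genes_tested(self) -> int:
        return int(self.frame["pvalue"].notna().sum())

    def select_degs(self, p_adj_max: float = 0.05, abs_log2fc_min: float = 0.2) -> DEGSet:
        return select_degs(self, p_adj_max, abs_log2fc_min)

    def to_tsv(self, path) -> None:
        out = self.frame[RESULT_COLUMNS].rename(
            columns={"log2fc": "log2fc", "pvalue": "pvalue", "padj": "padj"}
        )
        out.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, contrast: tuple, direction_label: str | None = None) -> "ContrastResults":
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = [c for c in RESULT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"contrast table missing columns: {missing}")
        return cls(frame=df, contrast=tuple(contrast), direction_label=direction_label)

    def summary(self) -> str:
        df = self.frame
        n = len(df)
        n_tested = self.genes_tested
        n_sig = int((df["padj"] < 0.05).sum())
        lines = [
            f"Contrast {self.name} (log2FC oriented {self.contrast[1]} over {self.contrast[0]})",
            f"  genes in table: {n}; tested: {n_tested}; padj < 0.05: {n_sig}",
            f"  excluded all-zero genes: {len(self.excluded_genes)}; unconverged fits: {self.n_unconverged}",
        ]
        top = df.nsmallest(min(10, n), "padj")[RESULT_COLUMNS]
        lines.append(top.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The model object
# ---------------------------------------------------------------------------

class NegativeBinomialDE:
    """Two-group negative-binomial DE model over a count matrix.

    Parameters
    ----------
    counts : CountMatrix
    samples : SampleSheet
        Must cover every analysed sample with a condition label.

    Examples
    --------
    >>> model = NegativeBinomialDE(counts, sheet)
    >>> res = model.fit("CTL", "ASD", direction_label="case_vs_control")
    >>> degs = res.select_degs(p_adj_max=0.05, abs_log2fc_min=0.2)
    """

    def __init__(self, counts: CountMatrix, samples: SampleSheet):
        self.counts = counts
        self.samples = samples

    def size_factors(
        self, conditions: Sequence[str] | None = None, pseudo_reference: bool = False
    ) -> pd.Series:
        if conditions is None:
            sub = self.counts
        else:
            smp = [s for c in conditions for s in self.samples.samples_for(c)]
            sub = self.counts.subset_samples(smp)
        return estimate_size_factors(sub, pseudo_reference=pseudo_reference)

    def fit(
        self,
        cond_a: str,
        cond_b: str,
        size_factors: pd.Series | None = None,
        dispersions: DispersionEstimates | None = None,
        direction_label: str | None = None,
        shrink_weight: float = 0.5,
        dispersion_floor: float = 1e-8,
        pseudo_reference: bool = False,
    ) -> ContrastResults:
        """Fit the contrast ``cond_b`` vs ``cond_a`` (log2FC = B minus A)."""
        self.samples.validate_against(self.counts, [cond_a, cond_b])
        sa = self.samples.samples_for(cond_a)
        sb = self.samples.samples_for(cond_b)
        samples = sa + sb
        sub = self.counts.subset_samples(samples)
        if size_factors is None:
            size_factors = estimate_size_factors(sub, pseudo_reference=pseudo_reference)
        sf = size_factors.loc[samples]
        if (sf <= 0).any():
            raise ValidationError("size factors must be positive")
        if dispersions is None:
            dispersions = estimate_dispersions(
                sub,
                self.samples,
                sf,
                conditions=[cond_a, cond_b],
                shrink_weight=shrink_weight,
                dispersion_floor=dispersion_floor,
            )

        genes = dispersions.frame.index
        y = sub.data.loc[genes].to_numpy(dtype=float)
        x = np.array([0.0] * len(sa) + [1.0] * len(sb))
        offset = np.log(sf.to_numpy())
        alpha = dispersions.final.to_numpy()

        b0, b1, se_b1, converged = _irls_two_group(y, x, offset, alpha)
        log2fc = b1 / LOG2
        se = se_b1 / LOG2
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = log2fc / se
        pvalue = 2.0 * stats.norm.sf(np.abs(stat))
        pvalue = np.where(converged, pvalue, np.nan)
        n_unconverged = int((~converged).sum())
        if n_unconverged:
            logger.warning(
                "fit %s_vs_%s: %d gene(s) failed IRLS convergence; p set missing",
                cond_b, cond_a, n_unconverged,
            )
        padj = bh_adjust(pvalue)
        base_mean = (y / np.exp(offset)).mean(axis=1)

        frame = pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2fc": log2fc,
                "se": se,
                "stat": stat,
                "pvalue": pvalue,
                "padj": padj,
                "converged": converged,
            },
            index=genes.copy(),
        )
        return ContrastResults(
            frame=frame,
            contrast=(cond_a, cond_b),
            direction_label=direction_label,
            excluded_genes=dispersions.excluded_genes,
            n_unconverged=n_unconverged,
        )
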