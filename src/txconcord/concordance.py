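"""Direction-concordance classification of model contrasts against a reference.

Given the DEG set of a reference disease contrast (e.g. patient cortex vs
control) and the DE results of one or more model contrasts (e.g. treated vs
untreated neurons), each reference DEG is labelled per model contrast:

* ``convergent``   — significant in the model contrast, same fold-change sign,
* ``divergent``    — significant, opposite sign,
* ``unresolved``   — tested but failing the model-side significance gates,
* ``absent``       — not tested in the model contrast.

Genes labelled identically in *every* model contrast form the exclusion sets
("all convergent" / "all divergent"); the residual per-contrast sets after
removing them feed enrichment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexp import ContrastResults, DEGSet
from .exceptions import OrientationError, ValidationError

LABELS = ("convergent", "divergent", "unresolved", "absent")

__all__ = [
    "LABELS",
    "ConcordanceTable",
    "ExclusionSets",
    "ResidualSets",
    "classify_genes",
    "build_exclusion_sets",
    "residual_degs",
    "summarize",
    "ConcordanceAnalysis",
    "ConcordanceResults",
]


@dataclass(frozen=True)
class ConcordanceTable:
    """Per-gene labels of one model contrast against one reference DEG set."""

    contrast: str           # model contrast name
    reference: str          # reference contrast name
    frame: pd.DataFrame     # index: reference DEGs; columns: label, ref_sign,
                            # model_sign (NaN when undefined), model_padj, model_log2fc

    def genes_with(self, label: str) -> frozenset:
        if label not in LABELS:
            raise ValidationError(f"unknown label {label!r}")
        return frozenset(self.frame.index[self.frame["label"] == label])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


@dataclass(frozen=True)
class ExclusionSets:
    """Genes concordant (or discordant) in every supplied model contrast."""

    all_convergent: frozenset
    all_divergent: frozenset
    reference: str

    def __post_init__(self):
        if self.all_convergent & self.all_divergent:
            raise ValidationError("exclusion sets must be disjoint")

    @property
    def union(self) -> frozenset:
        return self.all_convergent | self.all_divergent


@dataclass(frozen=True)
class ResidualSets:
    convergent: frozenset
    divergent: frozenset


def classify_genes(
    ref_degs: DEGSet,
    model: ContrastResults,
    p_adj_max: float = 0.05,
    abs_log2fc_min: float = 0.2,
    flip: bool | None = None,
) -> ConcordanceTable:
    """Label every reference DEG against one model contrast.

    Orientation: both results carry a ``direction_label`` stamp.  When both
    stamps are set and disagree, the caller must state ``flip`` explicitly
    (``True`` negates the model signs before comparison) — otherwise an
    :class:`OrientationError` is raised to prevent silent sign inversion.
    """
    if p_adj_max <= 0 or abs_log2fc_min <= 0:
        raise ValidationError("thresholds must be > 0")
    if flip is None:
        ref_lab, mod_lab = ref_degs.direction_label, model.direction_label
        if ref_lab is not None and mod_lab is not None and ref_lab != mod_lab:
            raise OrientationError(
                f"orientation stamps differ (reference {ref_lab!r} vs model "
                f"{mod_lab!r}); pass flip=True or flip=False explicitly"
            )
        flip = False

    genes = pd.Index(ref_degs.genes)
    ref_sign = ref_degs.signs.reindex(genes).astype(float)

    mf = model.frame.reindex(genes)
    model_lfc = mf["log2fc"] * (-1.0 if flip else 1.0)
    model_padj = mf["padj"]
    tested = mf["pvalue"].notna() & genes.isin(model.frame.index)
    gates = tested & (model_padj < p_adj_max) & (model_lfc.abs() >= abs_log2fc_min)
    model_sign = np.sign(model_lfc)
    same = gates & (model_sign == ref_sign) & (model_sign != 0)
    opposite = gates & (model_sign == -ref_sign) & (model_sign != 0)

    label = pd.Series("absent", index=genes, dtype=object)
    label[tested] = "unresolved"
    label[same] = "convergent"
    label[opposite] = "divergent"

    frame = pd.DataFrame(
        {
            "label": label,
            "ref_sign": ref_sign,
            "model_sign": model_sign.where(gates),
            "model_padj": model_padj,
            "model_log2fc": model_lfc,
        },
        index=genes.copy(),
    )
    frame.index.name = "gene"
    return ConcordanceTable(contrast=model.name, reference=ref_degs.name, frame=frame)


def build_exclusion_sets(tables: Sequence[ConcordanceTable]) -> ExclusionSets:
    """Intersect labels across all supplied model contrasts."""
    tables = list(tables)
    if not tables:
        raise ValidationError("need at least one concordance table")
    universe = set(tables[0].frame.index)
    reference = tables[0].reference
    for t in tables[1:]:
        if set(t.frame.index) != universe or t.reference != reference:
            raise ValidationError(
                f"table for contrast {t.contrast!r} uses a different reference DEG universe"
            )
    all_conv = frozenset.intersection(*[t.genes_with("convergent") for t in tables])
    all_div = frozenset.intersection(*[t.genes_with("divergent") for t in tables])
    return ExclusionSets(all_convergent=all_conv, all_divergent=all_div, reference=reference)


def residual_degs(table: ConcordanceTable, excl: ExclusionSets) -> ResidualSets:
    """Per-contrast label sets minus the all-convergent/all-divergent genes."""
    if excl.reference != table.reference:
        raise ValidationError("exclusion sets built from a different reference")
    drop = excl.union
    return ResidualSets(
        convergent=table.genes_with("convergent") - drop,
        divergent=table.genes_with("divergent") - drop,
    )


def summarize(table: ConcordanceTable) -> dict:
    """Counts and fractions of each label, plus a signed concordance fraction.

    With an empty reference DEG set the fractions are ``None`` (undefined),
    never NaN.  The signed fraction is ``(convergent - divergent) /
    (convergent + divergent)`` over the resolved genes, ``None`` when no gene
    is resolved.
    """
    counts = {lab: int((table.frame["label"] == lab).sum()) for lab in LABELS}
    n = len(table.frame)
    fractions = {lab: counts[lab] / n for lab in LABELS} if n else None
    resolved = counts["convergent"] + counts["divergent"]
    signed = (counts["convergent"] - counts["divergent"]) / resolved if resolved else None
    return {
        "contrast": table.contrast,
        "reference": table.reference,
        "n_reference_degs": n,
        "counts": counts,
        "fractions": fractions,
        "signed_concordance": signed,
    }


# ---------------------------------------------------------------------------
# Model/Results wrapper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResults:
    """Fitted concordance analysis: tables per model contrast, exclusion sets
    and residual sets, with a tabular summary."""

    tables: dict                    # contrast name -> ConcordanceTable
    exclusion_sets: ExclusionSets
    residuals: dict                 # contrast name -> ResidualSets

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, table in self.tables.items():
            s = summarize(table)
            row = {"contrast": name, "n_reference_degs": s["n_reference_degs"]}
            row.update({f"n_{lab}": s["counts"][lab] for lab in LABELS})
            row["signed_concordance"] = s["signed_concordance"]
            res = self.residuals[name]
            row["n_convergent_residual"] = len(res.convergent)
            row["n_divergent_residual"] = len(res.divergent)
            rows.append(row)
        return pd.DataFrame(rows).set_index("contrast")


class ConcordanceAnalysis:
    """Classify several model contrasts against one reference DEG set.

    Parameters
    ----------
    reference_degs : DEGSet
        DEGs of the reference (disease) contrast, signs included.
    models : mapping of name -> ContrastResults
        The model contrasts to classify.
    flips : mapping of name -> bool, optional
        Explicit orientation flips per model contrast.
    """

    def __init__(
        self,
        reference_degs: DEGSet,
        models: Mapping[str, ContrastResults],
        p_adj_max: float = 0.05,
        abs_log2fc_min: float = 0.2,
        flips: Mapping[str, bool] | None = None,
    ):
        if not models:
            raise ValidationError("need at least one model contrast")
        self.reference_degs = reference_degs
        self.models = dict(models)
        self.p_adj_max = p_adj_max
        self.abs_log2fc_min = abs_log2fc_min
        self.flips = dict(flips or {})

    def fit(self) -> ConcordanceResults:
        tables = {
            name: classify_genes(
                self.reference_degs,
                res,
                p_adj_max=self.p_adj_max,
                abs_log2fc_min=self.abs_log2fc_min,
                flip=self.flips.get(name),
            )
            for name, res in self.models.items()
        }
        excl = build_exclusion_sets(list(tables.values()))
        residuals = {name: residual_degs(t, excl) for name, t in tables.items()}
        return ConcordanceResults(tables=tables, exclusion_sets=excl, residuals=residuals)
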