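"""Readers, writers and identifier handling.

Covers the formats the pipeline touches: gene x sample count tables (TSV/CSV
or MatrixMarket triplet with sidecar name files), sample sheets, two-column
identifier maps, and GMT gene-set collections, plus deterministic
source-id -> symbol mapping and multi-source gene-list merging.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "GeneSet",
    "GeneSetCollection",
    "MappingReport",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "read_id_map",
    "map_gene_ids",
    "read_gmt",
    "write_gmt",
    "merge_gene_sources",
]


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Raw integer counts, genes x samples, wrapped around a DataFrame.

    Invariants: integer counts >= 0, no missing values, unique gene and
    sample identifiers, at least 1 gene and 2 samples.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValidationError(
                f"count matrix needs >=1 gene and >=2 samples, got shape {df.shape}"
            )
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:10]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:10]}")
        if df.isna().any().any():
            raise ValidationError("count matrix contains missing values")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            frac, _ = np.modf(values.astype(float))
            if np.any(frac != 0):
                g, s = np.argwhere(frac != 0)[0]
                raise FormatError(
                    f"non-integer count {values[g, s]!r} at gene "
                    f"{df.index[g]!r}, sample {df.columns[s]!r}"
                )
            object.__setattr__(self, "data", df.astype(np.int64))
            values = self.data.to_numpy()
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count {values[g, s]} at gene "
                f"{df.index[g]!r}, sample {df.columns[s]!r}"
            )

    # -- accessors ----------------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return CountMatrix(self.data.loc[:, list(samples)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.data.equals(other.data)


@dataclass(frozen=True)
class SampleSheet:
    """sample_id -> condition mapping; extra covariate columns carried through."""

    data: pd.DataFrame  # index sample_id, mandatory column "condition"

    def __post_init__(self):
        if "condition" not in self.data.columns:
            raise ValidationError("sample sheet must have a 'condition' column")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dups}")
        if self.data["condition"].isna().any():
            raise ValidationError("sample sheet has missing condition labels")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.data["condition"]))

    def samples_for(self, condition: str) -> list:
        sel = self.data.index[self.data["condition"] == condition].tolist()
        return sel

    def validate_against(self, m: CountMatrix, conditions: Iterable[str]) -> None:
        for cond in conditions:
            samples = self.samples_for(cond)
            if len(samples) < 2:
                raise ValidationError(
                    f"condition {cond!r} has {len(samples)} sample(s); need >=2"
                )
            missing = [s for s in samples if s not in m.data.columns]
            if missing:
                raise ValidationError(
                    f"samples of condition {cond!r} absent from count matrix: {missing}"
                )

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple  # deduplicated, first-seen order

    def __post_init__(self):
        if not self.name:
            raise ValidationError("gene set needs a non-empty name")
        if len(self.members) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            seen, dedup = set(), []
            for g in self.members:
                if g not in seen:
                    seen.add(g)
                    dedup.append(g)
            object.__setattr__(self, "members", tuple(dedup))

    def __len__(self):
        return len(self.members)

    def __contains__(self, gene):
        return gene in set(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets with unique names (GMT semantics)."""

    sets: dict = field(default_factory=dict)  # name -> GeneSet

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValidationError(f"duplicate gene-set name {gs.name!r}")
        self.sets[gs.name] = gs

    @property
    def names(self) -> list:
        return list(self.sets)

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name):
        return name in self.sets

    def __eq__(self, other):
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx-triplet"
    return "tsv"


def read_count_matrix(path, dialect: str | None = None) -> CountMatrix:
    """Read a gene x sample count table.

    TSV/CSV: header row of sample ids, first column gene ids; lines starting
    with '#' are comments.  MatrixMarket triplet requires sidecar files
    ``<stem>.rows.txt`` and ``<stem>.cols.txt`` carrying gene and sample ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        df.index = df.index.astype(str).str.strip()
        df.columns = [str(c).strip() for c in df.columns]
        return CountMatrix(df)
    if dialect == "mtx-triplet":
        from scipy.io import mmread

        mat = mmread(path)
        rows = _read_lines(path.with_suffix(".rows.txt"))
        cols = _read_lines(path.with_suffix(".cols.txt"))
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if dense.shape != (len(rows), len(cols)):
            raise FormatError(
                f"mtx shape {dense.shape} does not match sidecar names "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
        return CountMatrix(pd.DataFrame(dense, index=rows, columns=cols))
    raise ValidationError(f"unknown dialect {dialect!r}")


def _read_lines(path: Path) -> list:
    if not path.exists():
        raise FileNotFoundError(path)
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def write_count_matrix(m: CountMatrix, path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        m.data.to_csv(path, sep=sep, index_label="gene_id")
        return
    if dialect == "mtx-triplet":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(m.counts))
        path.with_suffix(".rows.txt").write_text("\n".join(map(str, m.gene_ids)) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(map(str, m.sample_ids)) + "\n")
        return
    raise ValidationError(f"unknown dialect {dialect!r}")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).str.strip()
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------

def read_id_map(path) -> pd.DataFrame:
    """Two-column TSV (source_id, target_symbol); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("id map must have two tab-separated columns")
    first = df.iloc[0]
    if str(first[0]).lower() in ("source_id", "source", "id"):
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["source_id", "target_symbol"]
    df = df.apply(lambda c: c.str.strip())
    if (df == "").any().any() or df.isna().any().any():
        raise FormatError("id map contains empty fields")
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class MappingReport:
    n_input: int
    n_mapped: int
    n_unmapped: int
    unmapped: tuple
    ambiguous_dropped: tuple  # source ids with >1 target under drop_ambiguous
    collided_symbols: tuple   # symbols fed by >1 source id
    n_output: int

    def __post_init__(self):
        assert self.n_mapped + self.n_unmapped == self.n_input


def map_gene_ids(
    m: CountMatrix,
    id_map: pd.DataFrame,
    policy: str = "drop_ambiguous",
    collision: str = "sum",
) -> tuple:
    """Map source gene ids to symbols.

    policy: how a source id with multiple target symbols is resolved —
    ``first`` keeps the first mapping in file order, ``drop_ambiguous``
    treats the gene as unmapped.  collision: how several source ids landing
    on one symbol are combined — ``sum`` adds their counts elementwise,
    ``drop`` removes the symbol entirely.

    Returns (mapped CountMatrix, MappingReport).
    """
    if policy not in ("first", "drop_ambiguous"):
        raise ValidationError(f"unknown policy {policy!r}")
    if collision not in ("sum", "drop"):
        raise ValidationError(f"unknown collision strategy {collision!r}")
    if id_map is None or len(id_map) == 0:
        raise ValidationError("empty id map")

    targets: dict = {}
    ambiguous: set = set()
    for src, tgt in zip(id_map["source_id"], id_map["target_symbol"]):
        if src in targets:
            if targets[src] != tgt:
                ambiguous.add(src)
        else:
            targets[src] = tgt

    resolved: dict = {}
    ambiguous_dropped: list = []
    for gene in m.gene_ids:
        if gene not in targets:
            continue
        if gene in ambiguous and policy == "drop_ambiguous":
            ambiguous_dropped.append(gene)
            continue
        resolved[gene] = targets[gene]

    mapped_rows = [g for g in m.gene_ids if g in resolved]
    unmapped = [g for g in m.gene_ids if g not in resolved]

    df = m.data.loc[mapped_rows].copy()
    df.index = pd.Index([resolved[g] for g in mapped_rows], name="gene_id")

    sym_counts = df.index.value_counts()
    collided = sorted(sym_counts.index[sym_counts > 1].tolist())
    if collided:
        if collision == "sum":
            order = list(dict.fromkeys(df.index))
            df = df.groupby(level=0, sort=False).sum().loc[order]
        else:  # drop
            keep = ~df.index.isin(collided)
            dropped_srcs = [g for g in mapped_rows if resolved[g] in collided]
            unmapped.extend(dropped_srcs)
            mapped_rows = [g for g in mapped_rows if resolved[g] not in collided]
            df = df.loc[keep]

    if df.shape[0] == 0:
        raise ValidationError("no genes survive mapping")
    report = MappingReport(
        n_input=len(m.gene_ids),
        n_mapped=len(mapped_rows),
        n_unmapped=len(unmapped),
        unmapped=tuple(unmapped),
        ambiguous_dropped=tuple(ambiguous_dropped),
        collided_symbols=tuple(collided),
        n_output=df.shape[0],
    )
    return CountMatrix(df), report


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, members, tab-separated."""
    path = Path(path)
    coll = GeneSetCollection()
    text = path.read_text()
    if not text.strip():
        logger.warning("GMT file %s is empty; returning empty collection", path)
        return coll
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
            )
        name, desc = fields[0], fields[1]
        members = [g for g in fields[2:] if g]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        coll.add(GeneSet(name, desc, tuple(members)))
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([gs.name, gs.description, *gs.members]) for gs in collection
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def merge_gene_sources(sources: Mapping[str, object], union_name: str = "combined") -> GeneSetCollection:
    """Merge one-symbol-per-line gene lists into a collection.

    ``sources`` maps source name -> path or iterable of symbols.  Emits one
    set per source plus a union set whose description records, per member,
    which sources contributed it.
    """
    if not sources:
        raise ValidationError("no sources given")
    lists: dict = {}
    for name, src in sources.items():
        if isinstance(src, (str, Path)):
            symbols = _read_lines(Path(src))
        else:
            symbols = [str(s).strip() for s in src if str(s).strip()]
        lists[name] = list(dict.fromkeys(symbols))
    if all(len(v) == 0 for v in lists.values()):
        raise ValidationError("all sources are empty")

    coll = GeneSetCollection()
    provenance: dict = {}
    for name, symbols in lists.items():
        if symbols:
            coll.add(GeneSet(name, f"source:{name}", tuple(symbols)))
        for s in symbols:
            provenance.setdefault(s, []).append(name)
    union_members = tuple(provenance)  # first-seen order across sources
    desc = "|".join(f"{g}:{','.join(provenance[g])}" for g in union_members)
    coll.add(GeneSet(union_name, desc, union_members))
    return coll
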