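"""Core domain types, file readers/writers and table transforms.

The universal input is an OTU count table (taxa x samples) carrying a
Greengenes-style lineage string per taxon and a kingdom tag, together with a
per-sample metadata table (compartment niche and host cultivar) and, for the
phylogenetic null models, a rooted tree whose tips are taxon IDs.

File formats are deliberately plain:

* OTU table: TSV, header ``#OTU_ID<TAB>S1..Sn<TAB>taxonomy``, one taxon per row.
* Metadata:  TSV ``sample_id<TAB>niche<TAB>cultivar``.
* Tree:      Newick with branch lengths.
* Config:    flat ``key = value`` text file mirroring :class:`AnalysisConfig`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

NICHES = ("bulk", "rhizosphere", "endosphere")
CULTIVARS = ("rabbiteye", "northern_highbush", "southern_highbush")
KINGDOMS = ("bacteria", "fungi")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__")))


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


class OtuTable:
    """An integer OTU count matrix with taxonomy and kingdom annotations.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, taxa as rows, samples as columns.
    taxonomy : pandas.Series
        Semicolon-delimited lineage string per taxon
        (``k__...;p__...;c__...;o__...;f__...;g__...``; missing ranks may be
        empty).
    kingdom : pandas.Series or str
        ``"bacteria"`` or ``"fungi"``; a scalar is broadcast to all taxa.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    kingdom: pd.Series

    def __init__(self, counts: pd.DataFrame, taxonomy: pd.Series | None = None,
                 kingdom: pd.Series | str = "bacteria"):
        counts = pd.DataFrame(counts)
        if taxonomy is None:
            taxonomy = pd.Series("", index=counts.index)
        taxonomy = pd.Series(taxonomy).reindex(counts.index).fillna("")
        if isinstance(kingdom, str):
            kingdom = pd.Series(kingdom, index=counts.index)
        kingdom = pd.Series(kingdom).reindex(counts.index)
        self.counts = counts
        self.taxonomy = taxonomy
        self.kingdom = kingdom
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValidationError(f"duplicate taxon ID: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample ID: {dup!r}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("counts must be finite")
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")
        sums = vals.sum(axis=0)
        if (sums <= 0).any():
            bad = c.columns[int(np.argmin(sums))]
            raise ValidationError(f"sample column sums to zero: {bad!r}")
        bad_k = ~self.kingdom.isin(KINGDOMS)
        if bad_k.any():
            raise ValidationError(
                f"unknown kingdom label {self.kingdom[bad_k].iloc[0]!r}")

    # -- basic accessors ----------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def copy(self) -> "OtuTable":
        return OtuTable(self.counts.copy(), self.taxonomy.copy(),
                        self.kingdom.copy())

    # -- transforms ---------------------------------------------------------

    def relative_abundance(self) -> pd.DataFrame:
        """Total-sum scaling: each sample column divided by its total."""
        c = self.counts.astype(float)
        return c / c.sum(axis=0)

    def filter_by_mean_abundance(self, min_fraction: float) -> "OtuTable":
        """Keep taxa whose mean relative abundance strictly exceeds
        ``min_fraction`` (averaged over this table's samples)."""
        if not 0 < min_fraction < 1:
            raise ValueError("min_fraction must be in (0, 1)")
        mean_rel = self.relative_abundance().mean(axis=1)
        keep = mean_rel > min_fraction
        if not keep.any():
            raise ValidationError(
                f"no taxa pass the {min_fraction:g} mean-abundance filter")
        return OtuTable(self.counts.loc[keep], self.taxonomy.loc[keep],
                        self.kingdom.loc[keep])

    def aggregate_by_rank(self, rank: str) -> "OtuTable":
        """Sum counts over taxa sharing a lineage label at ``rank``.

        Taxa without a label at that rank are pooled as ``"unclassified"``.
        """
        if rank not in ("phylum", "class", "order"):
            raise ValueError(f"unknown rank: {rank!r}")
        labels = self.taxonomy.map(lambda s: parse_lineage(s).get(rank) or
                                   "unclassified")
        grouped = self.counts.groupby(labels, sort=True).sum()
        tax = pd.Series(
            {name: _lineage_to_rank(self.taxonomy[labels == name].iloc[0], rank)
             if name != "unclassified" else ""
             for name in grouped.index})
        king = pd.Series(
            {name: self.kingdom[labels == name].iloc[0]
             for name in grouped.index})
        return OtuTable(grouped, tax, king)

    def rarefy(self, depth: int, seed: int = 0) -> "OtuTable":
        """Subsample each sample to ``depth`` reads without replacement."""
        if depth <= 0:
            raise ValueError("depth must be positive")
        rng = np.random.default_rng(seed)
        out = {}
        for s in self.sample_ids:
            col = self.counts[s].to_numpy()
            total = int(col.sum())
            if total < depth:
                raise ValidationError(
                    f"sample {s!r} has {total} reads (< depth {depth})")
            pool = np.repeat(np.arange(len(col)), col)
            take = rng.choice(pool, size=depth, replace=False)
            out[s] = np.bincount(take, minlength=len(col))
        new = pd.DataFrame(out, index=self.counts.index)[self.sample_ids]
        return OtuTable(new, self.taxonomy, self.kingdom)

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts[list(sample_ids)], self.taxonomy,
                        self.kingdom)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (self.counts.equals(other.counts)
                and self.taxonomy.equals(other.taxonomy)
                and self.kingdom.equals(other.kingdom))


def concat_tables(a: OtuTable, b: OtuTable) -> OtuTable:
    """Stack two kingdom tables over an identical sample set."""
    if set(a.sample_ids) != set(b.sample_ids):
        raise ValidationError("tables have mismatched sample sets")
    b = b.subset_samples(a.sample_ids)
    counts = pd.concat([a.counts, b.counts])
    tax = pd.concat([a.taxonomy, b.taxonomy])
    king = pd.concat([a.kingdom, b.kingdom])
    return OtuTable(counts, tax, king)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-delimited lineage into a rank->name dict.

    Greengenes-style prefixes (``k__`` ...) are recognised and stripped; bare
    names are assigned to ranks positionally. Empty fields yield ``None``.
    """
    out: dict[str, str | None] = dict.fromkeys(RANKS)
    if not lineage:
        return out
    tokens = [t.strip() for t in lineage.split(";")]
    prefix_to_rank = {v: k for k, v in RANK_PREFIXES.items()}
    pos = 0
    for tok in tokens:
        if len(tok) >= 3 and tok[:3] in prefix_to_rank:
            rank, name = prefix_to_rank[tok[:3]], tok[3:]
        else:
            if pos >= len(RANKS):
                break
            rank, name = RANKS[pos], tok
        out[rank] = name or None
        pos = RANKS.index(rank) + 1
    return out


def _lineage_to_rank(lineage: str, rank: str) -> str:
    """Truncate a lineage string at the given rank (inclusive)."""
    tokens = [t.strip() for t in lineage.split(";")]
    upto = RANKS.index(rank) + 1
    return ";".join(tokens[:upto])


# -- OTU table I/O -----------------------------------------------------------

def read_otu_table(path, kingdom: str = "bacteria") -> OtuTable:
    """Read a TSV OTU table (first column taxon ID, last column taxonomy)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 3:
        raise ValidationError("OTU table needs taxon ID, >=1 sample, taxonomy")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValidationError(f"duplicate taxon ID: {dup!r}")
    df = df.set_index(id_col)
    if df.columns[-1].lower() != "taxonomy":
        raise ValidationError("last column must be 'taxonomy'")
    tax = df.iloc[:, -1].fillna("")
    counts = df.iloc[:, :-1]
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count: {exc}") from exc
    if not np.allclose(counts.to_numpy(),
                       np.round(counts.to_numpy()), atol=1e-9):
        raise ValidationError("counts must be integers")
    counts = counts.round().astype(np.int64)
    counts.index.name = None
    return OtuTable(counts, tax, kingdom)


def write_otu_table(table: OtuTable, path) -> None:
    df = table.counts.copy()
    df.insert(len(df.columns), "taxonomy", table.taxonomy)
    df.index.name = "#OTU_ID"
    df.to_csv(path, sep="\t")


# -- sample metadata ---------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample factor table: compartment niche and blueberry cultivar."""

    table: pd.DataFrame  # index sample_id; columns niche, cultivar

    def __post_init__(self):
        t = self.table
        if t.index.duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        for col, vocab in (("niche", NICHES), ("cultivar", CULTIVARS)):
            if col not in t.columns:
                raise ValidationError(f"metadata missing column {col!r}")
            bad = ~t[col].isin(vocab)
            if bad.any():
                raise ValidationError(
                    f"unknown {col} value {t[col][bad].iloc[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def niche(self, sample_ids=None) -> pd.Series:
        s = self.table["niche"]
        return s if sample_ids is None else s.loc[list(sample_ids)]

    def cultivar(self, sample_ids=None) -> pd.Series:
        s = self.table["cultivar"]
        return s if sample_ids is None else s.loc[list(sample_ids)]

    def require(self, sample_ids) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing[:5]}")
        return SampleMetadata(self.table.loc[list(sample_ids)])


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# -- phylogenetic tree -------------------------------------------------------

def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValidationError("tree tip labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError("negative branch length in tree")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def patristic_distances(tree: TreeNode) -> pd.DataFrame:
    """Pairwise tip-to-tip (patristic) distance matrix as a DataFrame."""
    dm = tree.tip_tip_distances()
    return dm.to_data_frame()


# -- analysis configuration --------------------------------------------------

@dataclass
class AnalysisConfig:
    """Thresholds and sizes shared across pipeline stages.

    Defaults follow the study design: 999 null-model randomizations and
    permutations, network edges at Spearman |rho| > 0.7 with BH-adjusted
    P < 0.01, an OTU mean relative-abundance filter of 0.5%, an LDA effect
    size threshold of 4.0, and alpha = 0.05 for class tests.
    """

    rng_seed: int = 0
    n_null: int = 999
    n_permutations: int = 999
    r_threshold: float = 0.7
    p_threshold: float = 0.01
    abundance_filter: float = 0.005
    lda_threshold: float = 4.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_null < 1:
            raise ValidationError("n_null must be >= 1")
        for name in ("p_threshold", "abundance_filter", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValidationError(f"unknown config key {key!r}")
            caster = int if "int" in str(fields[key]) else float
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write any result table as TSV."""
    df.to_csv(path, sep="\t", index=index)
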