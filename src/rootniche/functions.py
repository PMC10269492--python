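"""Taxonomy-to-guild functional mapping engine.

A generic stand-in for database-driven guild annotation (FAPROTAX-style for
bacteria, FUNGuild-style for fungi): the user supplies a mapping table of
``matcher -> function``, where a matcher is either a taxon ID or a
lineage-prefix pattern (a whole-rank prefix of the lineage, or a single
rank token such as ``o__Helotiales``; matching is case-insensitive).

A taxon carrying m functions contributes its full relative abundance to
each of them by default (no splitting), mirroring FAPROTAX; a
split-assignment toggle divides the abundance by m instead. Unmatched taxa
are pooled as ``unassigned``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from statsmodels.stats.multitest import multipletests

from .diversity import significance_stars
from .io import OtuTable, SampleMetadata, ValidationError

UNASSIGNED = "unassigned"


def read_function_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "confidence" not in df.columns:
        df["confidence"] = ""
    if not {"matcher", "function"} <= set(df.columns):
        raise ValidationError("function map needs matcher/function columns")
    if (df["matcher"].fillna("") == "").any():
        raise ValidationError("empty matcher in function map")
    return df[["matcher", "function", "confidence"]]


def write_function_map(fmap: pd.DataFrame, path) -> None:
    fmap.to_csv(path, sep="\t", index=False)


def _match_keys(taxon_id: str, lineage: str) -> set[str]:
    """All case-folded keys a matcher may hit: the taxon ID, every
    whole-rank lineage prefix, and every single rank token."""
    keys = {taxon_id.lower()}
    tokens = [t.strip() for t in lineage.split(";") if t.strip()]
    for i in range(1, len(tokens) + 1):
        keys.add(";".join(tokens[:i]).lower())
    keys.update(t.lower() for t in tokens)
    return keys


def map_functions(table: OtuTable, fmap: pd.DataFrame,
                  split: bool = False) -> pd.DataFrame:
    """Function x sample relative-abundance table.

    Each function's abundance is the sum of its member taxa's relative
    abundances; with ``split=True`` a taxon with m functions contributes
    1/m of its abundance to each.
    """
    if (fmap["matcher"].fillna("") == "").any():
        raise ValidationError("empty matcher in function map")
    rel = table.relative_abundance()
    matcher_funcs: dict[str, list[str]] = {}
    for _, row in fmap.iterrows():
        matcher_funcs.setdefault(row["matcher"].lower(), []).append(
            row["function"])
    functions = sorted({f for fs in matcher_funcs.values() for f in fs})
    out = pd.DataFrame(0.0, index=functions + [UNASSIGNED],
                       columns=table.sample_ids)
    for taxon in table.taxon_ids:
        keys = _match_keys(taxon, table.taxonomy[taxon])
        funcs = sorted({f for key in keys
                        for f in matcher_funcs.get(key, [])})
        if not funcs:
            out.loc[UNASSIGNED] += rel.loc[taxon]
            continue
        weight = 1.0 / len(funcs) if split else 1.0
        for f in funcs:
            out.loc[f] += weight * rel.loc[taxon]
    return out


def compare_functions(function_table: pd.DataFrame,
                      metadata: SampleMetadata,
                      factor: str = "niche") -> pd.DataFrame:
    """Kruskal-Wallis per function across niches with BH adjustment and
    star coding (* P<0.05, ** P<0.01, *** P<0.001 on adjusted p)."""
    meta = metadata.require(function_table.columns).table
    labels = meta[factor].to_numpy()
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    rows = []
    vals_matrix = function_table.to_numpy(dtype=float)
    for name, vals in zip(function_table.index, vals_matrix):
        groups = [vals[labels == lv] for lv in levels]
        if np.allclose(vals, vals[0]):
            h, p = 0.0, 1.0
        else:
            h, p = kruskal(*groups)
        rows.append({"function": name, "H": float(h), "p_raw": float(p)})
    df = pd.DataFrame(rows).set_index("function")
    df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    df["stars"] = df["p_adj"].map(significance_stars)
    return df
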