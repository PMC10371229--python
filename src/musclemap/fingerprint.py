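"""The molecular fingerprint of insulin resistance.

Proteins make it into the fingerprint when they (i) associate negatively with
the Matsuda Index at the chosen q-threshold and (ii) carry a cis-pQTL.  The
negative direction selects candidates whose abundance is higher in
insulin-resistant animals ("up in IR"), and the cis filter enriches for
causality: when local genotype explains a protein's abundance, reverse
causation from the phenotype is implausible.

The fingerprint exports as a single-directional GMT gene set for querying
compound-signature databases: reversal then appears as negative enrichment of
this one set (no paired up/down query).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Fingerprint", "build_fingerprint", "map_orthologues", "export_query_set"]


@dataclass
class Fingerprint:
    """Ordered fingerprint entries (strongest negative effect first)."""

    entries: pd.DataFrame  # index protein_id; gene_symbol, fraction, effect_size, q_value, classification
    direction: str = "up-in-IR"

    @property
    def genes(self) -> list[str]:
        return list(self.entries["gene_symbol"])

    def __len__(self) -> int:
        return len(self.entries)


def build_fingerprint(
    assoc: pd.DataFrame,
    pqtl: pd.DataFrame,
    q_threshold: float = 0.05,
    gene_symbols: pd.Series | None = None,
) -> Fingerprint:
    """Intersect negative trait associations with cis-pQTL presence.

    ``assoc`` holds per-protein association results (columns ``effect_size``,
    ``q_value``, and ``fraction``); ``pqtl`` per-protein peak records with a
    ``classification`` column.  Proteins pass when effect_size < 0, q <
    q_threshold and classification == "cis".  Gene symbols default to protein
    ids; symbol collisions across fractions collapse to the entry with the
    smaller q.  Entries are ordered by effect size ascending.
    """
    required = {"effect_size", "q_value"}
    if not required <= set(assoc.columns):
        raise ValueError(f"assoc results missing columns {required - set(assoc.columns)}")
    neg = assoc[(assoc["effect_size"] < 0) & (assoc["q_value"] < q_threshold)]
    cis = set(pqtl.index[pqtl["classification"] == "cis"])
    selected = neg.loc[[p for p in neg.index if p in cis]].copy()
    selected["classification"] = "cis"
    if gene_symbols is not None:
        selected["gene_symbol"] = gene_symbols.reindex(selected.index).fillna(pd.Series(selected.index, index=selected.index))
    else:
        selected["gene_symbol"] = selected.index
    if "fraction" not in selected.columns:
        selected["fraction"] = "NA"
    selected = selected.sort_values(["q_value", "effect_size"], kind="mergesort")
    selected = selected[~selected["gene_symbol"].duplicated(keep="first")]
    selected = selected.sort_values(["effect_size", "gene_symbol"], kind="mergesort")
    by_frac = selected["fraction"].value_counts().to_dict()
    logger.info("fingerprint size=%d per_fraction=%s q<%g", len(selected), by_frac, q_threshold)
    if selected.empty:
        logger.warning("fingerprint is empty at q<%g", q_threshold)
    cols = ["gene_symbol", "fraction", "effect_size", "q_value", "classification"]
    return Fingerprint(entries=selected[cols])


def map_orthologues(fp: Fingerprint, mapping: pd.DataFrame) -> Fingerprint:
    """Annotate fingerprint entries with human orthologue symbols.

    ``mapping`` is a two-column table (mouse symbol, human symbol).  Unmapped
    entries are retained with ``human_symbol`` NA and ``mapped`` False.
    """
    if mapping.shape[1] < 2:
        raise ValueError("orthologue mapping needs two columns (mouse, human)")
    m = mapping.iloc[:, :2].copy()
    m.columns = ["mouse", "human"]
    bad = m[m.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"malformed mapping rows at lines {[int(i) + 2 for i in bad.index[:5]]}")
    lut = m.drop_duplicates("mouse").set_index("mouse")["human"]
    entries = fp.entries.copy()
    entries["human_symbol"] = lut.reindex(entries["gene_symbol"].to_numpy()).to_numpy()
    entries["mapped"] = entries["human_symbol"].notna()
    return Fingerprint(entries=entries, direction=fp.direction)


def export_query_set(
    fp: Fingerprint,
    name: str = "IR_fingerprint",
    description: str = "proteins up in insulin resistance with cis-pQTL",
) -> str:
    """Render the fingerprint as one GMT line (name, description, symbols)."""
    if len(fp) == 0:
        raise ValueError("cannot export an empty fingerprint")
    symbols = fp.genes
    for s in symbols:
        if any(ch.isspace() for ch in str(s)):
            raise ValueError(f"gene symbol with whitespace cannot be written to GMT: {s!r}")
    return "\t".join([name, description, *map(str, symbols)])
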