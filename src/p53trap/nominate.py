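"""Payload-target nomination: jointly essential and scarce proteins.

A bifunctional cytotoxin works best when its toxic moiety targets a protein
that is (a) highly essential, so partial inhibition kills, and (b) much less
abundant than the trapping protein (mutant p53, ~920 nM in 293T cells), so
the trapped compound pool saturates it.  Candidates are therefore filtered
to mean Chronos score <= -2 and protein abundance <= 920 nM, then ranked by

    score = log10(abundance_nM) + mean_chronos

ascending — the lower the score, the scarcer and more essential the target.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CHRONOS_MAX_DEFAULT = -2.0
ABUNDANCE_MAX_NM_DEFAULT = 920.0


class NominationError(ValueError):
    pass


def nominate_targets(
    essentiality: pd.Series | dict,
    abundance_nM: pd.Series | dict,
    chronos_max: float = CHRONOS_MAX_DEFAULT,
    abundance_max_nM: float = ABUNDANCE_MAX_NM_DEFAULT,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Filter-and-rank nomination table.

    Parameters
    ----------
    essentiality
        gene -> mean Chronos dependency score (negative = essential).
    abundance_nM
        gene -> protein concentration in nM (must be > 0 to be scored).
    chronos_max, abundance_max_nM
        Hit thresholds; a gene passes when ``mean_chronos <= chronos_max``
        and ``abundance_nM <= abundance_max_nM``.
    top_k
        Optional truncation after ranking.

    Returns a frame indexed 1..n by rank with columns gene, mean_chronos,
    abundance_nM, score, passes_filter (all True in the returned rows).
    Genes are inner-joined on their ids; rows with missing values are
    dropped before filtering.  Ties in score break lexicographically by
    gene id, so the ordering is deterministic.  Because the score is
    additive in log10(abundance), rescaling abundance units shifts every
    score by the same constant and never changes the ordering.
    """
    ess = pd.Series(essentiality, dtype=float)
    ab = pd.Series(abundance_nM, dtype=float)
    joined = pd.DataFrame({"mean_chronos": ess, "abundance_nM": ab}).dropna()
    if joined.empty:
        warnings.warn("no genes shared between essentiality and abundance tables")
        return _empty_table()
    if (joined["abundance_nM"] <= 0).any():
        raise NominationError("abundance must be positive for all scored genes")
    joined["score"] = np.log10(joined["abundance_nM"]) + joined["mean_chronos"]
    joined["passes_filter"] = (joined["mean_chronos"] <= chronos_max) & (
        joined["abundance_nM"] <= abundance_max_nM
    )
    # lexicographic pre-sort + stable sort on score => ties break by gene id
    hits = joined[joined["passes_filter"]].sort_index(kind="stable")
    hits = hits.sort_values("score", kind="stable")
    if top_k is not None:
        hits = hits.head(top_k)
    out = hits.rename_axis("gene").reset_index()
    out.index = pd.RangeIndex(1, len(out) + 1, name="rank")
    return out


def _empty_table() -> pd.DataFrame:
    out = pd.DataFrame(
        columns=["gene", "mean_chronos", "abundance_nM", "score", "passes_filter"]
    )
    out.index.name = "rank"
    return out


def read_gene_table(path, value_column: str) -> pd.Series:
    """Read a (gene, value) CSV/TSV into a gene-indexed series."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "gene" not in df.columns or value_column not in df.columns:
        raise NominationError(f"expected columns 'gene' and '{value_column}' in {path}")
    return df.set_index("gene")[value_column]
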