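"""Differential screening of feature matrices between TP53-mutant and WT samples.

Works on sample x feature score matrices — CRISPR dependency (Chronos)
scores, per-feature z-scored protein abundance, or compound-sensitivity
readouts — annotated with a TP53 status per sample.  The core contrast is
mutant versus wild type: per-feature group means, their difference, a Welch
two-sided t-test, and Benjamini-Hochberg q-values, followed by the hit rules
used for genome-wide synthetic-lethality and proteome-wide enrichment scans:

* dependency hits: ``mean_mut < -0.5`` and ``delta < -0.2``
* proteomic hits:  ``delta > 2`` and ``q < 0.05`` (on z-scored abundance)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TP53_STATUSES = ("WT", "missense", "truncating", "other")
#: statuses counted as "mutant" in the default mut-vs-WT contrast
DEFAULT_MUTANT_DEF = ("missense", "truncating", "other")

VALUE_KINDS = ("dependency", "abundance_z", "sensitivity")

DEPENDENCY_MEAN_MUT_MAX = -0.5
DEPENDENCY_DELTA_MAX = -0.2
PROTEOMIC_DELTA_MIN = 2.0
PROTEOMIC_Q_MAX = 0.05


class ScreenError(ValueError):
    pass


@dataclass
class SampleAnnotation:
    """Per-sample TP53 status with a closed vocabulary."""

    table: pd.DataFrame  # columns: sample_id, tp53_status

    def __post_init__(self) -> None:
        t = self.table
        if not {"sample_id", "tp53_status"}.issubset(t.columns):
            raise ScreenError("annotation needs sample_id and tp53_status columns")
        if t["sample_id"].duplicated().any():
            raise ScreenError("duplicate sample_ids in annotation")
        bad = set(t["tp53_status"]) - set(TP53_STATUSES)
        if bad:
            raise ScreenError(f"unknown tp53_status values: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_mapping(cls, status_by_sample: dict) -> "SampleAnnotation":
        return cls(
            pd.DataFrame(
                {
                    "sample_id": list(status_by_sample),
                    "tp53_status": list(status_by_sample.values()),
                }
            )
        )

    def status_for(self, sample_ids: Sequence[str]) -> pd.Series:
        s = self.table.set_index("sample_id")["tp53_status"]
        missing = [x for x in sample_ids if x not in s.index]
        if missing:
            raise ScreenError(f"samples missing from annotation: {missing[:5]}...")
        return s.loc[list(sample_ids)]


@dataclass
class ScoreMatrix:
    """Samples x features real matrix; NaN marks missing entries."""

    values: pd.DataFrame  # index = sample_id, columns = feature ids
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ScreenError(f"value_kind must be one of {VALUE_KINDS}")
        if self.values.index.duplicated().any():
            raise ScreenError("duplicate sample ids in matrix")

    @property
    def samples(self) -> list:
        return list(self.values.index)

    @property
    def features(self) -> list:
        return list(self.values.columns)


def _group_masks(
    matrix: ScoreMatrix,
    annotation: SampleAnnotation,
    mutant_def: Iterable[str],
) -> tuple[np.ndarray, np.ndarray]:
    mutant_def = tuple(mutant_def)
    if not mutant_def:
        raise ScreenError("mutant_def must be non-empty")
    bad = set(mutant_def) - (set(TP53_STATUSES) - {"WT"})
    if bad:
        raise ScreenError(f"invalid mutant_def statuses: {sorted(bad)}")
    status = annotation.status_for(matrix.samples)
    mut = status.isin(mutant_def).to_numpy()
    wt = (status == "WT").to_numpy()
    if not wt.any():
        raise ScreenError("no WT samples in the matrix")
    if not mut.any():
        raise ScreenError("no mutant samples in the matrix for the given mutant_def")
    return mut, wt


def group_means(
    matrix: ScoreMatrix,
    annotation: SampleAnnotation,
    mutant_def: Iterable[str] = DEFAULT_MUTANT_DEF,
) -> pd.DataFrame:
    """Per-feature mutant/WT means over non-missing values, and their difference.

    Returns a feature-indexed frame with columns mean_mut, mean_wt, delta
    (= mean_mut - mean_wt), n_mut, n_wt.  Features with an empty group get
    NaN means, never an imputed zero.
    """
    mut, wt = _group_masks(matrix, annotation, mutant_def)
    vals = matrix.values.to_numpy(dtype=float)
    out = {}
    for name, mask in (("mut", mut), ("wt", wt)):
        sub = vals[mask]
        n = np.sum(~np.isnan(sub), axis=0)
        mean = np.nansum(sub, axis=0) / np.maximum(n, 1)
        out[f"mean_{name}"] = np.where(n > 0, mean, np.nan)
        out[f"n_{name}"] = n
    df = pd.DataFrame(out, index=matrix.values.columns)
    df["delta"] = df["mean_mut"] - df["mean_wt"]
    return df[["mean_mut", "mean_wt", "delta", "n_mut", "n_wt"]]


def differential_test(
    matrix: ScoreMatrix,
    annotation: SampleAnnotation,
    mutant_def: Iterable[str] = DEFAULT_MUTANT_DEF,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Welch (default) two-sided t-test per feature, with BH q-values.

    Features with fewer than two non-missing observations in either group,
    or zero variance in both groups, get NaN p/q and are excluded from the
    multiplicity adjustment.  q-values are Benjamini-Hochberg across all
    tested features.
    """
    rows = group_means(matrix, annotation, mutant_def)
    mut, wt = _group_masks(matrix, annotation, mutant_def)
    vals = matrix.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(
            vals[mut], vals[wt], axis=0, equal_var=equal_var, nan_policy="omit"
        )
        pvals = np.asarray(res.pvalue, dtype=float)
    testable = (rows["n_mut"].to_numpy() >= 2) & (rows["n_wt"].to_numpy() >= 2)
    pvals = np.where(testable, pvals, np.nan)
    qvals = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    rows = rows.copy()
    rows["p_value"] = pvals
    rows["q_value"] = qvals
    return rows


def dependency_hits(
    rows: pd.DataFrame,
    mut_thresh: float = DEPENDENCY_MEAN_MUT_MAX,
    delta_thresh: float = DEPENDENCY_DELTA_MAX,
) -> list:
    """Synthetic-lethal candidates: strongly essential in mutants and more so than WT.

    A feature is a hit when ``mean_mut < mut_thresh`` and
    ``delta < delta_thresh`` (both strictly).  Returns feature ids sorted by
    delta ascending (strongest differential essentiality first).  An empty
    list is a valid outcome — on real TP53 panels it is the observed one.
    """
    hit = (rows["mean_mut"] < mut_thresh) & (rows["delta"] < delta_thresh)
    return list(rows.index[hit][rows.loc[hit, "delta"].argsort(kind="stable")])


def proteomic_screen(
    matrix: ScoreMatrix,
    annotation: SampleAnnotation,
    mutant_def: Iterable[str] = DEFAULT_MUTANT_DEF,
    delta_thresh: float = PROTEOMIC_DELTA_MIN,
    q_thresh: float = PROTEOMIC_Q_MAX,
    feature_subset: Iterable | None = None,
) -> tuple[pd.DataFrame, list]:
    """Proteome-wide enrichment scan on z-scored abundance.

    Runs the Welch test per protein and returns ``(rows, hits)`` where hits
    satisfy ``delta > delta_thresh`` and ``q < q_thresh``, sorted by delta
    descending.  ``feature_subset`` (e.g. a surface-protein list) restricts
    testing — and the multiplicity adjustment — to those features.
    """
    if matrix.value_kind != "abundance_z":
        raise ScreenError("proteomic_screen requires an abundance_z matrix")
    if feature_subset is not None:
        keep = [f for f in matrix.features if f in set(feature_subset)]
        matrix = ScoreMatrix(matrix.values[keep], matrix.value_kind)
    rows = differential_test(matrix, annotation, mutant_def)
    hit = (rows["delta"] > delta_thresh) & (rows["q_value"] < q_thresh)
    hit &= rows["q_value"].notna()
    hits = list(rows.index[hit][(-rows.loc[hit, "delta"]).argsort(kind="stable")])
    return rows, hits


# ---------------------------------------------------------------------------
# I/O helpers (CSV/TSV in the documented shapes)

def read_annotation(path) -> SampleAnnotation:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return SampleAnnotation(pd.read_csv(path, sep=sep))


def read_matrix(path, value_kind: str, features_in_rows: bool = False) -> ScoreMatrix:
    """Read a score matrix; first column is the row identifier.

    By default rows are samples and columns features; pass
    ``features_in_rows=True`` for the transposed layout.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if features_in_rows:
        df = df.T
    return ScoreMatrix(df, value_kind)
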