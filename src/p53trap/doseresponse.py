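"""Dose-response quantification: vehicle normalization, 4PL fits, Emax, ddCt.

Conventions used across the assay readouts:

* competition / viability readouts are normalized to the mean vehicle
  (DMSO, dose 0) response; NanoBiT luminescence is reported as fold over
  vehicle;
* potency is summarized by a four-parameter logistic (4PL) fit on log dose,
  ``response = bottom + (top - bottom) / (1 + (dose/ec50)^hill)``;
* Emax for a competition assay is the LOWEST per-dose mean fraction of
  marker-positive cells observed at any tested dose, and for NanoBiT the
  HIGHEST vehicle-normalized signal — observed extrema, not fit asymptotes;
* qPCR relative expression uses 2^-ddCt against a reference gene and a
  calibrator condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

READOUT_KINDS = ("competition_fraction", "viability", "nanobit")


class DoseResponseError(ValueError):
    pass


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    if not {"dose", "response"}.issubset(table.columns):
        raise DoseResponseError("table needs 'dose' and 'response' columns")
    if (table["dose"] < 0).any():
        raise DoseResponseError("doses must be >= 0 (0 = vehicle)")
    return table


def normalize_to_vehicle(table: pd.DataFrame) -> pd.DataFrame:
    """Divide every response by the mean dose-0 (vehicle) response.

    Vehicle rows are retained (value ~1).  Raises when the table has no
    vehicle rows or their mean response is zero.
    """
    table = _validate(table)
    vehicle = table.loc[table["dose"] == 0, "response"]
    if vehicle.empty:
        raise DoseResponseError("no vehicle (dose 0) rows to normalize against")
    baseline = vehicle.mean()
    if baseline == 0:
        raise DoseResponseError("vehicle mean response is zero")
    out = table.copy()
    out["response"] = out["response"] / baseline
    return out


def dose_means(table: pd.DataFrame, include_vehicle: bool = False,
               agg: str = "mean") -> pd.Series:
    """Per-dose aggregated response (replicates collapsed), dose-ascending."""
    table = _validate(table)
    if not include_vehicle:
        table = table[table["dose"] > 0]
    if table.empty:
        raise DoseResponseError("no dosed observations")
    return table.groupby("dose")["response"].agg(agg).sort_index()


def four_pl(dose, ec50, hill, top, bottom):
    """4PL response; by convention top is the low-dose asymptote when hill > 0."""
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


@dataclass(frozen=True)
class FitResult:
    """4PL fit summary; ``ec50`` is None when the fit did not converge."""

    ec50: float | None
    hill: float | None
    top: float | None
    bottom: float | None
    converged: bool
    residual_sd: float | None

    @property
    def emax(self) -> float | None:
        """Fitted high-dose asymptote (the extremum the curve approaches)."""
        if not self.converged:
            return None
        return self.bottom if self.hill > 0 else self.top


def fit_4pl(table: pd.DataFrame, agg: str = "mean") -> FitResult:
    """Least-squares 4PL fit of response versus dose.

    Replicates are kept as individual residuals; initialization uses
    per-dose aggregates (``agg``): top/bottom from the extreme-dose means,
    ec50 from the dose whose mean is nearest mid-response.  ec50 is bounded
    within [min_dose/100, max_dose*100].  A flat table (response range
    indistinguishable from zero) returns ``converged=False`` with no ec50
    rather than a fabricated potency.
    """
    table = _validate(table)
    dosed = table[table["dose"] > 0]
    doses = dosed["dose"].to_numpy(dtype=float)
    resp = dosed["response"].to_numpy(dtype=float)
    if not np.all(np.isfinite(resp)):
        raise DoseResponseError("responses must be finite")
    if np.unique(doses).size < 2:
        raise DoseResponseError("need >= 2 distinct nonzero doses to fit")

    means = dose_means(dosed)
    lo_mean, hi_mean = means.iloc[0], means.iloc[-1]
    span = float(means.max() - means.min())
    scale = max(abs(resp).max(), 1e-30)
    if span <= 1e-9 * scale:  # flat: no dose effect to summarize
        return FitResult(None, None, None, None, False, float(np.std(resp)))

    mid = (means.max() + means.min()) / 2.0
    ec50_0 = float(means.index[np.argmin(np.abs(means.to_numpy() - mid))])
    p0 = [math.log10(ec50_0), 1.0, float(lo_mean), float(hi_mean)]
    lo_b = [math.log10(doses.min()) - 2.0, -10.0, -np.inf, -np.inf]
    hi_b = [math.log10(doses.max()) + 2.0, 10.0, np.inf, np.inf]

    def model(d, log_ec50, hill, top, bottom):
        return four_pl(d, 10.0 ** log_ec50, hill, top, bottom)

    try:
        popt, _ = curve_fit(model, doses, resp, p0=p0, bounds=(lo_b, hi_b),
                            maxfev=20000)
    except (RuntimeError, ValueError):
        return FitResult(None, None, None, None, False, float(np.std(resp)))
    log_ec50, hill, top, bottom = popt
    if hill == 0 or abs(top - bottom) <= 1e-9 * scale:
        return FitResult(None, None, None, None, False, float(np.std(resp)))
    # orientation normalization: report bottom <= top, encode direction in hill
    if top < bottom:
        top, bottom, hill = bottom, top, -hill
    resid = resp - four_pl(doses, 10.0 ** log_ec50, hill, top, bottom)
    dof = max(len(resp) - 4, 1)
    return FitResult(
        ec50=float(10.0 ** log_ec50),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        converged=True,
        residual_sd=float(np.sqrt(np.sum(resid ** 2) / dof)),
    )


def emax_competition(table: pd.DataFrame, agg: str = "mean") -> float:
    """Lowest per-dose mean response at any tested dose (vehicle excluded).

    For a competition assay reporting % marker-positive cells, this is the
    deepest depletion actually observed.
    """
    return float(dose_means(table, agg=agg).min())


def emax_nanobit(table: pd.DataFrame, agg: str = "mean") -> float:
    """Highest per-dose mean vehicle-normalized signal at any tested dose.

    For a split-luciferase proximity assay, the strongest ternary-complex
    signal actually observed.
    """
    return float(dose_means(table, agg=agg).max())


@dataclass(frozen=True)
class DdCtResult:
    relative_expression: float
    dct_sample: float
    dct_calibrator: float


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> DdCtResult:
    """2^-ddCt relative expression.

    dCt = Ct(target) - Ct(reference) per condition; ddCt = dCt(sample) -
    dCt(calibrator); relative expression = 2^-ddCt.  One cycle fewer to
    threshold means twice the transcript.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise DoseResponseError("Ct values must be finite")
    dct_sample = ct_target_sample - ct_ref_sample
    dct_cal = ct_target_calibrator - ct_ref_calibrator
    return DdCtResult(
        relative_expression=2.0 ** -(dct_sample - dct_cal),
        dct_sample=dct_sample,
        dct_calibrator=dct_cal,
    )


def read_dose_response(path) -> pd.DataFrame:
    """Read a (dose, response, replicate[, readout_kind]) CSV/TSV."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return _validate(pd.read_csv(path, sep=sep))
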