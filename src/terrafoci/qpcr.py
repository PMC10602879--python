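"""ΔCt relative quantification and primer-efficiency standard curves.

For each sample, ΔCT = mean(target Ct) − mean(housekeeping Ct) and the
relative expression is 2^−ΔCT. Two error-propagation modes are provided for
the relative-expression error *i* given the ΔCT error
e = sqrt(sd_target² + sd_housekeeping²):

* ``corrected`` (default): first-order propagation, i = ln(2) · e · 2^−ΔCT.
* ``legacy``: i = e · 2^−ΔCT / ΔCT, a historically used form that is
  singular at ΔCT = 0; requesting it there raises.

Primer efficiency comes from a dilution-series standard curve: the
least-squares slope of Ct against log10(dilution) gives
E(%) = (10^(−1/slope) − 1) × 100, so a slope of −3.3219 (= −1/log10 2, perfect
doubling) gives exactly 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EfficiencyResult",
    "ExpressionResult",
    "primer_efficiency",
    "delta_ct",
    "rel_expression",
    "fold_change",
    "quantify_table",
]


@dataclass(frozen=True)
class EfficiencyResult:
    primer: str
    slope: float
    r_squared: float
    e_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must be in [0, 1]")


@dataclass(frozen=True)
class ExpressionResult:
    sample: str
    primer: str
    delta_ct: float
    e: float                      # ΔCT error
    rel_expr: float               # 2^-ΔCT
    i: float | None               # rel_expr error (None when undefined)
    error_mode: str
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if self.rel_expr <= 0:
            raise ValueError("rel_expr must be > 0")
        if self.e < 0:
            raise ValueError("e must be >= 0")
        if self.i is not None and self.i < 0:
            raise ValueError("i must be >= 0")


def primer_efficiency(
    dilution_series: list[tuple[float, float]] | np.ndarray,
    primer: str = "",
) -> EfficiencyResult:
    """Efficiency from (log10 dilution, Ct) pairs of a standard curve."""
    pts = np.asarray(dilution_series, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (log10 dilution, Ct) points")
    log_dil, ct = pts[:, 0], pts[:, 1]
    res = stats.linregress(log_dil, ct)
    slope = float(res.slope)
    if abs(slope) < 1e-12:
        raise ValueError("zero slope: Ct does not depend on dilution")
    e_percent = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return EfficiencyResult(primer=primer, slope=slope,
                            r_squared=float(res.rvalue**2), e_percent=float(e_percent))


def delta_ct(
    target_cts: list[float] | np.ndarray,
    housekeeping_cts: list[float] | np.ndarray | list[list[float]],
) -> tuple[float, float]:
    """ΔCT and its error from replicate Ct values.

    ``housekeeping_cts`` may be one replicate list or several (one per
    housekeeping primer); with several, the mean of the per-primer Ct means
    is used and their sds are pooled quadratically. The error is
    e = sqrt(sd_target² + sd_housekeeping²) with sample (ddof=1) sds.
    """
    tgt = np.asarray(target_cts, dtype=float)
    if tgt.ndim != 1 or tgt.size < 2:
        raise ValueError("need >= 2 target replicates")
    hk = housekeeping_cts
    if np.ndim(hk) == 1:
        hk_lists = [np.asarray(hk, dtype=float)]
    else:
        hk_lists = [np.asarray(h, dtype=float) for h in hk]
    for h in hk_lists:
        if h.size < 2:
            raise ValueError("need >= 2 housekeeping replicates")
    hk_mean = float(np.mean([h.mean() for h in hk_lists]))
    hk_var = float(np.mean([h.std(ddof=1) ** 2 for h in hk_lists]))
    dct = float(tgt.mean() - hk_mean)
    e = math.sqrt(tgt.std(ddof=1) ** 2 + hk_var)
    return dct, e


def rel_expression(dct: float, e: float, error_mode: str = "corrected") -> tuple[float, float | None]:
    """Relative expression 2^−ΔCT and its propagated error.

    ``corrected``: i = ln(2) · e · 2^−ΔCT. ``legacy``: i = e · 2^−ΔCT / ΔCT,
    which is singular at ΔCT = 0 and raises there.
    """
    rel = 2.0 ** (-dct)
    if error_mode == "corrected":
        return rel, math.log(2.0) * e * rel
    if error_mode == "legacy":
        if dct == 0:
            raise ZeroDivisionError("legacy error formula is singular at dCT = 0")
        return rel, abs(e * rel / dct)
    raise ValueError("error_mode must be 'corrected' or 'legacy'")


def fold_change(results: list[ExpressionResult], reference: str) -> list[ExpressionResult]:
    """Fold change of each sample's relative expression over the reference sample.

    Computed per primer; the reference's own fold change is exactly 1.
    """
    from dataclasses import replace

    ref_by_primer = {r.primer: r.rel_expr for r in results if r.sample == reference}
    out = []
    for r in results:
        if r.primer not in ref_by_primer:
            raise ValueError(f"no reference sample {reference!r} for primer {r.primer!r}")
        ref = ref_by_primer[r.primer]
        if ref <= 0:
            raise ValueError("reference expression must be > 0")
        fc = 1.0 if r.sample == reference else r.rel_expr / ref
        out.append(replace(r, fold_change=fc))
    return out


def quantify_table(
    ct_table: pd.DataFrame,
    reference: str | None = None,
    error_mode: str = "corrected",
) -> list[ExpressionResult]:
    """Run the full ΔCT quantification on a tidy Ct replicate table.

    Expects columns ``sample, primer, role, replicate, ct`` with role
    ``target`` or ``housekeeping``. All housekeeping primers of a sample are
    combined as in :func:`delta_ct`. Fold changes are added when a
    ``reference`` sample is given.
    """
    required = {"sample", "primer", "role", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    results = []
    for (sample, primer), grp in ct_table[ct_table["role"] == "target"].groupby(
            ["sample", "primer"], sort=True):
        hk = ct_table[(ct_table["sample"] == sample) & (ct_table["role"] == "housekeeping")]
        if hk.empty:
            raise ValueError(f"sample {sample!r} has no housekeeping measurements")
        hk_lists = [g["ct"].to_numpy() for _, g in hk.groupby("primer", sort=True)]
        dct, e = delta_ct(grp["ct"].to_numpy(), hk_lists)
        rel, i = rel_expression(dct, e, error_mode)
        results.append(ExpressionResult(sample=str(sample), primer=str(primer),
                                        delta_ct=dct, e=e, rel_expr=rel, i=i,
                                        error_mode=error_mode))
    if reference is not None:
        results = fold_change(results, reference)
    return results


def expression_to_frame(results: list[ExpressionResult]) -> pd.DataFrame:
    """Tabular view of expression results (one row per sample × primer)."""
    return pd.DataFrame([{
        "sample": r.sample, "primer": r.primer, "delta_ct": r.delta_ct, "e": r.e,
        "rel_expr": r.rel_expr, "i": r.i, "error_mode": r.error_mode,
        "fold_change": r.fold_change,
    } for r in results])
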