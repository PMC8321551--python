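"""Normalised fold changes, qPCR quantities, correlations, group tests.

The central quantity is the normalised log2 fold change of mutant versus
control abundance, log2(count_mutant / count_WT), computed after
normalising each library to a reference unaffected by the pathway under
study (miRNA reads or the flamenco uni-strand cluster).  qPCR relative
expression follows the delta-delta-Ct convention with
ddCt = dCt(wild type) - dCt(mutant), so a negative value means lower
expression in the mutant.  Group-level inference uses Welch's t
(pairwise) or one-sample t against zero, with Benjamini-Hochberg FDR
adjustment across all comparisons in a call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counting import CountMatrix, normalize


@dataclass(frozen=True)
class FoldChangeRecord:
    feature: str
    normalized_control: float
    normalized_mutant: float
    pseudocount: float  # the pseudocount actually applied
    log2fc: float | None  # None = undefined (both zero, pseudocount 0)
    percent_of_wt: float | None  # 100 * mutant / control when control > 0


def log2_fold_change(
    control_norm: float, mutant_norm: float, pseudocount: float = 0.5
) -> FoldChangeRecord:
    """log2((mutant + pc) / (control + pc)); the pseudocount is applied
    symmetrically, and only when either value is zero."""
    if control_norm < 0 or mutant_norm < 0 or pseudocount < 0:
        raise ValueError("values and pseudocount must be >= 0")
    pc = pseudocount if (control_norm == 0 or mutant_norm == 0) else 0.0
    num, den = mutant_norm + pc, control_norm + pc
    if num > 0 and den > 0:
        # difference of logs: exactly antisymmetric and safe against
        # quotient underflow at extreme magnitudes
        lfc = float(np.log2(num) - np.log2(den))
    else:
        lfc = None
    pct = 100.0 * mutant_norm / control_norm if control_norm > 0 else None
    return FoldChangeRecord(
        feature="", normalized_control=control_norm, normalized_mutant=mutant_norm,
        pseudocount=pc, log2fc=lfc, percent_of_wt=pct,
    )


def knockdown_panel(
    control: CountMatrix,
    mutant: CountMatrix,
    normalizer: str = "mirna",
    features: list[str] | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Normalised log2 fold changes per feature, for every mutant sample
    against every control sample.

    ``normalizer`` is ``mirna``, ``flamenco`` (per-million-reference) or
    ``rpm`` (total mapped reads).  Returns a tidy frame with one row per
    (feature, control sample, mutant sample).
    """
    if not len(control.samples):
        raise ValueError("missing control sample")
    if normalizer in ("mirna", "flamenco"):
        ctrl = normalize(control, "per_million_reference", normalizer)
        mut = normalize(mutant, "per_million_reference", normalizer)
    elif normalizer == "rpm":
        ctrl = normalize(control, "rpm_total")
        mut = normalize(mutant, "rpm_total")
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if features is None:
        features = [f for f in ctrl.features if f in set(mut.features)]
    rows = []
    for feature in features:
        for cs in ctrl.samples:
            for ms in mut.samples:
                rec = log2_fold_change(
                    float(ctrl.counts.at[feature, cs]),
                    float(mut.counts.at[feature, ms]),
                    pseudocount,
                )
                rows.append(
                    {
                        "feature": feature,
                        "control_sample": cs,
                        "mutant_sample": ms,
                        "normalizer": normalizer,
                        "normalized_control": rec.normalized_control,
                        "normalized_mutant": rec.normalized_mutant,
                        "pseudocount": rec.pseudocount,
                        "log2fc": rec.log2fc,
                        "percent_of_wt": rec.percent_of_wt,
                    }
                )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------- qPCR


@dataclass(frozen=True)
class QpcrResult:
    sample: str
    ct_target: float  # replicate mean
    ct_reference: float  # replicate mean
    delta_ct: float  # ct_target - ct_reference
    relative_quantity: float  # (1 + efficiency) ** (-delta_ct)


def qpcr_quantify(
    ct_target, ct_reference, efficiency: float = 1.0, sample: str = "sample"
) -> QpcrResult:
    """Relative quantity from replicate Ct values.

    dCt is computed from replicate means; relative quantity uses base
    (1 + efficiency), so the default efficiency of 1 gives the familiar
    2^(-dCt)."""
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    ct_t = float(np.mean(np.asarray(ct_target, dtype=float)))
    ct_r = float(np.mean(np.asarray(ct_reference, dtype=float)))
    dct = ct_t - ct_r
    return QpcrResult(sample, ct_t, ct_r, dct, float((1.0 + efficiency) ** (-dct)))


def delta_delta_ct(wild_type: QpcrResult, mutant: QpcrResult) -> float:
    """ddCt = dCt(wild type) - dCt(mutant); negative means lower
    expression in the mutant."""
    return wild_type.delta_ct - mutant.delta_ct


# ---------------------------------------------------------------- correlation


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    p_value: float
    n: int


def correlate(x, y) -> CorrelationResult | None:
    """Pearson correlation with the two-sided t-based p-value (n - 2 df).
    None (undefined) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r, r * r, float(res.pvalue), x.size)


# -------------------------------------------------------------- group testing


@dataclass(frozen=True)
class TestResult:
    comparison: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float | None  # filled by BH across the call


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def group_ttests(
    groups: dict[str, np.ndarray | list[float]],
    mode: str = "pairwise",
    mu: float = 0.0,
) -> list[TestResult]:
    """Pairwise Welch t-tests between groups, or one-sample t-tests of
    each group against ``mu``; two-sided p-values with BH adjustment
    across all comparisons in the call.  Groups of size < 2 are skipped
    with a warning."""
    if mode not in ("pairwise", "one_sample"):
        raise ValueError(f"unknown mode {mode!r}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    small = [k for k, v in arrays.items() if v.size < 2]
    for k in small:
        warnings.warn(f"group {k!r} has fewer than 2 values; skipped")
        del arrays[k]
    results: list[TestResult] = []
    if mode == "one_sample":
        for name, values in arrays.items():
            if values.std(ddof=1) == 0:  # degenerate: no sampling variance
                equal = values.mean() == mu
                stat, p = (0.0, 1.0) if equal else (np.sign(values.mean() - mu) * np.inf, 0.0)
            else:
                res = stats.ttest_1samp(values, popmean=mu)
                stat, p = float(res.statistic), float(res.pvalue)
            results.append(
                TestResult(f"{name} vs mu={mu:g}", stat, float(values.size - 1), p, None)
            )
    else:
        for a, b in combinations(arrays, 2):
            x, y = arrays[a], arrays[b]
            if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
                equal = x.mean() == y.mean()
                stat, p = (0.0, 1.0) if equal else (np.sign(x.mean() - y.mean()) * np.inf, 0.0)
                df = float(x.size + y.size - 2)
            else:
                res = stats.ttest_ind(x, y, equal_var=False)
                stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
            results.append(TestResult(f"{a} vs {b}", stat, df, p, None))
    if results:
        adjusted = benjamini_hochberg([r.p_raw for r in results])
        results = [
            TestResult(r.comparison, r.statistic, r.df, r.p_raw, float(p))
            for r, p in zip(results, adjusted)
        ]
    return results
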