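"""Differential screen: detection filter, 2^-ddCt fold changes, testing,
Benjamini-Hochberg adjustment, and the cross-platform double-positive rule.

A miRNA counts as *detected* where its aliquot-mean Cq is at or below the
detection ceiling (Cq <= 35, inclusive) in at least one strain.  The
2^-ddCt estimator converts the case-minus-control difference of mean
normalized Cq (ddCq) into a linear fold change, reported in the signed
convention: ratio r >= 1 is written +r (upregulated), r < 1 as -1/r
(downregulated), so |FC| >= 1 always and FC = +1 means no change.

Significance per (miRNA, strain) uses a two-sided two-sample t-test on
the per-aliquot normalized values.  The default pools variances: with
three technical aliquots per side drawn from a common noise process the
pooled test is calibrated, whereas the Welch correction is markedly
conservative at n = 3 (its Satterthwaite degrees of freedom are noisy);
Welch remains available via ``equal_var=False``.  P-values are adjusted
with the Benjamini-Hochberg step-up FDR within each (platform, strain)
family of detected assays.

The *double positive* rule declares a miRNA dysregulated in a strain when
|FC| reaches the threshold on both platforms with the same sign and the
validation-platform p-value is at or below alpha; the reported FC and p
are always the validation-platform values.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CqTable, ScreenConfig
from .normalize import NormalizedTable, global_mean_normalize, triplicate_mean

__all__ = [
    "detect_filter",
    "delta_delta_cq",
    "signed_fold_change",
    "per_mirna_test",
    "bh_adjust",
    "screen_platform",
    "double_positive_screen",
    "count_dysregulated",
]

PASS = "pass"
REASONS = ("pass", "fc1_below", "fc2_below", "discordant_sign", "p2_above", "undetected")


def detect_filter(
    table: CqTable, config: ScreenConfig | None = None
) -> tuple[set[str], pd.DataFrame]:
    """Apply the detection ceiling to an aliquot-level table.

    Returns the set of assays detected overall (strain-mean Cq at or
    below the ceiling in at least one strain; the boundary is inclusive)
    and a boolean assay x strain flag frame.  An assay missing in every
    aliquot of a strain is not detected there.
    """
    config = config or ScreenConfig()
    flags = {}
    for strain in table.strains():
        cols = table.samples_of(strain)
        strain_mean = table.values[cols].mean(axis=1, skipna=True)
        flags[strain] = strain_mean.notna() & (strain_mean <= config.detection_cq_max)
    flag_frame = pd.DataFrame(flags)
    detected = set(flag_frame.index[flag_frame.any(axis=1)])
    return detected, flag_frame


def delta_delta_cq(
    norm: NormalizedTable, strain: str, control: str, mirna: str
) -> float:
    """ddCq: mean normalized Cq of the case strain minus the control's.

    Negative values mean upregulation (fewer cycles = more transcript).
    Referent-scheme tables hold log2 abundances (sign flipped relative to
    Cq); their case-minus-control difference is negated so that ddCq is
    always on the Cq orientation and 2^-ddCq is always the fold change.
    If either side has no non-missing aliquot the result is NaN — an
    explicit undetermined flag, never silently zero.
    """
    case_vals = norm.values.loc[mirna, norm.samples_of(strain)].astype(float)
    ctrl_vals = norm.values.loc[mirna, norm.samples_of(control)].astype(float)
    if case_vals.notna().sum() == 0 or ctrl_vals.notna().sum() == 0:
        return math.nan
    diff = float(case_vals.mean(skipna=True) - ctrl_vals.mean(skipna=True))
    return -diff if norm.scheme == "referent" else diff


def signed_fold_change(ddcq: float) -> float:
    """2^-ddCt in the signed convention: +r for r >= 1, else -1/r.

    NaN propagates (undetermined ddCq stays undetermined).
    """
    if math.isnan(ddcq):
        return math.nan
    r = 2.0 ** (-ddcq)
    return r if r >= 1.0 else -1.0 / r


def per_mirna_test(
    norm: NormalizedTable, strain: str, control: str, mirna: str,
    equal_var: bool = True,
) -> float:
    """Two-sided two-sample t-test p-value on per-aliquot normalized values.

    The default pools variances: the two sides are technical aliquots of
    the same measurement process, and at n = 3 per side the pooled test
    holds its nominal level while the Welch correction under-rejects
    (pass ``equal_var=False`` for Welch when heteroscedasticity is a real
    concern).  Requires at least two non-missing aliquots per side (NaN
    otherwise).  Degenerate zero-variance inputs resolve to p = 1 when
    the group means are equal and p = 0 when they differ (the limit of
    the t statistic).
    """
    case = norm.values.loc[mirna, norm.samples_of(strain)].astype(float).dropna().to_numpy()
    ctrl = norm.values.loc[mirna, norm.samples_of(control)].astype(float).dropna().to_numpy()
    if len(case) < 2 or len(ctrl) < 2:
        return math.nan
    if case.var(ddof=1) == 0.0 and ctrl.var(ddof=1) == 0.0:
        return 1.0 if case.mean() == ctrl.mean() else 0.0
    res = stats.ttest_ind(case, ctrl, equal_var=equal_var)
    return float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    Missing p-values (NaN) pass through as NaN and do not count toward
    the family size.  Out-of-range p-values are a hard error.
    """
    p = np.asarray(list(p_values), dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def screen_platform(
    table: CqTable,
    config: ScreenConfig | None = None,
    *,
    norm: NormalizedTable | None = None,
    collapse_replicates: bool = True,
) -> pd.DataFrame:
    """Run the full per-platform differential screen.

    Pipeline: PCR-triplicate averaging -> detection filter -> global-mean
    normalization -> per (detected miRNA, pathological strain) ddCq,
    signed FC and t-test p -> BH adjustment within each strain family.

    Returns one row per (miRNA, strain) with columns ``mirna_id, strain,
    control_strain, delta_delta_cq, signed_fc, p_value, q_value,
    detected_case, detected_control, n_case, n_control, platform``.
    """
    config = config or ScreenConfig()
    aliquot = triplicate_mean(table) if collapse_replicates else table
    detected, flags = detect_filter(aliquot, config)
    if norm is None:
        norm = global_mean_normalize(aliquot, config)

    patho = [
        s for s in aliquot.strains()
        if any(m.strain == s and m.role == "pathological" for m in aliquot.samples)
    ]
    endo = [m for m in aliquot.panel.endogenous_ids if m in detected]

    rows: list[dict] = []
    for strain in patho:
        control = aliquot.strain_of_control(strain)
        if not control:
            continue
        for mirna in endo:
            ddcq = delta_delta_cq(norm, strain, control, mirna)
            case_n = int(norm.values.loc[mirna, norm.samples_of(strain)].notna().sum())
            ctrl_n = int(norm.values.loc[mirna, norm.samples_of(control)].notna().sum())
            rows.append(
                {
                    "mirna_id": mirna,
                    "strain": strain,
                    "control_strain": control,
                    "delta_delta_cq": ddcq,
                    "signed_fc": signed_fold_change(ddcq),
                    "p_value": per_mirna_test(norm, strain, control, mirna),
                    "detected_case": bool(flags.loc[mirna, strain]),
                    "detected_control": bool(flags.loc[mirna, control]),
                    "n_case": case_n,
                    "n_control": ctrl_n,
                    "platform": aliquot.panel.platform_label,
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        result["q_value"] = pd.Series(dtype=float)
        return result
    # BH within each (platform, strain) family
    result["q_value"] = np.nan
    for strain in result["strain"].unique():
        idx = result.index[result["strain"] == strain]
        result.loc[idx, "q_value"] = bh_adjust(result.loc[idx, "p_value"].to_numpy())
    cols = [
        "mirna_id", "strain", "control_strain", "delta_delta_cq", "signed_fc",
        "p_value", "q_value", "detected_case", "detected_control",
        "n_case", "n_control", "platform",
    ]
    return result[cols]


def double_positive_screen(
    results1: pd.DataFrame,
    results2: pd.DataFrame,
    config: ScreenConfig | None = None,
    *,
    allow_list: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Cross-platform concordance verdicts per (miRNA, strain).

    A call passes when |FC| reaches the threshold on both platforms
    (inclusive), the signs agree, and the platform-2 (validation) p-value
    is at or below alpha.  Reported FC and p are the platform-2 values.
    A (miRNA, strain) pair absent or with undetermined FC on either
    platform fails with reason ``undetected``.

    ``allow_list`` names (miRNA, strain) pairs exempt from the FC
    thresholds (borderline assays of particular interest); sign
    concordance and the p-value criterion still apply, and the exemption
    is recorded in the ``allowed`` column rather than applied silently.
    """
    config = config or ScreenConfig()
    allow = set(allow_list)
    r1 = results1.set_index(["mirna_id", "strain"])
    r2 = results2.set_index(["mirna_id", "strain"])
    keys = sorted(set(r1.index) | set(r2.index))

    rows = []
    for key in keys:
        mirna, strain = key
        fc1 = float(r1.loc[key, "signed_fc"]) if key in r1.index else math.nan
        fc2 = float(r2.loc[key, "signed_fc"]) if key in r2.index else math.nan
        p2 = float(r2.loc[key, "p_value"]) if key in r2.index else math.nan
        allowed = key in allow
        if math.isnan(fc1) or math.isnan(fc2):
            reason = "undetected"
        elif not allowed and abs(fc1) < config.fc_threshold:
            reason = "fc1_below"
        elif not allowed and abs(fc2) < config.fc_threshold:
            reason = "fc2_below"
        elif fc1 * fc2 < 0:
            reason = "discordant_sign"
        elif math.isnan(p2) or p2 > config.alpha:
            reason = "p2_above"
        else:
            reason = PASS
        rows.append(
            {
                "mirna_id": mirna,
                "strain": strain,
                "fc_screen1": fc1,
                "fc_screen2": fc2,
                "p_screen2": p2,
                "pass": reason == PASS,
                "reason": reason,
                "allowed": allowed,
            }
        )
    return pd.DataFrame(rows)


def count_dysregulated(calls: pd.DataFrame, per: str = "strain") -> pd.Series:
    """Count passing miRNAs per strain plus their union across strains.

    ``per="strain"`` gives one count per strain and an ``any_strain``
    union entry (a miRNA passing in several strains counts once there);
    ``per="any_strain"`` returns only the union count.
    """
    passing = calls[calls["pass"]]
    union = passing["mirna_id"].nunique()
    if per == "any_strain":
        return pd.Series({"any_strain": union})
    counts = passing.groupby("strain")["mirna_id"].nunique()
    all_strains = calls["strain"].unique()
    counts = counts.reindex(all_strains, fill_value=0)
    counts.loc["any_strain"] = union
    return counts.astype(int)
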