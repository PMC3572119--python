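"""Individual-level biomarker evaluation: features, ROC curves, AUC.

Two feature schemes are compared for case/control cohorts measured by
RT-qPCR:

* referent-normalized: relative log2 abundance of the target against the
  mean of stable referent assays (miR-29a / miR-30b style);
* ratio-to-reference: the per-subject log2 ratio of the target to a
  single reference miRNA (``cq(reference) - cq(target)``), computed on
  raw Cq.  Because both assays share the subject's RNA input, the ratio
  is exactly invariant to per-subject additive Cq shifts — no
  normalization step is needed.

The empirical ROC enumerates all thresholds (ties collapse into a single
diagonal step) and the AUC is computed two equivalent ways: trapezoidal
area and the normalized Mann-Whitney U statistic (ties at half credit);
the two agree to machine precision, which the test-suite enforces.  The
p-value is the two-sided Wilcoxon-Mann-Whitney rank-sum test, exact for
small tie-free groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .datamodel import CqTable
from .normalize import NormalizedTable, referent_normalize

__all__ = [
    "FeatureVector",
    "RocResult",
    "ratio_to_reference",
    "referent_feature",
    "empirical_roc",
    "auc_rank_test",
    "compare_normalizations",
]


@dataclass
class FeatureVector:
    """Per-subject values of one candidate biomarker feature.

    ``labels`` holds "case"/"control" per subject; missing measurements
    carry an explicit NaN, never a silent drop.
    """

    feature_id: str
    values: pd.Series
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share the same subjects")
        bad = set(self.labels.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"labels must be 'case'/'control', got {sorted(bad)}")

    def complete(self) -> tuple[np.ndarray, np.ndarray]:
        """(case values, control values) with missing entries removed."""
        ok = self.values.notna()
        v = self.values[ok]
        lab = self.labels[ok]
        return v[lab == "case"].to_numpy(float), v[lab == "control"].to_numpy(float)


@dataclass
class RocResult:
    """Empirical ROC with AUC and rank-test p-value for one feature.

    ``auc`` is oriented so that it is at least 0.5; ``auc_raw`` keeps the
    natural "higher value = case" orientation so a discordant marker is
    never silently reported as its mirror image.
    """

    feature_id: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_raw: float
    auc_trapezoid: float
    p_value: float
    n_case: int
    n_control: int
    higher_in_case: bool


def _labels_from_meta(table: CqTable | NormalizedTable) -> pd.Series:
    return pd.Series(
        {s.sample_id: ("case" if s.role == "pathological" else "control") for s in table.samples}
    )


def ratio_to_reference(
    table: CqTable | NormalizedTable, target: str, reference: str
) -> FeatureVector:
    """Per-subject log2 target/reference abundance ratio from raw Cq.

    value(subject) = cq(reference, subject) - cq(target, subject); the
    value is missing whenever either assay did not amplify.  Target and
    reference must differ.
    """
    if target == reference:
        raise ValueError("target and reference must be different assays")
    for m in (target, reference):
        if m not in table.values.index:
            raise ValueError(f"assay {m!r} absent from table")
    if isinstance(table, NormalizedTable) and table.scheme == "referent":
        # values already on the log2-abundance scale (higher = more)
        vals = table.values.loc[target] - table.values.loc[reference]
    else:
        vals = table.values.loc[reference] - table.values.loc[target]
    return FeatureVector(
        feature_id=f"{target}/{reference}",
        values=vals.astype(float),
        labels=_labels_from_meta(table),
    )


def referent_feature(table: CqTable, target: str, referent_ids: list[str]) -> FeatureVector:
    """Relative log2 abundance of ``target`` under referent normalization."""
    norm = referent_normalize(table, referent_ids)
    return FeatureVector(
        feature_id=target,
        values=norm.values.loc[target].astype(float),
        labels=_labels_from_meta(table),
    )


def _auc_pair_counting(case: np.ndarray, control: np.ndarray) -> float:
    """AUC as the normalized U statistic: ties count half."""
    n1, n0 = len(case), len(control)
    allv = np.concatenate([case, control])
    ranks = stats.rankdata(allv)  # midranks -> half credit for ties
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def empirical_roc(feature: FeatureVector) -> RocResult:
    """All-thresholds empirical ROC curve with AUC and rank p-value.

    Requires at least one non-missing case and control.  Tied values form
    a single threshold step, producing a diagonal ROC segment; the
    trapezoidal area then matches the half-credit U statistic exactly.
    """
    case, control = feature.complete()
    if len(case) == 0 or len(control) == 0:
        raise ValueError("need at least one case and one control with values")
    y = np.concatenate([np.ones(len(case)), np.zeros(len(control))])
    scores = np.concatenate([case, control])
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    auc_trap = float(np.trapezoid(tpr, fpr))
    auc_raw = _auc_pair_counting(case, control)
    auc_pv = auc_rank_test(feature)
    higher = auc_raw >= 0.5
    return RocResult(
        feature_id=feature.feature_id,
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc_raw if higher else 1.0 - auc_raw,
        auc_raw=auc_raw,
        auc_trapezoid=auc_trap,
        p_value=auc_pv[1],
        n_case=len(case),
        n_control=len(control),
        higher_in_case=higher,
    )


def auc_rank_test(feature: FeatureVector, exact_max_n: int = 12) -> tuple[float, float]:
    """(raw AUC, two-sided Wilcoxon-Mann-Whitney p-value).

    The exact null distribution is used when both groups have at most
    ``exact_max_n`` subjects and the data are tie-free; the normal
    approximation (tie-corrected) applies otherwise.  Swapping the class
    labels maps AUC to 1 - AUC and leaves p unchanged.
    """
    case, control = feature.complete()
    if len(case) == 0 or len(control) == 0:
        raise ValueError("need at least one case and one control with values")
    auc = _auc_pair_counting(case, control)
    has_ties = len(np.unique(np.concatenate([case, control]))) < len(case) + len(control)
    small = max(len(case), len(control)) <= exact_max_n
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(case, control, alternative="two-sided", method=method)
    return auc, float(res.pvalue)


def compare_normalizations(
    cohort: CqTable,
    targets: list[str],
    referents: list[str],
    ratio_reference: str,
) -> pd.DataFrame:
    """AUC/p of each target under referent vs ratio-to-reference schemes.

    One row per (target, scheme) with the oriented AUC, raw AUC and
    rank-test p-value, ready for a paired scheme comparison.
    """
    rows = []
    for target in targets:
        for scheme, fv in (
            ("referent", referent_feature(cohort, target, referents)),
            ("ratio", ratio_to_reference(cohort, target, ratio_reference)),
        ):
            roc = empirical_roc(fv)
            rows.append(
                {
                    "target": target,
                    "scheme": scheme,
                    "feature_id": fv.feature_id,
                    "auc": roc.auc,
                    "auc_raw": roc.auc_raw,
                    "p_value": roc.p_value,
                    "n_case": roc.n_case,
                    "n_control": roc.n_control,
                }
            )
    return pd.DataFrame(rows)
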