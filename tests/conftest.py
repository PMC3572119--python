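"""Shared fixtures: small hand-built Cq tables and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirscreen import AssayPanel, CqTable, SampleMeta, ScreenConfig


def build_table(
    values: dict[str, list[float]],
    mirnas: list[str],
    meta: list[dict],
    *,
    spike_in_ids: tuple[str, ...] = (),
    referent_ids: tuple[str, ...] = (),
    platform_label: str = "A",
) -> CqTable:
    """Construct a CqTable from plain dicts (columns = sample -> values)."""
    samples = tuple(SampleMeta(**m) for m in meta)
    df = pd.DataFrame(values, index=mirnas).astype(float)
    panel = AssayPanel(
        mirna_ids=tuple(mirnas),
        spike_in_ids=spike_in_ids,
        referent_ids=referent_ids,
        platform_label=platform_label,
    )
    return CqTable(panel=panel, samples=samples, values=df)


def pooled_meta(strain: str, n_aliquots: int = 3, role: str = "control",
                control_strain: str = "") -> list[dict]:
    """Aliquot-level metadata rows for one pooled strain."""
    return [
        {
            "sample_id": f"{strain}:a{a}",
            "strain": strain,
            "role": role,
            "control_strain": control_strain,
            "aliquot_index": a,
        }
        for a in range(1, n_aliquots + 1)
    ]


@pytest.fixture
def config() -> ScreenConfig:
    return ScreenConfig()


# ---------------------------------------------------------------------------
# independent oracles (never call package code)
# ---------------------------------------------------------------------------


def bh_stepup_brute(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg: sort, step-up, cumulative minimum."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    # step-up: enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def auc_pair_brute(case: np.ndarray, control: np.ndarray) -> float:
    """Exhaustive pair counting: wins count 1, ties 1/2."""
    wins = 0.0
    for c in case:
        for k in control:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(case) * len(control))
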