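"""Cq normalization: global-mean corrected Cq, stable-referent scheme, QC.

Two schemes are provided.

Global mean (large-scale screens).  Per sample, the normalizer is the
mean raw Cq over the *expressed set* — the assays detected (Cq at or
below the ceiling) in every sample, so each sample averages the same gene
set.  The corrected Cq is

    corrected(m, s) = cq(m, s) - normalizer(s) + grand_normalizer

where grand_normalizer is the mean of the per-sample normalizers.  By
construction the per-sample mean of corrected Cq over the expressed set
is the same constant for every sample, and any additive per-sample shift
(RNA input variation) cancels exactly.

Stable referents (individual assays).  Relative log2 abundance is

    abundance(m, s) = mean_referent_cq(s) - cq(m, s)

with the arithmetic mean of the referents' Cq (equivalently the geometric
mean of their linear abundances).  Higher abundance = more transcript.

Both operate on aliquot-level tables: PCR triplicates are first collapsed
with :func:`triplicate_mean`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import AssayPanel, CqTable, SampleMeta, ScreenConfig

__all__ = [
    "NormalizedTable",
    "QcReport",
    "triplicate_mean",
    "global_mean_normalize",
    "referent_normalize",
    "spike_in_qc",
]


@dataclass
class NormalizedTable:
    """A normalized miRNA x sample matrix plus the normalizers used.

    ``scheme`` is ``"global_mean"`` (values are corrected Cq; lower =
    more abundant) or ``"referent"`` (values are relative log2 abundance;
    higher = more abundant).
    """

    values: pd.DataFrame
    scheme: str
    normalizer_per_sample: pd.Series
    grand_normalizer: float
    samples: tuple[SampleMeta, ...]
    panel: AssayPanel
    expressed_set: tuple[str, ...] = ()

    def samples_of(self, strain: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.strain == strain]

    def strains(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.strain, None)
        return list(seen)

    def strain_of_control(self, strain: str) -> str:
        for s in self.samples:
            if s.strain == strain and s.control_strain:
                return s.control_strain
        return ""


@dataclass
class QcReport:
    """Spike-in recovery check: per-sample deviation from each spike-in's
    cross-sample median Cq, with a pass/fail verdict per sample."""

    deviations: pd.DataFrame  # spike_in x sample, cycles
    tolerance: float
    sample_pass: pd.Series  # sample -> bool
    findings: list[str]


def triplicate_mean(table: CqTable) -> CqTable:
    """Collapse PCR replicates to one Cq per (assay, strain, aliquot).

    The mean ignores missing replicates; a cell is missing only when all
    of its replicates failed to amplify.  Applying the operation to an
    already-collapsed table is the identity (idempotent).
    """
    groups: dict[tuple[str, int], list[str]] = {}
    templates: dict[tuple[str, int], SampleMeta] = {}
    for s in table.samples:
        key = (s.strain, s.aliquot_index)
        groups.setdefault(key, []).append(s.sample_id)
        templates.setdefault(key, s)

    columns: dict[str, pd.Series] = {}
    samples: list[SampleMeta] = []
    for key, sids in groups.items():
        strain, aliquot = key
        new_id = f"{strain}:a{aliquot}"
        columns[new_id] = table.values[sids].mean(axis=1, skipna=True)
        t = templates[key]
        samples.append(
            SampleMeta(
                sample_id=new_id,
                strain=strain,
                role=t.role,
                control_strain=t.control_strain,
                aliquot_index=aliquot,
                pcr_replicate_index=1,
                subject_level=t.subject_level,
            )
        )
    values = pd.DataFrame(columns, index=table.values.index)
    return CqTable(panel=table.panel, samples=tuple(samples), values=values)


def global_mean_normalize(table: CqTable, config: ScreenConfig | None = None) -> NormalizedTable:
    """Global-mean normalization to corrected Cq (see module docstring).

    The expressed set is the endogenous assays (spike-ins excluded)
    detected in *all* samples; assays outside it still receive corrected
    values through their sample's normalizer.  Raises if the expressed
    set is empty.
    """
    config = config or ScreenConfig()
    vals = table.values.loc[list(table.panel.endogenous_ids)]
    detected_everywhere = (vals.notna() & (vals <= config.detection_cq_max)).all(axis=1)
    expressed = list(vals.index[detected_everywhere])
    if not expressed:
        raise ValueError("expressed set is empty: no assay detected in all samples")

    normalizer = table.values.loc[expressed].mean(axis=0)
    grand = float(normalizer.mean())
    corrected = table.values.sub(normalizer, axis=1) + grand
    return NormalizedTable(
        values=corrected,
        scheme="global_mean",
        normalizer_per_sample=normalizer,
        grand_normalizer=grand,
        samples=table.samples,
        panel=table.panel,
        expressed_set=tuple(expressed),
    )


def referent_normalize(table: CqTable, referent_ids: list[str] | tuple[str, ...]) -> NormalizedTable:
    """Relative log2 abundance against the mean of stable referent assays.

    Every referent must be present and non-missing in every sample; the
    error names the offending sample and referent.
    """
    referent_ids = list(referent_ids)
    if not referent_ids:
        raise ValueError("at least one referent id is required")
    for ref in referent_ids:
        if ref not in table.values.index:
            raise ValueError(f"referent {ref!r} absent from panel")
        missing = table.values.loc[ref].isna()
        if missing.any():
            sample = missing.idxmax()
            raise ValueError(f"referent {ref!r} not detected in sample {sample!r}")

    mean_ref = table.values.loc[referent_ids].mean(axis=0)
    abundance = (-table.values).add(mean_ref, axis=1)
    return NormalizedTable(
        values=abundance,
        scheme="referent",
        normalizer_per_sample=mean_ref,
        grand_normalizer=float(mean_ref.mean()),
        samples=table.samples,
        panel=table.panel,
    )


def spike_in_qc(table: CqTable, tolerance: float = 1.5) -> QcReport:
    """Check exogenous spike-in recovery consistency across samples.

    For each declared spike-in, the deviation of each sample's Cq from the
    spike-in's cross-sample median is computed; a sample fails when any
    spike-in deviates by more than ``tolerance`` cycles (or did not
    amplify at all, which is also reported).
    """
    spikes = list(table.panel.spike_in_ids)
    if not spikes:
        raise ValueError("panel declares no spike-in assays")
    sub = table.values.loc[spikes]
    medians = sub.median(axis=1, skipna=True)
    deviations = sub.sub(medians, axis=0)

    findings: list[str] = []
    fail = pd.Series(False, index=sub.columns)
    for spike in spikes:
        dev = deviations.loc[spike]
        missing = sub.loc[spike].isna()
        for sid in sub.columns[missing]:
            findings.append(f"spike-in {spike!r} did not amplify in sample {sid!r}")
        fail |= missing | (dev.abs() > tolerance)
    for sid in sub.columns[fail]:
        findings.append(f"sample {sid!r} fails spike-in QC at tolerance {tolerance} cycles")
    return QcReport(
        deviations=deviations,
        tolerance=tolerance,
        sample_pass=~fail,
        findings=findings,
    )
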