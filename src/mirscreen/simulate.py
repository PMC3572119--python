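"""Synthetic Cq-screen generator with known ground truth.

Emulates the pooled-serum two-platform RT-qPCR design: per-strain serum
pools split into three aliquots, PCR triplicates per aliquot, per-miRNA
disease effects injected as log2 fold changes versus a control strain,
per-miRNA offsets shared by all strains of a genetic-background group,
per-miRNA per-platform additive offsets, Gaussian replicate noise on the
Cq scale, and a hard detection ceiling (Cq above the ceiling is censored
to missing).

Model (all terms in cycles; one cycle = one log2 unit of abundance):

    Cq(m, strain, aliquot, rep) = base(m) + bg(m, group(strain))
                                + platform(m) - log2FC(m, strain)
                                + e_aliquot + e_rep

An injected upregulation of log2FC = +2 therefore lowers the case Cq by
exactly 2 cycles relative to its control, the analytic identity the
2^-ddCt fold-change estimator inverts.  Spike-in assays are constant
abundance with replicate noise only; referent assays receive no strain or
background effects, which is what "most stable miRNA" means here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AssayPanel, CqTable, SampleMeta

__all__ = [
    "StrainSpec",
    "SimulationSpec",
    "SimulatedTruth",
    "simulate_screen",
    "simulate_two_platform_screens",
    "simulate_patient_cohort",
]

DEFAULT_REFERENTS = ("mmu-miR-29a", "mmu-miR-30b")
DEFAULT_SPIKE_INS = ("cel-miR-39",)


@dataclass(frozen=True)
class StrainSpec:
    """One strain in the design: name, genetic-background group, role."""

    name: str
    background_group: str
    role: str = "control"  # "pathological" | "control"
    control_strain: str = ""


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated pooled-serum screen.

    ``injected_log2fc`` maps ``(mirna, strain)`` to the true log2 fold
    change of that miRNA in that pathological strain versus its control;
    ``mirna`` may be a generated assay id (``"sim-miR-007"``) or an
    integer index into the simulated panel.  Standard deviations are in
    cycles.  ``aliquot_sd`` defaults to ``replicate_sd`` (the design
    cannot separate the two sources, so they default equal).
    """

    n_mirnas: int
    strains: tuple[StrainSpec, ...]
    injected_log2fc: Mapping[tuple[str | int, str], float] = field(default_factory=dict)
    base_cq_range: tuple[float, float] = (20.0, 33.0)
    replicate_sd: float = 0.2
    aliquot_sd: float | None = None
    background_sd: float = 0.5
    platform_offset_sd: float = 0.7
    detection_ceiling: float = 35.0
    aliquots_per_strain: int = 3
    pcr_replicates: int = 3
    stochastic_dropout: bool = False
    referent_ids: tuple[str, ...] = DEFAULT_REFERENTS
    spike_in_ids: tuple[str, ...] = DEFAULT_SPIKE_INS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        object.__setattr__(self, "injected_log2fc", dict(self.injected_log2fc))
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        for sd in (self.replicate_sd, self.background_sd, self.platform_offset_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.aliquot_sd is not None and self.aliquot_sd < 0:
            raise ValueError("aliquot_sd must be >= 0")
        if self.base_cq_range[0] >= self.base_cq_range[1]:
            raise ValueError("base_cq_range must be an increasing interval")
        if self.aliquots_per_strain < 1 or self.pcr_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        names = [s.name for s in self.strains]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strain names")
        name_set = set(names)
        for s in self.strains:
            if s.role == "pathological" and s.control_strain not in name_set:
                raise ValueError(
                    f"pathological strain {s.name!r} references unknown control {s.control_strain!r}"
                )
        sim_ids = set(self.sim_mirna_ids)
        for (m, strain) in self.injected_log2fc:
            if strain not in name_set:
                raise ValueError(f"injection references unknown strain {strain!r}")
            if isinstance(m, int):
                if not 0 <= m < self.n_mirnas:
                    raise ValueError(f"injection miRNA index {m} out of range")
            elif m not in sim_ids:
                raise ValueError(f"injection references unknown miRNA {m!r}")

    @property
    def sim_mirna_ids(self) -> tuple[str, ...]:
        return tuple(f"sim-miR-{i + 1:03d}" for i in range(self.n_mirnas))

    @property
    def effective_aliquot_sd(self) -> float:
        return self.replicate_sd if self.aliquot_sd is None else self.aliquot_sd

    def resolved_injections(self) -> dict[tuple[str, str], float]:
        """Injections keyed by (assay id, strain), indices resolved to ids."""
        ids = self.sim_mirna_ids
        out: dict[tuple[str, str], float] = {}
        for (m, strain), fc in self.injected_log2fc.items():
            mid = ids[m] if isinstance(m, int) else m
            out[(mid, strain)] = float(fc)
        return out


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated screen.

    ``true_log2fc`` covers every (endogenous assay, pathological strain)
    pair (0.0 where nothing was injected); ``true_detected`` flags, per
    (assay, strain), whether the noise-free expected Cq sits at or below
    the detection ceiling.
    """

    true_log2fc: dict[tuple[str, str], float]
    true_detected: dict[tuple[str, str], bool]
    seed: int
    spec: SimulationSpec

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": m,
                "strain": s,
                "true_log2fc": fc,
                "true_detected": self.true_detected.get((m, s), True),
            }
            for (m, s), fc in sorted(self.true_log2fc.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------


def _shared_effects(spec: SimulationSpec, rng: np.random.Generator):
    """Draw the platform-independent layers: base Cq, background shifts."""
    ids = spec.sim_mirna_ids
    lo, hi = spec.base_cq_range
    base = pd.Series(rng.uniform(lo, hi, size=spec.n_mirnas), index=ids)
    groups = sorted({s.background_group for s in spec.strains})
    bg = pd.DataFrame(
        rng.normal(0.0, spec.background_sd, size=(spec.n_mirnas, len(groups))),
        index=ids,
        columns=groups,
    )
    ref_base = pd.Series(
        rng.uniform(lo, hi, size=len(spec.referent_ids)), index=list(spec.referent_ids)
    )
    spike_base = pd.Series(
        rng.uniform(lo, hi, size=len(spec.spike_in_ids)), index=list(spec.spike_in_ids)
    )
    return base, bg, ref_base, spike_base


def _expected_cq(
    spec: SimulationSpec,
    base: pd.Series,
    bg: pd.DataFrame,
    injections: Mapping[tuple[str, str], float],
    strain: StrainSpec,
) -> pd.Series:
    exp = base + bg[strain.background_group]
    if strain.role == "pathological":
        for (m, s), fc in injections.items():
            if s == strain.name:
                exp[m] = exp[m] - fc  # upregulation lowers Cq
    return exp


def _simulate_platform(
    spec: SimulationSpec,
    base: pd.Series,
    bg: pd.DataFrame,
    ref_base: pd.Series,
    spike_base: pd.Series,
    injections: Mapping[tuple[str, str], float],
    platform_label: str,
    rng: np.random.Generator,
    panel_mirnas: Sequence[str] | None = None,
) -> CqTable:
    sim_ids = list(spec.sim_mirna_ids) if panel_mirnas is None else list(panel_mirnas)
    all_ids = sim_ids + list(spec.referent_ids) + list(spec.spike_in_ids)

    offset = pd.Series(
        rng.normal(0.0, spec.platform_offset_sd, size=len(all_ids)), index=all_ids
    )

    samples: list[SampleMeta] = []
    columns: dict[str, pd.Series] = {}
    al_sd = spec.effective_aliquot_sd
    for strain in spec.strains:
        exp_sim = _expected_cq(spec, base, bg, injections, strain).loc[sim_ids]
        for a in range(1, spec.aliquots_per_strain + 1):
            e_al = rng.normal(0.0, al_sd, size=len(all_ids)) if al_sd > 0 else np.zeros(len(all_ids))
            for r in range(1, spec.pcr_replicates + 1):
                sid = f"{strain.name}_a{a}_r{r}"
                e_rep = (
                    rng.normal(0.0, spec.replicate_sd, size=len(all_ids))
                    if spec.replicate_sd > 0
                    else np.zeros(len(all_ids))
                )
                cq = np.empty(len(all_ids))
                n_sim = len(sim_ids)
                n_ref = len(spec.referent_ids)
                cq[:n_sim] = exp_sim.to_numpy() + offset.to_numpy()[:n_sim]
                cq[n_sim : n_sim + n_ref] = (
                    ref_base.to_numpy() + offset.to_numpy()[n_sim : n_sim + n_ref]
                )
                # spike-ins: constant abundance, replicate noise only
                cq[n_sim + n_ref :] = spike_base.to_numpy()
                cq = cq + e_al + e_rep
                cq[n_sim + n_ref :] = spike_base.to_numpy() + e_rep[n_sim + n_ref :]
                # censoring at the detection ceiling
                if spec.stochastic_dropout:
                    p_drop = 1.0 / (1.0 + np.exp(-(cq - spec.detection_ceiling) / 0.5))
                    drop = rng.uniform(size=len(cq)) < p_drop
                else:
                    drop = cq > spec.detection_ceiling
                cq = np.where(drop, np.nan, cq)
                columns[sid] = pd.Series(cq, index=all_ids)
                samples.append(
                    SampleMeta(
                        sample_id=sid,
                        strain=strain.name,
                        role=strain.role,
                        control_strain=strain.control_strain,
                        aliquot_index=a,
                        pcr_replicate_index=r,
                        subject_level="pooled",
                    )
                )

    values = pd.DataFrame(columns, index=all_ids)
    panel = AssayPanel(
        mirna_ids=tuple(all_ids),
        spike_in_ids=tuple(spec.spike_in_ids),
        referent_ids=tuple(spec.referent_ids),
        platform_label=platform_label,
    )
    return CqTable(panel=panel, samples=tuple(samples), values=values)


def _build_truth(
    spec: SimulationSpec,
    base: pd.Series,
    bg: pd.DataFrame,
    ref_base: pd.Series,
    injections: Mapping[tuple[str, str], float],
) -> SimulatedTruth:
    true_fc: dict[tuple[str, str], float] = {}
    detected: dict[tuple[str, str], bool] = {}
    patho = [s for s in spec.strains if s.role == "pathological"]
    for strain in patho:
        exp = _expected_cq(spec, base, bg, injections, strain)
        for m in spec.sim_mirna_ids:
            true_fc[(m, strain.name)] = injections.get((m, strain.name), 0.0)
            detected[(m, strain.name)] = bool(exp[m] <= spec.detection_ceiling)
        for m in spec.referent_ids:
            true_fc[(m, strain.name)] = 0.0
            detected[(m, strain.name)] = bool(ref_base[m] <= spec.detection_ceiling)
    return SimulatedTruth(true_log2fc=true_fc, true_detected=detected, seed=spec.seed, spec=spec)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def simulate_screen(spec: SimulationSpec) -> tuple[CqTable, SimulatedTruth]:
    """Simulate one single-platform pooled-serum Cq screen.

    Output is a pure function of the spec (including its seed): the same
    spec yields bit-identical tables.
    """
    ss = np.random.SeedSequence(spec.seed)
    shared_rng, plat_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    base, bg, ref_base, spike_base = _shared_effects(spec, shared_rng)
    injections = spec.resolved_injections()
    table = _simulate_platform(
        spec, base, bg, ref_base, spike_base, injections, "A", plat_rng
    )
    truth = _build_truth(spec, base, bg, ref_base, injections)
    return table, truth


def simulate_two_platform_screens(
    spec: SimulationSpec, n_panel_b: int | None = None
) -> tuple[CqTable, CqTable, SimulatedTruth]:
    """Simulate a discovery screen (platform A) and a validation screen (B).

    Both platforms share the true abundances (base Cq, background shifts,
    injected effects) but draw independent per-miRNA platform offsets and
    replicate noise.  ``n_panel_b`` restricts platform B to the first n
    simulated assays (validation panels are typically subsets).
    """
    ss = np.random.SeedSequence(spec.seed)
    shared_rng, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))
    base, bg, ref_base, spike_base = _shared_effects(spec, shared_rng)
    injections = spec.resolved_injections()
    table_a = _simulate_platform(spec, base, bg, ref_base, spike_base, injections, "A", rng_a)
    panel_b = None if n_panel_b is None else list(spec.sim_mirna_ids[:n_panel_b])
    table_b = _simulate_platform(
        spec, base, bg, ref_base, spike_base, injections, "B", rng_b, panel_mirnas=panel_b
    )
    truth = _build_truth(spec, base, bg, ref_base, injections)
    return table_a, table_b, truth


def simulate_patient_cohort(
    n_cases: int,
    n_controls: int,
    effect_log2fc: Mapping[str, float],
    between_subject_sd: float,
    seed: int,
    *,
    base_cq_range: tuple[float, float] = (20.0, 30.0),
    case_strain: str = "DMD",
    control_strain: str = "CTRL",
) -> CqTable:
    """Simulate an individual-level case/control cohort (one column/subject).

    Each assay in ``effect_log2fc`` gets a base Cq drawn once; case
    subjects are shifted by ``-log2FC`` cycles and every subject adds
    Gaussian between-subject noise.  Referents or ratio references are
    included simply by giving them an effect of 0 (stable) or their true
    effect.  With ``between_subject_sd = 0`` and any nonzero effect the
    classes are perfectly separated.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("n_cases and n_controls must be >= 1")
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mirnas = list(effect_log2fc)
    lo, hi = base_cq_range
    base = rng.uniform(lo, hi, size=len(mirnas))
    effects = np.array([effect_log2fc[m] for m in mirnas])

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    for i in range(1, n_cases + 1):
        sid = f"case_{i:02d}"
        noise = rng.normal(0.0, between_subject_sd, size=len(mirnas)) if between_subject_sd > 0 else 0.0
        columns[sid] = base - effects + noise
        samples.append(
            SampleMeta(
                sample_id=sid,
                strain=case_strain,
                role="pathological",
                control_strain=control_strain,
                aliquot_index=i,
                subject_level="individual",
            )
        )
    for i in range(1, n_controls + 1):
        sid = f"control_{i:02d}"
        noise = rng.normal(0.0, between_subject_sd, size=len(mirnas)) if between_subject_sd > 0 else 0.0
        columns[sid] = base + noise
        samples.append(
            SampleMeta(
                sample_id=sid,
                strain=control_strain,
                role="control",
                aliquot_index=i,
                subject_level="individual",
            )
        )

    values = pd.DataFrame(columns, index=mirnas)
    panel = AssayPanel(mirna_ids=tuple(mirnas), platform_label="cohort")
    return CqTable(panel=panel, samples=tuple(samples), values=values)
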