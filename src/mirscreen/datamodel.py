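"""Core data types and tabular I/O for RT-qPCR quantification-cycle tables.

The central container is :class:`CqTable`: a miRNA x sample matrix of
quantification cycles (Cq) with explicit missingness (``NaN`` marks
no-amplification), an :class:`AssayPanel` describing the assays, and one
:class:`SampleMeta` record per column describing the replicate structure
(strain, pooled-aliquot index, PCR-replicate index).

On disk a dataset is a delimited wide table (first column = assay id,
remaining columns = sample ids) plus a sample-metadata sidecar table.
Missing entries are written as empty cells; ``Undetermined`` and other
instrument sentinels parse as missing.  Cq values are never rounded at
parse time; detection thresholds are applied downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayPanel",
    "SampleMeta",
    "CqTable",
    "ScreenConfig",
    "Finding",
    "read_cq_table",
    "read_sample_meta",
    "write_cq_table",
    "write_sample_meta",
    "validate_dataset",
]

#: cell contents treated as "no amplification" when parsing
MISSING_SENTINELS = {"", "na", "nan", "n/a", "undetermined", "undet", "null", "none"}

ROLES = ("pathological", "control")
SUBJECT_LEVELS = ("pooled", "individual")


@dataclass(frozen=True)
class AssayPanel:
    """The set of assays on one RT-qPCR platform.

    ``spike_in_ids`` are exogenous synthetic controls (e.g. cel-miR-39,
    Sp3/Sp6) added at a known amount; ``referent_ids`` are endogenous
    assays assumed stable across conditions (e.g. miR-29a, miR-30b).
    Both are disjoint subsets of ``mirna_ids``.
    """

    mirna_ids: tuple[str, ...]
    spike_in_ids: tuple[str, ...] = ()
    referent_ids: tuple[str, ...] = ()
    platform_label: str = "A"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mirna_ids", tuple(self.mirna_ids))
        object.__setattr__(self, "spike_in_ids", tuple(self.spike_in_ids))
        object.__setattr__(self, "referent_ids", tuple(self.referent_ids))
        ids = self.mirna_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({m for m in ids if list(ids).count(m) > 1})
            raise ValueError(f"duplicate assay ids in panel: {dupes}")
        id_set = set(ids)
        for name, sub in (("spike_in_ids", self.spike_in_ids), ("referent_ids", self.referent_ids)):
            missing = [m for m in sub if m not in id_set]
            if missing:
                raise ValueError(f"{name} not in panel: {missing}")
        if set(self.spike_in_ids) & set(self.referent_ids):
            raise ValueError("spike-in and referent sets must be disjoint")

    @property
    def endogenous_ids(self) -> tuple[str, ...]:
        """Assay ids excluding exogenous spike-ins."""
        spikes = set(self.spike_in_ids)
        return tuple(m for m in self.mirna_ids if m not in spikes)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one table column (one RT-qPCR measurement series).

    ``control_strain`` names the strain a pathological sample is compared
    against; it is empty for control samples.  Pooled-serum designs carry
    an ``aliquot_index`` (1..3 in the standard design: one serum pool per
    strain split into three aliquots) and a ``pcr_replicate_index``.
    """

    sample_id: str
    strain: str
    role: str = "control"
    control_strain: str = ""
    aliquot_index: int = 1
    pcr_replicate_index: int = 1
    subject_level: str = "pooled"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.subject_level not in SUBJECT_LEVELS:
            raise ValueError(
                f"subject_level must be one of {SUBJECT_LEVELS}, got {self.subject_level!r}"
            )
        if self.aliquot_index < 1 or self.pcr_replicate_index < 0:
            raise ValueError("replicate indices must be positive")


@dataclass
class CqTable:
    """A validated miRNA x sample matrix of quantification cycles.

    ``values`` is a float DataFrame indexed by assay id with one column
    per sample id; ``NaN`` is the in-memory missing marker for
    no-amplification.  Row order follows the panel, column order the
    sample list.
    """

    panel: AssayPanel
    samples: tuple[SampleMeta, ...]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.validate()

    def validate(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids in metadata")
        if list(self.values.index) != list(self.panel.mirna_ids):
            raise ValueError("value matrix rows do not match panel assay ids")
        if list(self.values.columns) != sample_ids:
            raise ValueError("value matrix columns do not match sample metadata")
        vals = self.values.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        bad = ~finite & ~np.isnan(vals)
        if bad.any():
            raise ValueError("non-finite Cq values present (inf)")
        if (vals[finite] <= 0).any():
            raise ValueError("Cq values must be positive")
        # strains referenced as controls must exist
        strains = {s.strain for s in self.samples}
        for s in self.samples:
            if s.role == "pathological" and s.control_strain and s.control_strain not in strains:
                raise ValueError(
                    f"sample {s.sample_id!r}: control strain {s.control_strain!r} absent from dataset"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample id."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "strain": [s.strain for s in self.samples],
                "role": [s.role for s in self.samples],
                "control_strain": [s.control_strain for s in self.samples],
                "aliquot_index": [s.aliquot_index for s in self.samples],
                "pcr_replicate_index": [s.pcr_replicate_index for s in self.samples],
                "subject_level": [s.subject_level for s in self.samples],
            }
        ).set_index("sample_id", drop=False)

    def strains(self) -> list[str]:
        """Strain names in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.strain, None)
        return list(seen)

    def samples_of(self, strain: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.strain == strain]

    def strain_of_control(self, strain: str) -> str:
        """Control strain recorded for a pathological strain ('' if none)."""
        for s in self.samples:
            if s.strain == strain and s.control_strain:
                return s.control_strain
        return ""

    def subset(self, mirna_ids: Sequence[str]) -> "CqTable":
        """Restrict to a subset of assays, preserving panel flags."""
        keep = [m for m in self.panel.mirna_ids if m in set(mirna_ids)]
        panel = AssayPanel(
            mirna_ids=tuple(keep),
            spike_in_ids=tuple(m for m in self.panel.spike_in_ids if m in set(keep)),
            referent_ids=tuple(m for m in self.panel.referent_ids if m in set(keep)),
            platform_label=self.panel.platform_label,
        )
        return CqTable(panel=panel, samples=self.samples, values=self.values.loc[keep].copy())


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the differential screen.

    detection_cq_max : Cq detection ceiling (cycles); an assay is detected
        where its mean Cq is at or below this value (inclusive).
    fc_threshold : minimum absolute linear fold change called dysregulated.
    alpha : significance level applied to the validation-platform p-value.
    referent_ids : stable endogenous assays for referent normalization.
    """

    detection_cq_max: float = 35.0
    fc_threshold: float = 1.5
    alpha: float = 0.05
    referent_ids: tuple[str, ...] = ("mmu-miR-29a", "mmu-miR-30b")

    def __post_init__(self) -> None:
        if not self.detection_cq_max > 0:
            raise ValueError("detection_cq_max must be > 0")
        if not self.fc_threshold >= 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        object.__setattr__(self, "referent_ids", tuple(self.referent_ids))


class Finding(NamedTuple):
    """One validation finding (report-only; never raised)."""

    severity: str  # "error" | "warning" | "info"
    code: str
    message: str


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_cell(x: object, max_valid_cq: float | None) -> float:
    if x is None:
        return math.nan
    if isinstance(x, float) and math.isnan(x):
        return math.nan
    s = str(x).strip()
    if s.lower() in MISSING_SENTINELS:
        return math.nan
    try:
        v = float(s)
    except ValueError:
        return math.nan
    if max_valid_cq is not None and v > max_valid_cq:
        return math.nan
    return v


def read_sample_meta(meta_path: str | Path) -> dict[str, SampleMeta]:
    """Read the sample-metadata sidecar (CSV/TSV) into a sample_id -> meta map."""
    meta_path = Path(meta_path)
    mdf = pd.read_csv(meta_path, sep=_sep_for(meta_path), dtype=str).fillna("")
    required = {"sample_id", "strain"}
    missing_cols = required - set(mdf.columns)
    if missing_cols:
        raise ValueError(f"metadata file lacks required columns: {sorted(missing_cols)}")
    metas: dict[str, SampleMeta] = {}
    for _, row in mdf.iterrows():
        sid = row["sample_id"]
        metas[sid] = SampleMeta(
            sample_id=sid,
            strain=row["strain"],
            role=row.get("role", "control") or "control",
            control_strain=row.get("control_strain", "") or "",
            aliquot_index=int(row.get("aliquot_index", "1") or 1),
            pcr_replicate_index=int(row.get("pcr_replicate_index", "1") or 1),
            subject_level=row.get("subject_level", "pooled") or "pooled",
        )
    return metas


def read_cq_table(
    path: str | Path,
    meta_path: str | Path,
    *,
    spike_in_ids: Iterable[str] = (),
    referent_ids: Iterable[str] = (),
    platform_label: str = "A",
    max_valid_cq: float | None = None,
    xlsx_header_row: int = 0,
    xlsx_id_column: int = 0,
    xlsx_sheet: int | str = 0,
) -> CqTable:
    """Read a wide Cq table plus its sample-metadata sidecar.

    CSV/TSV dialects are chosen by extension; ``.xlsx`` workbooks are read
    with a configurable header row and id column (supplementary-table
    layouts vary).  Empty cells, ``Undetermined`` and unparseable entries
    become missing; values above ``max_valid_cq`` (if given) are also
    treated as no-amplification.

    Raises a hard error when a data column has no metadata (naming the
    column) or an assay row id is duplicated.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path, sheet_name=xlsx_sheet, header=xlsx_header_row, dtype=object)
        id_col = raw.columns[xlsx_id_column]
        junk = list(raw.columns[:xlsx_id_column])  # columns left of the id column
        raw = raw.set_index(id_col).drop(columns=junk)
    else:
        raw = pd.read_csv(path, sep=_sep_for(path), dtype=object, index_col=0)
    raw.index = raw.index.map(lambda x: str(x).strip())
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValueError(f"duplicate assay rows: {dupes}")

    metas = read_sample_meta(meta_path)
    samples: list[SampleMeta] = []
    for col in raw.columns:
        if str(col) not in metas:
            raise ValueError(f"no sample metadata for column {str(col)!r}")
        samples.append(metas[str(col)])

    values = raw.map(lambda x: _parse_cell(x, max_valid_cq)).astype(float)
    values.columns = [str(c) for c in values.columns]
    values.index.name = None
    panel = AssayPanel(
        mirna_ids=tuple(values.index),
        spike_in_ids=tuple(m for m in spike_in_ids if m in set(values.index)),
        referent_ids=tuple(m for m in referent_ids if m in set(values.index)),
        platform_label=platform_label,
    )
    return CqTable(panel=panel, samples=tuple(samples), values=values)


def write_cq_table(table: CqTable, path: str | Path) -> None:
    """Write the Cq matrix as a delimited wide table.

    Missing entries become empty cells; floats are written at full repr
    precision so that a read-back reproduces values bit-for-bit.
    """
    path = Path(path)
    out = table.values.copy()
    out.index.name = "mirna_id"
    out.to_csv(path, sep=_sep_for(path), na_rep="")


def write_sample_meta(table: CqTable, path: str | Path) -> None:
    """Write the sample-metadata sidecar for ``table``."""
    path = Path(path)
    table.meta_frame().to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------


def validate_dataset(table: CqTable, config: ScreenConfig | None = None) -> list[Finding]:
    """Report design and plausibility findings without mutating the table.

    Checks the pooled-triplicate design (3 aliquots per strain), presence
    of the configured referents, assays missing in more than half the
    samples, and Cq values outside the plausible [5, 45] cycle window.
    """
    config = config or ScreenConfig()
    findings: list[Finding] = []

    meta = table.meta_frame()
    pooled = meta[meta["subject_level"] == "pooled"]
    for strain, grp in pooled.groupby("strain", sort=False):
        n_aliquots = grp["aliquot_index"].nunique()
        if n_aliquots != 3:
            findings.append(
                Finding(
                    "warning",
                    "aliquot_design",
                    f"strain {strain!r} has {n_aliquots} aliquots (expected 3)",
                )
            )

    present = set(table.panel.mirna_ids)
    for ref in config.referent_ids:
        if ref not in present:
            findings.append(
                Finding("warning", "referent_missing", f"referent {ref!r} absent from panel")
            )

    frac_missing = table.values.isna().mean(axis=1)
    for mirna, frac in frac_missing.items():
        if frac > 0.5:
            findings.append(
                Finding(
                    "info",
                    "high_missingness",
                    f"assay {mirna!r} missing in {frac:.0%} of samples",
                )
            )

    vals = table.values.to_numpy(dtype=float)
    n_out = int(np.sum((vals < 5) | (vals > 45)))
    if n_out:
        findings.append(
            Finding("warning", "cq_out_of_range", f"{n_out} Cq values outside [5, 45] cycles")
        )
    return findings
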