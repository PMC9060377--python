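"""Variant functional dataset: loading, labeling, and non-perturbing augmentation.

Each variant of the channel carries four electrophysiological parameters
measured in the homozygous state and normalized to wild type (100 %WT): peak
current density (I_Ks), half-maximal activation voltage (V1/2), and the
activation/deactivation time constants (tau_act, tau_deact).  A parameter is
labeled dysfunctional (1) when it falls outside its normal band, could not be
measured at all, or — for every parameter at once — when peak current density
collapses to <= 17 %WT (severe loss of function implies the kinetic and
voltage-dependence readouts are meaningless).

Non-perturbing variants are identity substitutions (wt == mut) added for every
residue resolved in the structural model; they are labeled fully normal and
give the downstream model a baseline for each structural neighborhood.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .aatables import CANONICAL_AAS

#: Sentinel for a biophysical parameter that could not be determined
#: (e.g. V1/2 of a voltage-insensitive variant).
UNMEASURABLE = None

PARAMETERS = ("iks", "vhalf", "tau_act", "tau_deact")

_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class DatasetError(ValueError):
    """Invalid variant name, residue code, record value, or table layout."""


@dataclass(frozen=True)
class VariantSpec:
    """One amino-acid substitution; wt_aa == mut_aa encodes a non-perturbing variant."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.position < 1:
            raise DatasetError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in CANONICAL_AAS:
                raise DatasetError(f"non-canonical residue code {aa!r}")

    @property
    def is_nonperturbing(self) -> bool:
        return self.wt_aa == self.mut_aa

    @property
    def name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def parse_variant_name(name: str) -> VariantSpec:
    """Parse 'R195Q'-style names; case-insensitive, surrounding whitespace ignored."""
    m = _VARIANT_RE.match(name.strip())
    if not m:
        raise DatasetError(f"unparseable variant name {name!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return VariantSpec(position=pos, wt_aa=wt, mut_aa=mut)


@dataclass(frozen=True)
class FunctionalRecord:
    """Four normalized %WT measurements for one variant (None = unmeasurable)."""

    variant: VariantSpec
    iks_pct: float | None
    vhalf_pct: float | None
    tau_act_pct: float | None
    tau_deact_pct: float | None

    def __post_init__(self):
        for name in PARAMETERS:
            v = self.value(name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise DatasetError(
                    f"{self.variant.name}: {name} must be a non-negative "
                    f"finite %WT value, got {v!r}"
                )

    def value(self, parameter: str) -> float | None:
        return getattr(self, f"{parameter}_pct")


@dataclass(frozen=True)
class PhenotypeLabels:
    """Binary phenotype per parameter: 0 = normal, 1 = dysfunctional."""

    iks: int
    vhalf: int
    tau_act: int
    tau_deact: int

    def __post_init__(self):
        for p in PARAMETERS:
            if getattr(self, p) not in (0, 1):
                raise DatasetError(f"label {p} must be 0 or 1")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.iks, self.vhalf, self.tau_act, self.tau_deact)


# Normal band per parameter as (low, high) in %WT: a measured value v is
# dysfunctional when v < low (LOF for iks/tau_deact, GOF for vhalf/tau_act)
# or v > high.  Bounds are exclusive: a value exactly at a bound is normal.
@dataclass(frozen=True)
class CriteriaTable:
    """Dysfunction criteria in %WT.  Defaults: I_Ks normal in (55, 115),
    V1/2 in (80, 130), tau_act in (70, 170), tau_deact in (75, 125);
    iks <= 17 %WT marks all four parameters dysfunctional."""

    iks_lof: float = 55.0      # iks <  55 -> LOF
    iks_gof: float = 115.0     # iks >  115 -> GOF
    vhalf_lof: float = 130.0   # vhalf > 130 -> LOF
    vhalf_gof: float = 80.0    # vhalf <  80 -> GOF
    tau_act_lof: float = 170.0
    tau_act_gof: float = 70.0
    tau_deact_lof: float = 75.0
    tau_deact_gof: float = 125.0
    severe_lof_cutoff: float = 17.0

    def __post_init__(self):
        for p in PARAMETERS:
            lo, hi = self.normal_band(p)
            if not (lo < 100.0 < hi):
                raise DatasetError(f"normal band for {p} must contain 100 %WT")

    def normal_band(self, parameter: str) -> tuple[float, float]:
        lof = getattr(self, f"{parameter}_lof")
        gof = getattr(self, f"{parameter}_gof")
        return (min(lof, gof), max(lof, gof))

    def direction(self, parameter: str, value: float | None) -> str:
        """LOF / GOF / WT-like call for one measured parameter (None -> LOF)."""
        if value is UNMEASURABLE:
            return "LOF"
        lof = getattr(self, f"{parameter}_lof")
        gof = getattr(self, f"{parameter}_gof")
        if lof < gof:  # low values are LOF (iks, tau_deact)
            if value < lof:
                return "LOF"
            if value > gof:
                return "GOF"
        else:          # high values are LOF (vhalf, tau_act)
            if value > lof:
                return "LOF"
            if value < gof:
                return "GOF"
        return "WT-like"


#: Original, narrower tau_act band (80-120 %WT) kept for the ablation where
#: slow-activating but otherwise WT-like variants degrade the tau_act labels.
ORIGINAL_TAU_ACT_CRITERIA = CriteriaTable(tau_act_lof=120.0, tau_act_gof=80.0)


def classify_record(record: FunctionalRecord, criteria: CriteriaTable | None = None) -> PhenotypeLabels:
    """Label each parameter 0/1; unmeasurable -> 1; iks <= cutoff -> all four 1."""
    criteria = criteria or CriteriaTable()
    iks = record.iks_pct
    if iks is not UNMEASURABLE and iks <= criteria.severe_lof_cutoff:
        return PhenotypeLabels(1, 1, 1, 1)
    labels = {}
    for p in PARAMETERS:
        v = record.value(p)
        labels[p] = 0 if criteria.direction(p, v) == "WT-like" else 1
    return PhenotypeLabels(**labels)


def classify_direction(record: FunctionalRecord, criteria: CriteriaTable | None = None) -> dict[str, str]:
    """Per-parameter LOF/GOF/WT-like call; the severe-iks cascade forces LOF."""
    criteria = criteria or CriteriaTable()
    iks = record.iks_pct
    if iks is not UNMEASURABLE and iks <= criteria.severe_lof_cutoff:
        return {p: "LOF" for p in PARAMETERS}
    return {p: criteria.direction(p, record.value(p)) for p in PARAMETERS}


_DEFAULT_COLUMNS = {
    "variant": "variant",
    "iks": "iks_pct",
    "vhalf": "vhalf_pct",
    "tau_act": "tau_act_pct",
    "tau_deact": "tau_deact_pct",
}

_UNMEASURABLE_SENTINELS = {"", "na", "nd", "nan", "none"}


def _parse_cell(raw, row_label) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return UNMEASURABLE
    if isinstance(raw, str):
        if raw.strip().lower() in _UNMEASURABLE_SENTINELS:
            return UNMEASURABLE
        try:
            return float(raw)
        except ValueError:
            raise DatasetError(f"row {row_label}: unparseable value {raw!r}") from None
    return float(raw)


def load_dataset(
    path: str | Path,
    criteria: CriteriaTable | None = None,
    column_map: dict[str, str] | None = None,
) -> list[tuple[FunctionalRecord, PhenotypeLabels]]:
    """Load a CSV/XLSX variant table and label every row.

    ``column_map`` maps the logical keys {variant, iks, vhalf, tau_act,
    tau_deact} to the file's column names (the deposited table's exact headers
    are not standardized, so they are configuration rather than guesswork).
    Blank cells and the sentinels NA/ND mean unmeasurable.  Row order is
    preserved; duplicate variants and unparseable names are load errors that
    name the offending row.
    """
    path = Path(path)
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path, dtype=object)
    else:
        try:
            table = pd.read_csv(path, dtype=object, skipinitialspace=True)
        except pd.errors.EmptyDataError:
            return []
    if table.empty and len(table.columns) == 0:
        return []
    for key in ("variant", "iks", "vhalf", "tau_act", "tau_deact"):
        if cols[key] not in table.columns:
            raise DatasetError(f"missing column {cols[key]!r} in {path.name}")
    out: list[tuple[FunctionalRecord, PhenotypeLabels]] = []
    seen: set[str] = set()
    for i, row in table.iterrows():
        label = f"{i + 2}"  # 1-based plus header, as a spreadsheet user counts
        try:
            spec = parse_variant_name(str(row[cols["variant"]]))
        except DatasetError as e:
            raise DatasetError(f"row {label}: {e}") from None
        if spec.name in seen:
            raise DatasetError(f"row {label}: duplicate variant {spec.name}")
        seen.add(spec.name)
        try:
            rec = FunctionalRecord(
                variant=spec,
                iks_pct=_parse_cell(row[cols["iks"]], label),
                vhalf_pct=_parse_cell(row[cols["vhalf"]], label),
                tau_act_pct=_parse_cell(row[cols["tau_act"]], label),
                tau_deact_pct=_parse_cell(row[cols["tau_deact"]], label),
            )
        except DatasetError as e:
            raise DatasetError(f"row {label}: {e}") from None
        out.append((rec, classify_record(rec, criteria)))
    return out


def augment_nonperturbing(
    resolved_positions: list[tuple[int, str]],
) -> list[tuple[FunctionalRecord, PhenotypeLabels]]:
    """One identity-substitution record per resolved residue, all parameters 100 %WT."""
    positions = [p for p, _ in resolved_positions]
    if len(positions) != len(set(positions)):
        raise DatasetError("resolved positions must be unique")
    out = []
    for pos, wt in resolved_positions:
        spec = VariantSpec(position=pos, wt_aa=wt, mut_aa=wt)
        rec = FunctionalRecord(spec, 100.0, 100.0, 100.0, 100.0)
        out.append((rec, PhenotypeLabels(0, 0, 0, 0)))
    return out


def labeled_records_to_frame(records) -> pd.DataFrame:
    """Flatten (record, labels) pairs to a DataFrame for CSV export."""
    rows = []
    for rec, lab in records:
        rows.append(
            {
                "variant": rec.variant.name,
                "position": rec.variant.position,
                "wt_aa": rec.variant.wt_aa,
                "mut_aa": rec.variant.mut_aa,
                **{f"{p}_pct": rec.value(p) for p in PARAMETERS},
                **{f"label_{p}": getattr(lab, p) for p in PARAMETERS},
            }
        )
    return pd.DataFrame(rows)
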