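"""Curation of sparse multitask permeability/efflux assay tables.

Raw assay readings (Caco-2 efflux ratio and apparent permeability, MDCK and
NIH-MDCK efflux ratios) arrive as one row per measurement: a SMILES string, an
endpoint name, a positive value — P_app in 1e-6 cm/s, ER dimensionless — an
optional out-of-bound qualifier (< or >), a date and a modality label.  This
module standardizes structures, log10-transforms values, aggregates replicates
per (compound, endpoint), models replicate noise as a linear function of the
mean (assay noise is heteroscedastic: low-permeability wells are hard to
quantify), removes compounds whose replicate spread is inconsistent with that
model, and pivots the result into a compounds x 4-endpoint sparse table.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Endpoint column order of the released multitask model.
ENDPOINTS: tuple[str, ...] = ("Caco2ER", "Caco2Papp", "MDCKER", "NIHMDCKER")

QUALIFIERS = ("none", "lower_bound", "upper_bound")
MODALITIES = ("small_molecule", "macrocycle", "peptide", "PROTAC", "unknown")


class StandardizationError(ValueError):
    """Raised when a SMILES string cannot be parsed/standardized."""


class InsufficientDataError(ValueError):
    """Raised when too few records are available to fit the noise model."""


@dataclass(frozen=True)
class RawMeasurement:
    """A single assay reading."""

    smiles: str
    endpoint: str
    value: float
    qualifier: str = "none"
    timestamp: date | None = None
    modality: str = "unknown"

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown qualifier {self.qualifier!r}")
        if not self.value > 0:
            raise ValueError(f"measurement value must be positive, got {self.value}")


@dataclass(frozen=True)
class AggregatedRecord:
    """Replicate-aggregated log10 value for one (standardized SMILES, endpoint)."""

    smiles_std: str
    endpoint: str
    mean_log: float
    sd_log: float | None
    n_measurements: int
    earliest_timestamp: date | None = None
    any_qualifier: bool = False
    modality: str = "unknown"

    def __post_init__(self) -> None:
        if (self.sd_log is None) != (self.n_measurements == 1):
            raise ValueError("sd_log must be absent exactly for singletons")
        if not math.isfinite(self.mean_log):
            raise ValueError("mean_log must be finite")


@dataclass(frozen=True)
class SigmaModel:
    """OLS fit of replicate SD against replicate mean for one endpoint.

    sigma_pred(m) = intercept + slope * m, clipped below at ``sigma_floor``
    when used for outlier flagging.
    """

    intercept: float
    slope: float
    endpoint: str
    n_fit: int

    def predict(self, mean_log: float | np.ndarray, floor: float = 0.01):
        return np.maximum(floor, self.intercept + self.slope * np.asarray(mean_log))


# ---------------------------------------------------------------------------
# elementary operations


def standardize_structure(smiles_raw: str) -> str:
    """Canonicalize a SMILES: cleanup, keep largest fragment, neutralize.

    Deterministic; identical molecules map to identical strings.  Unparsable
    input raises :class:`StandardizationError`.
    """
    if not smiles_raw or not smiles_raw.strip():
        raise StandardizationError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {smiles_raw!r}")
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
        mol = rdMolStandardize.Uncharger().uncharge(mol)
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        raise StandardizationError(f"standardization failed for {smiles_raw!r}: {exc}")
    return Chem.MolToSmiles(mol)


def parse_bounded_value(raw) -> tuple[float, str]:
    """Parse a numeric value with an optional leading < or > qualifier.

    Out-of-bound assay readings ("lower than X" / "greater than X") keep their
    numeric payload; the bound direction is recorded, not discarded.
    """
    if isinstance(raw, (int, float)):
        return float(raw), "none"
    text = str(raw).strip()
    qualifier = "none"
    if text.startswith("<"):
        qualifier, text = "lower_bound", text[1:]
    elif text.startswith(">"):
        qualifier, text = "upper_bound", text[1:]
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"cannot parse measurement value {raw!r}")
    return value, qualifier


def to_log(value: float) -> float:
    """log10 transform; assay values are strictly positive."""
    if not value > 0:
        raise ValueError(f"log transform requires a positive value, got {value}")
    return math.log10(value)


def efflux_ratio(papp_ba: float, papp_ab: float) -> float:
    """ER = P_app(b-a) / P_app(a-b); values >> 1 indicate active efflux."""
    if not papp_ab > 0 or not papp_ba > 0:
        raise ValueError("both directional permeabilities must be positive")
    return papp_ba / papp_ab


# ---------------------------------------------------------------------------
# aggregation and noise model


def aggregate(measurements: Iterable[RawMeasurement]) -> list[AggregatedRecord]:
    """Group measurements by (SMILES, endpoint) on the log10 scale.

    Assumes SMILES are already standardized.  ``mean_log`` is the arithmetic
    mean of log10 values, ``sd_log`` the sample (n-1) standard deviation when
    n >= 2.  The earliest timestamp is kept (temporal splits need one date per
    record) and ``any_qualifier`` marks groups containing bounded values.
    """
    groups: dict[tuple[str, str], list[RawMeasurement]] = defaultdict(list)
    for m in measurements:
        groups[(m.smiles, m.endpoint)].append(m)

    records = []
    for (smi, ep), ms in groups.items():
        logs = np.array([to_log(m.value) for m in ms])
        quals = {m.qualifier for m in ms if m.qualifier != "none"}
        if len(quals) > 1:
            logger.warning(
                "mixed-direction qualifiers for %s/%s; aggregating anyway", smi, ep
            )
        stamps = [m.timestamp for m in ms if m.timestamp is not None]
        modalities = [m.modality for m in ms if m.modality != "unknown"]
        records.append(
            AggregatedRecord(
                smiles_std=smi,
                endpoint=ep,
                mean_log=float(logs.mean()),
                sd_log=float(logs.std(ddof=1)) if len(logs) >= 2 else None,
                n_measurements=len(logs),
                earliest_timestamp=min(stamps) if stamps else None,
                any_qualifier=bool(quals),
                modality=modalities[0] if modalities else "unknown",
            )
        )
    return records


def fit_sigma_model(
    records: Sequence[AggregatedRecord], endpoint: str
) -> SigmaModel:
    """OLS of replicate SD (dependent) on replicate mean (independent).

    Only records with n >= 2 carry an SD and enter the fit; at least three are
    required.
    """
    pts = [
        (r.mean_log, r.sd_log)
        for r in records
        if r.endpoint == endpoint and r.n_measurements >= 2
    ]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"{endpoint}: need >= 3 replicated records to fit the noise model, "
            f"got {len(pts)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    return SigmaModel(intercept=intercept, slope=slope, endpoint=endpoint, n_fit=len(pts))


def flag_outliers(
    records: Sequence[AggregatedRecord],
    model: SigmaModel,
    k: float = 2.0,
    sigma_floor: float = 0.01,
) -> set[tuple[str, str]]:
    """Flag replicated records whose observed SD exceeds k x predicted SD.

    The predicted SD is clipped below at ``sigma_floor`` so the rule stays
    meaningful where the regression line crosses zero.  Singletons carry no SD
    and are never flagged (their variability is assumed comparable to that of
    replicated compounds, so they are retained).
    """
    flagged = set()
    for r in records:
        if r.endpoint != model.endpoint or r.n_measurements < 2:
            continue
        if r.sd_log > k * float(model.predict(r.mean_log, floor=sigma_floor)):
            flagged.add((r.smiles_std, r.endpoint))
    return flagged


# ---------------------------------------------------------------------------
# the multitask table


@dataclass
class MultitaskTable:
    """Compounds x 4-endpoint sparse table with an observation mask.

    ``values`` holds mean log10 values (NaN where unobserved); ``mask`` is the
    boolean observed indicator; per-cell metadata (earliest timestamp,
    measurement count, replicate SD) and a per-compound modality label ride
    along.  Column order is fixed to the released-model order.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    n_measurements: pd.DataFrame
    timestamps: pd.DataFrame
    sd: pd.DataFrame
    modality: pd.Series

    @property
    def smiles(self) -> list[str]:
        return list(self.values.index)

    @property
    def endpoints(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def observed_cells(self) -> set[tuple[str, str]]:
        """All (smiles, endpoint) pairs with a measured value."""
        rows, cols = np.nonzero(self.mask.to_numpy())
        idx = self.values.index
        return {(idx[i], ENDPOINTS[j]) for i, j in zip(rows, cols)}

    def to_records(self) -> list[AggregatedRecord]:
        records = []
        for smi, ep in sorted(self.observed_cells()):
            n = int(self.n_measurements.at[smi, ep])
            sd = self.sd.at[smi, ep]
            ts = self.timestamps.at[smi, ep]
            records.append(
                AggregatedRecord(
                    smiles_std=smi,
                    endpoint=ep,
                    mean_log=float(self.values.at[smi, ep]),
                    sd_log=None if n == 1 or pd.isna(sd) else float(sd),
                    n_measurements=n,
                    earliest_timestamp=None if pd.isna(ts) else _as_date(ts),
                    modality=str(self.modality.get(smi, "unknown")),
                )
            )
        return records

    def to_measurements(self) -> list[RawMeasurement]:
        """One linear-scale measurement per observed cell (for round-trips)."""
        return [
            RawMeasurement(
                smiles=r.smiles_std,
                endpoint=r.endpoint,
                value=10.0 ** r.mean_log,
                timestamp=r.earliest_timestamp,
                modality=r.modality,
            )
            for r in self.to_records()
        ]

    # -- serialization -----------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {
                "smiles_std": r.smiles_std,
                "endpoint": r.endpoint,
                "mean_log": r.mean_log,
                "sd_log": "" if r.sd_log is None else r.sd_log,
                "n": r.n_measurements,
                "date": "" if r.earliest_timestamp is None else r.earliest_timestamp.isoformat(),
                "modality": r.modality,
            }
            for r in self.to_records()
        ]
        return pd.DataFrame(
            rows, columns=["smiles_std", "endpoint", "mean_log", "sd_log", "n", "date", "modality"]
        )

    def to_wide_frame(self) -> pd.DataFrame:
        wide = self.values.copy()
        wide.insert(0, "smiles_std", wide.index)
        wide["modality"] = self.modality.reindex(wide.index).values
        return wide.reset_index(drop=True)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "MultitaskTable":
        records = []
        for row in frame.itertuples(index=False):
            n = int(row.n)
            sd = getattr(row, "sd_log", "")
            ts = getattr(row, "date", "")
            records.append(
                AggregatedRecord(
                    smiles_std=row.smiles_std,
                    endpoint=row.endpoint,
                    mean_log=float(row.mean_log),
                    sd_log=None if n == 1 or sd in ("", None) or pd.isna(sd) else float(sd),
                    n_measurements=n,
                    earliest_timestamp=(
                        None if ts in ("", None) or pd.isna(ts) else date.fromisoformat(str(ts))
                    ),
                    modality=str(getattr(row, "modality", "unknown")),
                )
            )
        return build_multitask_table(records)


def _as_date(ts) -> date:
    if isinstance(ts, datetime):
        return ts.date()
    if isinstance(ts, date):
        return ts
    return pd.Timestamp(ts).date()


def build_multitask_table(records: Sequence[AggregatedRecord]) -> MultitaskTable:
    """Pivot aggregated records into the sparse compounds x endpoints table.

    Records must already be aggregated: a duplicate (smiles, endpoint) pair is
    a contract violation, not data to be merged here.
    """
    seen = set()
    for r in records:
        key = (r.smiles_std, r.endpoint)
        if key in seen:
            raise ValueError(f"duplicate aggregated record for {key}")
        seen.add(key)

    smiles = sorted({r.smiles_std for r in records})
    values = pd.DataFrame(np.nan, index=smiles, columns=list(ENDPOINTS))
    mask = pd.DataFrame(False, index=smiles, columns=list(ENDPOINTS))
    n_meas = pd.DataFrame(0, index=smiles, columns=list(ENDPOINTS))
    stamps = pd.DataFrame(pd.NaT, index=smiles, columns=list(ENDPOINTS))
    sd = pd.DataFrame(np.nan, index=smiles, columns=list(ENDPOINTS))
    modality = pd.Series("unknown", index=smiles, dtype=object)

    for r in records:
        values.at[r.smiles_std, r.endpoint] = r.mean_log
        mask.at[r.smiles_std, r.endpoint] = True
        n_meas.at[r.smiles_std, r.endpoint] = r.n_measurements
        if r.earliest_timestamp is not None:
            stamps.at[r.smiles_std, r.endpoint] = pd.Timestamp(r.earliest_timestamp)
        if r.sd_log is not None:
            sd.at[r.smiles_std, r.endpoint] = r.sd_log
        if r.modality != "unknown":
            modality.at[r.smiles_std] = r.modality

    return MultitaskTable(
        values=values, mask=mask, n_measurements=n_meas, timestamps=stamps, sd=sd,
        modality=modality,
    )


def coverage_summary(table: MultitaskTable) -> dict[int, float]:
    """Fraction of compounds with exactly 1, 2, 3 or 4 measured endpoints."""
    if len(table) == 0:
        raise ValueError("empty table")
    counts = table.mask.sum(axis=1)
    n = len(table)
    return {k: float((counts == k).sum()) / n for k in (1, 2, 3, 4)}


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class CurationResult:
    """Outcome of the full curation pipeline."""

    table: MultitaskTable
    records: list[AggregatedRecord]
    sigma_models: dict[str, SigmaModel]
    outliers: set[tuple[str, str]]
    rejected: list[tuple[RawMeasurement, str]] = field(default_factory=list)


def curate(
    measurements: Iterable[RawMeasurement],
    sigma_k: float = 2.0,
    sigma_floor: float = 0.01,
    standardize: bool = True,
    sigma_refits: int = 1,
) -> CurationResult:
    """Standardize, aggregate, remove noise-model outliers, build the table.

    The replicate-noise regression is fitted per endpoint; endpoints with
    fewer than three replicated records skip outlier removal (with a log
    message) rather than failing the whole run.

    Outliers inflate the very regression used to detect them, so after the
    first removal the model is refitted on the surviving records and flagging
    repeated (``sigma_refits`` extra passes; the reported sigma model is the
    final refit).  High-leverage contamination is exactly the situation where
    a single-pass threshold under-flags.
    """
    accepted: list[RawMeasurement] = []
    rejected: list[tuple[RawMeasurement, str]] = []
    cache: dict[str, str] = {}
    for m in measurements:
        if standardize:
            try:
                if m.smiles not in cache:
                    cache[m.smiles] = standardize_structure(m.smiles)
                m = replace(m, smiles=cache[m.smiles])
            except StandardizationError as exc:
                logger.warning("rejected measurement: %s", exc)
                rejected.append((m, str(exc)))
                continue
        accepted.append(m)

    records = aggregate(accepted)
    sigma_models: dict[str, SigmaModel] = {}
    outliers: set[tuple[str, str]] = set()
    kept = records
    for _ in range(1 + max(0, sigma_refits)):
        new_flags: set[tuple[str, str]] = set()
        for ep in ENDPOINTS:
            try:
                model = fit_sigma_model(kept, ep)
            except InsufficientDataError:
                logger.info(
                    "endpoint %s: too few replicated records for outlier removal", ep
                )
                continue
            sigma_models[ep] = model
            new_flags |= flag_outliers(kept, model, k=sigma_k, sigma_floor=sigma_floor)
        if not new_flags:
            break
        outliers |= new_flags
        kept = [r for r in kept if (r.smiles_std, r.endpoint) not in outliers]
    return CurationResult(
        table=build_multitask_table(kept),
        records=kept,
        sigma_models=sigma_models,
        outliers=outliers,
        rejected=rejected,
    )


# ---------------------------------------------------------------------------
# external public datasets


#: Default column layouts for supported external sources.  Values are scaled
#: into 1e-6 cm/s; `unit_scale` multiplies the raw value.
EXTERNAL_LAYOUTS: Mapping[str, dict] = {
    # CycPeptMPDB-style export: permeability in cm/s, Caco-2 only
    "cycpeptmpdb": {
        "smiles_col": "SMILES",
        "value_col": "Permeability",
        "endpoint": "Caco2Papp",
        "unit_scale": 1e6,
    },
    # NMMPDB-style export: values already in 1e-6 cm/s (P_app) or unitless (ER)
    "nmmpdb": {
        "smiles_col": "SMILES",
        "value_col": "Value",
        "endpoint_col": "Endpoint",
        "unit_scale": 1.0,
    },
}


def ingest_external(
    table: pd.DataFrame | str,
    source: str,
    column_map: dict | None = None,
) -> list[RawMeasurement]:
    """Map an external CSV layout onto raw measurements.

    Sentinel permeabilities marking undetectable compounds (e.g. the
    -10e-10 cm/s convention) and any non-positive value are dropped as
    outliers; the rest are unit-normalized to 1e-6 cm/s.
    """
    if source not in EXTERNAL_LAYOUTS:
        raise ValueError(
            f"unknown external source {source!r}; known: {sorted(EXTERNAL_LAYOUTS)}"
        )
    layout = dict(EXTERNAL_LAYOUTS[source])
    if column_map:
        layout.update(column_map)
    if isinstance(table, str):
        table = pd.read_csv(table)

    out: list[RawMeasurement] = []
    n_dropped = 0
    for _, row in table.iterrows():
        value = float(row[layout["value_col"]]) * layout["unit_scale"]
        if value <= 0:
            n_dropped += 1
            continue
        endpoint = layout.get("endpoint") or str(row[layout["endpoint_col"]])
        out.append(
            RawMeasurement(
                smiles=str(row[layout["smiles_col"]]),
                endpoint=endpoint,
                value=value,
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d non-positive/sentinel values", source, n_dropped)
    if not out:
        logger.warning("%s: no valid rows ingested", source)
    return out


# ---------------------------------------------------------------------------
# raw-measurement CSV I/O (shared by CLI and synthetic module)


def measurements_to_frame(measurements: Sequence[RawMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "smiles": [m.smiles for m in measurements],
            "endpoint": [m.endpoint for m in measurements],
            "value": [m.value for m in measurements],
            "qualifier": [m.qualifier for m in measurements],
            "date": [
                "" if m.timestamp is None else m.timestamp.isoformat()
                for m in measurements
            ],
            "modality": [m.modality for m in measurements],
        }
    )


def measurements_from_frame(frame: pd.DataFrame) -> list[RawMeasurement]:
    out = []
    for row in frame.itertuples(index=False):
        raw_qual = getattr(row, "qualifier", "none")
        qual = "none" if raw_qual in ("", None) or pd.isna(raw_qual) else str(raw_qual)
        ts = getattr(row, "date", "")
        out.append(
            RawMeasurement(
                smiles=str(row.smiles),
                endpoint=str(row.endpoint),
                value=float(row.value),
                qualifier=qual,
                timestamp=(
                    None if ts in ("", None) or pd.isna(ts)
                    else date.fromisoformat(str(ts))
                ),
                modality=str(getattr(row, "modality", "unknown")),
            )
        )
    return out
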