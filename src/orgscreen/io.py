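"""Readers, writers and schema validation for screen data.

Three tables drive the analysis:

* **measurements** — long/tidy, one row per organoid per timepoint, with the
  image-derived quantities (masked brightfield area, dead-signal overlap,
  invasive-annulus area and its dead overlap, brightness, texture).
  Plain CSV; areas in µm², time in hours.
* **plate layout** — YAML mapping each well to its role
  (negative_control / positive_control / treatment / baseline), drug regimen,
  replicate and patient. Wells not listed are treated as empty and excluded.
* **clinical** — CSV with one row per patient: progression-free survival in
  months, a censoring flag and the categorical clinical response.

Organoid identity across timepoints is taken as given (tracking happens in
the upstream imaging platform). Well names are normalized to zero-padded
form ("A1" -> "A01").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError

logger = logging.getLogger(__name__)

#: required columns of a measurement table, in canonical order
MEASUREMENT_COLUMNS = [
    "plate_id",
    "well",
    "time_h",
    "organoid_id",
    "bf_area",
    "green_area",
    "inv_area",
    "inv_green_area",
    "brightness",
    "texture",
]

_NUMERIC_COLUMNS = [
    "time_h",
    "bf_area",
    "green_area",
    "inv_area",
    "inv_green_area",
    "brightness",
    "texture",
]

_AREA_COLUMNS = ["bf_area", "green_area", "inv_area", "inv_green_area"]

WELL_ROLES = ("negative_control", "positive_control", "treatment", "baseline")

CLINICAL_COLUMNS = ["patient_id", "pfs_months", "censored", "response_category", "regimen"]

RESPONSE_CATEGORIES = ("good", "mixed", "bad")


def normalize_well(name: str) -> str:
    """Normalize a well name to zero-padded form, e.g. ``"a1" -> "A01"``."""
    name = str(name).strip().upper()
    row, col = name[0], name[1:]
    if not row.isalpha() or not col.isdigit():
        raise SchemaError(f"unparseable well name: {name!r}")
    return f"{row}{int(col):02d}"


def validate_measurements(df: pd.DataFrame, *, clip: bool = True) -> tuple[pd.DataFrame, int]:
    """Validate and normalize a measurement table.

    Checks the schema, coerces numeric columns, rejects negative areas and
    clips dead-signal overlaps to their containing mask area
    (``green_area <= bf_area``, ``inv_green_area <= inv_area``).

    Returns the validated copy and the number of rows whose overlaps were
    clipped. Clipping is idempotent.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table missing required column(s): {', '.join(missing)}")
    out = df[MEASUREMENT_COLUMNS].copy()
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            raise SchemaError(f"non-numeric value in column {col!r} at row index {int(bad.idxmax())}")
        out[col] = coerced.astype(float)
    out["organoid_id"] = pd.to_numeric(out["organoid_id"], errors="raise").astype(int)
    out["well"] = out["well"].map(normalize_well)
    out["plate_id"] = out["plate_id"].astype(str)

    neg = (out[_AREA_COLUMNS] < 0).any(axis=1)
    if neg.any():
        raise SchemaError(f"negative area value at row index {int(neg.idxmax())}")
    if (out["time_h"] < 0).any():
        raise SchemaError("negative time_h value")

    over = (out["green_area"] > out["bf_area"]) | (out["inv_green_area"] > out["inv_area"])
    n_clipped = int(over.sum())
    if n_clipped and clip:
        out["green_area"] = np.minimum(out["green_area"], out["bf_area"])
        out["inv_green_area"] = np.minimum(out["inv_green_area"], out["inv_area"])
        logger.warning("clipped dead-signal overlap to mask area in %d row(s)", n_clipped)
    return out, n_clipped


def read_measurements(path, *, clip: bool = True) -> pd.DataFrame:
    """Read a measurement CSV, validate its schema and clip overlaps."""
    df = pd.read_csv(path)
    out, _ = validate_measurements(df, clip=clip)
    return out


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class WellEntry:
    """Layout annotation for one well."""

    role: str
    drugs: tuple[tuple[str, float], ...] = ()  # (compound, concentration) pairs
    replicate_id: int = 1
    patient_id: str = ""

    @property
    def regimen(self) -> str:
        """Canonical regimen name: compounds joined by '+'; drug-free wells are 'vehicle'."""
        return "+".join(c for c, _ in self.drugs) or "vehicle"

    @property
    def total_conc(self) -> float:
        return float(sum(c for _, c in self.drugs))


@dataclass
class PlateLayout:
    """Mapping well -> :class:`WellEntry` for one plate."""

    plate_id: str
    wells: dict[str, WellEntry] = field(default_factory=dict)

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, e in self.wells.items() if e.role == role)

    @property
    def negative_controls(self) -> list[str]:
        return self.wells_with_role("negative_control")

    @property
    def positive_controls(self) -> list[str]:
        return self.wells_with_role("positive_control")

    def validate(self) -> None:
        for well, entry in self.wells.items():
            if entry.role not in WELL_ROLES:
                raise ConfigError(f"well {well}: unknown role {entry.role!r}")
            if entry.role == "treatment":
                if not entry.drugs or not all(c > 0 for _, c in entry.drugs):
                    raise ConfigError(
                        f"well {well}: treatment wells need >= 1 compound with concentration > 0"
                    )
        if not self.positive_controls:
            raise ConfigError(
                f"plate {self.plate_id}: no positive_control (staurosporine) wells; "
                "NDR normalization is impossible without a positive control"
            )
        if not self.negative_controls:
            raise ConfigError(f"plate {self.plate_id}: no negative_control (vehicle) wells")
        for role in ("negative_control", "positive_control"):
            if len(self.wells_with_role(role)) < 2:
                logger.warning(
                    "plate %s: only %d %s well(s); control anchors will not be averaged",
                    self.plate_id, len(self.wells_with_role(role)), role,
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "well": w,
                "role": e.role,
                "regimen": e.regimen,
                "drugs": ";".join(f"{c}:{conc:g}" for c, conc in e.drugs),
                "total_conc": e.total_conc,
                "replicate_id": e.replicate_id,
                "patient_id": e.patient_id,
            }
            for w, e in sorted(self.wells.items())
        ]
        return pd.DataFrame(rows)


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (duplicate wells)."""


def _no_duplicates(loader, node, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ConfigError(f"duplicate key in layout: {key!r}")
        seen.add(key)
    return yaml.SafeLoader.construct_mapping(loader, node, deep)


_StrictLoader.add_constructor(yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates)


def _parse_drugs(raw) -> tuple[tuple[str, float], ...]:
    if not raw:
        return ()
    drugs = []
    for item in raw:
        if isinstance(item, dict):
            drugs.append((str(item["compound"]), float(item["concentration"])))
        else:  # "compound:conc" shorthand
            compound, conc = str(item).rsplit(":", 1)
            drugs.append((compound, float(conc)))
    return tuple(drugs)


def read_layout(path) -> PlateLayout:
    """Read and validate a plate-layout YAML file.

    Schema::

        plate_id: P1
        wells:
          A01: {role: negative_control, replicate: 1, patient: PDAC002}
          B01:
            role: treatment
            replicate: 1
            patient: PDAC002
            drugs:
              - {compound: gemcitabine, concentration: 400}
              - {compound: paclitaxel, concentration: 80}
    """
    with open(path) as fh:
        raw = yaml.load(fh, Loader=_StrictLoader)
    if not isinstance(raw, dict) or "wells" not in raw:
        raise SchemaError("layout file must be a mapping with a 'wells' key")
    wells = {}
    for name, entry in raw["wells"].items():
        if "role" not in entry:
            raise SchemaError(f"well {name}: missing 'role'")
        wells[normalize_well(name)] = WellEntry(
            role=str(entry["role"]),
            drugs=_parse_drugs(entry.get("drugs")),
            replicate_id=int(entry.get("replicate", 1)),
            patient_id=str(entry.get("patient", "")),
        )
    layout = PlateLayout(plate_id=str(raw.get("plate_id", "plate1")), wells=wells)
    layout.validate()
    return layout


def write_layout(layout: PlateLayout, path) -> None:
    doc = {
        "plate_id": layout.plate_id,
        "wells": {
            w: {
                "role": e.role,
                "replicate": e.replicate_id,
                "patient": e.patient_id,
                **(
                    {"drugs": [{"compound": c, "concentration": conc} for c, conc in e.drugs]}
                    if e.drugs
                    else {}
                ),
            }
            for w, e in sorted(layout.wells.items())
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_clinical(path) -> pd.DataFrame:
    """Read the per-patient clinical table (PFS months, censoring, response category)."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing column(s): {', '.join(missing)}")
    df = df[CLINICAL_COLUMNS].copy()
    df["pfs_months"] = pd.to_numeric(df["pfs_months"])
    df["censored"] = df["censored"].astype(bool)
    bad = ~df["response_category"].isin(RESPONSE_CATEGORIES)
    if bad.any():
        raise SchemaError(
            f"unknown response_category {df.loc[bad, 'response_category'].iloc[0]!r}"
        )
    if (df["pfs_months"] <= 0).any():
        raise SchemaError("pfs_months must be > 0")
    return df


@dataclass
class ValidationReport:
    """Report-only consistency check between measurements and a layout."""

    findings: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        return "\n".join(self.findings) if self.findings else "no findings"


def validate_dataset(measurements: pd.DataFrame, layout: PlateLayout) -> ValidationReport:
    """Cross-check wells and time grids; never mutates its inputs."""
    report = ValidationReport()
    measured = set(measurements["well"].unique())
    declared = set(layout.wells)
    for well in sorted(declared - measured):
        report.findings.append(f"well {well} declared in layout but absent from measurements")
    for well in sorted(measured - declared):
        report.findings.append(f"well {well} measured but not declared in layout (will be excluded)")

    for plate_id, plate_df in measurements.groupby("plate_id"):
        grids = plate_df.groupby("well")["time_h"].agg(lambda t: tuple(sorted(t.unique())))
        if grids.nunique() > 1:
            common = grids.mode().iloc[0]
            offenders = sorted(grids.index[grids != common])
            report.findings.append(
                f"plate {plate_id}: ragged time grids in wells {', '.join(offenders)}"
            )
    return report
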