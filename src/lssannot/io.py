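"""File formats: compound library, feature list, calibrants, config, output.

All files are UTF-8.  Tabular inputs are RFC-4180 CSV with a header row;
the run configuration is a small YAML document; annotations are written as
versioned JSON.  Units are fixed throughout: minutes for all times, Da for
masses, dimensionless natural-log units for (ln kw, S).  Instrument specs
often quote a dwell *volume* instead of a dwell time;
:func:`dwell_time_from_volume` converts (volume / flow rate).

Library CSV columns
    compound_id, name, monoisotopic_mass, ln_kw, S, provenance
    [, iupac, cas, smiles, pathway, xrefs]          (optional metadata)
Feature CSV columns
    mz, rt [, identity, adduct, formula]            (extras ignored)
Calibrant CSV columns
    compound_id, observed_rt_min
Config YAML
    gradient:   phi0, delta_phi, t_gradient_min, t_dead_min, t_dwell_min
    tolerances: mass_ppm, rt_experimental, rt_qsrr   (optional section)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .annotation import Feature, ToleranceConfig
from .lss import PROVENANCE_VALUES, GradientProgram, LSSParams

__all__ = [
    "CompoundRecord",
    "LibraryManifest",
    "LibraryFormatError",
    "FeatureFormatError",
    "ANNOTATION_SCHEMA_VERSION",
    "read_library",
    "write_library",
    "read_features",
    "read_calibrants",
    "read_config",
    "write_config",
    "write_annotations",
    "dwell_time_from_volume",
]

ANNOTATION_SCHEMA_VERSION = "1.0"

_REQUIRED_LIBRARY_COLUMNS = (
    "compound_id",
    "name",
    "monoisotopic_mass",
    "ln_kw",
    "S",
    "provenance",
)
_METADATA_COLUMNS = ("iupac", "cas", "smiles", "pathway", "xrefs")


class LibraryFormatError(ValueError):
    """Malformed compound-library file."""


class FeatureFormatError(ValueError):
    """Malformed feature-list file."""


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry: identity, neutral mass and LSS descriptors."""

    compound_id: str
    name: str
    monoisotopic_mass: float
    lss: LSSParams
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0.0:
            raise ValueError(
                f"monoisotopic_mass must be > 0, got {self.monoisotopic_mass}"
            )


@dataclass(frozen=True)
class LibraryManifest:
    """A validated compound library with per-provenance counts."""

    compounds: tuple[CompoundRecord, ...]

    @property
    def counts_by_provenance(self) -> dict[str, int]:
        counts = {p: 0 for p in PROVENANCE_VALUES}
        for c in self.compounds:
            counts[c.lss.provenance] += 1
        return counts

    def __len__(self) -> int:
        return len(self.compounds)

    def get(self, compound_id: str) -> CompoundRecord:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)


def read_library(path) -> LibraryManifest:
    """Read and validate a compound-library CSV.

    Rows violating an invariant (non-positive mass, negative S, unknown
    provenance) are rejected with their file row number; duplicate ids and
    missing required columns are format errors.
    """
    df = pd.read_csv(path, dtype={"compound_id": str, "name": str})
    missing = [c for c in _REQUIRED_LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryFormatError(f"{path}: missing required column(s) {missing}")
    dupes = df["compound_id"][df["compound_id"].duplicated()].unique()
    if len(dupes):
        raise LibraryFormatError(
            f"{path}: duplicate compound_id value(s): {', '.join(dupes)}"
        )
    compounds = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after the header line
        try:
            lss = LSSParams(
                ln_kw=float(row["ln_kw"]),
                S=float(row["S"]),
                provenance=str(row["provenance"]).strip(),
            )
            meta = {
                c: str(row[c])
                for c in _METADATA_COLUMNS
                if c in df.columns and pd.notna(row[c])
            }
            compounds.append(
                CompoundRecord(
                    compound_id=str(row["compound_id"]),
                    name=str(row["name"]),
                    monoisotopic_mass=float(row["monoisotopic_mass"]),
                    lss=lss,
                    metadata=meta,
                )
            )
        except (ValueError, TypeError) as exc:
            raise LibraryFormatError(f"{path}: row {rownum}: {exc}") from exc
    return LibraryManifest(compounds=tuple(compounds))


def write_library(manifest: LibraryManifest, path) -> None:
    """Write a library CSV; lossless round trip with :func:`read_library`."""
    meta_cols = sorted(
        {k for c in manifest.compounds for k in c.metadata if k in _METADATA_COLUMNS}
    )
    rows = []
    for c in manifest.compounds:
        row = {
            "compound_id": c.compound_id,
            "name": c.name,
            "monoisotopic_mass": repr(c.monoisotopic_mass),
            "ln_kw": repr(c.lss.ln_kw),
            "S": repr(c.lss.S),
            "provenance": c.lss.provenance,
        }
        for k in meta_cols:
            row[k] = c.metadata.get(k, "")
        rows.append(row)
    pd.DataFrame(rows, columns=list(_REQUIRED_LIBRARY_COLUMNS) + meta_cols).to_csv(
        path, index=False
    )


def read_features(path) -> list[Feature]:
    """Read a feature-list CSV, preserving file order.

    Requires ``mz`` and ``rt`` columns; an ``identity`` column, when
    present, populates ``known_identity``.  Other columns (adduct,
    formula, abundance, ...) are ignored.  An empty file (header only)
    yields an empty list.
    """
    df = pd.read_csv(path)
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise FeatureFormatError(f"{path}: missing required column {col!r}")
    features = []
    for idx, row in df.iterrows():
        rownum = idx + 2
        try:
            identity = None
            if "identity" in df.columns and pd.notna(row["identity"]):
                identity = str(row["identity"])
            features.append(
                Feature(mz=float(row["mz"]), rt=float(row["rt"]), known_identity=identity)
            )
        except (ValueError, TypeError) as exc:
            raise FeatureFormatError(f"{path}: row {rownum}: {exc}") from exc
    return features


def read_calibrants(path) -> list[tuple[str, float]]:
    """Read (compound_id, observed_rt_min) calibrant pairs."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    for col in ("compound_id", "observed_rt_min"):
        if col not in df.columns:
            raise FeatureFormatError(f"{path}: missing required column {col!r}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append((str(row["compound_id"]), float(row["observed_rt_min"])))
        except (ValueError, TypeError) as exc:
            raise FeatureFormatError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


def read_config(path) -> tuple[GradientProgram, ToleranceConfig]:
    """Read the gradient + tolerance YAML configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "gradient" not in doc:
        raise FeatureFormatError(f"{path}: config must contain a 'gradient' section")
    grad = doc["gradient"]
    try:
        gradient = GradientProgram(
            phi0=float(grad["phi0"]),
            delta_phi=float(grad["delta_phi"]),
            t_gradient=float(grad["t_gradient_min"]),
            t_dead=float(grad["t_dead_min"]),
            t_dwell=float(grad["t_dwell_min"]),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise FeatureFormatError(f"{path}: invalid gradient section: {exc}") from exc
    tol = doc.get("tolerances", {})
    tolerances = ToleranceConfig(
        tol_mass=float(tol.get("mass_ppm", 5.0)) * 1e-6,
        tol_rt_experimental=float(tol.get("rt_experimental", 0.005)),
        tol_rt_qsrr=float(tol.get("rt_qsrr", 0.05)),
    )
    return gradient, tolerances


def write_config(
    gradient: GradientProgram, tolerances: ToleranceConfig, path
) -> None:
    doc = {
        "gradient": {
            "phi0": gradient.phi0,
            "delta_phi": gradient.delta_phi,
            "t_gradient_min": gradient.t_gradient,
            "t_dead_min": gradient.t_dead,
            "t_dwell_min": gradient.t_dwell,
        },
        "tolerances": {
            "mass_ppm": tolerances.tol_mass * 1e6,
            "rt_experimental": tolerances.tol_rt_experimental,
            "rt_qsrr": tolerances.tol_rt_qsrr,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def _sig6(x: float) -> float:
    """Round to 6 significant digits for byte-stable JSON output."""
    return float(f"{x:.6g}")


def annotations_to_records(features, match_lists, library) -> list[dict]:
    """Build the JSON-ready per-feature annotation records."""
    by_id = {c.compound_id: c for c in library.compounds}
    out = []
    for feat, matches in zip(features, match_lists):
        rec = {
            "feature": {"mz": _sig6(feat.mz), "rt": _sig6(feat.rt)},
            "matches": [
                {
                    "compound_id": m.compound_id,
                    "name": by_id[m.compound_id].name,
                    "adduct": m.adduct_name,
                    "level": m.level,
                    "predicted_rt_min": _sig6(m.predicted_rt),
                    "rel_mass_error_ppm": _sig6(m.rel_mass_error * 1e6),
                    "rel_rt_error_pct": _sig6(m.rel_rt_error * 100.0),
                    "metadata": by_id[m.compound_id].metadata,
                }
                for m in matches
            ],
        }
        out.append(rec)
    return out


def write_annotations(features, match_lists, library, path) -> None:
    """Write the annotation JSON document.

    Top level is an array with one ``{"feature": {...}, "matches": [...]}``
    object per feature (schema version :data:`ANNOTATION_SCHEMA_VERSION`,
    documented in docs/methods.md).  Output is byte-stable for identical
    inputs: sorted keys, floats at 6 significant digits.
    """
    doc = annotations_to_records(features, match_lists, library)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def dwell_time_from_volume(dwell_volume_ml: float, flow_ml_per_min: float) -> float:
    """Dwell time (min) from dwell volume (mL) and flow rate (mL/min)."""
    if flow_ml_per_min <= 0.0:
        raise ValueError("flow rate must be > 0")
    if dwell_volume_ml < 0.0:
        raise ValueError("dwell volume must be >= 0")
    return dwell_volume_ml / flow_ml_per_min
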