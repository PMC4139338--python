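"""Build the model's feature matrix from FreeSurfer-style regional tables.

The pipeline mirrors standard ROI practice for dementia staging: regional
volumes are normalized by intracranial volume (ICV), cortical thicknesses
are left in mm, left/right homologues are averaged, and a small set of
unreliable regions (vessel, choroid plexus, optic chiasm, white-matter
hypointensities) is excluded.  With the default ROI configuration this
yields 57 features per subject: 34 averaged cortical thicknesses and 23
volumes.

The exact ROI composition is a configuration, not a constant: edit or
replace :data:`DEFAULT_ROI_CONFIG` (or a YAML copy of it) to change the
region set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RawRegionTable",
    "FeatureMatrix",
    "build_features",
    "standardize",
    "DEFAULT_ROI_CONFIG",
    "read_raw_wide",
    "read_raw_long",
    "load_roi_config",
]

# Desikan-Killiany cortical parcellation: 34 paired thickness regions.
DK_THICKNESS_REGIONS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

# Default editable ROI composition: 34 thickness pairs + 21 volume pairs
# + 2 midline volumes = 57 features; the six excluded volumes are the
# standard unreliable segmentations.
DEFAULT_ROI_CONFIG: dict = {
    "thickness_paired": list(DK_THICKNESS_REGIONS),
    "volume_paired": [
        "Lateral-Ventricle", "Inf-Lat-Vent", "Cerebellum-White-Matter",
        "Cerebellum-Cortex", "Thalamus-Proper", "Caudate", "Putamen",
        "Pallidum", "Hippocampus", "Amygdala", "Accumbens-area", "VentralDC",
        "Cerebral-White-Matter", "Cerebral-Cortex", "Frontal-White-Matter",
        "Temporal-White-Matter", "Parietal-White-Matter",
        "Occipital-White-Matter", "Cingulate-White-Matter",
        "Insula-White-Matter", "Basal-Forebrain",
    ],
    "volume_midline": ["3rd-Ventricle", "4th-Ventricle"],
    "excluded": [
        "WM-hypointensities", "Optic-Chiasm", "vessel", "choroid-plexus",
    ],
    "excluded_paired": ["vessel", "choroid-plexus"],
    "icv_column": "EstimatedTotalIntraCranialVol",
    "sd_convention": "population",
}

_HEMI_PREFIXES = (("Left-", "lh"), ("Right-", "rh"), ("lh_", "lh"), ("rh_", "rh"))


@dataclass
class RawRegionTable:
    """One subject's regional measures plus intracranial volume.

    ``measures`` maps raw region names (hemisphere-tagged, e.g.
    ``Left-Hippocampus`` or ``lh_bankssts``) to values: thickness in mm,
    volume in mm^3.
    """

    subject_id: str
    measures: dict[str, float]
    icv: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.icv) or self.icv <= 0:
            raise ValueError(
                f"subject {self.subject_id}: ICV must be positive, got {self.icv}"
            )
        bad = [k for k, v in self.measures.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"subject {self.subject_id}: non-finite measures {bad}")


@dataclass
class FeatureMatrix:
    """N x M feature values with names, subject ids, and scaling provenance."""

    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    standardization: dict | str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("values shape must be (n_subjects, n_features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing/non-finite values")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, index=False)
        sidecar = {
            "feature_names": self.feature_names,
            "standardization": self.standardization,
        }
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        ids = df["subject_id"].astype(str).tolist()
        names = [c for c in df.columns if c != "subject_id"]
        std: dict | str = "raw"
        sidecar = Path(path).with_suffix(".json")
        if sidecar.exists():
            std = json.loads(sidecar.read_text()).get("standardization", "raw")
        return cls(df[names].to_numpy(float), names, ids, std)


def _split_hemi(name: str) -> tuple[str, str | None]:
    for prefix, hemi in _HEMI_PREFIXES:
        if name.startswith(prefix):
            return name[len(prefix):], hemi
    return name, None


def build_features(
    tables: list[RawRegionTable],
    exclusion_list: list[str] | None = None,
    volume_names: list[str] | None = None,
) -> FeatureMatrix:
    """Assemble the per-subject feature vector from raw regional tables.

    Volumes (any region whose base name is in ``volume_names``) are divided
    by the subject's ICV *before* left/right averaging; thicknesses are
    averaged unscaled.  Regions whose base name appears in
    ``exclusion_list`` are dropped.  Columns are sorted by feature name so
    the output order is deterministic.

    Raises if a paired region is missing its hemisphere partner (error names
    the subject and region).  An excluded region absent from the data only
    warns.
    """
    if not tables:
        raise ValueError("no subjects provided")
    excluded = set(exclusion_list or [])
    volumes = set(volume_names or [])

    seen_bases: set[str] = set()
    rows: list[dict[str, float]] = []
    for t in tables:
        grouped: dict[str, dict[str | None, float]] = {}
        for raw_name, value in t.measures.items():
            base, hemi = _split_hemi(raw_name)
            grouped.setdefault(base, {})[hemi] = value
        seen_bases |= set(grouped)
        feats: dict[str, float] = {}
        for base, by_hemi in grouped.items():
            if base in excluded:
                continue
            vals = []
            if None in by_hemi:  # midline region
                if len(by_hemi) > 1:
                    raise ValueError(
                        f"subject {t.subject_id}: region {base} mixes midline "
                        "and hemisphere entries"
                    )
                vals = [by_hemi[None]]
            else:
                if set(by_hemi) != {"lh", "rh"}:
                    missing = {"lh", "rh"} - set(by_hemi)
                    raise ValueError(
                        f"subject {t.subject_id}: region {base} missing "
                        f"hemisphere {sorted(missing)}"
                    )
                vals = [by_hemi["lh"], by_hemi["rh"]]
            if base in volumes:
                vals = [v / t.icv for v in vals]
            feats[base] = float(np.mean(vals))
        rows.append(feats)

    not_found = excluded - seen_bases
    if not_found:
        warnings.warn(f"excluded regions not present in data: {sorted(not_found)}")

    names = sorted(rows[0])
    for t, r in zip(tables, rows):
        if sorted(r) != names:
            raise ValueError(
                f"subject {t.subject_id}: inconsistent region set with first subject"
            )
    values = np.array([[r[n] for n in names] for r in rows])
    return FeatureMatrix(values, names, [t.subject_id for t in tables])


def standardize(
    fm: FeatureMatrix, stats: dict | None = None
) -> FeatureMatrix:
    """Z-score features; fitting-set statistics are recorded and reusable.

    When ``stats`` is omitted it is computed from ``fm`` (population SD,
    i.e. divide by N) and stored in the result.  Passing recorded training
    statistics is the only legal path for test data.
    """
    if stats is None:
        mean = fm.values.mean(axis=0)
        sd = fm.values.std(axis=0, ddof=0)
        stats = {
            "feature_names": list(fm.feature_names),
            "mean": mean.tolist(),
            "sd": sd.tolist(),
            "sd_convention": "population",
        }
    else:
        if list(stats["feature_names"]) != list(fm.feature_names):
            raise ValueError("standardization stats feature names do not match")
        mean = np.asarray(stats["mean"], dtype=float)
        sd = np.asarray(stats["sd"], dtype=float)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero variance feature(s): {[fm.feature_names[i] for i in zero]}"
        )
    return FeatureMatrix(
        (fm.values - mean) / sd,
        list(fm.feature_names),
        list(fm.subject_ids),
        standardization=stats,
    )


def read_raw_wide(
    path: str | Path,
    icv_column: str = "EstimatedTotalIntraCranialVol",
    subject_column: str = "subject_id",
) -> list[RawRegionTable]:
    """One row per subject; every non-id, non-ICV column is a raw measure."""
    df = pd.read_csv(path, sep=None, engine="python")
    if subject_column not in df.columns:
        raise ValueError(f"missing subject column {subject_column!r}")
    if icv_column not in df.columns:
        raise ValueError(f"missing ICV column {icv_column!r}")
    measure_cols = [c for c in df.columns if c not in (subject_column, icv_column)]
    return [
        RawRegionTable(
            subject_id=str(row[subject_column]),
            measures={c: float(row[c]) for c in measure_cols},
            icv=float(row[icv_column]),
        )
        for _, row in df.iterrows()
    ]


def read_raw_long(
    path: str | Path,
    icv_region: str = "EstimatedTotalIntraCranialVol",
) -> list[RawRegionTable]:
    """Long format: columns subject_id, region, value; ICV appears as a region row."""
    df = pd.read_csv(path, sep=None, engine="python")
    needed = {"subject_id", "region", "value"}
    if not needed <= set(df.columns):
        raise ValueError(f"long format requires columns {sorted(needed)}")
    tables = []
    for sid, grp in df.groupby("subject_id", sort=True):
        measures = dict(zip(grp["region"].astype(str), grp["value"].astype(float)))
        if icv_region not in measures:
            raise ValueError(f"subject {sid}: no ICV row ({icv_region})")
        icv = measures.pop(icv_region)
        tables.append(RawRegionTable(str(sid), measures, icv))
    return tables


def load_roi_config(path: str | Path | None = None) -> dict:
    """Load an ROI composition from YAML, or return a copy of the default."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_ROI_CONFIG))
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    merged = json.loads(json.dumps(DEFAULT_ROI_CONFIG))
    merged.update(cfg or {})
    return merged


def roi_feature_names(config: dict) -> list[str]:
    """Feature names implied by an ROI configuration, in output order."""
    kept = (
        list(config["thickness_paired"])
        + list(config["volume_paired"])
        + list(config["volume_midline"])
    )
    return sorted(set(kept) - set(config["excluded"]))


def roi_volume_names(config: dict) -> list[str]:
    return sorted(
        set(config["volume_paired"])
        | set(config["volume_midline"])
        | set(config["excluded"])
    )
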