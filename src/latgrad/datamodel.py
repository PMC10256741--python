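"""Shared data model and tabular I/O.

All on-disk formats are UTF-8 tab-separated tables with a header row.
Region identifiers are opaque integers; hemisphere membership is always
explicit in the atlas and never inferred from the id itself.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The seven canonical resting-state networks used throughout the pipeline,
#: ordered roughly from unimodal to association cortex.
CANONICAL_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)

UNIMODAL_NETWORKS = ("visual", "somatomotor")

RELATIONS = ("MZ_twin", "DZ_twin", "full_sibling", "singleton")

#: Edinburgh-style handedness score below which a subject counts as left-handed.
HANDEDNESS_CUTOFF = 30.0


class DataValidationError(ValueError):
    """A table violated one of the structural invariants of the data model."""


class AtlasValidationError(DataValidationError):
    pass


class PedigreeValidationError(DataValidationError):
    pass


# ---------------------------------------------------------------------------
# Region atlas
# ---------------------------------------------------------------------------

ATLAS_COLUMNS = (
    "region_id",
    "hemisphere",
    "homotopic_partner",
    "network",
    "is_language_roi",
    "is_hub",
)


@dataclass(eq=False)
class RegionAtlas:
    """Region bookkeeping: hemisphere, homotopic pairing, network, language flags.

    The row order of ``table`` is the canonical region order: every per-region
    array in the package (time-series rows, task betas, gradient values) is
    aligned to it.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self._validate()
        ids = self.table["region_id"].to_numpy()
        self._pos = {int(r): i for i, r in enumerate(ids)}

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        t = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in t.columns]
        if missing:
            raise AtlasValidationError(f"atlas is missing columns {missing}")
        if t["region_id"].duplicated().any():
            dup = t.loc[t["region_id"].duplicated(), "region_id"].tolist()
            raise AtlasValidationError(f"duplicate region ids {dup}")
        bad_hemi = set(t["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise AtlasValidationError(f"unknown hemisphere labels {sorted(bad_hemi)}")
        bad_net = set(t["network"]) - set(CANONICAL_NETWORKS)
        if bad_net:
            raise AtlasValidationError(f"unknown network labels {sorted(bad_net)}")
        ids = dict(zip(t["region_id"].astype(int), t["hemisphere"]))
        for rid, partner, hemi in zip(
            t["region_id"].astype(int), t["homotopic_partner"].astype(int), t["hemisphere"]
        ):
            if partner not in ids:
                raise AtlasValidationError(f"region {rid}: partner {partner} not in atlas")
            if ids[partner] == hemi:
                raise AtlasValidationError(
                    f"region {rid}: homotopic partner {partner} is in the same hemisphere"
                )
        partner_of = dict(zip(t["region_id"].astype(int), t["homotopic_partner"].astype(int)))
        for rid, partner in partner_of.items():
            if partner_of[partner] != rid:
                raise AtlasValidationError(
                    f"homotopic pairing is not a bijection: partner of partner of region "
                    f"{rid} is {partner_of[partner]}"
                )
        lang = t["is_language_roi"].astype(bool)
        hub = t["is_hub"].astype(bool)
        if (hub & ~lang).any():
            bad = t.loc[hub & ~lang, "region_id"].tolist()
            raise AtlasValidationError(f"hub regions not flagged as language ROIs: {bad}")
        n_l = int((lang & (t["hemisphere"] == "L")).sum())
        n_r = int((lang & (t["hemisphere"] == "R")).sum())
        if n_l != n_r:
            raise AtlasValidationError(
                f"language ROI count differs between hemispheres (L={n_l}, R={n_r})"
            )

    # -- convenience views -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy(dtype=int)

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy(dtype=object)

    @property
    def networks(self) -> np.ndarray:
        return self.table["network"].to_numpy(dtype=object)

    @property
    def is_language(self) -> np.ndarray:
        return self.table["is_language_roi"].to_numpy(dtype=bool)

    @property
    def is_hub(self) -> np.ndarray:
        return self.table["is_hub"].to_numpy(dtype=bool)

    @property
    def left_mask(self) -> np.ndarray:
        return self.hemispheres == "L"

    @property
    def right_mask(self) -> np.ndarray:
        return self.hemispheres == "R"

    @property
    def partner_positions(self) -> np.ndarray:
        """Positional index of each region's homotopic partner."""
        return np.array(
            [self._pos[int(p)] for p in self.table["homotopic_partner"]], dtype=int
        )

    def position(self, region_id: int) -> int:
        return self._pos[int(region_id)]


def read_atlas(path: str | Path) -> RegionAtlas:
    """Read and validate a region atlas TSV."""
    df = pd.read_csv(path, sep="\t")
    return RegionAtlas(df)


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Subject-level functional data
# ---------------------------------------------------------------------------


@dataclass
class SubjectFunctionalData:
    """Per-subject BOLD scans, task-contrast betas and covariates.

    ``scans`` are region x time arrays in atlas row order; ``task_betas`` is a
    per-region vector of story-minus-math style contrast coefficients.
    """

    subject_id: str
    scans: list[np.ndarray]
    task_betas: np.ndarray
    covariates: dict = field(default_factory=dict)

    def validate(self, atlas: RegionAtlas) -> None:
        if len(self.scans) < 1:
            raise DataValidationError(f"subject {self.subject_id}: no scans")
        for k, scan in enumerate(self.scans):
            if scan.ndim != 2 or scan.shape[0] != atlas.n_regions:
                raise DataValidationError(
                    f"subject {self.subject_id} scan {k}: expected "
                    f"{atlas.n_regions} region rows, got shape {scan.shape}"
                )
        if np.asarray(self.task_betas).shape != (atlas.n_regions,):
            raise DataValidationError(
                f"subject {self.subject_id}: task betas must be one value per region"
            )


def hemisphere_swap(subject: SubjectFunctionalData, atlas: RegionAtlas) -> SubjectFunctionalData:
    """Return a mirrored copy of a subject: every region's data is exchanged
    with its homotopic partner. Used for antisymmetry checks."""
    perm = atlas.partner_positions
    return SubjectFunctionalData(
        subject_id=subject.subject_id + "_mirrored",
        scans=[scan[perm, :].copy() for scan in subject.scans],
        task_betas=np.asarray(subject.task_betas)[perm].copy(),
        covariates=dict(subject.covariates),
    )


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

PEDIGREE_COLUMNS = ("family_id", "subject_id", "relation", "twin_pair_id")


@dataclass(eq=False)
class Pedigree:
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        t = self.table
        missing = [c for c in ("family_id", "subject_id", "relation") if c not in t.columns]
        if missing:
            raise PedigreeValidationError(f"pedigree is missing columns {missing}")
        if "twin_pair_id" not in t.columns:
            t["twin_pair_id"] = pd.NA
        if len(t) == 0:
            warnings.warn("pedigree is empty", stacklevel=3)
            return
        if t["subject_id"].duplicated().any():
            dup = t.loc[t["subject_id"].duplicated(), "subject_id"].tolist()
            raise PedigreeValidationError(f"duplicate subject ids {dup}")
        bad = set(t["relation"]) - set(RELATIONS)
        if bad:
            raise PedigreeValidationError(f"unknown relation labels {sorted(bad)}")
        twins = t[t["relation"].isin(["MZ_twin", "DZ_twin"])]
        if twins["twin_pair_id"].isna().any():
            raise PedigreeValidationError("twin rows must carry a twin_pair_id")
        for pid, grp in twins.groupby("twin_pair_id"):
            if len(grp) != 2:
                raise PedigreeValidationError(
                    f"twin pair {pid} has {len(grp)} members (expected exactly 2)"
                )
            if grp["family_id"].nunique() != 1:
                raise PedigreeValidationError(f"twin pair {pid} spans multiple families")
            if grp["relation"].nunique() != 1:
                raise PedigreeValidationError(f"twin pair {pid} mixes MZ and DZ labels")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy(dtype=object)

    @property
    def n_subjects(self) -> int:
        return len(self.table)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "subject_id": str, "twin_pair_id": str})
    return Pedigree(df)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

BASE_COVARIATE_COLUMNS = ("subject_id", "age", "sex", "handedness_score", "intracranial_volume")
DERIVED_COVARIATE_COLUMNS = ("sex_female", "is_left_handed", "age2", "age_x_sex", "age2_x_sex")


def derive_covariates(df: pd.DataFrame, cutoff: float = HANDEDNESS_CUTOFF) -> pd.DataFrame:
    """Append the derived covariate columns (handedness class from the score
    cut, age^2 and the age-by-sex products) to a base covariate table."""
    missing = [c for c in BASE_COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"covariate table is missing columns {missing}")
    out = df.copy()
    out["sex_female"] = (out["sex"].astype(str) == "F").astype(int)
    out["is_left_handed"] = (out["handedness_score"].astype(float) < cutoff).astype(int)
    out["age2"] = out["age"].astype(float) ** 2
    out["age_x_sex"] = out["age"].astype(float) * out["sex_female"]
    out["age2_x_sex"] = out["age2"] * out["sex_female"]
    return out


@dataclass(eq=False)
class CovariateTable:
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        missing = [
            c
            for c in BASE_COVARIATE_COLUMNS + DERIVED_COVARIATE_COLUMNS
            if c not in self.table.columns
        ]
        if missing:
            raise DataValidationError(f"covariate table is missing columns {missing}")
        check = derive_covariates(self.table[list(BASE_COVARIATE_COLUMNS)])
        for col in DERIVED_COVARIATE_COLUMNS:
            got = self.table[col].to_numpy(dtype=float)
            want = check[col].to_numpy(dtype=float)
            if not np.allclose(got, want, rtol=1e-12, atol=1e-12):
                raise DataValidationError(
                    f"derived covariate column {col!r} is not an exact function of the base columns"
                )

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy(dtype=object)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "sex_female" not in df.columns:
        df = derive_covariates(df)
    return CovariateTable(df)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

FLOAT_FORMAT = "%.12g"


def config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config, sort_keys=True, default=str) if config is not None else ""
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    manifest_name: str = "manifest.json",
) -> dict:
    """Write one TSV per named table plus a JSON manifest.

    Numeric columns are formatted deterministically so re-running with the
    same inputs reproduces byte-identical files.
    """
    if not tables:
        raise DataValidationError("no result tables to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(config), "files": {}}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][name] = {
            "path": path.name,
            "rows": int(len(df)),
            "sha256": digest,
        }
    with open(out_dir / manifest_name, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Time-series files
# ---------------------------------------------------------------------------


def write_timeseries(
    scan: np.ndarray, region_ids: Sequence[int], path: str | Path, float_format: str = "%.8g"
) -> None:
    """Write one region x time scan as a TSV with region_id as first column."""
    n, t = scan.shape
    df = pd.DataFrame(scan, columns=[f"t{j}" for j in range(t)])
    df.insert(0, "region_id", list(region_ids))
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_timeseries(path: str | Path, atlas: RegionAtlas) -> np.ndarray:
    """Read a scan TSV and return it in atlas row order."""
    df = pd.read_csv(path, sep="\t")
    if "region_id" not in df.columns:
        raise DataValidationError(f"{path}: missing region_id column")
    order = [atlas.position(int(r)) for r in df["region_id"]]
    if sorted(order) != list(range(atlas.n_regions)):
        raise DataValidationError(f"{path}: regions do not match the atlas")
    values = df.drop(columns="region_id").to_numpy(dtype=float)
    out = np.empty_like(values)
    out[order, :] = values
    return out
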