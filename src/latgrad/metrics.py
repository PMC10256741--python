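"""The five functional metrics of language-network organization.

Per subject: the task-contrast asymmetry at network and hub level (L-R),
the homotopic inter-hemispheric connectivity of the language ROIs in
Fisher-z units, and the sum and asymmetry of the within-hemisphere language
connectivity strength. Connectivity matrices are Pearson correlations
averaged across scans in Fisher-z space and back-transformed with tanh.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .datamodel import RegionAtlas, SubjectFunctionalData

__all__ = [
    "ConnectivityMatrix",
    "LanguageFeatureVector",
    "FEATURE_NAMES",
    "build_connectivity",
    "task_asymmetry",
    "strength_metrics",
    "homotopic_connectivity",
    "compute_language_features",
    "features_table",
]

FEATURE_NAMES = (
    "beta_network_asym",
    "beta_hubs_asym",
    "interhemi_rz",
    "strength_sum",
    "strength_asym",
)

#: |r| is capped at 1 - R_CLIP before the Fisher transform so degenerate
#: (perfectly correlated) inputs keep a finite z.
R_CLIP = 1e-7


class MetricsError(ValueError):
    pass


@dataclass
class ConnectivityMatrix:
    """Scan-averaged correlation matrix; diagonal stored as 0 and excluded
    from every downstream sum. ``values = tanh(z_values)`` entrywise."""

    values: np.ndarray
    z_values: np.ndarray
    n_scans_averaged: int


def build_connectivity(scans: Sequence[np.ndarray], clip: float = R_CLIP) -> ConnectivityMatrix:
    """Pearson correlations per scan, Fisher-z averaged across scans, then
    back-transformed with tanh."""
    if len(scans) < 1:
        raise MetricsError("need at least one scan")
    n = scans[0].shape[0]
    z_sum = np.zeros((n, n))
    for k, scan in enumerate(scans):
        scan = np.asarray(scan, dtype=float)
        if scan.shape[0] != n:
            raise MetricsError(
                f"scan {k} has {scan.shape[0]} regions, scan 0 has {n}"
            )
        if scan.shape[1] < 3:
            raise MetricsError(f"scan {k}: need at least 3 time points")
        sd = scan.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise MetricsError(
                f"scan {k}: constant time series for region row(s) {dead.tolist()}"
            )
        r = np.corrcoef(scan)
        r = np.clip(r, -(1.0 - clip), 1.0 - clip)
        z_sum += np.arctanh(r)
    z = z_sum / len(scans)
    np.fill_diagonal(z, 0.0)
    values = np.tanh(z)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, z_values=z, n_scans_averaged=len(scans))


def task_asymmetry(
    betas: np.ndarray, atlas: RegionAtlas, roi_set: Literal["network", "hubs"] = "network"
) -> float:
    """Mean task beta over the flagged left ROIs minus the flagged right ROIs."""
    betas = np.asarray(betas, dtype=float)
    if roi_set == "network":
        mask = atlas.is_language
    elif roi_set == "hubs":
        mask = atlas.is_hub
    else:
        raise MetricsError(f"unknown roi_set {roi_set!r}")
    left = mask & atlas.left_mask
    right = mask & atlas.right_mask
    if not left.any() or not right.any():
        raise MetricsError(f"roi_set {roi_set!r} is empty in one hemisphere")
    return float(betas[left].mean() - betas[right].mean())


def strength_metrics(conn: ConnectivityMatrix, atlas: RegionAtlas) -> tuple[float, float]:
    """Language-network strength (degree centrality) per hemisphere.

    Each language ROI's strength is the sum of its r values to the other
    language ROIs of the same hemisphere (self excluded); strengths are
    averaged within hemisphere. Returns (L + R, L - R).
    """
    sums = {}
    for hemi_mask, hemi in ((atlas.left_mask, "L"), (atlas.right_mask, "R")):
        pos = np.flatnonzero(atlas.is_language & hemi_mask)
        if pos.size < 2:
            raise MetricsError(f"need at least 2 language ROIs in hemisphere {hemi}")
        block = conn.values[np.ix_(pos, pos)]
        sums[hemi] = float(block.sum(axis=1).mean())  # diagonal is 0
    return sums["L"] + sums["R"], sums["L"] - sums["R"]


def homotopic_connectivity(conn: ConnectivityMatrix, atlas: RegionAtlas) -> float:
    """Mean Fisher-z correlation across the language homotopic region pairs."""
    left_lang = np.flatnonzero(atlas.is_language & atlas.left_mask)
    partner = atlas.partner_positions[left_lang]
    if not atlas.is_language[partner].all():
        bad = atlas.region_ids[left_lang[~atlas.is_language[partner]]].tolist()
        raise MetricsError(f"language ROIs without a language homotopic partner: {bad}")
    return float(conn.z_values[left_lang, partner].mean())


@dataclass
class LanguageFeatureVector:
    """The five per-subject metrics driving the lateralization phenotype."""

    beta_network_asym: float
    beta_hubs_asym: float
    interhemi_rz: float
    strength_sum: float
    strength_asym: float

    def as_series(self, subject_id: str | None = None) -> pd.Series:
        s = pd.Series(
            [getattr(self, f) for f in FEATURE_NAMES], index=list(FEATURE_NAMES)
        )
        if subject_id is not None:
            s.name = subject_id
        return s

    def __post_init__(self) -> None:
        for f in FEATURE_NAMES:
            if not np.isfinite(getattr(self, f)):
                raise MetricsError(f"non-finite feature {f}")


def compute_language_features(
    subject: SubjectFunctionalData, atlas: RegionAtlas, clip: float = R_CLIP
) -> LanguageFeatureVector:
    subject.validate(atlas)
    conn = build_connectivity(subject.scans, clip=clip)
    s_sum, s_asym = strength_metrics(conn, atlas)
    return LanguageFeatureVector(
        beta_network_asym=task_asymmetry(subject.task_betas, atlas, "network"),
        beta_hubs_asym=task_asymmetry(subject.task_betas, atlas, "hubs"),
        interhemi_rz=homotopic_connectivity(conn, atlas),
        strength_sum=s_sum,
        strength_asym=s_asym,
    )


def features_table(
    subjects: Iterable[SubjectFunctionalData], atlas: RegionAtlas, clip: float = R_CLIP
) -> pd.DataFrame:
    """Per-subject feature table (subject_id + the five metric columns)."""
    rows = []
    for s in subjects:
        fv = compute_language_features(s, atlas, clip=clip)
        row = {"subject_id": s.subject_id}
        row.update({f: getattr(fv, f) for f in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", *FEATURE_NAMES])
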