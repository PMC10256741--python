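"""Synthetic twin-cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* a latent 1-D "gradient" coordinate per region (unimodal -> association
  within each hemisphere, identical across hemispheres) that shapes the
  region-by-region BOLD covariance through an exponential-decay kernel;
* homotopic inter-hemispheric coupling and within-network coupling;
* three lateralization groups (strong typical / mild typical / atypical)
  whose task-contrast asymmetries in the language ROIs follow the configured
  group effect sizes, with the connectivity of the left (typical) or right
  (atypical) language block boosted accordingly;
* an additive-genetic latent asymmetry score shared within families
  (MZ covariance h2, DZ/sibling covariance h2/2) which drives both group
  membership and within-group effect magnitude, so the phenotype is
  heritable by construction.

Nothing hemodynamic is modeled: scans are draws from a zero-mean Gaussian
process with the constructed covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CANONICAL_NETWORKS,
    CovariateTable,
    Pedigree,
    RegionAtlas,
    SubjectFunctionalData,
    derive_covariates,
    read_atlas,
    read_covariates,
    read_pedigree,
    read_timeseries,
    write_atlas,
    write_covariates,
    write_pedigree,
    write_timeseries,
)
from .heritability import kinship_matrix

__all__ = [
    "GROUPS",
    "GroupEffect",
    "PedigreeSpec",
    "CohortConfig",
    "CohortBundle",
    "make_atlas",
    "make_pedigree",
    "simulate_heritable_trait",
    "build_region_covariance",
    "simulate_timeseries",
    "simulate_task_betas",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Phenotype groups ordered by decreasing leftward asymmetry.
GROUPS = ("strong_typical", "mild_typical", "atypical")


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GroupEffect:
    """Per-group effect sizes, in the units of the downstream metrics.

    beta_network / beta_hub: mean L-R task-beta asymmetry (contrast units).
    strength_sym: connectivity boost applied to both language blocks (r units).
    strength_asym: additional boost to the dominant-hemisphere language block.
    homotopic: extra coupling on language homotopic pairs.
    """

    beta_network: float
    beta_hub: float
    strength_sym: float = 0.0
    strength_asym: float = 0.0
    homotopic: float = 0.0


# Group task-effect means follow the reported group profiles: strong typical
# 1.74 (network) / 2.64 (hubs), mild typical 0.70 / 1.17, atypical -0.96 / -1.16.
# Resting-state boosts reproduce the qualitative pattern: typical groups are
# left-dominant in language strength, the atypical group is bilateral, and the
# mild group has weaker overall language connectivity and homotopic coupling.
DEFAULT_EFFECTS: Mapping[str, GroupEffect] = {
    "strong_typical": GroupEffect(1.74, 2.64, strength_sym=0.10, strength_asym=0.14, homotopic=0.12),
    "mild_typical": GroupEffect(0.70, 1.17, strength_sym=0.00, strength_asym=0.10, homotopic=0.00),
    "atypical": GroupEffect(-0.96, -1.16, strength_sym=0.10, strength_asym=0.00, homotopic=0.12),
}


@dataclass(frozen=True)
class PedigreeSpec:
    n_mz_pairs: int
    n_dz_pairs: int
    n_sib_pairs: int
    n_singletons: int

    @property
    def n_subjects(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs + self.n_sib_pairs) + self.n_singletons


def default_pedigree_spec(n_subjects: int) -> PedigreeSpec:
    """HCP-like family composition: roughly 26% MZ twins, 14% DZ twins,
    48% non-twin sib-pair members, the remainder unrelated singletons."""
    n_mz = int(round(0.13 * n_subjects))
    n_dz = int(round(0.07 * n_subjects))
    n_sib = int(round(0.24 * n_subjects))
    n_single = n_subjects - 2 * (n_mz + n_dz + n_sib)
    while n_single < 0:
        n_sib -= 1
        n_single += 2
    return PedigreeSpec(n_mz, n_dz, n_sib, n_single)


@dataclass
class CohortConfig:
    n_subjects: int = 120
    group_proportions: tuple[float, float, float] = (0.48, 0.44, 0.08)
    n_regions_per_hemisphere: int = 40
    n_language_rois: int = 9
    n_hubs: int = 2
    ts_length: int = 200
    n_scans: int = 4
    homotopic_coupling: float = 0.35
    within_network_coupling: float = 0.10
    within_hemisphere_base: float = 0.65
    cross_hemisphere_base: float = 0.30
    gradient_bandwidth: float = 0.20
    beta_effects: Mapping[str, GroupEffect] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    beta_noise_sd: float = 0.25
    h2_asym: float = 0.30
    within_group_scale: float = 0.10
    pedigree: PedigreeSpec | None = None
    # Optional latent-coordinate injection: add `inject_offset` to the latent
    # coordinate of the left-hemisphere regions of `inject_network`, for the
    # groups listed (None = all groups).
    inject_network: str | None = None
    inject_offset: float = 0.0
    inject_groups: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise CohortConfigError("n_subjects must be nonnegative")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise CohortConfigError("group proportions must sum to 1")
        if not 0.0 <= self.h2_asym < 1.0:
            raise CohortConfigError("h2_asym must be in [0, 1)")
        for name, val in (
            ("homotopic_coupling", self.homotopic_coupling),
            ("within_network_coupling", self.within_network_coupling),
            ("within_hemisphere_base", self.within_hemisphere_base),
            ("cross_hemisphere_base", self.cross_hemisphere_base),
        ):
            if not 0.0 <= val < 1.0:
                raise CohortConfigError(f"{name} must be in [0, 1)")
        if self.gradient_bandwidth <= 0:
            raise CohortConfigError("gradient_bandwidth must be positive")
        if self.n_language_rois < 2 or self.n_language_rois > self.n_regions_per_hemisphere:
            raise CohortConfigError("need between 2 and n_regions_per_hemisphere language ROIs")
        if self.n_hubs < 1 or self.n_hubs >= self.n_language_rois:
            raise CohortConfigError("n_hubs must be >= 1 and < n_language_rois")
        if self.inject_network is not None and self.inject_network not in CANONICAL_NETWORKS:
            raise CohortConfigError(f"unknown injection network {self.inject_network!r}")
        for g in self.beta_effects:
            if g not in GROUPS:
                raise CohortConfigError(f"unknown group {g!r} in beta_effects")

    def pedigree_spec(self) -> PedigreeSpec:
        return self.pedigree if self.pedigree is not None else default_pedigree_spec(self.n_subjects)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_effects"] = {k: asdict(v) if isinstance(v, GroupEffect) else v
                             for k, v in self.beta_effects.items()}
        return d


# ---------------------------------------------------------------------------
# Atlas and pedigree construction
# ---------------------------------------------------------------------------


def make_atlas(
    n_per_hemisphere: int = 40, n_language: int = 9, n_hubs: int = 2
) -> tuple[RegionAtlas, np.ndarray]:
    """Build a symmetric two-hemisphere atlas plus the latent gradient
    coordinate of every region.

    Regions are ordered left hemisphere first, by ascending latent coordinate
    (equally spaced in [0, 1], identical across hemispheres). The seven
    canonical networks occupy contiguous stretches of the latent axis from
    unimodal to association cortex; the language ROIs are the association-end
    regions, with the first and the middle language ROI flagged as hubs
    (frontal and temporal hub analogues).
    """
    n = n_per_hemisphere
    if n < len(CANONICAL_NETWORKS):
        raise CohortConfigError("need at least one region per network and hemisphere")
    g_hemi = np.linspace(0.0, 1.0, n)
    blocks = np.array_split(np.arange(n), len(CANONICAL_NETWORKS))
    network_of = np.empty(n, dtype=object)
    for net, idx in zip(CANONICAL_NETWORKS, blocks):
        network_of[idx] = net
    lang_idx = np.arange(n - n_language, n)
    hub_idx = {lang_idx[0], lang_idx[len(lang_idx) // 2]}
    if n_hubs > 2:
        extra = [i for i in lang_idx if i not in hub_idx]
        hub_idx.update(extra[: n_hubs - 2])
    rows = []
    for hemi, offset in (("L", 0), ("R", 1000)):
        for i in range(n):
            rid = offset + i + 1
            partner = (1000 if hemi == "L" else 0) + i + 1
            rows.append(
                {
                    "region_id": rid,
                    "hemisphere": hemi,
                    "homotopic_partner": partner,
                    "network": network_of[i],
                    "is_language_roi": bool(i in set(lang_idx)),
                    "is_hub": bool(i in hub_idx),
                }
            )
    atlas = RegionAtlas(pd.DataFrame(rows))
    g = np.concatenate([g_hemi, g_hemi])
    return atlas, g


def make_pedigree(spec: PedigreeSpec) -> Pedigree:
    """Deterministic pedigree layout: MZ pairs first, then DZ pairs, sibling
    pairs, and singletons; one family per pair or singleton."""
    rows = []
    sid = 0
    fam = 0
    pair = 0

    def next_sid():
        nonlocal sid
        sid += 1
        return f"S{sid:05d}"

    for _ in range(spec.n_mz_pairs):
        fam += 1
        pair += 1
        for _ in range(2):
            rows.append({"family_id": f"F{fam:05d}", "subject_id": next_sid(),
                         "relation": "MZ_twin", "twin_pair_id": f"T{pair:05d}"})
    for _ in range(spec.n_dz_pairs):
        fam += 1
        pair += 1
        for _ in range(2):
            rows.append({"family_id": f"F{fam:05d}", "subject_id": next_sid(),
                         "relation": "DZ_twin", "twin_pair_id": f"T{pair:05d}"})
    for _ in range(spec.n_sib_pairs):
        fam += 1
        for _ in range(2):
            rows.append({"family_id": f"F{fam:05d}", "subject_id": next_sid(),
                         "relation": "full_sibling", "twin_pair_id": None})
    for _ in range(spec.n_singletons):
        fam += 1
        rows.append({"family_id": f"F{fam:05d}", "subject_id": next_sid(),
                     "relation": "singleton", "twin_pair_id": None})
    df = pd.DataFrame(rows, columns=["family_id", "subject_id", "relation", "twin_pair_id"])
    return Pedigree(df)


# ---------------------------------------------------------------------------
# Latent heritable asymmetry
# ---------------------------------------------------------------------------


def simulate_heritable_trait(
    pedigree: Pedigree, h2: float, seed: int | np.random.Generator = 0
) -> pd.Series:
    """Draw a unit-variance latent trait with additive-genetic family
    covariance h2 * 2Phi (1 for MZ, 0.5 for DZ/siblings, 0 across families)."""
    if not 0.0 <= h2 < 1.0:
        raise CohortConfigError("h2 must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = pedigree.table
    n = len(t)
    rel = t["relation"].to_numpy(dtype=object)
    pair = t["twin_pair_id"].to_numpy(dtype=object)
    out = np.empty(n)
    z = rng.standard_normal(n)
    for idx in t.groupby("family_id", sort=False).indices.values():
        idx = np.asarray(idx)
        m = len(idx)
        if m == 1:
            out[idx] = z[idx]
            continue
        K = np.full((m, m), 0.5)
        np.fill_diagonal(K, 1.0)
        for a in range(m):
            for b in range(a + 1, m):
                ia, ib = idx[a], idx[b]
                if (
                    rel[ia] == "MZ_twin"
                    and rel[ib] == "MZ_twin"
                    and pd.notna(pair[ia])
                    and pair[ia] == pair[ib]
                ):
                    K[a, b] = K[b, a] = 1.0
        cov = h2 * K + (1.0 - h2) * np.eye(m)
        L = np.linalg.cholesky(cov)
        out[idx] = L @ z[idx]
    return pd.Series(out, index=t["subject_id"].to_numpy(), name="latent_score")


# ---------------------------------------------------------------------------
# Region covariance and scans
# ---------------------------------------------------------------------------

_OFFDIAG_CAP = 0.97
_EIG_FLOOR = 1e-6


def build_region_covariance(
    atlas: RegionAtlas,
    g: np.ndarray,
    group: str,
    latent_mult: float,
    config: CohortConfig,
) -> np.ndarray:
    """Analytic region-by-region correlation matrix for one subject.

    Terms: exponential decay over the latent coordinate (attenuated across
    hemispheres), within-network and homotopic coupling, plus the group's
    language-block boosts. The result is clipped, floored to positive
    definite by eigenvalue clipping, and rescaled to unit diagonal.
    """
    if group not in GROUPS:
        raise CohortConfigError(f"unknown group {group!r}")
    eff = config.beta_effects.get(group, DEFAULT_EFFECTS[group])
    n = atlas.n_regions
    g = np.asarray(g, dtype=float)
    D = np.abs(g[:, None] - g[None, :])
    sigma = np.exp(-D / config.gradient_bandwidth)
    same_hemi = atlas.hemispheres[:, None] == atlas.hemispheres[None, :]
    sigma = np.where(
        same_hemi,
        config.within_hemisphere_base * sigma,
        config.cross_hemisphere_base * sigma,
    )
    same_net = atlas.networks[:, None] == atlas.networks[None, :]
    sigma = sigma + config.within_network_coupling * (same_net & ~np.eye(n, dtype=bool))
    partner = atlas.partner_positions
    homotopic = np.zeros((n, n), dtype=bool)
    homotopic[np.arange(n), partner] = True
    sigma = sigma + config.homotopic_coupling * homotopic
    lang = atlas.is_language
    left_lang = lang & atlas.left_mask
    right_lang = lang & atlas.right_mask
    off = ~np.eye(n, dtype=bool)
    ll = np.outer(left_lang, left_lang) & off
    rr = np.outer(right_lang, right_lang) & off
    sigma = sigma + (eff.strength_sym + eff.strength_asym * latent_mult) * ll
    sigma = sigma + eff.strength_sym * rr
    lang_hom = homotopic & np.outer(lang, lang)
    sigma = sigma + eff.homotopic * lang_hom
    sigma = np.clip(sigma, -_OFFDIAG_CAP, _OFFDIAG_CAP)
    np.fill_diagonal(sigma, 1.0)
    sigma = 0.5 * (sigma + sigma.T)
    # positive-definite projection by eigenvalue clipping
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() < _EIG_FLOOR:
        vals = np.clip(vals, _EIG_FLOOR, None)
        sigma = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
        sigma = 0.5 * (sigma + sigma.T)
    if np.linalg.eigvalsh(sigma).min() <= 0:
        raise CohortConfigError("region covariance not positive definite after projection")
    return sigma


def _apply_injection(g: np.ndarray, atlas: RegionAtlas, config: CohortConfig) -> np.ndarray:
    g = g.copy()
    mask = (atlas.networks == config.inject_network) & atlas.left_mask
    g[mask] += config.inject_offset
    return g


def simulate_timeseries(
    atlas: RegionAtlas,
    group: str,
    latent_mult: float,
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
    g: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Draw ``n_scans`` region x time matrices from the subject's Gaussian
    process. ``sigma`` may be passed to reuse a precomputed covariance."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if g is None:
        _, g = make_atlas(
            int(atlas.left_mask.sum()), config.n_language_rois, config.n_hubs
        )
    if sigma is None:
        sigma = build_region_covariance(atlas, g, group, latent_mult, config)
    L = np.linalg.cholesky(sigma)
    n = atlas.n_regions
    return [L @ rng.standard_normal((n, config.ts_length)) for _ in range(config.n_scans)]


def simulate_task_betas(
    atlas: RegionAtlas,
    group: str,
    latent_mult: float,
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-region task-contrast betas.

    Language-ROI betas carry +effect/2 (left) and -effect/2 (right) so the
    network-level L-R asymmetry equals the group's network effect times the
    subject's latent multiplier exactly; hub ROIs carry the hub effect.
    Non-language regions have zero mean. Gaussian noise with the configured
    SD is added everywhere.
    """
    if group not in GROUPS:
        raise CohortConfigError(f"unknown group {group!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eff = config.beta_effects.get(group, DEFAULT_EFFECTS[group])
    lang = atlas.is_language
    hub = atlas.is_hub
    n_lang = int((lang & atlas.left_mask).sum())
    n_hub = int((hub & atlas.left_mask).sum())
    if n_lang == n_hub:
        nonhub_eff = eff.beta_network
    else:
        # chosen so the all-ROI mean asymmetry equals beta_network exactly
        nonhub_eff = (n_lang * eff.beta_network - n_hub * eff.beta_hub) / (n_lang - n_hub)
    per_region = np.where(hub, eff.beta_hub, np.where(lang, nonhub_eff, 0.0))
    sign = np.where(atlas.left_mask, 0.5, -0.5)
    mean = per_region * sign * latent_mult
    return mean + config.beta_noise_sd * rng.standard_normal(atlas.n_regions)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

# Left-handedness is enriched in the atypical group (as observed empirically:
# ~1/3 of atypicals versus ~9% of typicals).
_P_LEFT_HANDED = {"strong_typical": 0.075, "mild_typical": 0.11, "atypical": 0.32}


def _simulate_covariates(subject_ids, groups, rng) -> pd.DataFrame:
    n = len(subject_ids)
    age = np.clip(rng.normal(28.7, 3.7, size=n), 22, 37).round(1)
    sex = np.where(rng.random(n) < 0.48, "F", "M")
    p_left = np.array([_P_LEFT_HANDED[g] for g in groups])
    left = rng.random(n) < p_left
    score = np.where(
        left,
        rng.normal(-30.0, 35.0, size=n),
        rng.normal(70.0, 20.0, size=n),
    )
    score = np.clip(score, -100, 100)
    # keep the drawn handedness class consistent with the score cut
    score = np.where(left, np.minimum(score, 25.0), np.maximum(score, 35.0)).round(1)
    icv = rng.normal(1.45e6, 1.2e5, size=n) + np.where(sex == "M", 1.0e5, 0.0)
    base = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": sex,
            "handedness_score": score,
            "intracranial_volume": icv.round(0),
        }
    )
    return derive_covariates(base)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortBundle:
    atlas: RegionAtlas
    latent_coordinate: np.ndarray
    subjects: list[SubjectFunctionalData]
    covariates: CovariateTable
    pedigree: Pedigree
    truth: pd.DataFrame
    config: CohortConfig

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def _group_thresholds(proportions):
    """Latent-score cut points: the lowest-scoring fraction is atypical, the
    middle mild typical, the top strong typical."""
    p_strong, p_mild, p_atypical = proportions
    t_atyp = stats.norm.ppf(p_atypical)
    t_mild = stats.norm.ppf(p_atypical + p_mild)
    return t_atyp, t_mild


def _latent_multiplier(score, group, thresholds, scale):
    """1 + scale * (within-group standardized score); the standardization uses
    the truncated-normal moments of the group's latent-score slice so the
    multiplier has mean 1 within each group."""
    t_atyp, t_mild = thresholds
    bounds = {
        "atypical": (-np.inf, t_atyp),
        "mild_typical": (t_atyp, t_mild),
        "strong_typical": (t_mild, np.inf),
    }[group]
    m, v = stats.truncnorm.stats(bounds[0], bounds[1], moments="mv")
    s = np.sqrt(float(v))
    return 1.0 + scale * (score - float(m)) / s


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full cohort bundle (atlas, scans, betas, covariates,
    pedigree, and the ground-truth table used only by tests)."""
    config.validate()
    atlas, g = make_atlas(
        config.n_regions_per_hemisphere, config.n_language_rois, config.n_hubs
    )
    spec = config.pedigree_spec()
    if config.n_subjects == 0 or spec.n_subjects == 0:
        warnings.warn("empty cohort requested", stacklevel=2)
        empty_ped = Pedigree(pd.DataFrame(columns=["family_id", "subject_id", "relation", "twin_pair_id"]))
        empty_cov = derive_covariates(
            pd.DataFrame(columns=["subject_id", "age", "sex", "handedness_score", "intracranial_volume"])
        )
        return CohortBundle(
            atlas, g, [], CovariateTable(empty_cov), empty_ped,
            pd.DataFrame(columns=["subject_id", "family_id", "group", "latent_score", "latent_multiplier"]),
            config,
        )
    if spec.n_subjects != config.n_subjects:
        raise CohortConfigError(
            f"pedigree spec covers {spec.n_subjects} subjects, config says {config.n_subjects}"
        )
    pedigree = make_pedigree(spec)
    score = simulate_heritable_trait(
        pedigree, config.h2_asym, np.random.default_rng([config.seed, 10])
    )
    thresholds = _group_thresholds(config.group_proportions)
    t_atyp, t_mild = thresholds
    groups = np.where(
        score.to_numpy() < t_atyp,
        "atypical",
        np.where(score.to_numpy() < t_mild, "mild_typical", "strong_typical"),
    )
    cov_df = _simulate_covariates(
        score.index.to_numpy(), groups, np.random.default_rng([config.seed, 11])
    )
    covariates = CovariateTable(cov_df)

    inject_groups = (
        set(config.inject_groups) if config.inject_groups is not None else set(GROUPS)
    )
    subjects = []
    mults = []
    for i, (sid, grp) in enumerate(zip(score.index, groups)):
        rng_i = np.random.default_rng([config.seed, i])
        mult = _latent_multiplier(score.iloc[i], grp, thresholds, config.within_group_scale)
        mults.append(mult)
        injected = config.inject_network is not None and grp in inject_groups
        g_i = _apply_injection(g, atlas, config) if injected else g
        scans = simulate_timeseries(atlas, grp, mult, config, rng_i, g=g_i)
        betas = simulate_task_betas(atlas, grp, mult, config, rng_i)
        subjects.append(
            SubjectFunctionalData(
                subject_id=str(sid),
                scans=scans,
                task_betas=betas,
                covariates=cov_df.loc[cov_df["subject_id"] == sid].iloc[0].to_dict(),
            )
        )
    truth = pd.DataFrame(
        {
            "subject_id": score.index.to_numpy(),
            "family_id": pedigree.table["family_id"].to_numpy(),
            "group": groups,
            "latent_score": score.to_numpy(),
            "latent_multiplier": mults,
        }
    )
    bundle = CohortBundle(atlas, g, subjects, covariates, pedigree, truth, config)
    for s in subjects:
        s.validate(atlas)
    return bundle


# ---------------------------------------------------------------------------
# Disk round trip
# ---------------------------------------------------------------------------


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Write a cohort directory: atlas.tsv, covariates.tsv, pedigree.tsv,
    betas.tsv, ground_truth.tsv and one timeseries TSV per subject and scan.
    The ground-truth table is never read by analysis stages."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(bundle.atlas, out / "atlas.tsv")
    write_covariates(bundle.covariates, out / "covariates.tsv")
    write_pedigree(bundle.pedigree, out / "pedigree.tsv")
    rows = []
    for s in bundle.subjects:
        for rid, b in zip(bundle.atlas.region_ids, s.task_betas):
            rows.append({"subject_id": s.subject_id, "region_id": rid, "beta": b})
    pd.DataFrame(rows, columns=["subject_id", "region_id", "beta"]).to_csv(
        out / "betas.tsv", sep="\t", index=False, float_format="%.12g"
    )
    truth = bundle.truth.copy()
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False, float_format="%.12g")
    gt_regions = pd.DataFrame(
        {"region_id": bundle.atlas.region_ids, "latent_coordinate": bundle.latent_coordinate}
    )
    gt_regions.to_csv(out / "ground_truth_regions.tsv", sep="\t", index=False, float_format="%.12g")
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for s in bundle.subjects:
        for k, scan in enumerate(s.scans):
            write_timeseries(
                scan, bundle.atlas.region_ids, ts_dir / f"{s.subject_id}_scan{k}.tsv"
            )


def read_cohort(cohort_dir: str | Path) -> CohortBundle:
    """Read a cohort directory back into memory (truth table included when
    present; the analysis stages themselves never consume it)."""
    d = Path(cohort_dir)
    atlas = read_atlas(d / "atlas.tsv")
    covariates = read_covariates(d / "covariates.tsv")
    pedigree = read_pedigree(d / "pedigree.tsv")
    betas = pd.read_csv(d / "betas.tsv", sep="\t", dtype={"subject_id": str})
    gt_path = d / "ground_truth.tsv"
    truth = pd.read_csv(gt_path, sep="\t", dtype={"subject_id": str}) if gt_path.exists() else pd.DataFrame()
    gr_path = d / "ground_truth_regions.tsv"
    if gr_path.exists():
        gr = pd.read_csv(gr_path, sep="\t")
        order = [atlas.position(int(r)) for r in gr["region_id"]]
        g = np.empty(atlas.n_regions)
        g[order] = gr["latent_coordinate"].to_numpy(dtype=float)
    else:
        g = np.full(atlas.n_regions, np.nan)
    subjects = []
    ts_dir = d / "timeseries"
    for sid, sub_betas in betas.groupby("subject_id", sort=False):
        order = [atlas.position(int(r)) for r in sub_betas["region_id"]]
        b = np.empty(atlas.n_regions)
        b[order] = sub_betas["beta"].to_numpy(dtype=float)
        scans = []
        k = 0
        while (ts_dir / f"{sid}_scan{k}.tsv").exists():
            scans.append(read_timeseries(ts_dir / f"{sid}_scan{k}.tsv", atlas))
            k += 1
        cov_row = covariates.table.loc[covariates.table["subject_id"] == sid]
        cov = cov_row.iloc[0].to_dict() if len(cov_row) else {}
        subjects.append(SubjectFunctionalData(str(sid), scans, b, cov))
    return CohortBundle(atlas, g, subjects, covariates, pedigree, truth, CohortConfig())
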