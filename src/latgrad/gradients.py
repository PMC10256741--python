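"""Macroscale connectivity gradients and their hemispheric asymmetry.

Per subject the connectivity matrix is row-sparsified (top 10% strongest
connections per region retained), converted to a normalized-angle similarity
matrix, and decomposed by diffusion-map embedding with anisotropic
normalization (alpha = 0.5). Individual gradients are aligned to a
group-level template by iterative orthogonal Procrustes rotation, min-max
scaled to 0-100 at the whole-brain level, and averaged per canonical
network; network asymmetry is the left-minus-right mean gradient value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .datamodel import RegionAtlas

__all__ = [
    "GradientConfig",
    "GradientSet",
    "sparsify_rows",
    "normalized_angle_affinity",
    "diffusion_embedding",
    "procrustes_align",
    "iterative_alignment",
    "minmax_scale",
    "subject_gradients",
    "embed_cohort",
    "serial_position_reference",
    "fix_component_signs",
    "network_gradient_asymmetry",
    "cohort_asymmetry_table",
]


class GradientError(ValueError):
    pass


@dataclass(frozen=True)
class GradientConfig:
    """Embedding parameters. ``retained`` is the fraction of strongest
    connections kept per row (0.10 = sparsity 0.9); ``diffusion_time = 0``
    selects the multiscale lambda/(1-lambda) component scaling."""

    retained: float = 0.10
    n_components: int = 3
    diffusion_alpha: float = 0.5
    diffusion_time: float = 0.0
    align_iterations: int = 10
    scale_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.retained <= 1.0:
            raise GradientError("retained fraction must be in (0, 1]")
        if self.n_components < 1:
            raise GradientError("need at least one component")
        if self.diffusion_time < 0:
            raise GradientError("diffusion_time must be nonnegative")


@dataclass
class GradientSet:
    """Region x component embedding with its eigenvalue spectrum."""

    values: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


def sparsify_rows(matrix: np.ndarray, retained: float) -> np.ndarray:
    """Keep the ceil(retained * (n-1)) largest off-diagonal entries of each
    row (by signed value; ties keep the lowest column index) and zero the
    rest. The output is generally asymmetric."""
    if retained <= 0:
        raise GradientError("retained fraction must be positive")
    M = np.asarray(matrix, dtype=float)
    n, m = M.shape
    if n != m:
        raise GradientError("matrix must be square")
    if retained >= 1.0:
        return M.copy()
    k = int(np.ceil(retained * (n - 1)))
    out = np.zeros_like(M)
    for i in range(n):
        row = M[i].copy()
        row[i] = -np.inf  # diagonal never competes
        order = np.argsort(-row, kind="stable")  # stable: lowest index wins ties
        keep = order[:k]
        out[i, keep] = M[i, keep]
    return out


def normalized_angle_affinity(matrix: np.ndarray) -> np.ndarray:
    """s_ij = 1 - arccos(cos(row_i, row_j)) / pi; symmetric, diagonal 1."""
    M = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(M, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise GradientError(f"all-zero row(s) at region position(s) {dead.tolist()}")
    C = (M @ M.T) / np.outer(norms, norms)
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)
    S = 1.0 - np.arccos(C) / np.pi
    np.fill_diagonal(S, 1.0)
    return S


# ---------------------------------------------------------------------------
# Diffusion-map embedding
# ---------------------------------------------------------------------------


def diffusion_embedding(affinity: np.ndarray, config: GradientConfig) -> GradientSet:
    """Diffusion maps with anisotropic normalization.

    W = D^-alpha S D^-alpha; the transition operator P = D_w^-1 W is
    diagonalized through its symmetric conjugate. The trivial constant
    eigenvector is dropped; components are the right eigenvectors of P
    (normalized against the trivial one) scaled by lambda^t, or by
    lambda/(1-lambda) for the multiscale t = 0 case. Variance explained is
    lambda_i^2 over the summed squared nontrivial spectrum.
    """
    S = np.asarray(affinity, dtype=float)
    n = S.shape[0]
    if S.shape[0] != S.shape[1]:
        raise GradientError("affinity must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise GradientError("affinity must be symmetric")
    if (S < 0).any():
        raise GradientError("affinity must be nonnegative")
    n_comp, _ = connected_components(S > 0, directed=False)
    if n_comp > 1:
        raise GradientError("affinity graph is disconnected")
    if config.n_components > n - 1:
        raise GradientError("more components requested than nontrivial eigenpairs")

    d = S.sum(axis=1)
    alpha = config.diffusion_alpha
    d_alpha = d**alpha
    W = S / np.outer(d_alpha, d_alpha)
    dw = W.sum(axis=1)
    sqrt_dw = np.sqrt(dw)
    Msym = W / np.outer(sqrt_dw, sqrt_dw)
    Msym = 0.5 * (Msym + Msym.T)
    evals, evecs = eigh(Msym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of P; psi0 is constant, used as the normalizer
    psi = evecs / sqrt_dw[:, None]
    psi0 = psi[:, 0]
    if psi0[0] < 0:
        psi0 = -psi0
    phi = psi / psi0[:, None]
    lam = np.clip(evals[1:], None, 1.0 - 1e-12)
    k = config.n_components
    lam_k = lam[:k]
    if config.diffusion_time == 0:
        scale = lam_k / (1.0 - lam_k)
    else:
        scale = np.sign(lam_k) * np.abs(lam_k) ** config.diffusion_time
    values = phi[:, 1 : k + 1] * scale
    total = float(np.sum(lam**2))
    ve = lam_k**2 / total if total > 0 else np.zeros(k)
    return GradientSet(values=values, eigenvalues=lam_k.copy(), variance_explained=ve)


# ---------------------------------------------------------------------------
# Alignment and scaling
# ---------------------------------------------------------------------------


def procrustes_align(individual: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Rotate/reflect (no scaling) the individual embedding onto the template,
    minimizing the Frobenius distance."""
    X = np.asarray(individual, dtype=float)
    T = np.asarray(template, dtype=float)
    if X.shape != T.shape:
        raise GradientError("individual and template must have matching shapes")
    R, _ = orthogonal_procrustes(X, T)
    return X @ R


def iterative_alignment(
    embeddings: Sequence[np.ndarray], template: np.ndarray, iterations: int = 10
) -> tuple[list[np.ndarray], np.ndarray, list[float]]:
    """Align every embedding to the template, refresh the template as the
    mean of the aligned set, and repeat. Returns (aligned, final template,
    per-iteration mean squared misfit)."""
    current = np.asarray(template, dtype=float)
    aligned = [np.asarray(e, dtype=float) for e in embeddings]
    errors: list[float] = []
    for _ in range(max(iterations, 1)):
        aligned = [procrustes_align(e, current) for e in embeddings]
        err = float(np.mean([np.sum((a - current) ** 2) for a in aligned]))
        errors.append(err)
        current = np.mean(aligned, axis=0)
    return aligned, current, errors


def minmax_scale(values: np.ndarray, scale_range: tuple[float, float] = (0.0, 100.0)) -> np.ndarray:
    """Per-component linear map of the whole-brain values onto the range."""
    V = np.asarray(values, dtype=float)
    lo, hi = scale_range
    vmin = V.min(axis=0)
    vmax = V.max(axis=0)
    flat = np.flatnonzero(vmax - vmin == 0)
    if flat.size:
        raise GradientError(f"constant component(s) {flat.tolist()}; cannot min-max scale")
    return lo + (V - vmin) / (vmax - vmin) * (hi - lo)


def serial_position_reference(atlas: RegionAtlas) -> np.ndarray:
    """Within-hemisphere serial position of each region, normalized to [0, 1].

    Used as the sign convention for eigenvector components: atlas rows are
    ordered from the unimodal to the association end within each hemisphere,
    so fixing the sign by positive correlation with serial position makes the
    association end of the first gradient positive. The reference is
    identical for homotopic partners, so it is invariant under hemisphere
    exchange.
    """
    hemis = atlas.hemispheres
    ref = np.empty(atlas.n_regions)
    for h in ("L", "R"):
        pos = np.flatnonzero(hemis == h)
        m = len(pos)
        ref[pos] = np.arange(m) / max(m - 1, 1)
    return ref


def fix_component_signs(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip any component negatively correlated with the reference vector.
    Eigenvector sign is arbitrary; this makes it reproducible."""
    V = np.asarray(values, dtype=float).copy()
    ref = np.asarray(reference, dtype=float)
    rc = ref - ref.mean()
    for j in range(V.shape[1]):
        vc = V[:, j] - V[:, j].mean()
        if float(vc @ rc) < 0:
            V[:, j] = -V[:, j]
    return V


# ---------------------------------------------------------------------------
# Subject- and cohort-level drivers
# ---------------------------------------------------------------------------


def subject_gradients(
    conn_values: np.ndarray,
    config: GradientConfig,
    sign_reference: np.ndarray | None = None,
    scale: bool = True,
) -> GradientSet:
    """Sparsify -> normalized angle -> diffusion embedding for one subject,
    without template alignment (single-subject path)."""
    A = sparsify_rows(conn_values, config.retained)
    S = normalized_angle_affinity(A)
    gs = diffusion_embedding(S, config)
    values = gs.values
    if sign_reference is not None:
        values = fix_component_signs(values, sign_reference)
    if scale:
        values = minmax_scale(values, config.scale_range)
    return GradientSet(values, gs.eigenvalues, gs.variance_explained)


def embed_cohort(
    conn_values: Sequence[np.ndarray],
    config: GradientConfig,
    sign_reference: np.ndarray | None = None,
) -> tuple[list[GradientSet], GradientSet]:
    """Embed every subject, align to the group template, min-max scale.

    The template is the embedding of the cohort-mean connectivity matrix
    (Fisher-z averaged across subjects and back-transformed). Template
    component signs follow ``sign_reference`` when given; individuals
    inherit the sign through alignment.
    """
    if len(conn_values) == 0:
        raise GradientError("no subjects to embed")
    zbar = np.mean([np.arctanh(np.clip(c, -1 + 1e-7, 1 - 1e-7)) for c in conn_values], axis=0)
    np.fill_diagonal(zbar, 0.0)
    group_conn = np.tanh(zbar)
    template = subject_gradients(group_conn, config, sign_reference, scale=False)
    raw = [subject_gradients(c, config, sign_reference=None, scale=False) for c in conn_values]
    aligned_vals, _, _ = iterative_alignment(
        [g.values for g in raw], template.values, config.align_iterations
    )
    out = [
        GradientSet(minmax_scale(v, config.scale_range), g.eigenvalues, g.variance_explained)
        for v, g in zip(aligned_vals, raw)
    ]
    template_scaled = GradientSet(
        minmax_scale(template.values, config.scale_range),
        template.eigenvalues,
        template.variance_explained,
    )
    return out, template_scaled


# ---------------------------------------------------------------------------
# Network asymmetry
# ---------------------------------------------------------------------------


def network_gradient_asymmetry(gradients: GradientSet | np.ndarray, atlas: RegionAtlas) -> pd.DataFrame:
    """Per network and gradient: mean over left regions minus mean over right
    regions, in normalized gradient units."""
    V = gradients.values if isinstance(gradients, GradientSet) else np.asarray(gradients)
    networks = atlas.networks
    rows = []
    for net in pd.unique(networks):
        lmask = (networks == net) & atlas.left_mask
        rmask = (networks == net) & atlas.right_mask
        if not lmask.any() or not rmask.any():
            raise GradientError(f"network {net!r} missing from one hemisphere")
        for j in range(V.shape[1]):
            rows.append(
                {
                    "network": net,
                    "gradient": j + 1,
                    "asymmetry": float(V[lmask, j].mean() - V[rmask, j].mean()),
                }
            )
    return pd.DataFrame(rows)


def cohort_asymmetry_table(
    gradient_sets: Sequence[GradientSet],
    atlas: RegionAtlas,
    subject_ids: Sequence[str],
) -> pd.DataFrame:
    """Long-format (subject, network, gradient, asymmetry) table."""
    frames = []
    for sid, gs in zip(subject_ids, gradient_sets):
        df = network_gradient_asymmetry(gs, atlas)
        df.insert(0, "subject_id", sid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
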