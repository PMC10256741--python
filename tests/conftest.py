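import numpy as np
import pandas as pd
import pytest

from latgrad.cohort import CohortConfig, PedigreeSpec, simulate_cohort
from latgrad.datamodel import RegionAtlas


def toy_atlas_frame():
    """4-region atlas: 2 homotopic pairs, one language pair (also hubs)."""
    return pd.DataFrame(
        {
            "region_id": [1, 2, 11, 12],
            "hemisphere": ["L", "L", "R", "R"],
            "homotopic_partner": [11, 12, 1, 2],
            "network": ["visual", "default", "visual", "default"],
            "is_language_roi": [False, True, False, True],
            "is_hub": [False, True, False, True],
        }
    )


@pytest.fixture
def toy_atlas():
    return RegionAtlas(toy_atlas_frame())


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_subjects=40,
        n_regions_per_hemisphere=16,
        n_language_rois=5,
        n_hubs=2,
        ts_length=120,
        n_scans=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_size_bundle():
    """Three subjects at the default atlas/scan geometry (40 regions per
    hemisphere, 4 scans x 200 time points), one per phenotype group."""
    cfg = CohortConfig(
        n_subjects=3,
        pedigree=PedigreeSpec(0, 0, 0, 3),
        seed=5,
    )
    bundle = simulate_cohort(cfg)
    # re-draw betas/scans per forced group so all three phenotypes appear
    from latgrad.cohort import simulate_task_betas, simulate_timeseries

    for sub, grp, s in zip(bundle.subjects, ("strong_typical", "mild_typical", "atypical"), (21, 22, 23)):
        rng = np.random.default_rng(s)
        sub.scans = simulate_timeseries(bundle.atlas, grp, 1.0, cfg, rng, g=bundle.latent_coordinate)
        sub.task_betas = simulate_task_betas(bundle.atlas, grp, 1.0, cfg, rng)
    bundle.truth["group"] = ["strong_typical", "mild_typical", "atypical"]
    return bundle


# ---------------------------------------------------------------------------
# Independent oracles shared between unit and acceptance tests
# ---------------------------------------------------------------------------


def ward_lance_williams_reference(X):
    """O(n^3) Ward agglomeration via the Lance-Williams recurrence on squared
    Euclidean distances; returns merge heights in distance units."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                val = d2[(i, j)]
                if best is None or val < best[0]:
                    best = (val, i, j)
        val, i, j = best
        heights.append(np.sqrt(val))
        ni, nj = sizes[i], sizes[j]
        for k in sorted(active):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * val) / (ni + nj + nk)
            d2[(min(k, next_id), max(k, next_id))] = new
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        sizes[next_id] = ni + nj
        next_id += 1
    return np.array(heights)


def dense_embedding_reference(conn, retained=0.10, alpha=0.5, n_components=3):
    """Monolithic sparsify -> normalized angle -> diffusion-map reference
    using the dense nonsymmetric eigendecomposition of the transition
    operator (independent code path from the package's symmetric solver)."""
    C = np.asarray(conn, dtype=float)
    n = C.shape[0]
    k = int(np.ceil(retained * (n - 1)))
    A = np.zeros_like(C)
    for i in range(n):
        cand = sorted(
            (j for j in range(n) if j != i), key=lambda j: (-C[i, j], j)
        )[:k]
        for j in cand:
            A[i, j] = C[i, j]
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            num = float(A[i] @ A[j])
            den = float(np.linalg.norm(A[i]) * np.linalg.norm(A[j]))
            cos = np.clip(num / den, -1.0, 1.0)
            S[i, j] = 1.0 - np.arccos(cos) / np.pi
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    d = S.sum(axis=1)
    W = S / np.outer(d**alpha, d**alpha)
    dw = W.sum(axis=1)
    P = W / dw[:, None]
    evals_c, evecs_c = np.linalg.eig(P)
    order = np.argsort(-evals_c.real)
    evals = evals_c[order].real
    evecs_c = evecs_c[:, order]
    sqrt_dw = np.sqrt(dw)
    out = np.empty((n, n_components))
    norm_const = float(np.linalg.norm(sqrt_dw))
    for c in range(n_components):
        # simple real eigenvalues have real eigenvectors; degenerate blocks
        # are compared through the (complex) basis by the caller instead
        u = evecs_c[:, c + 1].real
        u = u / np.linalg.norm(u * sqrt_dw)  # match unit-norm symmetric vector
        lam = min(evals[c + 1], 1.0 - 1e-12)
        out[:, c] = u * norm_const * (lam / (1.0 - lam))
    return out, evals[1 : n_components + 1], evals[1:], evecs_c[:, 1:]


def match_signs(A, B):
    """Flip columns of B to the sign best matching A (eigenvector sign is
    arbitrary); returns the flipped copy."""
    B = B.copy()
    for c in range(B.shape[1]):
        if float(A[:, c] @ B[:, c]) < 0:
            B[:, c] = -B[:, c]
    return B
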