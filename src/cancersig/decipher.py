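"""Deciphering shared mutational signatures by non-negative matrix
factorization.

The merged fraction matrix M (features x samples) is factorized as
M ~ P @ E with P the signature-probability matrix (columns sum to 1) and
E the per-sample exposures.  The number of signatures k is selected by a
bootstrap-stability procedure: each sample's feature fractions are
perturbed by multinomial resampling of its per-group event totals, NMF
is re-run on every replicate, the pooled replicate signatures are
clustered by cosine-distance k-medoids, and the mean silhouette of that
clustering measures how reproducible a k-signature solution is.  The
suggested k is the largest one whose stability clears a floor
(default 0.8); diagnostics for every k are always reported so the
caller can override.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.metrics import silhouette_score

from .catalogs import GROUPS
from .matrix import ExposureMatrix, FeatureMatrix, SignatureMatrix

_EPS = 1e-12


@dataclass
class DecipherConfig:
    k_min: int = 2
    k_max: int = 15
    bootstrap_iterations: int = 100
    nmf_max_iter: int = 500
    tolerance: float = 1e-6          # relative change of the Frobenius objective
    stability_floor: float = 0.8     # minimum mean silhouette for a usable k
    bootstrap_events: int = 1000     # per-sample per-group multinomial total
    n_restarts: int = 5              # NMF restarts for the final factorization
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError(f"invalid k range {self.k_min}..{self.k_max}")
        if self.bootstrap_iterations < 2:
            raise ValueError("need at least 2 bootstrap iterations")


@dataclass
class KDiagnostic:
    k: int
    stability: float               # mean silhouette on cosine distance, in [-1, 1]
    reconstruction_error: float    # mean relative Frobenius error over replicates


@dataclass
class DecipherResult:
    P: SignatureMatrix
    E: ExposureMatrix
    k_selected: int
    suggested_k: int | None
    diagnostics: list[KDiagnostic] = field(default_factory=list)


def signature_labels(k: int) -> list[str]:
    """Signature ids A, B, C, ... (AA, AB, ... past 26)."""
    letters = string.ascii_uppercase
    labels = list(letters) + [a + b for a in letters for b in letters]
    return [f"Signature {labels[i]}" for i in range(k)]


# ---------------------------------------------------------------- NMF core

def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 500,
    tolerance: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF under the Frobenius objective.

    Returns (P, E, error_history) with P column-stochastic (the scale is
    absorbed into E) and the per-iteration Frobenius error, which is
    non-increasing.  Deterministic for a given seed.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-d array")
    if not np.all(np.isfinite(V)) or np.any(V < 0):
        raise ValueError("V must be non-negative and finite")
    n_features, n_samples = V.shape
    if not (1 <= k <= min(n_features, n_samples)):
        raise ValueError(f"k={k} out of range for a {V.shape} matrix")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / max(k, 1)) or 1.0
    W = scale * (rng.random((n_features, k)) + 0.1)
    H = scale * (rng.random((k, n_samples)) + 0.1)

    errors: list[float] = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(V - W @ H))
        errors.append(err)
        if prev is not None and prev - err <= tolerance * max(prev, _EPS):
            break
        prev = err

    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    W = W / colsum
    H = H * colsum[:, None]
    return W, H, errors


# ---------------------------------------------------- bootstrap resampling

def _group_masks(matrix: FeatureMatrix) -> list[np.ndarray]:
    masks = []
    for g in GROUPS:
        mask = np.array([f.group == g for f in matrix.features])
        if mask.any():
            masks.append(mask)
    return masks


def bootstrap_matrix(
    values: np.ndarray,
    group_masks: list[np.ndarray],
    events: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial resampling of each sample's per-group fraction block.

    Each block is resampled as ``Multinomial(events, block/blocksum)`` and
    rescaled to its original block sum, preserving column stochasticity
    and group weighting while injecting count-level sampling noise.
    """
    out = values.copy()
    for mask in group_masks:
        block = values[mask]
        sums = block.sum(axis=0)
        for j in np.nonzero(sums > 0)[0]:
            p = block[:, j] / sums[j]
            counts = rng.multinomial(events, p)
            out[mask, j] = counts / events * sums[j]
    return out


# --------------------------------------------------- k-medoids + stability

def _kmedoids(D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    """Plain k-medoids (Voronoi iteration) on a precomputed distance matrix."""
    n = D.shape[0]
    # k-means++-style greedy spread initialization
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d = D[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(d)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new[c] = members[int(np.argmin(within))]
        if np.array_equal(new, medoids):
            break
        medoids = new
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids


def _cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances between the columns of X."""
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    U = X / norms
    sim = np.clip(U.T @ U, -1.0, 1.0)
    return 1.0 - sim


def _matched_cluster_labels(
    replicates: list[np.ndarray], k: int, rng: np.random.Generator, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster pooled replicate signatures with the partition constraint
    that every replicate contributes exactly one signature per cluster.

    Each replicate's k signatures are Hungarian-matched to k consensus
    centroids (cosine similarity), centroids are recomputed, and the
    process iterates to a fixed point.  The constraint is what makes the
    silhouette discriminative: when the data support only k0 < k
    signatures, the surplus components vary across replicates and are
    forced together into incoherent clusters instead of padding out the
    real ones with near-duplicates.  Centroids are initialized from a
    cosine-distance k-medoids pass over the pool.

    Returns (labels over the pooled columns, cosine distance matrix).
    """
    X = np.hstack(replicates)
    Xn = X / np.maximum(np.linalg.norm(X, axis=0), _EPS)
    D = _cosine_distance_matrix(X)
    _, medoids = _kmedoids(D, k, rng)
    C = Xn[:, medoids].copy()
    n_rep = len(replicates)
    labels = np.zeros(n_rep * k, dtype=int)
    for _ in range(max_iter):
        for b in range(n_rep):
            block = slice(b * k, (b + 1) * k)
            sim = C.T @ Xn[:, block]  # clusters x replicate signatures
            rows, cols = linear_sum_assignment(-sim)
            labels[b * k + cols] = rows
        new_C = np.empty_like(C)
        for c in range(k):
            m = Xn[:, labels == c].mean(axis=1)
            new_C[:, c] = m / max(np.linalg.norm(m), _EPS)
        if np.allclose(new_C, C, atol=1e-12):
            break
        C = new_C
    return labels, D


def select_k(
    matrix: FeatureMatrix, config: DecipherConfig
) -> tuple[list[KDiagnostic], int | None]:
    """Bootstrap-stability diagnostics for every k in the configured range.

    Returns (diagnostics, suggested_k); the suggestion is the largest k
    whose stability reaches the floor, or None when no k qualifies.
    """
    V = matrix.values
    n_samples = len(matrix.samples)
    if config.k_max >= min(V.shape[0], n_samples):
        raise ValueError(
            f"k_max={config.k_max} must be below both the number of features "
            f"({V.shape[0]}) and samples ({n_samples})"
        )
    masks = _group_masks(matrix)
    diagnostics: list[KDiagnostic] = []
    root = np.random.SeedSequence(config.seed)
    for k in range(config.k_min, config.k_max + 1):
        ss_boot, ss_nmf = root.spawn(2)
        boot_rng = np.random.default_rng(ss_boot.generate_state(1)[0] + k)
        replicates: list[np.ndarray] = []
        rel_errors: list[float] = []
        for b in range(config.bootstrap_iterations):
            Vb = bootstrap_matrix(V, masks, config.bootstrap_events, boot_rng)
            seed_b = int(ss_nmf.generate_state(1)[0] % (2**31 - 1)) + 1000 * k + b
            W, H, errs = nmf_factorize(
                Vb, k, seed_b, max_iter=config.nmf_max_iter, tolerance=config.tolerance
            )
            replicates.append(W)
            rel_errors.append(errs[-1] / max(np.linalg.norm(Vb), _EPS))
        cluster_rng = np.random.default_rng(ss_boot.generate_state(2)[1] + k)
        labels, D = _matched_cluster_labels(replicates, k, cluster_rng)
        if k == 1:
            # silhouette is undefined for one cluster; use mean cosine
            # similarity of the replicate signatures to their medoid
            _, medoids = _kmedoids(D, 1, cluster_rng)
            stability = float(np.mean(1.0 - D[:, medoids[0]]))
        else:
            stability = float(silhouette_score(D, labels, metric="precomputed"))
        diagnostics.append(KDiagnostic(k, stability, float(np.mean(rel_errors))))
    passing = [d.k for d in diagnostics if d.stability >= config.stability_floor]
    return diagnostics, (max(passing) if passing else None)


# ------------------------------------------------------------- deciphering

def decipher(
    matrix: FeatureMatrix,
    config: DecipherConfig | None = None,
    k: int | None = None,
) -> DecipherResult:
    """Full deciphering: rank selection (unless ``k`` is forced) followed
    by a multi-restart factorization of M at the chosen rank."""
    config = config or DecipherConfig()
    diagnostics, suggested = select_k(matrix, config)
    k_selected = k if k is not None else suggested
    if k_selected is None:
        raise ValueError(
            "no k in the configured range reached the stability floor "
            f"({config.stability_floor}); inspect the diagnostics and pass k explicitly"
        )
    best: tuple[np.ndarray, np.ndarray] | None = None
    best_err = np.inf
    for r in range(config.n_restarts):
        W, H, errs = nmf_factorize(
            matrix.values, k_selected, config.seed + 7919 * r,
            max_iter=config.nmf_max_iter, tolerance=config.tolerance,
        )
        if errs[-1] < best_err:
            best, best_err = (W, H), errs[-1]
    W, H = best
    # deterministic presentation: order signatures by descending total exposure
    order = np.argsort(-H.sum(axis=1), kind="stable")
    W, H = W[:, order], H[order]
    labels = signature_labels(k_selected)
    P = SignatureMatrix(matrix.features, labels, W)
    E = ExposureMatrix(labels, list(matrix.samples), H)
    return DecipherResult(P, E, k_selected, suggested, diagnostics)


# ---------------------------------------------------------------- refitting

@dataclass
class RefitResult:
    exposures: np.ndarray       # raw non-negative least-squares solution
    fractions: np.ndarray       # exposures / sum (zeros if sum is 0)
    reconstruction: np.ndarray  # P @ exposures
    residual: np.ndarray        # observed - reconstruction
    error: float                # Euclidean norm of the residual
    all_zero: bool = False


def refit_exposures(P: SignatureMatrix | np.ndarray, m: np.ndarray) -> RefitResult:
    """Non-negative least-squares refit of one sample profile against a
    fixed signature matrix: minimize ||m - P e|| subject to e >= 0."""
    A = P.values if isinstance(P, SignatureMatrix) else np.asarray(P, dtype=float)
    m = np.asarray(m, dtype=float)
    if m.shape != (A.shape[0],):
        raise ValueError(f"profile length {m.shape} does not match P {A.shape}")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("profile must be non-negative and finite")
    if not m.any():
        e = np.zeros(A.shape[1])
        return RefitResult(e, e.copy(), A @ e, m - A @ e, 0.0, all_zero=True)
    e, _ = nnls(A, m)
    total = e.sum()
    fractions = e / total if total > 0 else np.zeros_like(e)
    recon = A @ e
    residual = m - recon
    return RefitResult(e, fractions, recon, residual, float(np.linalg.norm(residual)))


def match_signatures(
    P_true: np.ndarray, P_est: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal column matching (Hungarian assignment on cosine similarity).

    Returns (perm, cosines): column j of P_est corresponds to column
    perm[j] of P_true, with the matched cosine similarities.
    """
    A = P_true / np.maximum(np.linalg.norm(P_true, axis=0), _EPS)
    B = P_est / np.maximum(np.linalg.norm(P_est, axis=0), _EPS)
    sim = A.T @ B  # true x est
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(len(cols), dtype=int)
    cosines = np.empty(len(cols))
    for r, c in zip(rows, cols):
        perm[c] = r
        cosines[c] = sim[r, c]
    return perm, cosines
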