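"""Independent oracles shared across test modules."""

import numpy as np


def grid_search_refit(P, m, resolution=1e-3):
    """Exhaustive refit oracle: scan exposure fractions on the simplex at
    the given resolution, optimal scale per direction in closed form."""
    k = P.shape[1]
    steps = int(round(1.0 / resolution))
    if k == 2:
        fracs = [(i / steps, 1 - i / steps) for i in range(steps + 1)]
    elif k == 3:
        fracs = [
            (i / steps, j / steps, (steps - i - j) / steps)
            for i in range(steps + 1)
            for j in range(steps + 1 - i)
        ]
    else:
        raise ValueError("oracle supports k=2,3")
    F = np.array(fracs).T  # k x n_grid
    R = P @ F
    numer = m @ R
    denom = np.einsum("ij,ij->j", R, R)
    scale = np.where(denom > 0, np.maximum(numer, 0) / np.maximum(denom, 1e-300), 0.0)
    errs = np.linalg.norm(m[:, None] - R * scale, axis=0)
    j = int(np.argmin(errs))
    return np.array(fracs[j]), errs[j]


def random_signatures(k, seed, n_features=146):
    """Disjoint-support random probability columns (well separated)."""
    rng = np.random.default_rng(seed)
    P = np.zeros((n_features, k))
    supports = np.array_split(rng.permutation(n_features), k)
    for j, s in enumerate(supports):
        P[s, j] = rng.dirichlet(np.ones(len(s)))
    return P
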