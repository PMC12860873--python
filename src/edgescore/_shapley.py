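"""Model-agnostic Shapley attribution by permutation sampling.

For each explained sample x, features of a background reference are
replaced by the corresponding features of x in random order; the change in
model output when feature j is inserted is j's marginal contribution.
Averaging over sampled permutations and background references estimates
the Shapley value.  Because every permutation's contributions telescope
from f(reference) to f(x), additivity

    sum_j phi_j(x) = f(x) - mean_ref f(ref)

holds to floating-point precision by construction, for any model.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def shapley_values(predict: Callable[[np.ndarray], np.ndarray],
                   X_eval: np.ndarray,
                   X_background: np.ndarray,
                   n_permutations: int = 8,
                   rng: np.random.Generator | None = None) -> tuple[np.ndarray, float]:
    """Per-sample Shapley attributions.

    Parameters
    ----------
    predict : callable mapping (n, m) arrays to (n,) scores
        Typically ``lambda X: model.predict_proba(X)[:, 1]``.
    X_eval : (n_eval, m) array of samples to explain.
    X_background : (n_bg, m) array of reference samples.
    n_permutations : permutations sampled per (sample, reference) pair.

    Returns
    -------
    phi : (n_eval, m) attribution matrix.
    base : mean model output over the background.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X_eval = np.asarray(X_eval, dtype=np.float64)
    X_background = np.asarray(X_background, dtype=np.float64)
    n_eval, m = X_eval.shape
    n_bg = X_background.shape[0]
    perms = np.array([rng.permutation(m) for _ in range(n_permutations)])

    # states[e, p, b, s] = background b with the first s features of
    # permutation p replaced by the values of sample e
    states = np.empty((n_eval, n_permutations, n_bg, m + 1, m), dtype=np.float64)
    states[:, :, :, 0, :] = X_background[None, None, :, :]
    for s in range(m):
        states[:, :, :, s + 1, :] = states[:, :, :, s, :]
        for p in range(n_permutations):
            j = perms[p, s]
            states[:, p, :, s + 1, j] = X_eval[:, None, j]

    out = predict(states.reshape(-1, m)).reshape(n_eval, n_permutations, n_bg, m + 1)
    deltas = np.diff(out, axis=-1)  # (n_eval, n_perm, n_bg, m) in insertion order
    phi = np.zeros((n_eval, m))
    for p in range(n_permutations):
        # contribution at step s belongs to feature perms[p, s]
        phi[:, perms[p]] += deltas[:, p].mean(axis=1)
    phi /= n_permutations
    base = float(predict(X_background).mean())
    return phi, base


def mean_abs_ranking(phi: np.ndarray, feature_names: list[str]) -> list[tuple[str, float]]:
    """Features ordered by descending mean absolute attribution."""
    imp = np.abs(phi).mean(axis=0)
    order = np.argsort(-imp, kind="stable")
    return [(feature_names[i], float(imp[i])) for i in order]
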