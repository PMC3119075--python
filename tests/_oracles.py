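"""Independent oracles used by the test suite.

The split-plot oracle fits the two error strata explicitly with projection
matrices / residual sums of squares from least-squares model comparisons,
sharing no code with the package's closed-form implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def splitplot_oracle(y: np.ndarray, groups) -> dict:
    """Split-plot ANOVA of (N, 2) data via explicit GLM projections.

    Between stratum: one-way model on subject means.  Within stratum:
    difference scores regressed on [intercept | effect-coded groups]; each
    effect's hypothesis SS is the RSS increase when its columns are dropped
    (Type III for the intercept under effect coding).
    """
    y = np.asarray(y, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    a, N = labels.size, y.shape[0]
    s = y.mean(axis=1)
    d = y[:, 1] - y[:, 0]

    # between stratum: projections onto group space vs intercept
    X1 = np.zeros((N, a))
    X1[np.arange(N), codes] = 1.0
    P1 = X1 @ np.linalg.pinv(X1)
    P0 = np.full((N, N), 1.0 / N)
    ss_h = s @ (P1 - P0) @ s
    ss_e = s @ (np.eye(N) - P1) @ s
    F_group = (ss_h / (a - 1)) / (ss_e / (N - a))

    # within stratum: model comparisons on difference scores
    E = np.zeros((N, a - 1))
    for i in range(a - 1):
        E[codes == i, i] = 1.0
    E[codes == a - 1, :] = -1.0
    ones = np.ones((N, 1))

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, d, rcond=None)
        r = d - X @ beta
        return float(r @ r)

    X_full = np.hstack([ones, E])
    rss_full = rss(X_full)
    rss_no_intercept = rss(E)
    rss_no_group = rss(ones)
    mse = rss_full / (N - a)
    F_time = (rss_no_intercept - rss_full) / mse
    F_int = ((rss_no_group - rss_full) / (a - 1)) / mse

    return {
        "F": {"group": F_group, "time": F_time, "interaction": F_int},
        "p": {"group": sps.f.sf(F_group, a - 1, N - a),
              "time": sps.f.sf(F_time, 1, N - a),
              "interaction": sps.f.sf(F_int, a - 1, N - a)},
        "df": {"group": (a - 1, N - a), "time": (1, N - a),
               "interaction": (a - 1, N - a)},
    }


def random_design(rng: np.random.Generator, balanced: bool) -> tuple[np.ndarray, np.ndarray]:
    """A random small two-scan dataset with 2-4 groups."""
    a = int(rng.integers(2, 5))
    if balanced:
        sizes = [int(rng.integers(3, 8))] * a
    else:
        sizes = [int(rng.integers(2, 9)) for _ in range(a)]
    groups = np.repeat([f"g{i}" for i in range(a)], sizes)
    n = len(groups)
    subject_effect = rng.normal(0, 1.0, n)
    y = (subject_effect[:, None] + rng.normal(0, 0.7, (n, 2))
         + rng.normal(0, 0.5, (a, 2))[np.repeat(np.arange(a), sizes)])
    return y, groups
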