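"""Comparison of an estimated OD matrix against a reference matrix.

The reference is typically a survey-derived matrix of journey counts.
Agreement is measured two ways: Kendall's tau-b rank correlation between
the stacked entries (robust to the strong non-normality of journey
counts), and a Monte-Carlo null comparison — fit a lognormal to the
reference's positive off-diagonal counts, draw random OD matrices with
i.i.d. lognormal entries on the same support, and report the fraction of
draws lying farther (in Frobenius distance) from the reference than the
estimate does.  An exceedance near 1 means the estimate is much closer to
the reference than chance; near 0.5 means no better than the null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class NullComparison:
    """Result of the lognormal random-matrix null comparison."""

    n_trials: int
    d_est: float
    d_null: np.ndarray
    exceedance: float
    lognormal_params: tuple  # (mu, sigma) of log counts
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_trials": self.n_trials, "d_est": self.d_est,
                       "d_null": self.d_null.tolist(),
                       "exceedance": self.exceedance,
                       "lognormal_mu": self.lognormal_params[0],
                       "lognormal_sigma": self.lognormal_params[1],
                       "seed": self.seed}, fh)


def kendall_tau(a, b):
    """Tie-corrected Kendall tau-b with asymptotic two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("tau undefined for a constant vector")
    res = stats.kendalltau(a, b, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def fit_lognormal(counts) -> tuple:
    """Maximum-likelihood (mu, sigma) of a lognormal on positive counts.

    mu is the mean and sigma the population standard deviation of the log
    counts.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty input")
    if np.any(counts <= 0):
        raise ValueError("counts must be strictly positive")
    logs = np.log(counts)
    return float(logs.mean()), float(logs.std(ddof=0))


def random_od_matrices(shape, params, n_trials: int, seed: int = 0,
                       support_mask: np.ndarray = None) -> list:
    """Draw i.i.d. lognormal OD matrices with zero diagonal.

    Entries are nonzero only on ``support_mask`` (default: all off-diagonal
    cells), mirroring the sparsity of the reference.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    mu, sigma = params
    n_r, n_c = shape
    if support_mask is None:
        support_mask = ~np.eye(n_r, n_c, dtype=bool)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trials):
        m = np.zeros(shape)
        k = int(support_mask.sum())
        m[support_mask] = rng.lognormal(mu, sigma, size=k)
        if n_r == n_c:
            np.fill_diagonal(m, 0.0)
        out.append(m)
    return out


def frobenius_distance(a, b) -> float:
    """Euclidean norm of the stacked elementwise difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.linalg.norm(a - b))


def rescale_to_reference(estimate: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rescale the estimate so its total equals the reference's total.

    Probability-scale estimates and count-scale references are not directly
    comparable; matching totals puts the Frobenius comparison on the
    reference's scale.
    """
    est_total = estimate.sum()
    if est_total <= 0:
        raise ValueError("estimate has no mass")
    return estimate * (reference.sum() / est_total)


def null_comparison(estimate, reference, n_trials: int = 100, seed: int = 0,
                    rescale: bool = True) -> NullComparison:
    """Monte-Carlo null comparison of estimate vs reference OD matrices.

    Fits a lognormal to the reference's positive off-diagonal entries,
    draws ``n_trials`` random matrices on that support, and reports the
    fraction whose Frobenius distance to the reference exceeds the
    estimate's.
    """
    estimate = np.asarray(estimate, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if estimate.shape != reference.shape:
        raise ValueError("estimate and reference must share a shape")
    offdiag = ~np.eye(*reference.shape, dtype=bool)
    support = offdiag & (reference > 0)
    pos = reference[support]
    if pos.size == 0:
        raise ValueError("reference has no positive off-diagonal entries")
    mu, sigma = fit_lognormal(pos)
    if rescale:
        estimate = rescale_to_reference(estimate, reference)
    d_est = frobenius_distance(estimate, reference)
    draws = random_od_matrices(reference.shape, (mu, sigma), n_trials,
                               seed=seed, support_mask=support)
    d_null = np.array([frobenius_distance(m, reference) for m in draws])
    exceedance = float(np.mean(d_null > d_est))
    return NullComparison(n_trials=n_trials, d_est=d_est, d_null=d_null,
                          exceedance=exceedance,
                          lognormal_params=(mu, sigma), seed=seed)
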