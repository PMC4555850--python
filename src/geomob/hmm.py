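"""Per-user latent-context model: a Gaussian-emission hidden Markov model.

Each user's movement is modelled as a Markov chain over K latent "contexts"
(home, workplace, holiday region, ...), each emitting observed (lon, lat)
coordinates from a full-covariance bivariate Gaussian.  K and the initial
state means come from density-based clustering of the user's events;
parameters are then refined by Baum-Welch (EM with scaled forward-backward
recursions) and the most likely state sequence is decoded with Viterbi.

The public surface follows the statsmodels convention: build a
:class:`ContextHMM` from a trajectory, call :meth:`ContextHMM.fit`, and
read estimates, diagnostics and ``summary()`` off the returned
:class:`ContextHMMResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import clustering
from .ingest import Trajectory

COV_FLOOR = 1e-6      # degrees^2, minimum emission covariance eigenvalue
INIT_DIAG = 0.9       # initial self-transition probability
DEFAULT_MAX_ITER = 100
DEFAULT_REL_TOL = 1e-4


class DegenerateModelError(RuntimeError):
    """Raised when the likelihood turns non-finite despite the covariance floor."""


@dataclass(frozen=True)
class UserModel:
    """Parameters of one user's fitted (or initial) context HMM."""

    user_id: str
    means: np.ndarray        # (K, 2) lon/lat degrees
    covariances: np.ndarray  # (K, 2, 2) degrees^2, SPD
    transition: np.ndarray   # (K, K) row-stochastic
    initial: np.ndarray      # (K,) simplex
    occupancy: np.ndarray    # (K,) Viterbi-path state frequencies
    log_likelihood: float
    n_events: int

    @property
    def k(self) -> int:
        return self.means.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=atol):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=atol):
            raise ValueError("initial distribution must sum to 1")
        if not np.isclose(self.occupancy.sum(), 1.0, atol=atol):
            raise ValueError("occupancy must sum to 1")
        for c in self.covariances:
            if np.linalg.eigvalsh(c).min() < COV_FLOOR * (1 - 1e-6):
                raise ValueError("covariance eigenvalue below floor")

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "occupancy": self.occupancy.tolist(),
            "log_likelihood": float(self.log_likelihood),
            "n_events": int(self.n_events),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UserModel":
        return cls(user_id=d["user_id"],
                   means=np.asarray(d["means"], dtype=float),
                   covariances=np.asarray(d["covariances"], dtype=float),
                   transition=np.asarray(d["transition"], dtype=float),
                   initial=np.asarray(d["initial"], dtype=float),
                   occupancy=np.asarray(d["occupancy"], dtype=float),
                   log_likelihood=float(d["log_likelihood"]),
                   n_events=int(d["n_events"]))


def floor_covariance(cov: np.ndarray, floor: float = COV_FLOOR) -> np.ndarray:
    """Clamp eigenvalues of a symmetric 2x2 matrix at ``floor``."""
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    w = np.maximum(w, floor)
    return (v * w) @ v.T


def _log_emissions(coords: np.ndarray, means: np.ndarray,
                   covariances: np.ndarray) -> np.ndarray:
    """(T, K) matrix of log N(x_t; mu_k, Sigma_k), planar degree metric."""
    T = coords.shape[0]
    K = means.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        cov = covariances[k]
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
        inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
        d = coords - means[k]
        maha = (d @ inv * d).sum(axis=1)
        out[:, k] = -0.5 * (maha + np.log(det)) - np.log(2.0 * np.pi)
    return out


def _forward_backward(initial, transition, log_b):
    """Scaled forward-backward pass.

    Returns (gamma, xi_sum, log_likelihood).  Per-frame shifts keep the
    scaled emission matrix in [0, 1]; the shifts cancel in gamma and xi and
    are restored in the log-likelihood.
    """
    T, K = log_b.shape
    shift = log_b.max(axis=1)
    b = np.exp(log_b - shift[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = initial * b[0]
    c[0] = a.sum()
    if not c[0] > 0:
        raise DegenerateModelError("zero forward mass at t=0")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * b[t]
        c[t] = a.sum()
        if not c[t] > 0:
            raise DegenerateModelError(f"zero forward mass at t={t}")
        alpha[t] = a / c[t]
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    beta = np.ones(K)
    gamma[-1] = alpha[-1]
    for t in range(T - 2, -1, -1):
        w = b[t + 1] * beta / c[t + 1]
        xi_sum += alpha[t][:, None] * transition * w[None, :]
        beta = transition @ w
        g = alpha[t] * beta
        gamma[t] = g / g.sum()
    log_likelihood = float(np.log(c).sum() + shift.sum())
    if not np.isfinite(log_likelihood):
        raise DegenerateModelError("non-finite log-likelihood")
    return gamma, xi_sum, log_likelihood


def log_likelihood_of(model: UserModel, coords: np.ndarray) -> float:
    """Log-likelihood of a coordinate sequence under fixed model parameters."""
    log_b = _log_emissions(np.asarray(coords, dtype=float), model.means,
                           model.covariances)
    _, _, ll = _forward_backward(model.initial, model.transition, log_b)
    return ll


def init_from_clusters(trajectory: Trajectory,
                       assignment: clustering.ClusterAssignment,
                       diag: float = INIT_DIAG,
                       cov_floor: float = COV_FLOOR) -> UserModel:
    """Initial HMM from a DBSCAN assignment.

    K equals the number of clusters (1 if everything is noise, with the
    global mean as fallback).  Initial means are the cluster centroids;
    initial covariances are per-cluster sample covariances with noise
    events attributed to the nearest centroid for this statistic only;
    the transition matrix gets ``diag`` self-transition mass.
    """
    coords = trajectory.coords
    if len(coords) != len(assignment.labels):
        raise ValueError("trajectory and assignment length mismatch")
    n_clusters = assignment.n_clusters
    if n_clusters == 0:
        k = 1
        means = coords.mean(axis=0, keepdims=True)
        labels = np.zeros(len(coords), dtype=int)
    else:
        k = n_clusters
        means = clustering.cluster_centroids(coords, assignment)
        labels = assignment.labels.copy()
        noise = labels == -1
        if noise.any():
            d2 = ((coords[noise, None, :] - means[None, :, :]) ** 2).sum(axis=2)
            labels[noise] = d2.argmin(axis=1)
    covs = np.empty((k, 2, 2))
    for j in range(k):
        member = coords[labels == j]
        if len(member) < 2:
            covs[j] = np.eye(2) * max(cov_floor, 1e-4)
        else:
            d = member - member.mean(axis=0)
            covs[j] = floor_covariance(d.T @ d / len(member), cov_floor)
    if k == 1:
        transition = np.ones((1, 1))
    else:
        transition = np.full((k, k), (1.0 - diag) / (k - 1))
        np.fill_diagonal(transition, diag)
    initial = np.full(k, 1.0 / k)
    return UserModel(user_id=trajectory.user_id, means=means, covariances=covs,
                     transition=transition, initial=initial,
                     occupancy=np.full(k, 1.0 / k),
                     log_likelihood=np.nan, n_events=len(coords))


def fit_em(trajectory: Trajectory, init: UserModel,
           max_iter: int = DEFAULT_MAX_ITER, rel_tol: float = DEFAULT_REL_TOL,
           cov_floor: float = COV_FLOOR, callback=None):
    """Baum-Welch refinement of ``init`` on one trajectory.

    Stops when the relative log-likelihood improvement drops below
    ``rel_tol`` or after ``max_iter`` iterations.  The covariance floor is
    re-applied at every M-step.  Returns ``(UserModel, loglik_history)``
    where the history holds one log-likelihood per E-step (non-decreasing
    up to numerical slack).
    """
    coords = trajectory.coords
    means = init.means.copy()
    covs = init.covariances.copy()
    transition = init.transition.copy()
    initial = init.initial.copy()
    K = means.shape[0]
    T = coords.shape[0]
    history = []
    converged = False
    for _ in range(max_iter):
        log_b = _log_emissions(coords, means, covs)
        gamma, xi_sum, ll = _forward_backward(initial, transition, log_b)
        if callback is not None:
            callback(ll)
        if history and (ll - history[-1]) < rel_tol * abs(history[-1]):
            history.append(ll)
            converged = True
            break
        history.append(ll)
        # M-step
        initial = gamma[0] / gamma[0].sum()
        if T > 1:
            row = xi_sum.sum(axis=1, keepdims=True)
            ok = row[:, 0] > 0
            new_trans = transition.copy()
            new_trans[ok] = xi_sum[ok] / row[ok]
            transition = new_trans
        occ = gamma.sum(axis=0)
        occ_safe = np.maximum(occ, 1e-12)
        means = (gamma.T @ coords) / occ_safe[:, None]
        for k in range(K):
            d = coords - means[k]
            cov = (gamma[:, k][:, None] * d).T @ d / occ_safe[k]
            covs[k] = floor_covariance(cov, cov_floor)
        # row-stochastic / simplex invariants must survive every M-step
        if (not np.allclose(transition.sum(axis=1), 1.0, atol=1e-9)
                or not np.isclose(initial.sum(), 1.0, atol=1e-9)):
            raise DegenerateModelError("M-step broke a stochasticity invariant")
    final_ll = history[-1] if history else np.nan
    model = UserModel(user_id=init.user_id, means=means, covariances=covs,
                      transition=transition, initial=initial,
                      occupancy=init.occupancy, log_likelihood=final_ll,
                      n_events=T)
    return model, np.asarray(history), converged


def viterbi(trajectory: Trajectory, model: UserModel) -> np.ndarray:
    """Jointly most probable state path (log-space DP, ties to lower index)."""
    coords = trajectory.coords
    log_b = _log_emissions(coords, model.means, model.covariances)
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transition)
        delta = np.log(model.initial) + log_b[0]
    T, K = log_b.shape
    psi = np.empty((T, K), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + log_a
        psi[t] = scores.argmax(axis=0)  # first max -> lowest index
        delta = scores[psi[t], np.arange(K)] + log_b[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def path_summaries(path: np.ndarray, k: int):
    """Occupancy fractions and transition counts of a decoded state path."""
    path = np.asarray(path, dtype=int)
    if path.size == 0 or path.min() < 0 or path.max() >= k:
        raise ValueError("path states must lie in 0..k-1 and be non-empty")
    occupancy = np.bincount(path, minlength=k) / path.size
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (path[:-1], path[1:]), 1)
    return occupancy, counts


class ContextHMM:
    """Latent-context model of one user's trajectory.

    Parameters
    ----------
    trajectory : Trajectory
        Time-ordered (lon, lat) events of a single user.
    eps, min_fraction : float
        Density-clustering parameters used to choose K and initialize the
        state means when no explicit assignment is supplied.
    """

    def __init__(self, trajectory: Trajectory, eps: float = clustering.DEFAULT_EPS,
                 min_fraction: float = clustering.DEFAULT_MIN_FRACTION):
        self.trajectory = trajectory
        self.eps = eps
        self.min_fraction = min_fraction

    @classmethod
    def from_dataframe(cls, events: pd.DataFrame, user_id: str = None, **kwargs):
        """Build from an event table; ``user_id`` selects one user if given."""
        if user_id is not None:
            events = events[events["user_id"] == user_id]
        from .ingest import split_trajectories
        trajs = split_trajectories(events)
        if len(trajs) != 1:
            raise ValueError("from_dataframe expects exactly one user's events")
        return cls(trajs[0], **kwargs)

    def cluster(self) -> clustering.ClusterAssignment:
        min_pts = clustering.min_points_for_user(len(self.trajectory),
                                                 self.min_fraction)
        return clustering.dbscan(self.trajectory.coords, self.eps, min_pts)

    def initialize(self, assignment: clustering.ClusterAssignment = None) -> UserModel:
        if assignment is None:
            assignment = self.cluster()
        return init_from_clusters(self.trajectory, assignment)

    def fit(self, init: UserModel = None, max_iter: int = DEFAULT_MAX_ITER,
            rel_tol: float = DEFAULT_REL_TOL,
            cov_floor: float = COV_FLOOR) -> "ContextHMMResults":
        if init is None:
            init = self.initialize()
        model, history, converged = fit_em(self.trajectory, init,
                                           max_iter=max_iter, rel_tol=rel_tol,
                                           cov_floor=cov_floor)
        path = viterbi(self.trajectory, model)
        occupancy, counts = path_summaries(path, model.k)
        model = replace(model, occupancy=occupancy)
        return ContextHMMResults(model=self, params=model, state_path=path,
                                 transition_counts=counts,
                                 loglik_history=history, converged=converged)


@dataclass
class ContextHMMResults:
    """Fitted context HMM: estimates, decoded path and diagnostics."""

    model: ContextHMM
    params: UserModel
    state_path: np.ndarray
    transition_counts: np.ndarray
    loglik_history: np.ndarray
    converged: bool

    @property
    def k(self) -> int:
        return self.params.k

    @property
    def log_likelihood(self) -> float:
        return self.params.log_likelihood

    @property
    def n_iter(self) -> int:
        return len(self.loglik_history)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Context HMM results",
            "===================",
            f"user:            {p.user_id}",
            f"events (T):      {p.n_events}",
            f"states (K):      {p.k}",
            f"log-likelihood:  {p.log_likelihood:.3f}",
            f"EM iterations:   {self.n_iter} (converged: {self.converged})",
            "",
            "state    mean_lon   mean_lat   occupancy   self-trans",
        ]
        for k in range(p.k):
            lines.append(f"{k:5d}   {p.means[k, 0]:9.4f}  {p.means[k, 1]:9.4f}"
                         f"   {p.occupancy[k]:9.4f}   {p.transition[k, k]:9.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# serialization

def write_models_json(models, path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh)


def read_models_json(path) -> list:
    with open(path) as fh:
        return [UserModel.from_dict(d) for d in json.load(fh)]


def write_states_csv(models, path) -> None:
    """Flat per-state table: user_id,state,mean_lon,mean_lat,cov_xx,cov_xy,cov_yy,occupancy."""
    rows = []
    for m in models:
        for k in range(m.k):
            c = m.covariances[k]
            rows.append((m.user_id, k, m.means[k, 0], m.means[k, 1],
                         c[0, 0], c[0, 1], c[1, 1], m.occupancy[k]))
    pd.DataFrame(rows, columns=["user_id", "state", "mean_lon", "mean_lat",
                                "cov_xx", "cov_xy", "cov_yy", "occupancy"]
                 ).to_csv(path, index=False)


def write_transitions_csv(models, path) -> None:
    """Flat transition table: user_id,i,j,prob,count."""
    rows = []
    for m in models:
        for i in range(m.k):
            for j in range(m.k):
                rows.append((m.user_id, i, j, m.transition[i, j]))
    pd.DataFrame(rows, columns=["user_id", "i", "j", "prob"]).to_csv(path, index=False)


def read_states_csv(path) -> dict:
    """Read the per-state CSV dialect back into {user_id: dict of arrays}."""
    df = pd.read_csv(path, dtype={"user_id": str})
    out = {}
    for uid, grp in df.groupby("user_id", sort=True):
        grp = grp.sort_values("state")
        covs = np.array([[[r.cov_xx, r.cov_xy], [r.cov_xy, r.cov_yy]]
                         for r in grp.itertuples()])
        out[uid] = {"means": grp[["mean_lon", "mean_lat"]].to_numpy(),
                    "covariances": covs,
                    "occupancy": grp["occupancy"].to_numpy()}
    return out


def read_transitions_csv(path) -> dict:
    """Read the transition CSV dialect back into {user_id: (K, K) matrix}."""
    df = pd.read_csv(path, dtype={"user_id": str})
    out = {}
    for uid, grp in df.groupby("user_id", sort=True):
        k = int(grp["i"].max()) + 1
        mat = np.zeros((k, k))
        mat[grp["i"].to_numpy(), grp["j"].to_numpy()] = grp["prob"].to_numpy()
        out[uid] = mat
    return out
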