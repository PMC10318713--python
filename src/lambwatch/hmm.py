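"""Three-state hidden Markov model with independent gamma emissions.

The behavioural model: at each 2-h fix an animal occupies one of three
latent movement states (high movement / low movement / non-movement) that
evolve as a first-order Markov chain.  Conditional on the state, the three
observed movement metrics (DIST, RT100, HR) are independent gamma variates,
each state owning its own mean (log-scale parameterization) and shape per
channel.  Parameters are estimated by Baum–Welch EM jointly over all
training animals (each animal-season is an independent sequence sharing
transition, emission, and initial-state parameters), and states are decoded
with the Viterbi algorithm.

Gamma support excludes zero but DIST can be exactly zero for a stationary
pair of fixes, so every channel is floored at half its smallest positive
observed value before fitting; the floors are stored on the model and
re-applied when decoding new data.

Semantic state labels are assigned after fitting from the emission means:
the state with the largest RT100 mean is "non-movement", the larger DIST
mean among the remaining two is "high-movement", the last is
"low-movement".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import digamma, gammaln, polygamma

__all__ = [
    "CHANNELS",
    "GammaHmm",
    "fit_hmm",
    "forward_loglik",
    "viterbi",
    "label_states",
    "floor_channels",
]

CHANNELS = ("dist", "rt100", "hr")


# ----------------------------------------------------------------------------
# Model container
# ----------------------------------------------------------------------------


@dataclass
class GammaHmm:
    """Fitted model: probabilities, gamma emission parameters, labels."""

    initial: np.ndarray  # (S,)
    transition: np.ndarray  # (S, S) row-stochastic
    means: np.ndarray  # (S, C) gamma means
    shapes: np.ndarray  # (S, C) gamma shapes
    channel_names: tuple[str, ...] = CHANNELS
    channel_floors: np.ndarray | None = None  # (C,)
    state_labels: tuple[str, ...] | None = None
    loglik: float = float("-inf")
    converged: bool = False
    n_iter: int = 0
    seed: int | None = None
    loglik_history: list[float] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.initial)

    def validate(self) -> None:
        if not np.allclose(self.initial.sum(), 1.0, atol=1e-10):
            raise ValueError("initial probabilities must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.means <= 0) or np.any(self.shapes <= 0):
            raise ValueError("gamma means and shapes must be strictly positive")

    def to_json(self, path) -> None:
        d = asdict(self)
        for k in ("initial", "transition", "means", "shapes", "channel_floors"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        d["channel_names"] = list(self.channel_names)
        d["state_labels"] = None if self.state_labels is None else list(self.state_labels)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GammaHmm":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("initial", "transition", "means", "shapes"):
            d[k] = np.asarray(d[k], dtype=float)
        if d.get("channel_floors") is not None:
            d["channel_floors"] = np.asarray(d["channel_floors"], dtype=float)
        d["channel_names"] = tuple(d["channel_names"])
        if d.get("state_labels") is not None:
            d["state_labels"] = tuple(d["state_labels"])
        return cls(**d)


# ----------------------------------------------------------------------------
# Numerics
# ----------------------------------------------------------------------------


def floor_channels(obs: np.ndarray, floors: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Floor each channel at half its smallest positive value (or given floors)."""
    obs = np.asarray(obs, dtype=float)
    if floors is None:
        floors = np.empty(obs.shape[1])
        for c in range(obs.shape[1]):
            pos = obs[:, c][obs[:, c] > 0]
            if len(pos) == 0:
                raise ValueError(f"channel {c} has no positive values")
            floors[c] = 0.5 * pos.min()
    return np.maximum(obs, floors), floors


def _gamma_logpdf(x: np.ndarray, shape: float, mean: float) -> np.ndarray:
    scale = mean / shape
    return (shape - 1.0) * np.log(x) - x / scale - shape * np.log(scale) - gammaln(shape)


def _emission_loglik(obs: np.ndarray, means: np.ndarray, shapes: np.ndarray) -> np.ndarray:
    """log B matrix, shape (T, S): per-fix per-state emission log-density."""
    T, C = obs.shape
    S = means.shape[0]
    logb = np.zeros((T, S))
    for s in range(S):
        for c in range(C):
            logb[:, s] += _gamma_logpdf(obs[:, c], shapes[s, c], means[s, c])
    if not np.all(np.isfinite(logb)):
        bad = np.argwhere(~np.isfinite(logb))
        raise FloatingPointError(
            f"non-finite emission log-likelihood (first at t={bad[0][0]}, state={bad[0][1]})"
        )
    return logb


@njit(cache=True)
def _forward_backward(logb, log_init, log_trans):  # pragma: no cover (numba)
    """Scaled forward-backward. Returns (loglik, gamma (T,S), xi_sum (S,S))."""
    T, S = logb.shape
    # Work in linear space with per-step scaling; shift logb rows for safety.
    b = np.empty((T, S))
    for t in range(T):
        m = logb[t, 0]
        for s in range(1, S):
            if logb[t, s] > m:
                m = logb[t, s]
        for s in range(S):
            b[t, s] = np.exp(logb[t, s] - m)
    init = np.exp(log_init)
    trans = np.exp(log_trans)

    alpha = np.empty((T, S))
    cnorm = np.empty(T)
    for s in range(S):
        alpha[0, s] = init[s] * b[0, s]
    cnorm[0] = alpha[0].sum()
    for s in range(S):
        alpha[0, s] /= cnorm[0]
    for t in range(1, T):
        tot = 0.0
        for s in range(S):
            acc = 0.0
            for r in range(S):
                acc += alpha[t - 1, r] * trans[r, s]
            alpha[t, s] = acc * b[t, s]
            tot += alpha[t, s]
        cnorm[t] = tot
        for s in range(S):
            alpha[t, s] /= tot

    beta = np.empty((T, S))
    for s in range(S):
        beta[T - 1, s] = 1.0
    for t in range(T - 2, -1, -1):
        for s in range(S):
            acc = 0.0
            for r in range(S):
                acc += trans[s, r] * b[t + 1, r] * beta[t + 1, r]
            beta[t, s] = acc / cnorm[t + 1]

    gam = np.empty((T, S))
    for t in range(T):
        tot = 0.0
        for s in range(S):
            gam[t, s] = alpha[t, s] * beta[t, s]
            tot += gam[t, s]
        for s in range(S):
            gam[t, s] /= tot

    xi = np.zeros((S, S))
    for t in range(T - 1):
        for r in range(S):
            for s in range(S):
                xi[r, s] += alpha[t, r] * trans[r, s] * b[t + 1, s] * beta[t + 1, s] / cnorm[t + 1]

    ll = 0.0
    for t in range(T):
        ll += np.log(cnorm[t])
    # undo the per-row shift of logb
    for t in range(T):
        m = logb[t, 0]
        for s in range(1, S):
            if logb[t, s] > m:
                m = logb[t, s]
        ll += m
    return ll, gam, xi


@njit(cache=True)
def _viterbi_path(logb, log_init, log_trans):  # pragma: no cover (numba)
    T, S = logb.shape
    delta = np.empty((T, S))
    back = np.zeros((T, S), dtype=np.int64)
    for s in range(S):
        delta[0, s] = log_init[s] + logb[0, s]
    for t in range(1, T):
        for s in range(S):
            best = delta[t - 1, 0] + log_trans[0, s]
            arg = 0
            for r in range(1, S):
                v = delta[t - 1, r] + log_trans[r, s]
                if v > best:  # strict: ties stay at the lower index
                    best = v
                    arg = r
            delta[t, s] = best + logb[t, s]
            back[t, s] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for s in range(1, S):
        if delta[T - 1, s] > best:
            best = delta[T - 1, s]
            arg = s
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


def _solve_gamma_shape(s_stat: float) -> float:
    """Solve log(k) - digamma(k) = s_stat for k (weighted gamma MLE)."""
    if s_stat < 1e-10:
        return 1e4  # near-degenerate: effectively deterministic channel
    k = (3.0 - s_stat + np.sqrt((s_stat - 3.0) ** 2 + 24.0 * s_stat)) / (12.0 * s_stat)
    for _ in range(40):
        f = np.log(k) - digamma(k) - s_stat
        fp = 1.0 / k - polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    return float(np.clip(k, 1e-3, 1e4))


# ----------------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------------


def _as_obs_list(metric_sets) -> list[np.ndarray]:
    arrs = []
    for m in metric_sets:
        if isinstance(m, pd.DataFrame):
            arrs.append(m[list(CHANNELS)].to_numpy(dtype=float))
        else:
            arrs.append(np.asarray(m, dtype=float))
    return arrs


def _initial_params(
    obs_all: np.ndarray, n_states: int, rng: np.random.Generator, jitter: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Provisional parameters from a tercile (quantile) split of the RT100 channel."""
    C = obs_all.shape[1]
    rt_col = 1 if C > 1 else 0
    q = np.quantile(obs_all[:, rt_col], np.linspace(0, 1, n_states + 1))
    groups = np.clip(np.searchsorted(q[1:-1], obs_all[:, rt_col], side="right"), 0, n_states - 1)
    means = np.empty((n_states, C))
    shapes = np.empty((n_states, C))
    for s in range(n_states):
        sel = obs_all[groups == s]
        if len(sel) < 2:
            sel = obs_all
        mu = sel.mean(axis=0)
        var = sel.var(axis=0)
        means[s] = np.maximum(mu, 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(var > 0, mu**2 / np.maximum(var, 1e-300), 10.0)
        shapes[s] = np.clip(k, 0.1, 1e3)
    if jitter:
        means *= rng.lognormal(0.0, 0.35, size=means.shape)
        shapes = np.clip(shapes * rng.lognormal(0.0, 0.35, size=shapes.shape), 0.05, 1e3)
        trans = rng.dirichlet(np.full(n_states, 1.0), size=n_states)
        trans = 0.5 * trans + 0.5 * np.eye(n_states)
        trans /= trans.sum(axis=1, keepdims=True)
    else:
        trans = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
        np.fill_diagonal(trans, 0.9)
    init = np.full(n_states, 1.0 / n_states)
    return init, trans, means, shapes


def _em_once(
    obs_list: list[np.ndarray],
    init: np.ndarray,
    trans: np.ndarray,
    means: np.ndarray,
    shapes: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    S, C = means.shape
    history: list[float] = []
    converged = False
    obs_cat = np.concatenate(obs_list, axis=0)
    log_obs_cat = np.log(obs_cat)
    for it in range(max_iter):
        with np.errstate(divide="ignore"):
            log_init = np.log(np.maximum(init, 1e-300))
            log_trans = np.log(np.maximum(trans, 1e-300))
        total_ll = 0.0
        gam_list = []
        xi_sum = np.zeros((S, S))
        init_acc = np.zeros(S)
        for obs in obs_list:
            logb = _emission_loglik(obs, means, shapes)
            ll, gam, xi = _forward_backward(logb, log_init, log_trans)
            total_ll += ll
            gam_list.append(gam)
            xi_sum += xi
            init_acc += gam[0]
        history.append(total_ll)
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol * abs(history[-2]):
            converged = True
            break
        # M-step
        init = init_acc / init_acc.sum()
        row = xi_sum.sum(axis=1, keepdims=True)
        trans = np.where(row > 0, xi_sum / np.maximum(row, 1e-300), 1.0 / S)
        gam_cat = np.concatenate(gam_list, axis=0)  # (N, S)
        w_sum = gam_cat.sum(axis=0)  # (S,)
        for s in range(S):
            w = gam_cat[:, s]
            if w_sum[s] <= 0:
                continue
            xbar = w @ obs_cat / w_sum[s]
            logxbar = w @ log_obs_cat / w_sum[s]
            for c in range(C):
                s_stat = np.log(max(xbar[c], 1e-300)) - logxbar[c]
                shapes[s, c] = _solve_gamma_shape(max(s_stat, 0.0))
                means[s, c] = max(xbar[c], 1e-300)
    return init, trans, means, shapes, history, converged


def fit_hmm(
    metric_sets,
    n_states: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GammaHmm:
    """Fit the gamma HMM by Baum–Welch EM over one or more metric tables.

    ``metric_sets`` is a list of per-animal tables (DataFrames with columns
    ``dist``, ``rt100``, ``hr``, or plain (T, C) arrays).  Transition,
    emission, and initial-state parameters are shared across sequences.  The
    best of ``n_restarts`` EM runs (first from a quantile-split
    initialization, the rest jittered) by final log-likelihood is returned.
    """
    obs_list = _as_obs_list(metric_sets)
    total = sum(len(o) for o in obs_list)
    if len(obs_list) < 2 and total < 500 and n_states > 1:
        raise ValueError("need >= 2 sequences or >= 500 total fixes to fit")
    cat = np.concatenate(obs_list, axis=0)
    _, floors = floor_channels(cat)
    obs_list = [np.maximum(o, floors) for o in obs_list]

    rng = np.random.default_rng(seed)
    best: GammaHmm | None = None
    for r in range(max(n_restarts, 1)):
        init, trans, means, shapes = _initial_params(
            np.concatenate(obs_list, axis=0), n_states, rng, jitter=(r > 0)
        )
        try:
            init, trans, means, shapes, history, converged = _em_once(
                obs_list, init, trans, means, shapes, tol, max_iter
            )
        except FloatingPointError:
            continue
        model = GammaHmm(
            initial=init,
            transition=trans,
            means=means,
            shapes=shapes,
            channel_names=CHANNELS[: cat.shape[1]]
            if cat.shape[1] <= len(CHANNELS)
            else tuple(f"ch{c}" for c in range(cat.shape[1])),
            channel_floors=floors,
            loglik=history[-1],
            converged=converged,
            n_iter=len(history),
            seed=seed,
            loglik_history=history,
        )
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise FloatingPointError("every EM restart failed with non-finite likelihood")
    best.validate()
    return best


def forward_loglik(model: GammaHmm, obs) -> float:
    """Total log-likelihood of one observation sequence under the model."""
    obs = _as_obs_list([obs])[0]
    if model.channel_floors is not None:
        obs = np.maximum(obs, model.channel_floors)
    logb = _emission_loglik(obs, model.means, model.shapes)
    with np.errstate(divide="ignore"):
        ll, _, _ = _forward_backward(
            logb,
            np.log(np.maximum(model.initial, 1e-300)),
            np.log(np.maximum(model.transition, 1e-300)),
        )
    return float(ll)


def viterbi(model: GammaHmm, metrics) -> pd.DataFrame:
    """Decode the most probable state path; ties break toward lower state index.

    Returns a DataFrame with columns ``state`` (index) and, if the model is
    labelled, ``label``; timestamps and animal_id are carried through when
    the input is a metric table.
    """
    obs = _as_obs_list([metrics])[0]
    if model.channel_floors is not None:
        obs = np.maximum(obs, model.channel_floors)
    logb = _emission_loglik(obs, model.means, model.shapes)
    with np.errstate(divide="ignore"):
        path, best = _viterbi_path(
            logb,
            np.log(np.maximum(model.initial, 1e-300)),
            np.log(np.maximum(model.transition, 1e-300)),
        )
    if not np.isfinite(best):
        raise FloatingPointError("observation has zero probability under every state")
    out = pd.DataFrame({"state": path})
    if isinstance(metrics, pd.DataFrame):
        out.index = metrics.index
        for col in ("animal_id", "timestamp"):
            if col in metrics.columns:
                out.insert(0, col, metrics[col].to_numpy())
    if model.state_labels is not None:
        out["label"] = [model.state_labels[s] for s in path]
    return out


def label_states(model: GammaHmm) -> GammaHmm:
    """Attach semantic labels from the emission means (3-state models).

    non-movement = largest RT100 mean; high-movement = largest DIST mean of
    the remaining two; low-movement = the remainder.  Raises on ties (the
    fit is degenerate and should be redone).
    """
    if model.n_states != 3:
        raise ValueError("semantic labelling is defined for 3-state models")
    names = list(model.channel_names)
    i_rt = names.index("rt100")
    i_dist = names.index("dist")
    rt_means = model.means[:, i_rt]
    order = np.argsort(rt_means)
    if abs(rt_means[order[-1]] - rt_means[order[-2]]) < 1e-9:
        raise ValueError("tied RT100 emission means: degenerate states, refit required")
    non = int(order[-1])
    rest = [s for s in range(3) if s != non]
    d = model.means[rest, i_dist]
    if abs(d[0] - d[1]) < 1e-9:
        raise ValueError("tied DIST emission means: degenerate states, refit required")
    high = rest[int(np.argmax(d))]
    low = [s for s in rest if s != high][0]
    labels = [""] * 3
    labels[non] = "non-movement"
    labels[high] = "high-movement"
    labels[low] = "low-movement"
    model.state_labels = tuple(labels)
    return model
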