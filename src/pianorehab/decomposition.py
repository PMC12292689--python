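"""Non-negative CP tensor factorization, NMF, FIT metric and rank selection.

The 3-way EMG tensor is approximated by a sum of rank-one outer products
F_r o T_r o S_r (frequency, temporal-activation and muscle-weight factors),
fitted by alternating least squares over the mode-n unfoldings with negative
entries clipped after every update and a monotonicity safeguard that rejects
any sweep raising the residual.  The 2-D path is classical multiplicative-
update NMF on the rectified EMG matrix.

Reconstruction quality is FIT = 1 - ||X - Xhat||_F^2 / ||X||_F^2; the synergy
count is the smallest rank whose mean FIT over restarts reaches 90% while the
gain from one more synergy is at most 2 percentage points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import khatri_rao

from .errors import DataError
from .tfr import EMGTensor

__all__ = [
    "SynergyModel3D",
    "SynergyModel2D",
    "RankSelection",
    "cp_als",
    "fit_metric",
    "select_rank",
    "nmf",
    "save_model",
    "load_model",
]

_EPS = 1e-12


@dataclass
class SynergyModel3D:
    """Non-negative CP factor set {F, T, S} with reconstruction FIT.

    F : (f_bins x R) frequency coefficients.
    T : (t_samples x R) activation scaling coefficients (carries scale).
    S : (channels x R) muscle weights, unit-norm columns.
    """

    F: np.ndarray
    T: np.ndarray
    S: np.ndarray
    rank: int
    fit: float
    n_iter: int = 0
    seed: int = 0
    converged: bool = True
    restart_fits: list[float] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("fr,tr,sr->fts", self.F, self.T, self.S)


@dataclass
class SynergyModel2D:
    """Non-negative matrix factorization E ~ W @ H of a rectified EMG matrix."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    fit: float
    n_iter: int = 0
    seed: int = 0
    converged: bool = True
    objective_history: list[float] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class RankSelection:
    """Outcome of the synergy-count rule."""

    rank: int
    fit_curve: np.ndarray  # mean FIT over restarts for ranks 1..r_max
    satisfied: bool  # False => rule never fired, rank is argmax FIT


def fit_metric(original: np.ndarray | EMGTensor, reconstructed: np.ndarray) -> float:
    """FIT = 1 - ||X - Y||_F^2 / ||X||_F^2; equals 1 iff Y == X."""
    x = original.values if isinstance(original, EMGTensor) else np.asarray(original, float)
    y = np.asarray(reconstructed, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    nx = float(np.sum(x**2))
    if nx == 0.0:
        if np.any(y != 0):
            raise ValueError("FIT undefined: zero original, nonzero reconstruction")
        return 1.0
    return 1.0 - float(np.sum((x - y) ** 2)) / nx


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _solve_nn(unfolded: np.ndarray, kr: np.ndarray, gram: np.ndarray) -> np.ndarray:
    """Least-squares factor update with non-negativity by clipping."""
    try:
        sol = np.linalg.solve(gram.T, (unfolded @ kr).T).T
    except np.linalg.LinAlgError:
        sol = unfolded @ kr @ np.linalg.pinv(gram)
    return np.maximum(sol, 0.0)


def _cp_single(
    x: np.ndarray, rank: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    f_dim, t_dim, s_dim = x.shape
    F = np.abs(rng.standard_normal((f_dim, rank)))
    T = np.abs(rng.standard_normal((t_dim, rank)))
    S = np.abs(rng.standard_normal((s_dim, rank)))
    # scale the init so the reconstruction magnitude matches the data;
    # |N(0,1)| entries have mean ~0.798, so entries of F o T o S sum to
    # ~0.798^3 * rank -- without this a first clipped sweep from an
    # off-scale start can raise the residual and trip the safeguard
    scale = (x.mean() / (0.798**3 * rank)) ** (1.0 / 3.0)
    F *= scale
    T *= scale
    S *= scale
    x1, x2, x3 = _unfold(x, 0), _unfold(x, 1), _unfold(x, 2)
    norm_x2 = float(np.sum(x**2))

    def current_fit() -> float:
        return fit_metric(x, np.einsum("fr,tr,sr->fts", F, T, S))

    prev_fit = current_fit()
    n_iter = 0
    converged = False
    eye = _EPS * np.eye(rank)
    warmup = 2  # clipped sweeps are not monotone from an arbitrary start
    for n_iter in range(1, max_iter + 1):
        keep = (F.copy(), T.copy(), S.copy())
        # update order S -> F -> T
        S = _solve_nn(x3, khatri_rao(F, T), (F.T @ F) * (T.T @ T) + eye)
        F = _solve_nn(x1, khatri_rao(T, S), (T.T @ T) * (S.T @ S) + eye)
        T = _solve_nn(x2, khatri_rao(F, S), (F.T @ F) * (S.T @ S) + eye)
        fit = current_fit()
        if n_iter > warmup and fit < prev_fit - 1e-12:
            # safeguard: reject the residual-raising sweep and stop
            F, T, S = keep
            converged = True
            break
        if n_iter > warmup and abs(fit - prev_fit) < tol * max(abs(prev_fit), _EPS):
            prev_fit = fit
            converged = True
            break
        prev_fit = fit
    # normalization convention: unit-norm spatial columns, scale into T
    norms = np.linalg.norm(S, axis=0)
    nz = norms > 0
    S[:, nz] /= norms[nz]
    T[:, nz] *= norms[nz]
    del norm_x2
    return F, T, S, prev_fit, n_iter, converged


def cp_als(
    tensor: EMGTensor | np.ndarray,
    rank: int,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed: int = 0,
    restarts: int = 5,
) -> SynergyModel3D:
    """Best-of-restarts non-negative CP-ALS decomposition.

    Each restart starts from seeded |N(0,1)| factors; alternating clipped
    least-squares updates run in the order S, F, T until the relative FIT
    change falls below ``tol`` or ``max_iter`` sweeps elapse.  The model with
    the highest FIT is returned; per-restart FITs are kept for rank selection.
    """
    names = tensor.channel_names if isinstance(tensor, EMGTensor) else []
    x = tensor.values if isinstance(tensor, EMGTensor) else np.asarray(tensor, float)
    if x.ndim != 3 or x.size == 0:
        raise ValueError("tensor must be non-empty and 3-dimensional")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if np.any(x < 0):
        raise DataError("tensor must be non-negative")
    if rank > min(x.shape):
        warnings.warn(
            f"rank {rank} exceeds smallest tensor dimension {min(x.shape)}; "
            "attempting anyway", stacklevel=2,
        )
    if not np.any(x):
        # all-zero tensor: trivial perfect reconstruction by convention
        f_dim, t_dim, s_dim = x.shape
        return SynergyModel3D(
            np.zeros((f_dim, rank)), np.zeros((t_dim, rank)), np.zeros((s_dim, rank)),
            rank=rank, fit=1.0, n_iter=0, seed=seed, restart_fits=[1.0] * restarts,
            channel_names=list(names),
        )

    best = None
    fits = []
    for k in range(restarts):
        rng = np.random.default_rng(seed + k)
        F, T, S, fit, n_iter, conv = _cp_single(x, rank, max_iter, tol, rng)
        fits.append(fit)
        if best is None or fit > best.fit:
            best = SynergyModel3D(F, T, S, rank=rank, fit=fit, n_iter=n_iter,
                                  seed=seed + k, converged=conv,
                                  channel_names=list(names))
    if not best.converged:
        warnings.warn("CP-ALS did not converge within max_iter", stacklevel=2)
    best.restart_fits = fits
    return best


def select_rank(
    tensor: EMGTensor | np.ndarray,
    r_max: int = 6,
    restarts: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> RankSelection:
    """Choose the synergy count by the FIT-threshold rule.

    Returns the smallest rank r with mean-over-restarts FIT(r) >= 0.90 and
    FIT(r+1) - FIT(r) <= 0.02.  If no rank qualifies, the argmax-FIT rank is
    returned with ``satisfied=False`` and a warning.
    """
    x = tensor.values if isinstance(tensor, EMGTensor) else np.asarray(tensor, float)
    if r_max < 2:
        raise ValueError("r_max must be >= 2")
    if r_max > min(x.shape):
        warnings.warn(
            f"r_max {r_max} clipped to smallest tensor dimension {min(x.shape)}",
            stacklevel=2,
        )
        r_max = min(x.shape)
    curve = np.empty(r_max)
    for r in range(1, r_max + 1):
        model = cp_als(tensor, r, max_iter=max_iter, tol=tol,
                       seed=seed + 1000 * r, restarts=restarts)
        curve[r - 1] = float(np.mean(model.restart_fits))
    for r in range(1, r_max):
        if curve[r - 1] >= 0.90 and curve[r] - curve[r - 1] <= 0.02:
            return RankSelection(rank=r, fit_curve=curve, satisfied=True)
    warnings.warn("rank-selection rule not satisfied; returning argmax FIT",
                  stacklevel=2)
    return RankSelection(rank=int(np.argmax(curve)) + 1, fit_curve=curve,
                         satisfied=False)


def nmf(
    matrix: np.ndarray,
    rank: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    restarts: int = 3,
) -> SynergyModel2D:
    """Multiplicative-update NMF of a non-negative (rectified) EMG matrix.

    Minimizes the Frobenius loss ||E - W H||_F^2; the objective is
    non-increasing at every iteration (Lee-Seung updates).  Negative input
    raises :class:`DataError` — rectify or envelope the EMG first.
    """
    v = np.asarray(matrix, dtype=float)
    if v.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if np.any(v < 0):
        raise DataError(
            "NMF input has negative entries; rectify the EMG first "
            "(PreprocessConfig(rectify=True))"
        )
    if rank < 1:
        raise ValueError("rank must be >= 1")
    ne, ns = v.shape
    norm_v = float(np.sum(v**2))
    if norm_v == 0.0:
        return SynergyModel2D(np.zeros((ne, rank)), np.zeros((rank, ns)),
                              rank=rank, fit=1.0, seed=seed)

    best = None
    for k in range(restarts):
        rng = np.random.default_rng(seed + k)
        W = np.abs(rng.standard_normal((ne, rank))) + _EPS
        H = np.abs(rng.standard_normal((rank, ns))) + _EPS
        history = []
        prev = np.inf
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            H *= (W.T @ v) / (W.T @ W @ H + _EPS)
            W *= (v @ H.T) / (W @ H @ H.T + _EPS)
            obj = float(np.sum((v - W @ H) ** 2))
            history.append(obj)
            if prev - obj < tol * max(prev, _EPS):
                converged = True
                break
            prev = obj
        fit = 1.0 - history[-1] / norm_v
        if best is None or fit > best.fit:
            norms = np.linalg.norm(W, axis=0)
            nz = norms > 0
            W = W.copy()
            H = H.copy()
            W[:, nz] /= norms[nz]
            H[nz, :] *= norms[nz, None]
            best = SynergyModel2D(W, H, rank=rank, fit=fit, n_iter=n_iter,
                                  seed=seed + k, converged=converged,
                                  objective_history=history)
    return best


def save_model(model: SynergyModel3D | SynergyModel2D, path: str | Path) -> None:
    """Serialize a synergy model to JSON (factors as nested lists)."""
    path = Path(path)
    if isinstance(model, SynergyModel3D):
        payload = {
            "kind": "cp3",
            "F": model.F.tolist(), "T": model.T.tolist(), "S": model.S.tolist(),
            "rank": model.rank, "fit": model.fit, "n_iter": model.n_iter,
            "seed": model.seed, "converged": model.converged,
            "restart_fits": list(map(float, model.restart_fits)),
            "channel_names": model.channel_names,
        }
    else:
        payload = {
            "kind": "nmf2",
            "W": model.W.tolist(), "H": model.H.tolist(),
            "rank": model.rank, "fit": model.fit, "n_iter": model.n_iter,
            "seed": model.seed, "converged": model.converged,
        }
    path.write_text(json.dumps(payload))


def load_model(path: str | Path) -> SynergyModel3D | SynergyModel2D:
    d = json.loads(Path(path).read_text())
    if d["kind"] == "cp3":
        return SynergyModel3D(
            np.array(d["F"]), np.array(d["T"]), np.array(d["S"]),
            rank=d["rank"], fit=d["fit"], n_iter=d["n_iter"], seed=d["seed"],
            converged=d["converged"], restart_fits=d.get("restart_fits", []),
            channel_names=d.get("channel_names", []),
        )
    return SynergyModel2D(
        np.array(d["W"]), np.array(d["H"]), rank=d["rank"], fit=d["fit"],
        n_iter=d["n_iter"], seed=d["seed"], converged=d["converged"],
    )
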