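"""Reorientation of fitted latents into ecological normal modes (ECNs).

A fitted factorization is only defined up to an invertible K × K gauge
transform. The gauge is resolved in three steps, none of which changes
the predicted propensities:

1. **Orthonormalization** — modified Gram–Schmidt on the latent matrix z
   gives z' with z'^T z' = I; the rotation B = z^+ z' (Moore–Penrose
   pseudoinverse) transforms the loadings, Theta' = B^{-1} Theta.
2. **Linear dynamics** — a "return to normal" model
   z'_{t+1} = A z'_t + u + noise with *symmetric* A is fitted by
   least squares (closed form on complete data; simulated annealing with
   gap propagation when samples are missing).
3. **Diagonalization** — A = v^T Lambda v with v orthogonal; the
   reoriented latents y_t = v z'_t (the ECNs) then fluctuate
   independently: y_{t+1,k} = Lambda_k y_tk + u'_k + noise.

The ECNs are unique up to per-mode sign and ordering; both are fixed by
convention here (descending |Lambda|; sign so that each mode's
largest-magnitude loading is positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import propensities as _propensities

__all__ = [
    "OrthonormalFactors",
    "DynamicsFit",
    "ECNResults",
    "orthonormalize_latents",
    "fit_linear_dynamics",
    "diagonalize_to_ecns",
]


# ----------------------------------------------------------------------
@dataclass
class OrthonormalFactors:
    """Gauge-fixed factors: orthonormal latents and rotated loadings."""

    z: np.ndarray        # (T, K), z^T z = I
    theta: np.ndarray    # (K, O, S)
    rotation: np.ndarray  # B = z_orig^+ z, (K, K)

    def propensities(self) -> np.ndarray:
        return _propensities(self.z, self.theta)


def _modified_gram_schmidt(z: np.ndarray) -> np.ndarray:
    """Column-wise modified Gram–Schmidt; raises on rank deficiency."""
    z = np.array(z, dtype=float)
    T, K = z.shape
    q = np.empty_like(z)
    for j in range(K):
        v = z[:, j].copy()
        nrm = np.linalg.norm(v)
        if nrm <= 1e-12 * max(1.0, np.linalg.norm(z[:, j])) or nrm == 0.0:
            raise np.linalg.LinAlgError(
                f"latent matrix is rank deficient at column {j}; "
                "refit with a smaller K"
            )
        q[:, j] = v / nrm
        for i in range(j + 1, K):
            z[:, i] -= q[:, j] * (q[:, j] @ z[:, i])
        # rank check on the *deflated* columns happens on their turn
    return q


def orthonormalize_latents(results) -> OrthonormalFactors:
    """Orthonormalize fitted latents; rotate loadings to compensate.

    Parameters
    ----------
    results : EMBEDResults or (z, theta) tuple

    Returns
    -------
    OrthonormalFactors with identical predictions.
    """
    if isinstance(results, tuple):
        z, theta = results
    else:
        z, theta = results.z, results.theta
    T, K = z.shape
    # rank check before orthogonalization: MGS detects deficiency late
    if np.linalg.matrix_rank(z, tol=1e-10 * max(1.0, np.linalg.norm(z))) < K:
        raise np.linalg.LinAlgError(
            "latent matrix does not have full column rank; use a smaller K"
        )
    z_prime = _modified_gram_schmidt(z)
    B = np.linalg.pinv(z) @ z_prime
    theta_prime = np.einsum(
        "ij,jos->ios", np.linalg.inv(B), theta
    )
    return OrthonormalFactors(z=z_prime, theta=theta_prime, rotation=B)


# ----------------------------------------------------------------------
@dataclass
class DynamicsFit:
    """Symmetric linear dynamics z_{t+1} = A z_t + u + Gaussian noise."""

    A: np.ndarray            # (K, K), symmetric by construction
    u: np.ndarray            # (K,)
    residual_error: float    # squared-error objective at the optimum
    method: str              # "analytic" | "anneal"
    converged: bool
    n_pairs: int


def _pack(A: np.ndarray, u: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(A.shape[0])
    return np.concatenate([A[iu], u])


def _unpack(p: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(K)
    n_a = len(iu[0])
    A = np.zeros((K, K))
    A[iu] = p[:n_a]
    A = A + A.T - np.diag(np.diag(A))
    return A, p[n_a:]


def _dynamics_energy(
    A: np.ndarray, u: np.ndarray, z: np.ndarray, obs_idx: np.ndarray
) -> float:
    """Squared prediction error over consecutive observed pairs.

    Multi-step gaps between observed time points are bridged by applying
    the noiseless dynamics iteratively.
    """
    err = 0.0
    for a, b in zip(obs_idx[:-1], obs_idx[1:]):
        pred = z[a]
        for _ in range(b - a):
            pred = A @ pred + u
        err += float(np.sum((z[b] - pred) ** 2))
    return err


def _analytic_symmetric_ls(
    z: np.ndarray, pairs: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact least squares over symmetric A and u (unit-step pairs only)."""
    K = z.shape[1]
    iu = np.triu_indices(K)
    n_a = len(iu[0])
    rows, rhs = [], []
    for a, b in pairs:
        for k in range(K):
            coeff = np.zeros(n_a + K)
            for m, (i, j) in enumerate(zip(*iu)):
                if i == j:
                    if k == i:
                        coeff[m] = z[a, i]
                elif k == i:
                    coeff[m] = z[a, j]
                elif k == j:
                    coeff[m] = z[a, i]
            coeff[n_a + k] = 1.0
            rows.append(coeff)
            rhs.append(z[b, k])
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    return _unpack(sol, K)


def fit_linear_dynamics(
    z: np.ndarray,
    time_observed: np.ndarray | None = None,
    method: str = "auto",
    n_proposals: int = 20_000,
    t_start: float = 1.0,
    t_end: float = 1e-4,
    seed: int = 0,
    polish: bool = True,
) -> DynamicsFit:
    """Fit symmetric A and baseline u to latent time series.

    Parameters
    ----------
    z : (T, K) latents (orthonormal columns in the standard pipeline,
        though nothing here requires it).
    time_observed : bool (T,) — time points with at least one sample.
        Missing points are bridged by noiseless propagation and the fit
        switches to simulated annealing (the propagated prediction is a
        polynomial in A, no longer linear least squares).
    method : "auto" (analytic when complete, anneal otherwise),
        "analytic", or "anneal".
    n_proposals : annealing budget; exponential cooling from ``t_start``
        to ``t_end``; Gaussian proposals on the upper triangle of A and
        on u. A deterministic quasi-Newton polish refines the annealing
        optimum unless ``polish=False``.
    """
    z = np.asarray(z, float)
    T, K = z.shape
    if time_observed is None:
        time_observed = np.ones(T, dtype=bool)
    obs_idx = np.flatnonzero(time_observed)
    pairs = [
        (a, b) for a, b in zip(obs_idx[:-1], obs_idx[1:]) if b - a == 1
    ]
    n_unknowns = K * (K + 1) // 2 + K
    n_all_pairs = len(obs_idx) - 1
    if n_all_pairs * K < n_unknowns:
        raise ValueError(
            f"too few time points: {n_all_pairs} consecutive-pair "
            f"constraints x {K} components < {n_unknowns} unknowns"
        )
    complete = len(pairs) == n_all_pairs

    if method == "auto":
        method = "analytic" if complete else "anneal"
    if method == "analytic":
        if not complete:
            raise ValueError(
                "analytic solution requires complete (gap-free) data"
            )
        A, u = _analytic_symmetric_ls(z, pairs)
        resid = _dynamics_energy(A, u, z, obs_idx)
        return DynamicsFit(A, u, resid, "analytic", True, n_all_pairs)

    # --- simulated annealing over (triu(A), u) --------------------------
    rng = np.random.default_rng(seed)
    if pairs and len(pairs) * K >= n_unknowns:
        A0, u0 = _analytic_symmetric_ls(z, pairs)  # warm start from unit-step pairs
    else:
        A0, u0 = np.zeros((K, K)), np.zeros(K)
    p = _pack(A0, u0)
    energy = lambda pv: _dynamics_energy(*_unpack(pv, K), z, obs_idx)
    e = energy(p)
    best_p, best_e = p.copy(), e
    scale = max(best_e / (n_all_pairs * K), 1e-12)  # temperature in energy units
    cool = (t_end / t_start) ** (1.0 / max(n_proposals - 1, 1))
    temp = t_start
    for _ in range(n_proposals):
        cand = p.copy()
        i = rng.integers(len(p))
        cand[i] += rng.normal(0.0, 0.2 * np.sqrt(temp) + 1e-4)
        e_c = energy(cand)
        if e_c <= e or rng.random() < np.exp(-(e_c - e) / (temp * scale)):
            p, e = cand, e_c
            if e < best_e:
                best_p, best_e = p.copy(), e
        temp *= cool
    converged = True
    if polish:
        opt = minimize(energy, best_p, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        if opt.fun <= best_e:
            best_p, best_e = opt.x, float(opt.fun)
        converged = bool(opt.success or opt.fun <= best_e)
    if not converged:
        warnings.warn("annealing did not converge; returning best found")
    A, u = _unpack(best_p, K)
    return DynamicsFit(A, u, float(best_e), "anneal", converged, n_all_pairs)


# ----------------------------------------------------------------------
@dataclass
class ECNResults:
    """Ecological normal modes: uniquely oriented latents and loadings.

    ``y[:, k]`` is the k-th ECN (orthonormal columns); ``phi[k]`` its
    loadings on every (OTU, subject); ``eigenvalues[k]`` its relaxation
    eigenvalue under the decoupled dynamics
    y_{t+1,k} = Lambda_k y_tk + u'_k + noise. Modes are numbered 1..K in
    descending |Lambda| and signed so that each mode's largest-magnitude
    loading entry is positive.
    """

    y: np.ndarray             # (T, K)
    phi: np.ndarray           # (K, O, S)
    eigenvalues: np.ndarray   # (K,)
    rotation: np.ndarray      # v, (K, K) orthogonal: A = v^T diag(Lambda) v
    baseline: np.ndarray      # u' = v u
    dynamics: DynamicsFit
    factors: OrthonormalFactors
    results: object | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.y.shape[1]

    def propensities(self, mode_subset=None) -> np.ndarray:
        """Propensities from the ECN parameterization.

        ``mode_subset`` — iterable of 1-based mode numbers; only those
        modes' terms enter the exponent (others zeroed), renormalized per
        sample. Default: all modes (identical to the source model).
        """
        if mode_subset is None:
            return _propensities(self.y, self.phi)
        modes = sorted(set(int(m) for m in mode_subset))
        if any(m < 1 or m > self.k for m in modes):
            raise ValueError(f"mode numbers must lie in 1..{self.k}")
        if not modes:
            warnings.warn("empty mode subset: returning uniform compositions")
            O, S = self.phi.shape[1:]
            T = self.y.shape[0]
            return np.full((O, S, T), 1.0 / O)
        idx = [m - 1 for m in modes]
        return _propensities(self.y[:, idx], self.phi[idx])

    def summary(self) -> str:
        lines = [
            "Ecological normal modes",
            "=" * 52,
            f"K = {self.k} modes, {self.y.shape[0]} time points, "
            f"{self.phi.shape[1]} OTUs x {self.phi.shape[2]} subjects",
            f"dynamics fit: {self.dynamics.method} "
            f"(residual {self.dynamics.residual_error:.4e}, "
            f"{self.dynamics.n_pairs} pairs)",
            "mode  eigenvalue   baseline u'",
        ]
        for i, (lam, up) in enumerate(zip(self.eigenvalues, self.baseline), 1):
            lines.append(f"{i:>4}  {lam:>10.4f}   {up:>10.4f}")
        return "\n".join(lines)


def diagonalize_to_ecns(
    factors: OrthonormalFactors, dynamics: DynamicsFit, results=None
) -> ECNResults:
    """Rotate orthonormal factors into the eigenbasis of the dynamics.

    With A = v^T Lambda v (v orthogonal, rows = eigenvectors), the ECNs
    are y_t = v z_t with loadings Phi = v theta, so that
    sum_k y_tk Phi_kos = sum_k z_tk theta_kos and predictions are
    untouched, while the fitted dynamics decouple mode by mode.
    """
    A = dynamics.A
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("interaction matrix must be symmetric")
    w, V = np.linalg.eigh(A)          # A = V diag(w) V^T
    order = np.argsort(-np.abs(w))
    lam = w[order]
    v = V[:, order].T                 # rows are eigenvectors
    y = factors.z @ v.T
    phi = np.einsum("kj,jos->kos", v, factors.theta)
    u_prime = v @ dynamics.u
    # sign convention: largest-|.| loading entry of each mode positive
    for k in range(v.shape[0]):
        flat = phi[k].ravel()
        if flat[np.argmax(np.abs(flat))] < 0:
            v[k] *= -1
            y[:, k] *= -1
            phi[k] *= -1
            u_prime[k] *= -1
    return ECNResults(
        y=y, phi=phi, eigenvalues=lam, rotation=v, baseline=u_prime,
        dynamics=dynamics, factors=factors, results=results,
    )
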