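"""Multinomial Gibbs–Boltzmann tensor factorization of longitudinal counts.

Read counts ``n_os(t)`` are modelled per observed sample as multinomial
with propensities

    q_os(t) = exp(-sum_k z_tk * theta_kos) / Omega_st,

where ``z`` (T × K) are time-specific latents shared by all OTUs and
subjects and ``theta`` (K × O × S) are OTU- and subject-specific loadings.
The log-likelihood (multinomial coefficient dropped) is

    ln L = sum_{s,t observed} sum_o n_os(t) log q_os(t),

maximized by plain gradient ascent. The factorization carries a gauge
freedom — (z B, B^{-1} theta) predicts identically for any invertible B —
which is resolved downstream (see :mod:`embed.ecn`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountTensor

__all__ = ["EMBED", "FitPreset", "PRESETS", "scan_k"]


@dataclass(frozen=True)
class FitPreset:
    """Stopping profile for gradient ascent."""

    tol: float
    max_iter: int


#: ``benchmark`` — reconstruction benchmarking; ``analysis`` — final analyses.
PRESETS = {
    "benchmark": FitPreset(tol=1e-3, max_iter=100_000),
    "analysis": FitPreset(tol=1e-4, max_iter=1_000_000),
}


def _check_shapes(data: CountTensor, z: np.ndarray, theta: np.ndarray) -> None:
    O, S, T = data.counts.shape
    if z.ndim != 2 or theta.ndim != 3:
        raise ValueError("z must be (T, K), theta (K, O, S)")
    K = z.shape[1]
    if z.shape[0] != T or theta.shape != (K, O, S):
        raise ValueError(
            f"inconsistent dimensions: z {z.shape}, theta {theta.shape}, "
            f"data (O,S,T)=({O},{S},{T})"
        )


def propensities(z: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Softmax propensities q[o, s, t] from latents and loadings.

    The per-sample maximum exponent is subtracted before exponentiation;
    in exact arithmetic the result is unchanged (the shift cancels in the
    normalizer Omega_st).
    """
    if z.ndim != 2 or theta.ndim != 3 or z.shape[1] != theta.shape[0]:
        raise ValueError("z must be (T, K) and theta (K, O, S) with matching K")
    logits = -np.einsum("tk,kos->ost", z, theta)
    logits -= logits.max(axis=0, keepdims=True)
    q = np.exp(logits)
    q /= q.sum(axis=0, keepdims=True)
    return q


class EMBED:
    """Tensor-factorization model of a :class:`~embed.data.CountTensor`.

    Parameters
    ----------
    data : CountTensor
    k : int
        Latent dimension K; K << min(O*S, T) is recommended but any
        positive K is accepted (larger K over-parameterizes the model
        without breaking it).
    normalized : bool or None
        Gradient scaling regime. When all observed samples share the same
        total (equal sequencing depth), the likelihood is normalized by
        the total read count and gradients use relative abundances; this
        is chosen automatically when ``None``.
    """

    def __init__(self, data: CountTensor, k: int, normalized: bool | None = None):
        if k < 1:
            raise ValueError("k must be a positive integer")
        if data.n_samples == 0:
            raise ValueError("no observed samples in data")
        self.data = data
        self.k = int(k)
        self.normalized = data.equal_depth() if normalized is None else bool(normalized)
        self._x = data.relative_abundances()
        self._mask3 = data.observed_mask[None, :, :]
        # per-sample weights entering gradients: N_s(t), or 1 in normalized mode
        w = np.where(data.observed_mask, data.totals, 0.0)
        self._w = np.ones_like(w) * data.observed_mask if self.normalized else w
        self._total_reads = float(data.totals[data.observed_mask].sum())
        # time points no subject observed: unconstrained by data
        self._unobserved_times = ~data.observed_mask.any(axis=0)

    # ------------------------------------------------------------------
    def propensities(self, z: np.ndarray, theta: np.ndarray) -> np.ndarray:
        _check_shapes(self.data, z, theta)
        return propensities(z, theta)

    def loglike(
        self, z: np.ndarray, theta: np.ndarray, normalized: bool | None = None
    ) -> float:
        """Multinomial log-likelihood (constant term omitted).

        With ``normalized=True`` the value is divided by the total read
        count over all observed samples.
        """
        q = self.propensities(z, theta)
        return self._loglike_from_q(q, normalized)

    def _loglike_from_q(self, q: np.ndarray, normalized: bool | None = None) -> float:
        # effective counts x * N: equal to raw counts when totals are
        # column sums, weighted compositions in absolute-abundance mode
        n = self._x * np.where(self.data.observed_mask, self.data.totals, 0.0)
        ll = float(np.sum(n * np.log(q), where=n > 0))
        if normalized is None:
            normalized = self.normalized
        return ll / self._total_reads if normalized else ll

    def score(
        self, z: np.ndarray, theta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Exact gradients of the (raw) log-likelihood wrt (z, theta).

        d lnL / d z_tk     = -sum_{o,s} N_s(t) (x_os(t) - q_os(t)) theta_kos
        d lnL / d theta_kos = -sum_t    N_s(t) z_tk (x_os(t) - q_os(t))

        Missing samples contribute zero. These match central finite
        differences of ``loglike(..., normalized=False)``; the optimizer
        internally rescales them in normalized mode.
        """
        q = self.propensities(z, theta)
        w = np.where(self.data.observed_mask, self.data.totals, 0.0)
        resid = w[None] * (self._x - q) * self._mask3  # (O, S, T)
        g_z = -np.einsum("ost,kos->tk", resid, theta)
        g_theta = -np.einsum("tk,ost->kos", z, resid)
        return g_z, g_theta

    def _score_from_q(
        self, q: np.ndarray, z: np.ndarray, theta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Ascent-direction gradients: N-weighted, or relative-abundance
        weighted in normalized mode, with a negligible ridge pulling the
        latents of fully unobserved time points toward zero."""
        resid = self._w[None] * (self._x - q) * self._mask3  # (O, S, T)
        g_z = -np.einsum("ost,kos->tk", resid, theta)
        g_theta = -np.einsum("tk,ost->kos", z, resid)
        if self._unobserved_times.any():
            g_z[self._unobserved_times] -= 2e-8 * z[self._unobserved_times]
        return g_z, g_theta

    # ------------------------------------------------------------------
    def fit(
        self,
        learning_rate: float = 0.005,
        preset: str = "benchmark",
        tol: float | None = None,
        max_iter: int | None = None,
        seed: int = 0,
        init_scale: float = 0.1,
    ) -> "EMBEDResults":
        """Maximize the likelihood by gradient ascent.

        Latents and loadings are initialized i.i.d. uniform on
        ``[-init_scale, init_scale]`` from ``seed``. Ascent stops when the
        relative gradient norms ``||g|| / max(||param||, 1)`` of both z
        and theta fall below ``tol``, or at ``max_iter``. A step that
        decreases the likelihood (or makes it non-finite) is retried at a
        halved step size; the step size then relaxes back toward
        ``learning_rate``.
        """
        from .results import EMBEDResults

        prof = PRESETS[preset]
        tol = prof.tol if tol is None else float(tol)
        max_iter = prof.max_iter if max_iter is None else int(max_iter)
        rng = np.random.default_rng(seed)
        T = self.data.n_times
        O, S = self.data.n_otus, self.data.n_subjects
        z = rng.uniform(-init_scale, init_scale, size=(T, self.k))
        theta = rng.uniform(-init_scale, init_scale, size=(self.k, O, S))

        q = self.propensities(z, theta)
        ll = self._loglike_from_q(q)
        eta = float(learning_rate)
        trace = [ll]
        n_backtracks = 0
        converged = False
        rel_g = (np.inf, np.inf)
        n_steps = 0
        for it in range(1, max_iter + 1):
            g_z, g_theta = self._score_from_q(q, z, theta)
            rel_g = (
                np.linalg.norm(g_z) / max(np.linalg.norm(z), 1.0),
                np.linalg.norm(g_theta) / max(np.linalg.norm(theta), 1.0),
            )
            if max(rel_g) < tol:
                converged = True
                break
            for attempt in range(60):
                z_new = z + eta * g_z
                theta_new = theta + eta * g_theta
                q_new = self.propensities(z_new, theta_new)
                ll_new = self._loglike_from_q(q_new)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-13 * max(abs(ll), 1.0):
                    break
                eta *= 0.5
                n_backtracks += 1
            else:
                raise RuntimeError(
                    "gradient ascent failed: likelihood not improvable at "
                    f"iteration {it} (step size {eta:.2e})"
                )
            z, theta, q, ll = z_new, theta_new, q_new, ll_new
            trace.append(ll)
            n_steps += 1
            eta = min(float(learning_rate), eta * 1.5)

        return EMBEDResults(
            model=self,
            z=z,
            theta=theta,
            converged=converged,
            n_iter=n_steps,
            rel_grad_z=float(rel_g[0]),
            rel_grad_theta=float(rel_g[1]),
            loglike_trace=np.asarray(trace),
            n_backtracks=n_backtracks,
            seed=int(seed),
            learning_rate=float(learning_rate),
            tol=tol,
            max_iter=max_iter,
        )


def scan_k(
    data: CountTensor,
    k_values: list[int],
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one model per K (same seed policy) for elbow-style selection.

    Returns a DataFrame sorted by K with the final normalized
    log-likelihood and the mean time-normalized KL divergence between
    data and reconstruction; the caller inspects the elbow. Fit failures
    are recorded per row rather than raised.
    """
    from .analysis import kl_reconstruction_error

    if not k_values or any(k < 1 for k in k_values):
        raise ValueError("k_values must be non-empty positive integers")
    rows = []
    for k in sorted(k_values):
        row: dict = {"K": k}
        try:
            res = EMBED(data, k).fit(seed=seed, **fit_kwargs)
            row["loglike"] = res.model._loglike_from_q(
                res.fitted_propensities(), normalized=True
            )
            row["normalized_kl"] = float(
                np.mean(
                    kl_reconstruction_error(
                        data.relative_abundances(),
                        res.fitted_propensities(),
                        data.observed_mask,
                    )
                )
            )
            row["converged"] = res.converged
            row["error"] = ""
        except Exception as exc:  # annotate, keep scanning
            row.update(loglike=np.nan, normalized_kl=np.nan, converged=False,
                       error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
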