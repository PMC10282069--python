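"""Results object for the fitted factorization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import EMBED

__all__ = ["EMBEDResults"]


@dataclass
class EMBEDResults:
    """Fitted latents/loadings plus optimizer diagnostics.

    The parameters are defined only up to an invertible K × K gauge
    transform (z -> zB, theta -> B^{-1} theta leaves propensities
    unchanged); :meth:`to_ecn` resolves the gauge into the unique
    orthonormal ecological normal modes.
    """

    model: EMBED
    z: np.ndarray            # (T, K)
    theta: np.ndarray        # (K, O, S)
    converged: bool
    n_iter: int
    rel_grad_z: float
    rel_grad_theta: float
    loglike_trace: np.ndarray
    n_backtracks: int
    seed: int
    learning_rate: float
    tol: float
    max_iter: int
    _q: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.z.shape[1]

    def fitted_propensities(self) -> np.ndarray:
        """Model propensities q[o, s, t] at the fitted parameters."""
        if self._q is None:
            self._q = self.model.propensities(self.z, self.theta)
        return self._q

    def loglike(self, normalized: bool | None = None) -> float:
        return self.model._loglike_from_q(self.fitted_propensities(), normalized)

    # ------------------------------------------------------------------
    def orthonormalize(self):
        """Gauge-fix the latents to an orthonormal basis (Gram–Schmidt)."""
        from .ecn import orthonormalize_latents

        return orthonormalize_latents(self)

    def to_ecn(self, seed: int | None = None, **dynamics_kwargs):
        """Run the full reorientation chain to ecological normal modes.

        Orthonormalizes the latents, fits the symmetric linear dynamics
        z_{t+1} = A z_t + u + noise, and rotates into the eigenbasis of
        A. Predictions are unchanged at every step.
        """
        from .ecn import diagonalize_to_ecns, fit_linear_dynamics

        factors = self.orthonormalize()
        if seed is None:
            seed = self.seed
        dyn = fit_linear_dynamics(
            factors.z,
            time_observed=self.model.data.observed_mask.any(axis=0),
            seed=seed,
            **dynamics_kwargs,
        )
        return diagonalize_to_ecns(factors, dyn, results=self)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        d = self.model.data
        lines = [
            "Gibbs-Boltzmann tensor factorization",
            "=" * 52,
            f"OTUs: {d.n_otus}   subjects: {d.n_subjects}   "
            f"time points: {d.n_times} ({d.n_samples} observed samples)",
            f"latent dimension K:      {self.k}",
            f"mode:                    "
            f"{'normalized (equal depth)' if self.model.normalized else 'raw counts'}",
            f"converged:               {self.converged} "
            f"({self.n_iter} iterations, {self.n_backtracks} backtracks)",
            f"rel. gradient (z, theta): {self.rel_grad_z:.3e}, "
            f"{self.rel_grad_theta:.3e}  (tol {self.tol:g})",
            f"log-likelihood:          {self.loglike():.6f}"
            + (" (per read)" if self.model.normalized else ""),
            f"seed: {self.seed}   learning rate: {self.learning_rate:g}",
        ]
        return "\n".join(lines)
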