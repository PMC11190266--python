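"""Regularized maximum-pseudolikelihood inference of Potts models.

The pseudolikelihood replaces the intractable full likelihood by the
product over positions of the conditional likelihood of each symbol
given the rest of the sequence. For sequence ``s`` with redundancy
weight ``w``, the (negative) objective minimized here is

    f(h, J) = sum_s w_s sum_i [ log Z_i(s) - h[i, s_i]
                                 - sum_{j != i} J[i, j, s_i, s_j] ]
              + lambda_h ||h||^2 + lambda_J ||J||^2

with ``Z_i(s)`` the per-site normalizer over the alphabet. ``J`` is
estimated asymmetrically (each site's conditional owns its own rows)
and the returned couplings are the average of the two asymmetric
estimates, the standard plmDCA symmetrization.

The interface follows the statsmodels convention: construct a
:class:`PottsPseudolikelihood` model from an alignment, call ``fit()``,
and read estimates and diagnostics off the returned :class:`PlmResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .msa import Alignment, WeightSet, sequence_weights
from .potts import PottsModel


class PottsPseudolikelihood:
    """Potts model estimator for a filtered, reweighted alignment.

    Parameters
    ----------
    alignment : Alignment
        Filtered alignment; its alphabet defines q.
    weights : WeightSet, optional
        Redundancy weights; computed at ``theta`` if omitted.
    theta : float
        Distance cutoff used when weights are computed here.
    lambda_h, lambda_J : float
        L2 penalty strengths. ``lambda_J`` defaults to
        ``lambda_h * (L - 1) * (q - 1)``, scaling the coupling penalty
        with the number of interaction partners per site.
    """

    def __init__(
        self,
        alignment: Alignment,
        weights: WeightSet | None = None,
        theta: float = 0.2,
        lambda_h: float = 0.01,
        lambda_J: float | None = None,
    ) -> None:
        self.alignment = alignment
        self.weights = weights if weights is not None else sequence_weights(alignment, theta)
        if self.weights.weights.shape[0] != alignment.n_records:
            raise ValueError("weights do not align 1:1 with alignment records")
        self.X = alignment.encoded()
        self.n, self.L = self.X.shape
        self.q = len(alignment.alphabet)
        self.lambda_h = float(lambda_h)
        self.lambda_J = (
            float(lambda_J) if lambda_J is not None
            else self.lambda_h * (self.L - 1) * (self.q - 1)
        )
        # one-hot encoding used by both objective and gradient
        self._onehot = np.zeros((self.n, self.L, self.q))
        self._onehot[np.arange(self.n)[:, None], np.arange(self.L)[None, :], self.X] = 1.0

    # -- parameter vector layout: h (L*q) then asymmetric J (L*L*q*q) ----

    def _unflatten(self, theta_vec: np.ndarray):
        L, q = self.L, self.q
        h = theta_vec[: L * q].reshape(L, q)
        J = theta_vec[L * q :].reshape(L, L, q, q)
        return h, J

    def _objective(self, theta_vec: np.ndarray):
        L, q = self.L, self.q
        h, J = self._unflatten(theta_vec)
        J = J.copy()
        J[np.arange(L), np.arange(L)] = 0.0
        O = self._onehot
        w = self.weights.weights

        logits = h[None] + np.tensordot(O, J, axes=([1, 2], [1, 3]))  # (n, i, a)
        lse = logsumexp(logits, axis=2)  # (n, i)
        picked = np.take_along_axis(logits, self.X[:, :, None], axis=2)[:, :, 0]
        f = float((w[:, None] * (lse - picked)).sum())
        f += self.lambda_h * float((h * h).sum()) + self.lambda_J * float((J * J).sum())

        P = softmax(logits, axis=2)
        G = w[:, None, None] * (P - O)  # (n, i, a)
        grad_h = G.sum(axis=0) + 2.0 * self.lambda_h * h
        grad_J = np.tensordot(G, O, axes=([0], [0]))  # (i, a, j, b)
        grad_J = np.transpose(grad_J, (0, 2, 1, 3)) + 2.0 * self.lambda_J * J
        grad_J[np.arange(L), np.arange(L)] = 0.0
        return f, np.concatenate([grad_h.ravel(), grad_J.ravel()])

    def fit(self, maxiter: int = 500, gtol: float = 1e-5, ftol: float = 1e-9,
            start_params=None) -> "PlmResults":
        """Minimize the penalized negative pseudolikelihood with L-BFGS-B.

        Non-convergence within ``maxiter`` emits a warning and is flagged
        in the result and the model metadata, never silently ignored.
        """
        n_params = self.L * self.q + self.L * self.L * self.q * self.q
        x0 = np.zeros(n_params) if start_params is None else np.asarray(start_params, float)
        res = minimize(
            self._objective, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol,
                     "maxfun": 10 * maxiter},
        )
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"pseudolikelihood optimizer did not converge: {res.message}",
                RuntimeWarning, stacklevel=2,
            )
        h, J_asym = self._unflatten(res.x)
        J_asym = J_asym.copy()
        J_asym[np.arange(self.L), np.arange(self.L)] = 0.0
        J = 0.5 * (J_asym + np.transpose(J_asym, (1, 0, 3, 2)))

        aln = self.alignment
        index_map = np.asarray(aln.focus_columns, dtype=np.int64) + 1
        model = PottsModel(
            h=h.copy(), J=J, alphabet=aln.alphabet,
            index_map=index_map,
            target_seq=aln.encoded()[aln.target_index],
            metadata={
                "method": "pseudolikelihood",
                "theta": self.weights.theta,
                "n_eff": self.weights.n_eff,
                "n_records": self.n,
                "lambda_h": self.lambda_h,
                "lambda_J": self.lambda_J,
                "converged": converged,
                "n_iter": int(res.nit),
                "objective": float(res.fun),
                "optimizer_message": str(res.message),
            },
        )
        return PlmResults(self, model, converged=converged, n_iter=int(res.nit),
                          objective=float(res.fun),
                          grad_norm=float(np.abs(res.jac).max()))


@dataclass
class PlmResults:
    """Fit result: the estimated :class:`PottsModel` plus diagnostics."""

    estimator: PottsPseudolikelihood
    params: PottsModel
    converged: bool
    n_iter: int
    objective: float
    grad_norm: float

    @property
    def model(self) -> PottsModel:
        """The estimated Potts model (alias of ``params``)."""
        return self.params

    def summary(self) -> str:
        est = self.estimator
        lines = [
            "Potts pseudolikelihood fit",
            "=" * 42,
            f"{'Positions (L)':<28}{est.L:>14d}",
            f"{'Alphabet size (q)':<28}{est.q:>14d}",
            f"{'Sequences (n)':<28}{est.n:>14d}",
            f"{'Effective sequences (Neff)':<28}{est.weights.n_eff:>14.2f}",
            f"{'Reweighting theta':<28}{est.weights.theta:>14.3f}",
            f"{'lambda_h':<28}{est.lambda_h:>14.4g}",
            f"{'lambda_J':<28}{est.lambda_J:>14.4g}",
            f"{'Converged':<28}{str(self.converged):>14}",
            f"{'Iterations':<28}{self.n_iter:>14d}",
            f"{'Objective':<28}{self.objective:>14.4f}",
            f"{'Max |gradient|':<28}{self.grad_norm:>14.3e}",
            "=" * 42,
        ]
        return "\n".join(lines)


def fit_plm(
    aln: Alignment,
    weights: WeightSet | None = None,
    lambda_h: float = 0.01,
    lambda_J: float | None = None,
    maxiter: int = 500,
    gtol: float = 1e-5,
    ftol: float = 1e-9,
) -> PottsModel:
    """Convenience wrapper: fit and return the PottsModel directly."""
    return PottsPseudolikelihood(
        aln, weights=weights, lambda_h=lambda_h, lambda_J=lambda_J
    ).fit(maxiter=maxiter, gtol=gtol, ftol=ftol).params
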