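"""Propagation of Poisson bin errors into quantity covariances.

At a frozen-PMF optimum the quantities satisfy the score equations
sum_cells H(c) P_k(c) / M(c) = 1 for every active component.  Implicit
differentiation gives the sensitivity dQ/dH of the fitted quantities to each
histogram cell, and summing independent Poisson cell variances (sigma^2_H
taken as max(H, 1) so empty cells are not treated as noiseless) yields the
quantity covariance

    C = s * sum_c (dQ_i/dH_c)(dQ_j/dH_c) sigma^2_c,

where the scale s is the fit's chi^2 per degree of freedom, clamped at >= 1
so that an over-good fit never shrinks errors.  A finite-difference mode
re-runs the quantity fit under cell perturbations as an independent check,
and a full-training mode additionally propagates training-cohort cells
through PMF re-estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import lpm_core
from .histogram_builder import PairedHistogram
from .lpm_core import FitResult, LPModel, _fit_q

logger = logging.getLogger(__name__)

METHODS = ("analytic", "finite_difference", "full_training_propagation")


@dataclass
class QuantityCovariance:
    """K x K covariance of fitted quantities with its provenance."""

    cov: np.ndarray
    chi2_scale: float
    method: str

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
            raise ValueError("covariance must be symmetric")
        self.cov = 0.5 * (cov + cov.T)


def _active_set(q: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
    return q > rel_tol * max(q.sum(), 1.0)


def _analytic_dq_dh(P: np.ndarray, h: np.ndarray, q: np.ndarray) -> np.ndarray:
    K, C = P.shape
    D = np.zeros((K, C))
    active = _active_set(q)
    if not active.any():
        return D
    Pa = P[active]
    M = np.maximum(q @ P, lpm_core.LOG_FLOOR)
    A = (Pa * (h / M**2)) @ Pa.T
    B = Pa / M
    sol = np.linalg.solve(A, B)
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError("non-finite implicit-derivative solution")
    D[active] = sol
    return D


def _fd_dq_dh(P: np.ndarray, h: np.ndarray, q: np.ndarray,
              rel_step: float = 0.01, tol: float = 0.0,
              max_iter: int = 3000) -> np.ndarray:
    # tol 0 runs the refits for the full iteration budget: EM's tail is
    # slow, and a likelihood-change stop leaves the perturbed optimum
    # under-resolved relative to the small step
    K, C = P.shape
    D = np.zeros((K, C))
    for c in range(C):
        delta = max(1.0, rel_step * h[c])
        hp = h.copy()
        hp[c] = h[c] + delta
        hm = h.copy()
        hm[c] = max(h[c] - delta, 0.0)
        step = hp[c] - hm[c]
        qp, _, _, _ = _fit_q(P, hp, q, tol, max_iter)
        qm, _, _, _ = _fit_q(P, hm, q, tol, max_iter)
        D[:, c] = (qp - qm) / step
    return D


def dq_dh(model: LPModel, histo: PairedHistogram, fit: FitResult, *,
          method: str = "analytic", fd_rel_step: float = 0.01) -> np.ndarray:
    """Derivatives of fitted quantities w.r.t. each histogram cell, (K, B*2).

    ``analytic`` uses implicit differentiation of the score equations on the
    active component set (components with vanishing quantity get zero rows);
    ``finite_difference`` re-runs the frozen-PMF quantity fit with each cell
    perturbed by +-delta, delta = max(1, 0.01 * H_cell).  A singular score
    Hessian triggers a logged fallback to finite differences.
    """
    P = model.components.flat
    h = histo.counts.astype(float).ravel()
    q = fit.quantities
    if method == "analytic":
        try:
            return _analytic_dq_dh(P, h, q)
        except np.linalg.LinAlgError:
            logger.warning("singular score Hessian; falling back to finite "
                           "differences")
            return _fd_dq_dh(P, h, q, fd_rel_step)
    if method == "finite_difference":
        return _fd_dq_dh(P, h, q, fd_rel_step)
    raise ValueError(f"unknown derivative method {method!r}")


def _batched_em(Hb: np.ndarray, P0: np.ndarray, Q0: np.ndarray,
                n_frozen: int, tol: float, max_iter: int):
    """Run N independent warm-started EMs in one vectorized loop.

    ``Hb`` has shape (N, S, C): N perturbed copies of a cohort.  ``P0`` and
    ``Q0`` are the shared converged starting point (broadcast over N).
    Convergence is checked on the maximum relative quantity change.
    """
    N = Hb.shape[0]
    K = P0.shape[-2]
    P = np.broadcast_to(P0, (N,) + P0.shape[-2:]).copy()
    Q = np.broadcast_to(Q0, (N,) + Q0.shape[-2:]).copy()
    for it in range(1, max_iter + 1):
        M = Q @ P
        R = Hb / np.maximum(M, lpm_core.LOG_FLOOR)
        Q_new = Q * (R @ P.transpose(0, 2, 1))
        if n_frozen < K:
            upd = Q.transpose(0, 2, 1) @ R
            Pf = P[:, n_frozen:, :] * upd[:, n_frozen:, :]
            rs = Pf.sum(axis=2, keepdims=True)
            np.divide(Pf, rs, out=Pf, where=rs > 0)
            P[:, n_frozen:, :] = Pf
        if it % 10 == 0:
            delta = np.max(np.abs(Q_new - Q) / (np.abs(Q) + 1e-9))
            Q = Q_new
            if delta < tol:
                break
        else:
            Q = Q_new
    return P, Q


def _batched_fit_q(Pb: np.ndarray, hb: np.ndarray, q0: np.ndarray,
                   tol: float = 1e-10, max_iter: int = 5000) -> np.ndarray:
    """Quantities-only EM for N (PMF set, histogram) pairs at once."""
    N = Pb.shape[0]
    q = np.broadcast_to(q0, (N, q0.shape[-1])).copy()
    for it in range(1, max_iter + 1):
        M = np.einsum("nk,nkc->nc", q, Pb)
        R = hb / np.maximum(M, lpm_core.LOG_FLOOR)
        q_new = q * np.einsum("nkc,nc->nk", Pb, R)
        if it % 20 == 0:
            delta = np.max(np.abs(q_new - q) / (np.abs(q) + 1e-9))
            q = q_new
            if delta < tol:
                break
        else:
            q = q_new
    return q


class TrainingPropagation:
    """Precomputed PMF sensitivities to every training-cohort cell.

    One-sided finite differences: each occupied cell of the control and
    treated training cohorts is perturbed by delta = max(1, 0.01 * H) and
    the affected EM stages re-run warm-started from the converged solution,
    so only the local response is measured (no restart jumps).  The
    perturbed PMF sets are computed once per study and shared by every test
    tumor, whose quantity refits are then cheap batched EMs.
    """

    def __init__(self, model: LPModel, control_histos, treated_histos=None, *,
                 fd_rel_step: float = 0.01, warm_tol: float = 1e-9,
                 warm_iter: int = 300):
        self.model = model
        self.fd_rel_step = fd_rel_step
        n_c = model.components.n_control
        n_t = model.components.n_treatment
        P = model.components.flat
        self.control_ids = [h.tumor_id for h in control_histos]
        self.treated_ids = [h.tumor_id for h in (treated_histos or [])]
        Hc = np.stack([h.counts.astype(float).ravel() for h in control_histos])
        Qc = np.stack([model.quantities[t][:n_c] for t in self.control_ids])
        if n_t:
            if not treated_histos:
                raise ValueError("model has treatment components; "
                                 "treated_histos required")
            Ht = np.stack([h.counts.astype(float).ravel()
                           for h in treated_histos])
            Qt = np.stack([model.quantities[t] for t in self.treated_ids])

        # perturbation bookkeeping: (cohort, tumor index, cell, delta, sigma2);
        # the first record of each cohort block is an unperturbed reference,
        # so that residual EM drift from the warm pipeline cancels in the
        # one-sided differences instead of polluting them
        recs = [("control", -1, -1, 0.0, 0.0)]
        occupied_c = Hc.sum(axis=0) > 0
        for i in range(Hc.shape[0]):
            for c in np.flatnonzero(occupied_c):
                delta = max(1.0, fd_rel_step * Hc[i, c])
                recs.append(("control", i, c, delta, max(Hc[i, c], 1.0)))
        n_ctrl_block = len(recs)
        if n_t:
            recs.append(("treated", -1, -1, 0.0, 0.0))
            occupied_t = Ht.sum(axis=0) > 0
            for j in range(Ht.shape[0]):
                for c in np.flatnonzero(occupied_t):
                    delta = max(1.0, fd_rel_step * Ht[j, c])
                    recs.append(("treated", j, c, delta, max(Ht[j, c], 1.0)))
        self.records = recs
        self.ref_index = {"control": 0, "treated": n_ctrl_block}

        # batched control-stage retrains (reference row included)
        ctrl = recs[:n_ctrl_block]
        Hb = np.repeat(Hc[None], len(ctrl), axis=0)
        for n, (_, i, c, delta, _) in enumerate(ctrl):
            if i >= 0:
                Hb[n, i, c] += delta
        Pc_b, _ = _batched_em(Hb, P[:n_c], Qc, 0, warm_tol, warm_iter)
        if n_t:
            # push the perturbed control PMFs through the treatment stage
            P0 = np.concatenate(
                [Pc_b, np.repeat(P[None, n_c:], len(ctrl), axis=0)], axis=1)
            Hb_t = np.broadcast_to(Ht, (len(ctrl),) + Ht.shape).copy()
            Pb_ctrl, _ = _batched_em(Hb_t, P0, Qt, n_c, warm_tol, warm_iter)
            # treated-cohort perturbations: control PMFs unaffected
            trt = recs[n_ctrl_block:]
            Hb2 = np.repeat(Ht[None], len(trt), axis=0)
            for n, (_, j, c, delta, _) in enumerate(trt):
                if j >= 0:
                    Hb2[n, j, c] += delta
            Pb_trt, _ = _batched_em(Hb2, P, Qt, n_c, warm_tol, warm_iter)
            self.Pb = np.concatenate([Pb_ctrl, Pb_trt], axis=0)
        else:
            self.Pb = Pc_b

    def covariance_core(self, histo: PairedHistogram,
                        fit: FitResult) -> np.ndarray:
        """Derivative outer-product sum for one test tumor.

        If the test tumor belongs to a training cohort, perturbations of its
        training copy also perturb the test histogram (total derivative);
        otherwise a frozen-PMF analytic term covers its own cells.
        """
        h = histo.counts.astype(float).ravel()
        q = fit.quantities
        N = len(self.records)
        hb = np.broadcast_to(h, (N, h.size)).copy()
        own = None
        if histo.tumor_id in self.control_ids:
            own = ("control", self.control_ids.index(histo.tumor_id))
        elif histo.tumor_id in self.treated_ids:
            own = ("treated", self.treated_ids.index(histo.tumor_id))
        deltas = np.empty(N)
        sigma2 = np.empty(N)
        for n, (grp, i, c, delta, s2) in enumerate(self.records):
            deltas[n] = delta
            sigma2[n] = s2
            if own == (grp, i):
                hb[n, c] += delta
        qb = _batched_fit_q(self.Pb, hb, q)
        # difference against the same-stage unperturbed reference run
        q_ref = np.empty_like(qb)
        for n, (grp, i, _, _, _) in enumerate(self.records):
            q_ref[n] = qb[self.ref_index[grp]]
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(deltas[:, None] > 0,
                         (qb - q_ref) / np.where(deltas > 0, deltas, 1.0)[:, None],
                         0.0)
        core = np.einsum("nk,nl,n->kl", D, D, sigma2)
        if own is None:
            P = self.model.components.flat
            Dt = _analytic_dq_dh(P, h, q)
            core = core + (Dt * np.maximum(h, 1.0)) @ Dt.T
        return core


def quantity_covariance(model: LPModel, histo: PairedHistogram,
                        fit: FitResult, chi2_dof: float, *,
                        method: str = "analytic", clamp_scale: bool = True,
                        fd_rel_step: float = 0.01, control_histos=None,
                        treated_histos=None) -> QuantityCovariance:
    """Covariance of the fitted quantities from independent Poisson bin errors.

    sigma^2_H = max(H, 1) per cell; the chi^2_D goodness-of-fit scale boosts
    errors for poorly modeled data and, with ``clamp_scale`` (default), is
    never allowed below 1.  ``method`` selects the derivative route;
    ``full_training_propagation`` additionally needs the training cohorts
    (``control_histos`` and, for extended models, ``treated_histos``).
    """
    if chi2_dof < 0 or not np.isfinite(chi2_dof):
        raise ValueError("chi2_dof must be finite and non-negative")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    scale = max(1.0, chi2_dof) if clamp_scale else chi2_dof
    if method == "full_training_propagation":
        if control_histos is None:
            raise ValueError("full_training_propagation requires the "
                             "training cohorts")
        prop = TrainingPropagation(model, control_histos, treated_histos,
                                   fd_rel_step=fd_rel_step)
        core = prop.covariance_core(histo, fit)
    else:
        D = dq_dh(model, histo, fit, method=method, fd_rel_step=fd_rel_step)
        if not np.all(np.isfinite(D)):
            raise ValueError("non-finite derivatives")
        sigma2 = np.maximum(histo.counts.astype(float).ravel(), 1.0)
        core = (D * sigma2) @ D.T
    cov = scale * 0.5 * (core + core.T)
    return QuantityCovariance(cov, scale, method)


def total_treatment_error(cov: QuantityCovariance, treatment_indices) -> float:
    """1-SD error on the summed treatment quantities, sqrt(1^T C_TT 1)."""
    idx = np.asarray(treatment_indices, dtype=int)
    K = cov.cov.shape[0]
    if idx.size and (idx.min() < 0 or idx.max() >= K):
        raise IndexError("treatment indices out of range")
    if idx.size == 0:
        return 0.0
    var = float(cov.cov[np.ix_(idx, idx)].sum())
    if var < -1e-8 * max(np.trace(cov.cov), 1.0):
        raise ValueError("negative summed variance: PSD invariant broken")
    return float(np.sqrt(max(var, 0.0)))
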