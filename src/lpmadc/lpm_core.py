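"""Linear Poisson model core: extended-likelihood EM over paired histograms.

A cohort of paired ADC histograms H_i(ADC, t) is described as a non-negative
linear combination of K shared probability mass functions (PMFs) over the
B x 2 grid,

    H_i(ADC, t)  ~  Poisson( sum_k P_k(ADC, t) * q_ik ),

where each P_k sums to one over all cells and q_ik >= 0 is the expected
number of voxels of tumor i attributed to component k (its "quantity").
The extended Poisson log-likelihood

    ln L = sum_{i, cells} H_i ln M_i  -  sum_{i,k} q_ik,
    M_i = sum_k P_k q_ik,

treats the total expected count as fitted, so at a maximum sum_k q_ik equals
the observed total of each histogram.  Training is two-staged: control
components are learnt from the control cohort alone; treatment components
are then learnt from the treated cohort with the control PMFs frozen, so
that they absorb only variability the control model cannot express.  The EM
updates coincide with the multiplicative updates of non-negative matrix
factorization under generalized KL divergence and are monotone in ln L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .histogram_builder import BinningScheme, PairedHistogram

logger = logging.getLogger(__name__)

#: Floor applied inside logarithms of the model histogram during iteration,
#: protecting against -inf while components still have near-empty cells.
LOG_FLOOR = 1e-12

CONTROL = "control"
TREATMENT = "treatment"


@dataclass
class ComponentSet:
    """K non-negative PMFs over the B x 2 grid, control components first."""

    pmfs: np.ndarray  # (K, B, 2)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        pmfs = np.asarray(self.pmfs, dtype=float)
        if pmfs.ndim != 3 or pmfs.shape[2] != 2:
            raise ValueError("pmfs must have shape (K, B, 2)")
        if np.any(pmfs < 0):
            raise ValueError("PMFs must be non-negative")
        sums = pmfs.reshape(pmfs.shape[0], -1).sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            raise ValueError("every PMF must sum to 1 within 1e-12")
        labels = tuple(self.labels)
        if len(labels) != pmfs.shape[0]:
            raise ValueError("one label per component required")
        if any(lab not in (CONTROL, TREATMENT) for lab in labels):
            raise ValueError(f"labels must be {CONTROL!r} or {TREATMENT!r}")
        n_c = labels.count(CONTROL)
        if labels != (CONTROL,) * n_c + (TREATMENT,) * (len(labels) - n_c):
            raise ValueError("control components must precede treatment components")
        self.pmfs = pmfs
        self.labels = labels

    @property
    def n_components(self) -> int:
        return self.pmfs.shape[0]

    @property
    def n_control(self) -> int:
        return self.labels.count(CONTROL)

    @property
    def n_treatment(self) -> int:
        return self.labels.count(TREATMENT)

    @property
    def control_indices(self) -> np.ndarray:
        return np.arange(self.n_control)

    @property
    def treatment_indices(self) -> np.ndarray:
        return np.arange(self.n_control, self.n_components)

    @property
    def flat(self) -> np.ndarray:
        """PMFs flattened to (K, B*2) for linear algebra."""
        return self.pmfs.reshape(self.n_components, -1)


@dataclass
class LPModel:
    """Trained linear Poisson model: shared components + per-tumor quantities."""

    components: ComponentSet
    binning: BinningScheme
    quantities: dict[str, np.ndarray]  # tumor_id -> (K,) training quantities
    training_meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.components.n_components


@dataclass
class FitResult:
    """Quantity fit of a trained model to one histogram."""

    quantities: np.ndarray        # (K,)
    model_hist: np.ndarray        # (B, 2), M(ADC, t) = sum_k P_k q_k
    loglik: float
    chi2_dof: float
    converged: bool = True
    n_iter: int = 0

    @property
    def total_quantity(self) -> float:
        return float(self.quantities.sum())


# ---------------------------------------------------------------------------
# likelihood and goodness of fit


def _hist_matrix(histos: list[PairedHistogram]) -> np.ndarray:
    return np.stack([h.counts.astype(float).ravel() for h in histos])


def log_likelihood(histos, components: ComponentSet, quantities) -> float:
    """Extended Poisson log-likelihood of histograms under given quantities.

    ``quantities`` holds one (K,) vector per histogram.  Cells with H = 0
    contribute only through the -sum(q) term; a cell with H > 0 but model
    mass exactly zero makes the likelihood -inf.
    """
    P = components.flat
    total = 0.0
    for h, q in zip(histos, quantities):
        q = np.asarray(q, dtype=float)
        if np.any(q < 0):
            raise ValueError("quantities must be non-negative")
        H = h.counts.astype(float).ravel()
        if np.any(H < 0):
            raise ValueError("histogram counts must be non-negative")
        M = q @ P
        mask = H > 0
        if np.any(M[mask] <= 0):
            return float("-inf")
        total += float(H[mask] @ np.log(M[mask]) - q.sum())
    return total


def sqrt_residual_chi2(counts_list, model_list, n_free_params: int):
    """Variance-stabilized chi^2 per degree of freedom.

    chi2_D = (1/D) * sum_cells (sqrt(H) - sqrt(M))^2 / (1/4), where 1/4 is
    the asymptotic variance of the square root of a Poisson variate.  Cells
    with H = 0 and M = 0 carry no information and are excluded;
    D = (cells used) - n_free_params.

    Returns ``(chi2_dof, dof, n_cells_used, residuals)`` where ``residuals``
    is the concatenated array of per-cell normalized squared residuals.
    """
    res_parts = []
    used = 0
    for H, M in zip(counts_list, model_list):
        H = np.asarray(H, dtype=float).ravel()
        M = np.asarray(M, dtype=float).ravel()
        mask = (H > 0) | (M > 0)
        used += int(mask.sum())
        res_parts.append(4.0 * (np.sqrt(H[mask]) - np.sqrt(M[mask])) ** 2)
    dof = used - int(n_free_params)
    if dof <= 0:
        raise ValueError("model over-parameterized for data")
    residuals = np.concatenate(res_parts) if res_parts else np.empty(0)
    return float(residuals.sum() / dof), dof, used, residuals


# ---------------------------------------------------------------------------
# EM engine


def _loglik_floored(H: np.ndarray, M: np.ndarray, q_total: float) -> float:
    mask = H > 0
    return float(H[mask] @ np.log(np.maximum(M[mask], LOG_FLOOR)) - q_total)


def _em_run(H: np.ndarray, P: np.ndarray, Q: np.ndarray, n_frozen: int,
            tol: float, max_iter: int):
    """Joint EM on quantities + the non-frozen PMF rows.

    E-step responsibilities r_k = P_k q_k / M; M-step q_ik = sum_c H r_k and
    P_k(c) proportional to sum_i H_i(c) r_ik(c).  Both updates use the same
    responsibilities, which is the standard monotone EM step.
    """
    P = P.copy()
    Q = Q.copy()
    K = P.shape[0]
    ll_old = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = Q @ P
        R = H / np.maximum(M, LOG_FLOOR)
        Q_new = Q * (R @ P.T)          # rows of P sum to 1
        if n_frozen < K:
            upd = Q.T @ R              # (K, C)
            free = slice(n_frozen, K)
            P_free = P[free] * upd[free]
            rs = P_free.sum(axis=1, keepdims=True)
            alive = rs[:, 0] > 0
            P_free[alive] /= rs[alive]
            P[n_frozen:][alive] = P_free[alive]
        Q = Q_new
        M = Q @ P
        ll = sum(_loglik_floored(H[i], M[i], Q[i].sum()) for i in range(H.shape[0]))
        trace.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    return P, Q, trace[-1], np.asarray(trace), converged, it


def _bump_init(pooled: np.ndarray, n_components: int,
               rng: np.random.Generator) -> np.ndarray:
    """Quantile-spaced unimodal starting PMFs for shared-component EM.

    Histogram components describe tissue sub-populations, which are unimodal
    along the ADC axis, so each component starts as a Gaussian bump placed
    at an (optionally jittered) quantile of the cohort's pooled per-column
    distribution.  This keeps restarts well separated along ADC — flat
    random initializations tend to collapse onto duplicated blends — while
    a small uniform floor keeps every cell reachable by EM.
    """
    B = pooled.shape[0]
    bins = np.arange(B)
    P0 = np.empty((n_components, B, 2))
    for t in range(2):
        col = pooled[:, t].astype(float)
        col = col / col.sum() if col.sum() > 0 else np.full(B, 1.0 / B)
        cdf = np.cumsum(col)
        mean = float(bins @ col)
        sd = float(np.sqrt(max(((bins - mean) ** 2) @ col, 1.0)))
        width = max(sd / max(n_components, 2) * 1.5, 1.0)
        for k in range(n_components):
            target = (k + 0.5) / n_components + rng.uniform(-0.3, 0.3) \
                / n_components
            mu = float(np.searchsorted(cdf, np.clip(target, 0.01, 0.99)))
            bump = np.exp(-0.5 * ((bins - mu) / width) ** 2)
            bump = bump / bump.sum() + 0.02 / B
            P0[k, :, t] = 0.5 * bump / bump.sum()
    return P0.reshape(n_components, -1)


def _spawn_rngs(seed: int, stage: int, restarts: int):
    ss = np.random.SeedSequence([int(seed), int(stage)])
    return [np.random.default_rng(c) for c in ss.spawn(restarts)]


def em_fit_control(histos: list[PairedHistogram], n_components: int, *,
                   seed: int = 0, restarts: int = 5, tol: float = 1e-8,
                   max_iter: int = 2000) -> LPModel:
    """Learn N_C shared control PMFs and per-tumor quantities from controls.

    Runs ``restarts`` EM optimizations from seeded Dirichlet(1) PMF
    initializations and keeps the best log-likelihood (ties go to the
    earliest restart).  Quantities are per tumor, never pooled.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if not histos:
        raise ValueError("at least one histogram is required")
    binning = histos[0].binning
    for h in histos:
        if h.binning != binning:
            raise ValueError("all histograms must share one binning scheme")
    H = _hist_matrix(histos)
    if H.sum() <= 0:
        raise ValueError("total counts must be positive")
    n_nonempty = int((H.sum(axis=0) > 0).sum())
    if n_components > n_nonempty:
        raise ValueError(
            f"n_components={n_components} exceeds {n_nonempty} non-empty cells")
    S, C = H.shape
    totals = H.sum(axis=1)

    best = None
    restart_log = []
    pooled = H.sum(axis=0).reshape(-1, 2)
    for r, rng in enumerate(_spawn_rngs(seed, 0, restarts)):
        P0 = _bump_init(pooled, n_components, rng)
        Q0 = np.tile((totals / n_components)[:, None], (1, n_components))
        P, Q, ll, trace, conv, n_iter = _em_run(H, P0, Q0, 0, tol, max_iter)
        restart_log.append({"restart": r, "loglik": ll, "converged": conv,
                            "n_iter": n_iter})
        logger.info("control EM restart %d: loglik=%.6f converged=%s iters=%d",
                    r, ll, conv, n_iter)
        if best is None or ll > best[2]:
            best = (P, Q, ll, trace, conv)
    P, Q, ll, trace, conv = best
    if not conv:
        logger.warning("control EM: best restart did not converge; "
                       "returning best iterate")
    # canonicalize to vertex components (likelihood exactly preserved)
    P, Q = _sharpen_components(P, Q)
    components = ComponentSet(P.reshape(n_components, binning.n_bins, 2),
                              (CONTROL,) * n_components)
    quantities = {h.tumor_id: Q[i].copy() for i, h in enumerate(histos)}
    meta = {"stage": "control", "seed": int(seed), "restarts": restarts,
            "tol": tol, "max_iter": max_iter, "loglik": ll,
            "converged": bool(conv), "restart_log": restart_log,
            "cohort_size": S, "loglik_trace": trace.tolist()}
    return LPModel(components, binning, quantities, meta)


def _sharpen_components(P: np.ndarray, Q: np.ndarray, passes: int = 3):
    """Canonicalize shared PMFs toward extreme (vertex) components.

    Any elementwise-feasible combination of the other components inside a
    PMF can be stripped and moved into the quantities without changing any
    model histogram (an exactly likelihood-flat family), so EM alone only
    identifies components up to such mixing.  A small LP per component
    selects the extreme representative, which maximizes the cone of
    histograms the learnt model can express.  Returns adjusted (P, Q).
    """
    K = P.shape[0]
    if K < 2:
        return P, Q
    P = P.copy()
    Q = Q.copy()
    for _ in range(passes):
        moved = 0.0
        for k in range(K):
            others = [l for l in range(K) if l != k]
            res = linprog(-np.ones(K - 1), A_ub=P[others].T, b_ub=P[k],
                          bounds=[(0, None)] * (K - 1), method="highs")
            if not res.success:
                continue
            beta = np.maximum(res.x, 0.0)
            s = float(beta.sum())
            if s <= 1e-10 or s >= 1.0 - 1e-9:
                continue
            resid = np.maximum(P[k] - beta @ P[others], 0.0)
            rsum = float(resid.sum())
            if rsum < 1e-9:
                continue
            P[k] = resid / rsum
            qk = Q[:, k].copy()
            for b_i, l in enumerate(others):
                Q[:, l] += qk * beta[b_i]
            Q[:, k] = qk * rsum
            moved += s
        if moved < 1e-10:
            break
    return P, Q


def _purify_treatment(P_c: np.ndarray, P_t: np.ndarray, Q: np.ndarray):
    """Canonicalize treatment PMFs to the minimal-treatment-quantity solution.

    The extended likelihood is unchanged by moving any elementwise-feasible
    control mixture out of a treatment PMF and into the control quantities,
    so the maximum is a flat ridge.  For each treatment component the largest
    such mixture (an LP: maximize sum(beta) s.t. sum_C beta_C P_C <= P_T,
    beta >= 0) is removed, keeping every model histogram bit-for-bit
    equivalent while selecting the lower-bound reading of the responding
    quantities.  Returns adjusted (P_t, Q).
    """
    n_c = P_c.shape[0]
    n_t = P_t.shape[0]
    C = P_c.shape[1]
    P_t = P_t.copy()
    Q = Q.copy()
    for m in range(n_t):
        pt = P_t[m]
        res = linprog(-np.ones(n_c), A_ub=P_c.T, b_ub=pt,
                      bounds=[(0, None)] * n_c, method="highs")
        if not res.success:
            logger.warning("purification LP failed for treatment component %d", m)
            continue
        beta = np.maximum(res.x, 0.0)
        s = float(beta.sum())
        if s <= 1e-12:
            continue
        resid = np.maximum(pt - beta @ P_c, 0.0)
        rsum = float(resid.sum())
        col = n_c + m
        qm = Q[:, col].copy()
        Q[:, :n_c] += np.outer(qm, beta)
        if rsum < 1e-9:
            # component fully explained by control behavior: retire it
            P_t[m] = np.full(C, 1.0 / C)
            Q[:, col] = 0.0
        else:
            P_t[m] = resid / rsum
            Q[:, col] = qm * rsum
    return P_t, Q


def extend_with_treatment(model: LPModel, treated_histos: list[PairedHistogram],
                          n_treatment: int, *, seed: int = 0, restarts: int = 5,
                          tol: float = 1e-8, max_iter: int = 2000,
                          purify: bool = True,
                          support_sigma: float = 2.0) -> LPModel:
    """Learn N_T treatment PMFs from the treated cohort, controls frozen.

    Control PMFs are kept bit-identical; treatment PMFs and all per-treated-
    tumor quantities (control and treatment alike) are optimized.

    The extended likelihood is flat along a ridge that trades control-shaped
    mass between the treatment PMFs and the control quantities, so the
    treatment components are only identified up to that ridge.  Two measures
    select its minimal-treatment end — the lower-bound reading of the
    responding volume: (i) each restart initializes the treatment PMFs from
    a randomized split of the positive residual left after a control-only
    quantity fit of the treated cohort (the variability control behavior
    cannot express), and (ii) with ``purify`` (default) any remaining
    elementwise-feasible control mixture is stripped from the fitted
    treatment PMFs by a small LP that leaves every model histogram, and
    hence the likelihood, exactly unchanged.
    """
    if n_treatment < 1:
        raise ValueError("n_treatment must be >= 1")
    if model.components.n_treatment:
        raise ValueError("model already has treatment components")
    if not treated_histos:
        raise ValueError("at least one treated histogram is required")
    binning = model.binning
    for h in treated_histos:
        if h.binning != binning:
            raise ValueError("treated histograms must share the model binning")
    H = _hist_matrix(treated_histos)
    n_nonempty = int((H.sum(axis=0) > 0).sum())
    n_c = model.components.n_control
    K = n_c + n_treatment
    if K > n_nonempty:
        raise ValueError(f"{K} components exceed {n_nonempty} non-empty cells")
    S, C = H.shape
    totals = H.sum(axis=1)
    P_c = model.components.flat.copy()

    # Control-only fit of each treated tumor; the pooled signed residual is
    # the variability the control model cannot express.  Treatment was
    # delivered after the baseline scan, so treatment-specific behavior can
    # only surface in the post-treatment column: post-column support is
    # restricted to cells where the treated cohort shows a significant
    # excess over the control model (multiplicative EM preserves exact
    # zeros, so the support never regrows).  The baseline column stays
    # unrestricted — a responding sub-population's pre-treatment ADC values
    # look like any other tissue.
    Qc0 = np.empty((S, n_c))
    resid = np.zeros(C)
    for i in range(S):
        qi, _, _, _ = _fit_q(P_c, H[i], np.full(n_c, totals[i] / n_c),
                             1e-10, max_iter)
        Qc0[i] = qi
        resid += H[i] - qi @ P_c
    pooled = H.sum(axis=0)
    significant = resid > support_sigma * np.sqrt(np.maximum(pooled, 1.0))
    post_cells = (np.arange(C) % 2) == 1  # flattened (B, 2) row-major order
    support = np.where(post_cells, significant, True)
    rpos = np.maximum(resid, 0.0)
    seed_shape = np.where(support, rpos + 0.02 * max(rpos.mean(), 1.0), 0.0)
    if seed_shape.sum() <= 0:
        raise ValueError("no significant treatment excess over the control "
                         "model; nothing for treatment components to describe")
    seed_shape /= seed_shape.sum()
    q_t0 = max(rpos.sum() / S, 1e-3 * totals.mean()) / n_treatment

    best = None
    restart_log = []
    for r, rng in enumerate(_spawn_rngs(seed, 1, restarts)):
        # randomized split of the residual shape across components
        split = rng.gamma(1.0, size=(n_treatment, C)) * seed_shape
        P0 = np.vstack([P_c, split / split.sum(axis=1, keepdims=True)])
        Q0 = np.hstack([Qc0, np.full((S, n_treatment), q_t0)])
        P, Q, ll, trace, conv, n_iter = _em_run(H, P0, Q0, n_c, tol, max_iter)
        restart_log.append({"restart": r, "loglik": ll, "converged": conv,
                            "n_iter": n_iter})
        logger.info("treatment EM restart %d: loglik=%.6f converged=%s iters=%d",
                    r, ll, conv, n_iter)
        if best is None or ll > best[2]:
            best = (P, Q, ll, trace, conv)
    P, Q, ll, trace, conv = best
    assert np.array_equal(P[:n_c], P_c), "frozen control PMFs must not change"
    if purify:
        P_t, Q = _purify_treatment(P_c, P[n_c:], Q)
        P = np.vstack([P_c, P_t])
    components = ComponentSet(P.reshape(K, binning.n_bins, 2),
                              (CONTROL,) * n_c + (TREATMENT,) * n_treatment)
    quantities = {h.tumor_id: Q[i].copy() for i, h in enumerate(treated_histos)}
    # control-stage quantities are kept for control tumors, padded with zero
    # treatment mass so every stored vector has K entries
    for tid, q in model.quantities.items():
        if tid not in quantities:
            quantities[tid] = np.concatenate([q, np.zeros(n_treatment)])
    meta = {"stage": "treatment", "seed": int(seed), "restarts": restarts,
            "tol": tol, "max_iter": max_iter, "loglik": ll,
            "converged": bool(conv), "restart_log": restart_log,
            "cohort_size": S, "purified": bool(purify),
            "support_sigma": support_sigma,
            "n_support_cells": int(support.sum()),
            "control_meta": model.training_meta}
    return LPModel(components, binning, quantities, meta)


def _fit_q(P: np.ndarray, h: np.ndarray, q0: np.ndarray, tol: float,
           max_iter: int):
    """Quantities-only EM (concave problem) for a single histogram."""
    q = q0.copy()
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = q @ P
        q = q * (P @ (h / np.maximum(M, LOG_FLOOR)))
        M = q @ P
        ll = _loglik_floored(h, M, q.sum())
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    return q, ll, converged, it


def fit_quantities(model: LPModel, histo: PairedHistogram, *,
                   tol: float = 1e-12, max_iter: int = 20000) -> FitResult:
    """Fit the K quantities of a trained model to one histogram (PMFs frozen).

    The quantities-only extended likelihood is concave, so EM converges to
    the global optimum.  The returned chi^2 per degree of freedom uses
    D = (cells used) - K, the free parameters of a frozen-PMF fit.
    """
    if histo.binning != model.binning:
        raise ValueError("histogram binning does not match the model")
    if histo.total <= 0:
        raise ValueError("histogram is empty")
    P = model.components.flat
    K = model.n_components
    h = histo.counts.astype(float).ravel()
    q0 = np.full(K, h.sum() / K)
    q, ll, conv, n_iter = _fit_q(P, h, q0, tol, max_iter)
    M = q @ P
    chi2, _, _, _ = sqrt_residual_chi2([h], [M], K)
    return FitResult(q, M.reshape(model.binning.n_bins, 2), ll, chi2,
                     converged=conv, n_iter=n_iter)
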