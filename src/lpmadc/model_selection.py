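"""Model-order selection by variance-stabilized chi-square per degree of freedom.

The number of components needed to describe a cohort is found by scanning
candidate orders and evaluating, for each, the chi^2 per degree of freedom
between model and data.  Histogram counts are Poisson, so residuals are
computed on the square-root scale, where a Poisson variate has asymptotic
variance 1/4; for a correct model chi^2_D sits near unity.  To avoid
rewarding overfit the selection statistic is computed under leave-one-out
cross-validation: each tumor is excluded from PMF training, the reduced
model is quantity-fitted to it, and the held-out residuals are pooled.  The
in-sample curve is reported alongside for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import lpm_core
from .histogram_builder import PairedHistogram
from .lpm_core import LPModel, sqrt_residual_chi2

logger = logging.getLogger(__name__)


@dataclass
class Chi2Report:
    """chi^2 per degree of freedom with its bookkeeping."""

    chi2_dof: float
    dof: int
    n_cells_used: int
    residuals: np.ndarray
    free_param_rule: str = ""


@dataclass
class OrderScan:
    """Candidate component counts with their fit quality and the selection."""

    orders: list[int]
    chi2_insample: list[float]
    chi2_heldout: list[float]
    selected: int
    mode: str = "control"


def count_free_params(n_components: int, n_histograms: int = 1,
                      n_cells: int = 128,
                      stage: str = "frozen_fit") -> int:
    """Degrees of freedom consumed by a fit.

    ``shared_training``: each of K PMFs has (n_cells - 1) free entries (they
    are normalized) plus one quantity per component per histogram, so
    K * (n_cells - 1) + K * S.  ``frozen_fit``: only the K quantities.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if stage == "shared_training":
        return n_components * (n_cells - 1) + n_components * n_histograms
    if stage == "frozen_fit":
        return n_components
    raise ValueError(f"unknown stage {stage!r}")


def chi2_per_dof(histos: list[PairedHistogram], model_hists,
                 n_free_params: int) -> Chi2Report:
    """Pooled chi^2_D over matching (histogram, model histogram) pairs.

    Cells where both data and model are zero are excluded; the degrees of
    freedom are (cells used) - n_free_params.
    """
    counts = [h.counts for h in histos]
    for H, M in zip(counts, model_hists):
        if np.shape(H) != np.shape(M):
            raise ValueError("histogram and model shapes differ")
    chi2, dof, used, residuals = sqrt_residual_chi2(counts, model_hists,
                                                    n_free_params)
    return Chi2Report(chi2, dof, used, residuals,
                      free_param_rule=f"n_free_params={n_free_params}")


def _insample_chi2_control(model: LPModel, histos) -> float:
    P = model.components.flat
    Ms = [model.quantities[h.tumor_id] @ P for h in histos]
    counts = [h.counts.ravel() for h in histos]
    C = P.shape[1]
    free = count_free_params(model.n_components, len(histos), C,
                             "shared_training")
    chi2, _, _, _ = sqrt_residual_chi2(counts, Ms, free)
    return chi2


def _insample_chi2_treatment(model: LPModel, histos) -> float:
    P = model.components.flat
    Ms = [model.quantities[h.tumor_id] @ P for h in histos]
    counts = [h.counts.ravel() for h in histos]
    C = P.shape[1]
    n_t = model.components.n_treatment
    # only the treatment PMFs are free at this stage; all K quantities are
    free = n_t * (C - 1) + model.n_components * len(histos)
    chi2, _, _, _ = sqrt_residual_chi2(counts, Ms, free)
    return chi2


def select_order(histos: list[PairedHistogram], order_candidates, *,
                 mode: str = "control", base_model: LPModel | None = None,
                 seed: int = 0, restarts: int = 3, tol: float = 1e-8,
                 max_iter: int = 2000, tie_tol: float = 0.01,
                 purify: bool = True) -> OrderScan:
    """Scan candidate component counts and pick the held-out chi^2 minimizer.

    ``mode='control'`` scans N_C on a control cohort; ``mode='treatment'``
    scans N_T on a treated cohort given a trained control ``base_model``
    (control PMFs frozen throughout).  For each candidate every tumor is left
    out of PMF training in turn, the reduced model is quantity-fitted to it,
    and held-out residuals are pooled with K free quantities per held-out
    fit.  Orders whose held-out chi^2 lies within ``tie_tol`` (relative) of
    the minimum are tied and resolved toward the smaller order.
    """
    orders = sorted(int(k) for k in order_candidates)
    if len(orders) < 2:
        raise ValueError("at least two candidate orders are required")
    if mode not in ("control", "treatment"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "treatment" and base_model is None:
        raise ValueError("treatment mode requires a trained control model")
    S = len(histos)
    chi2_in: list[float] = []
    chi2_out: list[float] = []
    failures: dict[int, str] = {}
    for K in orders:
        try:
            if mode == "control":
                full = lpm_core.em_fit_control(histos, K, seed=seed,
                                               restarts=restarts, tol=tol,
                                               max_iter=max_iter)
                insample = _insample_chi2_control
                n_fit = K
            else:
                full = lpm_core.extend_with_treatment(
                    base_model, histos, K, seed=seed, restarts=restarts,
                    tol=tol, max_iter=max_iter, purify=purify)
                insample = _insample_chi2_treatment
                n_fit = base_model.n_components + K
            try:
                chi2_in.append(insample(full, histos))
            except ValueError as exc:
                # shared-training DoF can hit zero before the held-out
                # evaluation (K quantities per fit) does; keep scanning
                logger.info("in-sample chi2 unavailable at order %d: %s",
                            K, exc)
                chi2_in.append(float("nan"))
            counts, Ms = [], []
            for i in range(S):
                rest = histos[:i] + histos[i + 1:]
                if mode == "control":
                    sub = lpm_core.em_fit_control(rest, K, seed=seed,
                                                  restarts=restarts, tol=tol,
                                                  max_iter=max_iter)
                else:
                    sub = lpm_core.extend_with_treatment(
                        base_model, rest, K, seed=seed, restarts=restarts,
                        tol=tol, max_iter=max_iter, purify=purify)
                fit = lpm_core.fit_quantities(sub, histos[i])
                counts.append(histos[i].counts.ravel())
                Ms.append(fit.model_hist.ravel())
            chi2, _, _, _ = sqrt_residual_chi2(counts, Ms, n_fit * S)
            chi2_out.append(chi2)
        except Exception as exc:  # record and continue the scan
            logger.warning("order %d failed: %s", K, exc)
            failures[K] = str(exc)
            chi2_in.append(float("nan"))
            chi2_out.append(float("nan"))
    heldout = np.asarray(chi2_out)
    if not np.any(np.isfinite(heldout)):
        raise RuntimeError(f"all candidate orders failed: {failures}")
    cmin = np.nanmin(heldout)
    tied = [k for k, c in zip(orders, heldout)
            if np.isfinite(c) and c <= (1.0 + tie_tol) * cmin]
    selected = min(tied)
    logger.info("order scan (%s): heldout=%s selected=%d", mode,
                np.round(heldout, 4).tolist(), selected)
    return OrderScan(orders, chi2_in, chi2_out, selected, mode=mode)
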