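"""Per-tumor and cohort response statistics, validation, and the t-test arm.

A tumor's responding volume is the sum of its treatment-component quantities
sum_T Q_T; dividing by the propagated 1-SD error on that total gives a
Z-score, and the responding fraction sum_T Q_T / sum_K Q_K (as a percentage)
is the effect size with a delta-method error.  Per-tumor Z-scores are
combined across a cohort by root-sum-square, whose null distribution is chi
with k degrees of freedom.  Leave-one-out retraining of the control model
validates generalization and flags outlier control tumors (Z >= 2 on the
held-out fit).  The conventional benchmark arm applies two-sample Student
t-tests to volume change, mean-ADC change and IQR change and combines the
three equivalent Z values the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import lpm_core, uncertainty
from .histogram_builder import PairedHistogram, SummaryParams
from .lpm_core import FitResult, LPModel
from .uncertainty import QuantityCovariance, total_treatment_error

logger = logging.getLogger(__name__)

#: Text rendering threshold matching the tables' "<0.000001" convention.
P_FLOOR_TEXT = 1e-6


def format_p(p: float) -> str:
    """Render a p-value, printing values below 1e-6 as '<0.000001'."""
    return "<0.000001" if p < P_FLOOR_TEXT else f"{p:.6f}".rstrip("0").rstrip(".")


@dataclass
class TumorResponse:
    """One row of a response table: Z, P, effect %, error %."""

    tumor_id: str
    z: float
    p: float
    effect_pct: float
    error_pct: float


@dataclass
class ParamTest:
    """One conventional-arm row: a two-sample t-test on a summary parameter."""

    name: str
    t: float
    p: float
    z: float


@dataclass
class CohortResult:
    """Per-row results plus the combined cohort significance."""

    rows: list
    combined_z: float
    combined_p: float
    arm: str = "lpm"


@dataclass
class LooRecord:
    """Leave-all-in vs leave-one-out response for one control tumor."""

    tumor_id: str
    z_all_in: float
    z_loo: float
    flagged: bool
    effect_all_in: float = 0.0
    effect_loo: float = 0.0
    error_all_in: float = 0.0
    error_loo: float = 0.0
    valid: bool = True
    message: str = ""


def z_score(effect: float, sd: float) -> float:
    """Response size divided by its 1-SD error."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(effect / sd)


def p_two_tailed(z: float) -> float:
    """Two-tailed standard-normal p-value, p = 2 * (1 - Phi(|z|))."""
    return float(2.0 * sps.norm.sf(abs(z)))


def combine_cohort(z_values) -> tuple[float, float]:
    """Root-sum-square combination of per-tumor (or per-parameter) Z-scores.

    The rss of k independent standard normals is chi_k distributed, so the
    combined p comes from the chi^2_k survival function at sum(z^2).
    """
    z = np.asarray(list(z_values), dtype=float)
    if z.size == 0:
        raise ValueError("at least one Z value is required")
    s = float(np.sum(z**2))
    return float(np.sqrt(s)), float(sps.chi2.sf(s, df=z.size))


def tumor_response(fit: FitResult, cov: QuantityCovariance,
                   components: lpm_core.ComponentSet,
                   tumor_id: str = "") -> TumorResponse:
    """Per-tumor responding volume statistics from a fit and its covariance.

    effect_pct = 100 * sum_T Q_T / sum_K Q_K with a delta-method error from
    the quantity covariance; Z divides the raw responding quantity sum_T Q_T
    by its propagated SD.  When the treatment quantities are pinned at zero
    (no detectable response direction) Z is reported as 0.
    """
    q = fit.quantities
    total = float(q.sum())
    if total <= 0:
        raise ValueError("total quantity is zero")
    t_idx = components.treatment_indices
    a = float(q[t_idx].sum()) if t_idx.size else 0.0
    effect = 100.0 * a / total
    is_t = np.zeros(q.size)
    if t_idx.size:
        is_t[t_idx] = 1.0
    grad = 100.0 * (is_t * total - a) / total**2
    var_eff = float(grad @ cov.cov @ grad)
    error_pct = float(np.sqrt(max(var_eff, 0.0)))
    sd_t = total_treatment_error(cov, t_idx)
    z = z_score(a, sd_t) if sd_t > 0 else 0.0
    return TumorResponse(tumor_id, z, p_two_tailed(z), effect, error_pct)


def analyze_cohort(model: LPModel, histos: list[PairedHistogram], *,
                   cov_method: str = "analytic", clamp_scale: bool = True,
                   control_histos=None, treated_histos=None) -> CohortResult:
    """Fit each histogram with the trained model and combine the Z-scores.

    For the full-training covariance the PMF sensitivities are precomputed
    once and shared across the cohort's tumors.
    """
    prop = None
    if cov_method == "full_training_propagation":
        if control_histos is None:
            raise ValueError("full_training_propagation requires the "
                             "training cohorts")
        prop = uncertainty.TrainingPropagation(model, control_histos,
                                               treated_histos)
    rows = []
    for h in histos:
        fit = lpm_core.fit_quantities(model, h)
        if prop is not None:
            scale = max(1.0, fit.chi2_dof) if clamp_scale else fit.chi2_dof
            core = prop.covariance_core(h, fit)
            cov = uncertainty.QuantityCovariance(scale * core, scale,
                                                 cov_method)
        else:
            cov = uncertainty.quantity_covariance(
                model, h, fit, fit.chi2_dof, method=cov_method,
                clamp_scale=clamp_scale)
        rows.append(tumor_response(fit, cov, model.components, h.tumor_id))
    cz, cp = combine_cohort([r.z for r in rows])
    return CohortResult(rows, cz, cp, arm="lpm")


def leave_one_out(control_histos: list[PairedHistogram],
                  treated_histos: list[PairedHistogram], *,
                  n_control: int, n_treatment: int, seed: int = 0,
                  restarts: int = 5, cov_method: str = "analytic",
                  flag_threshold: float = 2.0) -> list[LooRecord]:
    """Control-cohort validation: leave-all-in vs leave-one-out Z-scores.

    The full model (control components from all controls, treatment
    components from the treated cohort) is fitted to every control tumor;
    then, for each control tumor, both stages are retrained with that tumor
    excluded and the tumor is assessed as an independent sample.  A tumor is
    flagged as a potential outlier when its held-out Z reaches
    ``flag_threshold`` (default 2); flagged tumors are reported, never
    removed.
    """
    if len(control_histos) < 3:
        raise ValueError("leave-one-out requires at least 3 control tumors")

    def respond(model, histo):
        fit = lpm_core.fit_quantities(model, histo)
        cov = uncertainty.quantity_covariance(model, histo, fit, fit.chi2_dof,
                                              method=cov_method)
        return tumor_response(fit, cov, model.components, histo.tumor_id)

    base = lpm_core.em_fit_control(control_histos, n_control, seed=seed,
                                   restarts=restarts)
    full = lpm_core.extend_with_treatment(base, treated_histos, n_treatment,
                                          seed=seed, restarts=restarts)
    records = []
    for i, histo in enumerate(control_histos):
        r_all = respond(full, histo)
        try:
            rest = control_histos[:i] + control_histos[i + 1:]
            sub = lpm_core.em_fit_control(rest, n_control, seed=seed,
                                          restarts=restarts)
            sub = lpm_core.extend_with_treatment(sub, treated_histos,
                                                 n_treatment, seed=seed,
                                                 restarts=restarts)
            r_loo = respond(sub, histo)
        except Exception as exc:
            logger.warning("leave-one-out retraining failed for %s: %s",
                           histo.tumor_id, exc)
            records.append(LooRecord(histo.tumor_id, r_all.z, float("nan"),
                                     flagged=False,
                                     effect_all_in=r_all.effect_pct,
                                     error_all_in=r_all.error_pct,
                                     valid=False, message=str(exc)))
            continue
        records.append(LooRecord(
            histo.tumor_id, r_all.z, r_loo.z,
            flagged=r_loo.z >= flag_threshold,
            effect_all_in=r_all.effect_pct, effect_loo=r_loo.effect_pct,
            error_all_in=r_all.error_pct, error_loo=r_loo.error_pct))
    return records


_PARAM_FIELDS = (("volume_change", "volume change"),
                 ("mean_adc_change", "mean ADC change"),
                 ("iqr_change", "IQR change"))


def conventional_arm(control: list[SummaryParams],
                     treated: list[SummaryParams], *,
                     equal_var: bool = True) -> CohortResult:
    """Two-sample t-tests on the three conventional summary parameters.

    Student's equal-variance t-test by default (Welch behind the flag).  Each
    two-tailed p is converted to a signed Z equivalent via the normal
    quantile, and the three Z values are combined by root-sum-square as if
    each parameter gave independent evidence of change.
    """
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("both groups need at least 2 tumors")
    rows = []
    for attr, name in _PARAM_FIELDS:
        x = np.array([getattr(s, attr) for s in control], dtype=float)
        y = np.array([getattr(s, attr) for s in treated], dtype=float)
        if np.var(x) == 0 and np.var(y) == 0:
            raise ValueError(f"zero variance in both groups for {name}")
        t, p = sps.ttest_ind(y, x, equal_var=equal_var)
        z = float(np.sign(t) * sps.norm.isf(p / 2.0))
        rows.append(ParamTest(name, float(t), float(p), z))
    cz, cp = combine_cohort([r.z for r in rows])
    return CohortResult(rows, cz, cp, arm="conventional")
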