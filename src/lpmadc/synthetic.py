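"""Synthetic paired-histogram cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: each
tumor's expected B x 2 histogram is a non-negative mixture of shared PMF
components, observed counts are independent Poisson draws per cell, and
treated tumors carry extra "treatment" components whose t = 72 h mass sits
at elevated ADC (therapy breaks down microstructure, raising diffusivity).
Control components are smooth unimodal densities over the ADC axis with
correlated baseline/post shapes (normal growth drifts the distribution
slightly); component profiles are truncated Gaussians, which emulates only
the shape features the model cares about, not any specific tumor biology.
Two presets mirror small preclinical xenograft studies of different
complexity: ``lovo_like`` (8 controls + 10 treated, 3 control + 2 treatment
components) and ``hct116_like`` (13 controls + 15 treated, 4 + 5).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .histogram_builder import BinningScheme, PairedHistogram
from .lpm_core import CONTROL, TREATMENT, ComponentSet

#: Default voxel budget per tumor per time point; a 300-400 mm^3 tumor at a
#: 0.2 x 0.2 x 0.6 mm acquisition holds roughly this many voxels.
DEFAULT_VOXELS = 15_000

#: Default responding fraction for treated tumors, mid-range of the 20-70%
#: responding volumes typical of effective single-dose radiotherapy.
DEFAULT_RESPONDING_FRACTION = 0.4

PRESETS = {
    "lovo_like": dict(n_control_tumors=8, n_treated_tumors=10,
                      n_control=3, n_treatment=2),
    "hct116_like": dict(n_control_tumors=13, n_treated_tumors=15,
                        n_control=4, n_treatment=5),
}


@dataclass
class GroundTruth:
    """True components and per-tumor quantities behind a simulated cohort."""

    components: ComponentSet
    binning: BinningScheme
    control_quantities: dict[str, np.ndarray]
    treated_quantities: dict[str, np.ndarray]
    responding_fraction: dict[str, float]
    seed: int


@dataclass
class StudyBundle:
    """A full simulated study: histograms, ground truth, and a manifest."""

    control_histos: list[PairedHistogram]
    treated_histos: list[PairedHistogram]
    truth: GroundTruth
    manifest: dict


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    g = np.exp(-0.5 * ((x - mu) / sd) ** 2)
    s = g.sum()
    if s <= 0:
        raise ValueError("degenerate component profile")
    return g / s


def make_components(n_control: int, n_treatment: int, n_bins: int = 64,
                    seed: int = 0, adc_max: float = 3.0e-3) -> ComponentSet:
    """Seeded ground-truth component set on a uniform ADC grid.

    Control components are unimodal with baseline means spread over the
    normal-tissue ADC range (~0.7-1.4e-3 mm^2/s) and a small upward drift at
    t = 72 h (growth).  Treatment components pair a normal-looking baseline
    column with a t = 72 h column centered at elevated ADC, placing at least
    60% of their post-treatment mass above the control components' t = 72 h
    mode.  Every PMF sums to 1; each column carries half the mass.
    """
    if n_control < 1 or n_treatment < 0:
        raise ValueError("component counts must be >= 1 control, >= 0 treatment")
    if n_bins < 16:
        raise ValueError("n_bins too small to separate component modes")
    binning = BinningScheme.uniform(n_bins, 0.0, adc_max)
    x = binning.centers
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51]))

    pmfs = []
    mus = np.linspace(0.75e-3, 1.35e-3, n_control)
    for k in range(n_control):
        mu = mus[k] + rng.uniform(-0.02e-3, 0.02e-3)
        sd = rng.uniform(0.09e-3, 0.14e-3)
        drift = rng.uniform(0.02e-3, 0.10e-3)
        pmf = np.empty((n_bins, 2))
        pmf[:, 0] = 0.5 * _gauss(x, mu, sd)
        pmf[:, 1] = 0.5 * _gauss(x, mu + drift, sd * rng.uniform(0.95, 1.15))
        pmfs.append(pmf)

    control_post = sum(p[:, 1] for p in pmfs)
    control_post_mode = x[int(np.argmax(control_post))]

    mus_t = np.linspace(1.9e-3, 2.45e-3, max(n_treatment, 1))
    for m in range(n_treatment):
        mu0 = rng.uniform(0.8e-3, 1.3e-3)
        sd0 = rng.uniform(0.09e-3, 0.14e-3)
        mu1 = mus_t[m] + rng.uniform(-0.03e-3, 0.03e-3)
        sd1 = rng.uniform(0.10e-3, 0.16e-3)
        pmf = np.empty((n_bins, 2))
        pmf[:, 0] = 0.5 * _gauss(x, mu0, sd0)
        pmf[:, 1] = 0.5 * _gauss(x, mu1, sd1)
        above = pmf[x > control_post_mode, 1].sum() / pmf[:, 1].sum()
        if above < 0.60:
            raise ValueError("treatment component insufficiently elevated; "
                             "increase n_bins or adc_max")
        pmfs.append(pmf)

    labels = (CONTROL,) * n_control + (TREATMENT,) * n_treatment
    return ComponentSet(np.stack(pmfs), labels)


def simulate_cohort(components: ComponentSet, n_control_tumors: int,
                    n_treated_tumors: int,
                    voxels_per_tumor: int = DEFAULT_VOXELS,
                    responding_fraction: float = DEFAULT_RESPONDING_FRACTION,
                    seed: int = 0, n_bins: int | None = None,
                    adc_max: float = 3.0e-3, quantity_alpha: float = 5.0):
    """Poisson-sample a cohort of paired histograms from true components.

    Control tumors draw their composition over control components from a
    seeded Dirichlet(alpha); treated tumors assign ``responding_fraction``
    of their total mass to the treatment components and the rest to a
    Dirichlet control composition.  Expected total counts are
    2 * voxels_per_tumor (both time points); observed counts are independent
    Poisson draws per cell.

    Returns ``(control_histos, treated_histos, truth)``.
    """
    if not 0.0 <= responding_fraction <= 1.0:
        raise ValueError("responding_fraction must lie in [0, 1]")
    if voxels_per_tumor < 100:
        raise ValueError("voxels_per_tumor must be >= 100")
    n_c = components.n_control
    n_t = components.n_treatment
    if n_treated_tumors > 0 and responding_fraction > 0 and n_t == 0:
        raise ValueError("treated tumors need treatment components")
    n_bins = components.pmfs.shape[1]
    binning = BinningScheme.uniform(n_bins, 0.0, adc_max)
    P = components.flat
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x52]))
    total = 2.0 * voxels_per_tumor

    control_histos, treated_histos = [], []
    q_control, q_treated, fracs = {}, {}, {}
    for i in range(n_control_tumors):
        tid = f"C{i + 1}"
        q = np.zeros(n_c + n_t)
        q[:n_c] = rng.dirichlet(np.full(n_c, quantity_alpha)) * total
        counts = rng.poisson((q @ P).reshape(n_bins, 2))
        control_histos.append(PairedHistogram(counts, tid, binning))
        q_control[tid] = q
    for j in range(n_treated_tumors):
        tid = f"T{j + 1}"
        q = np.zeros(n_c + n_t)
        q[:n_c] = rng.dirichlet(np.full(n_c, quantity_alpha)) \
            * total * (1.0 - responding_fraction)
        if n_t:
            q[n_c:] = rng.dirichlet(np.full(n_t, quantity_alpha)) \
                * total * responding_fraction
        counts = rng.poisson((q @ P).reshape(n_bins, 2))
        treated_histos.append(PairedHistogram(counts, tid, binning))
        q_treated[tid] = q
        fracs[tid] = responding_fraction
    truth = GroundTruth(components, binning, q_control, q_treated, fracs,
                        int(seed))
    return control_histos, treated_histos, truth


def _manifest_hash(histos) -> str:
    blob = b"".join(h.counts.tobytes() for h in histos)
    return hashlib.sha256(blob).hexdigest()


def simulate_study(preset: str, seed: int = 0, *,
                   voxels_per_tumor: int = DEFAULT_VOXELS,
                   responding_fraction: float = DEFAULT_RESPONDING_FRACTION,
                   n_bins: int = 64) -> StudyBundle:
    """Simulate a full preset study and return histograms, truth, manifest."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    components = make_components(cfg["n_control"], cfg["n_treatment"],
                                 n_bins=n_bins, seed=seed)
    controls, treated, truth = simulate_cohort(
        components, cfg["n_control_tumors"], cfg["n_treated_tumors"],
        voxels_per_tumor=voxels_per_tumor,
        responding_fraction=responding_fraction, seed=seed)
    manifest = {
        "preset": preset, "seed": int(seed),
        "n_control_tumors": cfg["n_control_tumors"],
        "n_treated_tumors": cfg["n_treated_tumors"],
        "n_control_components": cfg["n_control"],
        "n_treatment_components": cfg["n_treatment"],
        "voxels_per_tumor": voxels_per_tumor,
        "responding_fraction": responding_fraction,
        "n_bins": n_bins,
        "control_ids": [h.tumor_id for h in controls],
        "treated_ids": [h.tumor_id for h in treated],
        "counts_sha256": _manifest_hash(controls + treated),
    }
    return StudyBundle(controls, treated, truth, manifest)
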