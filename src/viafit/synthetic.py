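"""Synthetic study data with known ground truth.

Real-time cell analysis (RTCA) measures impedance on gold
microelectrodes; the cell index CI = (Rtn − Rt0)/F (F = 15 Ω) is
proportional to the number of attached, viable cells, and the
normalized cell index (NCI) rescales CI to 1.0 at treatment time.  Flow
cytometry with Annexin V / propidium iodide splits a sample into four
fractions — viable (−/−), early apoptotic (+/−), late apoptotic (+/+),
necrotic (−/+) — summing to 100%.  Early-apoptotic cells remain
adherent, so they are pooled with viable cells when flow data are
compared with impedance data.

This module emulates both readouts from a simulated ground-truth
viability curve: NCI traces sampled every 15 minutes with multiplicative
Gaussian replicate noise (the fit uses the 5-point subset at
24/36/48/60/72 h), four-fraction snapshots at 24 h and 72 h with
Dirichlet jitter (which preserves the sum-to-100 constraint), and
Gaussian-blob grayscale images standing in for the micrographs that
define the initial cell distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelParams
from .solver import SimConfig, SimGrid, Trajectory, simulate
from .estimation import ViabilitySeries

__all__ = [
    "FlowFractions",
    "SynthConfig",
    "RTCA_FIT_TIMES",
    "FLOW_TIMES",
    "default_control_params",
    "default_treatment_params",
    "generate_rtca",
    "generate_flow",
    "generate_blob_image",
]

#: fit time points (hours from treatment) for the two modalities
RTCA_FIT_TIMES = (24.0, 36.0, 48.0, 60.0, 72.0)
FLOW_TIMES = (24.0, 72.0)

#: impedance constant (Ω) of the cell-index definition CI = (Rtn − Rt0)/F
F_OHM = 15.0


def default_control_params() -> ModelParams:
    """A plausible aerobic control cell line.

    Oxygen parameters match a colorectal-carcinoma control estimate
    (Q = 5.32, Q1 = 4.97); growth outweighs death so the culture
    expands over the 72 h window.
    """
    return ModelParams(s1=1.0, s2=0.1, s3=0.1, s4=1.0, Q=5.32, Q1=4.97)


def default_treatment_params() -> ModelParams:
    """A cytotoxic treatment: death parameters raised, oxygen frozen.

    A partial responder — the cell fraction relaxes towards a lower
    carrying capacity, ending near 70% of the treatment-time mass
    rather than collapsing outright.
    """
    return ModelParams(s1=1.0, s2=0.4, s3=0.25, s4=0.0, Q=5.32, Q1=4.97)


@dataclass(frozen=True)
class FlowFractions:
    """One Annexin V/PI snapshot (percentages summing to 100)."""

    t: float
    viable_pct: float
    early_pct: float
    late_pct: float
    necrosis_pct: float

    def __post_init__(self) -> None:
        vals = (self.viable_pct, self.early_pct, self.late_pct,
                self.necrosis_pct)
        if any(v < 0 or v > 100 for v in vals):
            raise ValueError("fractions must lie in [0, 100]")
        if abs(sum(vals) - 100.0) > 1e-9:
            raise ValueError(f"fractions must sum to 100, got {sum(vals)}")

    @property
    def pooled_viable_pct(self) -> float:
        """Viable + early apoptotic — the adherent fraction RTCA sees."""
        return self.viable_pct + self.early_pct


@dataclass(frozen=True)
class SynthConfig:
    """Noise model and sampling layout for synthetic readouts.

    ``noise_sigma`` is the multiplicative SD of per-sample NCI noise,
    of the order of the replicate scatter seen in impedance assays;
    ``f_early`` is the share of model-viable cells reported as early
    apoptotic, ``f_late`` the share of non-viable reported as late
    apoptotic (rest necrotic); ``dirichlet_conc`` scales the Dirichlet
    jitter of the four fractions (larger = tighter).  A seed is
    mandatory for any stochastic call.
    """

    seed: int
    noise_sigma: float = 0.03
    f_early: float = 0.10
    f_late: float = 0.80
    dirichlet_conc: float = 200.0
    sample_interval_min: float = 15.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("f_early", "f_late"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dirichlet_conc <= 0:
            raise ValueError("dirichlet_conc must be > 0")
        if self.sample_interval_min <= 0:
            raise ValueError("sample_interval_min must be > 0")


def _truth_trajectory(truth, alpha0, grid, config) -> Trajectory:
    return simulate(alpha0, grid, truth, config or SimConfig())


def generate_rtca(
    truth: ModelParams,
    alpha0: np.ndarray,
    grid: SimGrid,
    config: SimConfig | None,
    synth: SynthConfig,
    return_raw: bool = False,
    r0_ohm: float = 30.0,
):
    """Synthesize an RTCA trace and its 5-point fit subset.

    The ground-truth viability curve is sampled every
    ``sample_interval_min`` minutes (linear interpolation between the
    hourly simulation records, mimicking the instrument's faster clock)
    and perturbed multiplicatively: NCI(t) = V(t)/100 · (1 + ε_t) with
    ε_t ~ N(0, σ²) i.i.d.  NCI(0) is pinned to exactly 1, as the
    normalization defines it.

    Returns ``(fit_series, full_series)`` — both as percent-viable
    ``ViabilitySeries`` — plus, when ``return_raw`` is set, a raw
    impedance trace R(t) = R0 + F·CI(t) with CI anchored so that
    NCI(0) = 1.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(synth.seed)
    traj = _truth_trajectory(truth, alpha0, grid, config)

    step_h = synth.sample_interval_min / 60.0
    n = int(np.floor(config.t_end / step_h + 1e-9))
    t_dense = np.round(np.arange(n + 1) * step_h, 9)
    v_dense = np.interp(t_dense, traj.times, traj.viability_pct)

    eps = rng.normal(0.0, synth.noise_sigma, size=t_dense.size)
    nci = v_dense / 100.0 * (1.0 + eps)
    nci[0] = 1.0  # normalization anchor
    nci = np.maximum(nci, 0.0)

    full = ViabilitySeries(times=t_dense, values=100.0 * nci, modality="rtca")
    fit_times = np.array(RTCA_FIT_TIMES)
    idx = [int(np.flatnonzero(np.isclose(t_dense, t))[0]) for t in fit_times]
    fit = ViabilitySeries(times=fit_times, values=100.0 * nci[idx],
                          modality="rtca")
    if not return_raw:
        return fit, full
    ci = nci  # CI0 = 1 so that NCI = CI/CI0
    r = r0_ohm + F_OHM * ci
    return fit, full, np.column_stack([t_dense, r])


def generate_flow(
    truth: ModelParams,
    alpha0: np.ndarray,
    grid: SimGrid,
    config: SimConfig | None,
    synth: SynthConfig,
    jitter: bool = True,
) -> list[FlowFractions]:
    """Synthesize Annexin V/PI snapshots at 24 h and 72 h.

    The model viability V(t)% splits into viable = V·(1−f_early) and
    early = V·f_early; the non-viable remainder splits into
    late = (100−V)·f_late and necrotic = (100−V)·(1−f_late).  With
    ``jitter`` the four fractions are resampled from a Dirichlet
    distribution concentrated on the base split, then rescaled to sum
    exactly 100.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(synth.seed + 1)  # decouple from RTCA noise
    traj = _truth_trajectory(truth, alpha0, grid, config)
    out = []
    for t in FLOW_TIMES:
        v = traj.viability_at(t)
        if not 0 <= v <= 100:
            raise ValueError(f"model viability {v} outside [0, 100] at t={t}")
        base = np.array([
            v * (1.0 - synth.f_early),
            v * synth.f_early,
            (100.0 - v) * synth.f_late,
            (100.0 - v) * (1.0 - synth.f_late),
        ]) / 100.0
        if jitter:
            pos = base > 0
            draw = np.zeros(4)
            draw[pos] = rng.dirichlet(synth.dirichlet_conc * base[pos])
            frac = draw / draw.sum()
        else:
            frac = base
        frac = 100.0 * frac / frac.sum()
        out.append(FlowFractions(t=t, viable_pct=float(frac[0]),
                                 early_pct=float(frac[1]),
                                 late_pct=float(frac[2]),
                                 necrosis_pct=float(frac[3])))
    return out


def flow_to_series(snapshots: list[FlowFractions]) -> ViabilitySeries:
    """Pool viable + early apoptotic into the series estimation consumes."""
    times = np.array([f.t for f in snapshots])
    vals = np.array([f.pooled_viable_pct for f in snapshots])
    return ViabilitySeries(times=times, values=vals, modality="flow")


def generate_blob_image(
    width: int = 256,
    height: int = 256,
    n_blobs: int = 12,
    seed: int = 0,
    blob_sigma_frac: float = 0.06,
) -> np.ndarray:
    """Gaussian-blob stand-in for a micrograph of adherent cell colonies.

    Sum of ``n_blobs`` isotropic Gaussian intensity bumps at seeded
    random centres, normalized to [0, 1] and quantized to 8 bits.
    Deterministic per seed.
    """
    if width < 16 or height < 16:
        raise ValueError("image dimensions must be >= 16")
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    img = np.zeros((height, width))
    sigma = blob_sigma_frac * max(width, height)
    for _ in range(n_blobs):
        cx = rng.uniform(0.15 * width, 0.85 * width)
        cy = rng.uniform(0.15 * height, 0.85 * height)
        amp = rng.uniform(0.5, 1.0)
        img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                            / (2.0 * sigma**2))
    img /= img.max()
    return np.round(img * 255).astype(np.uint8)
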