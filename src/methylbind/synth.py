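"""Synthetic data generators for every pipeline input.

Each generator emulates the data-generating process its consuming analysis
assumes, with an explicit seed for byte-identical reproducibility:

* FP titrations — log-spaced protein series on the ligand-depletion
  isotherm plus additive Gaussian noise scaled to the curve amplitude.
* CAPA dose–response — four-parameter logistic penetration fraction plus
  noise, clipped to [0, 1].
* Reader/peptide arrays — spot intensities proportional to single-site
  occupancy at the hybridization concentration, with a detection floor
  corresponding to a ~30 µM binder at 1 µM probe (weaker interactions are
  indistinguishable from background on such arrays) and multiplicative
  lognormal spot noise.
* Beta-value matrices — bimodal methylation fractions (unmethylated mode
  near 0.05, methylated mode near 0.9), a paired "treated" sample that is
  either a pure-noise null (LIG1-knockdown surrogate) or carries a global
  hypomethylation effect on a random subset of probes (UHRF1-knockdown
  surrogate); everything clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import Titration, four_param_logistic, fp_forward
from .arrays import IntensityMatrix
from .methylation import BetaMatrix

__all__ = [
    "GlobalHypo",
    "gen_fp_titration",
    "gen_capa_curve",
    "gen_array",
    "gen_beta_matrix",
]


def gen_fp_titration(
    kd: float,
    probe_conc: float = 0.01,
    n_points: int = 12,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int | None = None,
    r0: float = 0.05,
    rmax: float = 0.25,
) -> Titration:
    """Synthetic FP titration around a known Kd.

    Concentrations are log-spaced over [Kd/100, 100·Kd]; responses follow
    the depletion isotherm with additive Gaussian noise of standard
    deviation ``noise_sd`` times the curve amplitude (rmax − r0).
    """
    if not kd > 0:
        raise ValueError("kd must be positive")
    rng = np.random.default_rng(seed)
    conc = np.geomspace(kd / 100.0, kd * 100.0, n_points)
    x = np.tile(conc, n_replicates)
    reps = np.repeat(np.arange(n_replicates), n_points)
    clean = fp_forward(x, kd, r0, rmax, probe_conc=probe_conc, depletion=True)
    y = clean + rng.normal(0.0, noise_sd * (rmax - r0), size=x.shape)
    return Titration(x, y, replicate_ids=reps, probe_concentration=probe_conc)


def gen_capa_curve(
    cp50: float,
    slope: float = 1.0,
    n_points: int = 9,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int | None = None,
) -> Titration:
    """Synthetic CAPA penetration curve with a known CP50.

    Log-spaced peptide concentrations over [CP50/30, 30·CP50]; penetration
    fraction from a 0→1 four-parameter logistic plus Gaussian noise,
    clipped to [0, 1].
    """
    if not cp50 > 0:
        raise ValueError("cp50 must be positive")
    rng = np.random.default_rng(seed)
    conc = np.geomspace(cp50 / 30.0, cp50 * 30.0, n_points)
    x = np.tile(conc, n_replicates)
    reps = np.repeat(np.arange(n_replicates), n_points)
    clean = four_param_logistic(x, cp50, slope, 0.0, 1.0)
    y = np.clip(clean + rng.normal(0.0, noise_sd, size=x.shape), 0.0, 1.0)
    return Titration(x, y, replicate_ids=reps)


def gen_array(
    kd_matrix: pd.DataFrame,
    probe_conc: float = 1.0,
    detection_kd_ceiling: float = 30.0,
    noise_sd: float = 0.1,
    n_replicates: int = 2,
    seed: int | None = None,
    max_signal: float = 1000.0,
    floor_fraction: float = 0.02,
) -> dict[str, IntensityMatrix]:
    """Synthetic array intensities from a ground-truth affinity matrix.

    ``kd_matrix`` is readers (rows) × probe peptides (columns) in µM.  The
    clean signal of each spot is proportional to single-site occupancy at
    the hybridization concentration; occupancy below that of a binder at
    the detection ceiling collapses to a noise-level floor.  Replicates get
    independent multiplicative lognormal spot noise (sigma ``noise_sd`` in
    log space).  Returns one IntensityMatrix per probe peptide.
    """
    if (kd_matrix <= 0).any().any():
        raise ValueError("all Kds must be positive")
    rng = np.random.default_rng(seed)
    occ_floor = probe_conc / (detection_kd_ceiling + probe_conc)
    out: dict[str, IntensityMatrix] = {}
    for probe in kd_matrix.columns:
        kds = kd_matrix[probe].to_numpy(dtype=float)
        occ = probe_conc / (kds + probe_conc)
        clean = np.where(occ >= occ_floor, occ, floor_fraction * occ_floor) * max_signal
        noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=(len(kds), n_replicates))
        values = clean[:, None] * noise
        out[str(probe)] = IntensityMatrix(
            values=values,
            entity_labels=list(kd_matrix.index),
            probe_label=str(probe),
        )
    return out


@dataclass(frozen=True)
class GlobalHypo:
    """Global hypomethylation effect: ``fraction`` of probes lose
    ``magnitude`` beta units in the treated sample."""

    fraction: float
    magnitude: float

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0 and 0.0 <= self.magnitude <= 1.0):
            raise ValueError("fraction and magnitude must lie in [0, 1]")


def gen_beta_matrix(
    n_probes: int,
    effect: GlobalHypo | None = None,
    noise_sd: float = 0.03,
    seed: int | None = None,
    high_weight: float = 0.6,
    modes: tuple[float, float] = (0.05, 0.9),
    mode_sd: tuple[float, float] = (0.03, 0.05),
    control_label: str = "control",
    treated_label: str = "treated",
) -> BetaMatrix:
    """Paired control/treated beta-value matrix with a bimodal marginal.

    Control betas come from a two-component Gaussian mixture (defaults:
    modes 0.05 and 0.9, weight 0.6 on the methylated mode) clipped to
    [0, 1], placing a realistic mass of probes above the β > 0.8 filter.
    The treated column adds the hypomethylation effect (if any) on a random
    probe subset, then technical noise, then clips.  ``effect=None``
    reproduces a null comparison.
    """
    rng = np.random.default_rng(seed)
    high = rng.random(n_probes) < high_weight
    control = np.where(
        high,
        rng.normal(modes[1], mode_sd[1], n_probes),
        rng.normal(modes[0], mode_sd[0], n_probes),
    )
    control = np.clip(control, 0.0, 1.0)
    treated = control.copy()
    if effect is not None:
        hit = rng.random(n_probes) < effect.fraction
        treated = treated - hit * effect.magnitude
    if noise_sd > 0:
        treated = treated + rng.normal(0.0, noise_sd, n_probes)
    treated = np.clip(treated, 0.0, 1.0)
    frame = pd.DataFrame(
        {control_label: control, treated_label: treated},
        index=pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id"),
    )
    return BetaMatrix(frame)
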