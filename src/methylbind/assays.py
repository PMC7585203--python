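"""Binding- and penetration-assay estimators.

Two curve-fitting models, organised statsmodels-style (a model object built
from data whose ``fit()`` returns a results object):

* :class:`FluorescencePolarizationModel` — single-site saturation binding
  measured by fluorescence polarization.  The response is the change in
  anisotropy as labeled probe is bound by increasing protein.  By default
  the forward model is the ligand-depletion quadratic (exact 1:1 isotherm
  at finite probe concentration); the no-depletion hyperbola
  ``r0 + (rmax - r0) * P / (Kd + P)`` is available as an option.  At the
  low-nM dissociation constants typical of tight methyllysine readers the
  probe concentration is comparable to Kd and the hyperbola biases the
  estimate upward.

* :class:`PenetrationModel` — chloroalkane penetration assay (CAPA)
  dose–response.  The readout is a penetration fraction in [0, 1]
  (obtained from raw fluorescence by :func:`normalize_capa`, since raw
  fluorescence is inversely related to penetration); a four-parameter
  logistic is fitted and the CP50 is the inflection concentration, where
  half of the maximal penetration is reached.

Concentrations are µM.  Fits with an apparent Kd above ~5 µM are flagged
as non-saturating: such titrations do not approach plateau in practice and
their point estimates are unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Titration",
    "FitResult",
    "FluorescencePolarizationModel",
    "PenetrationModel",
    "fp_forward",
    "four_param_logistic",
    "fit_kd",
    "fit_cp50",
    "selectivity_ratio",
    "normalize_capa",
]

#: apparent Kd (µM) beyond which an FP titration is treated as non-saturating
NON_SATURATING_KD = 5.0


class FitError(RuntimeError):
    pass


@dataclass
class Titration:
    """A concentration series with measured responses.

    ``concentrations`` are protein (FP) or peptide (CAPA) concentrations in
    µM; ``responses`` are anisotropy changes (FP, arbitrary units) or
    penetration fractions in [0, 1] (CAPA).  ``replicate_ids`` groups points
    into independent replicate curves; ``probe_concentration`` is the fixed
    labeled-tracer concentration in an FP experiment.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    replicate_ids: np.ndarray | None = None
    probe_concentration: float | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)
            if self.replicate_ids.shape != self.concentrations.shape:
                raise ValueError("replicate_ids must align with concentrations")
        if len(np.unique(self.concentrations)) < 5:
            raise ValueError("need at least 5 distinct concentrations to fit")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, probe_concentration: float | None = None):
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(
            concentrations=df["concentration_uM"].to_numpy(),
            responses=df["response"].to_numpy(),
            replicate_ids=rep,
            probe_concentration=probe_concentration,
        )

    def to_dataframe(self) -> pd.DataFrame:
        d = {"concentration_uM": self.concentrations, "response": self.responses}
        if self.replicate_ids is not None:
            d["replicate"] = self.replicate_ids
        return pd.DataFrame(d)

    def replicates(self):
        """Yield (id, Titration) per replicate curve."""
        if self.replicate_ids is None:
            yield 0, self
            return
        for rid in pd.unique(self.replicate_ids):
            m = self.replicate_ids == rid
            yield rid, Titration(
                self.concentrations[m], self.responses[m],
                probe_concentration=self.probe_concentration,
            )


def fp_forward(
    protein_conc,
    kd: float,
    r0: float,
    rmax: float,
    probe_conc: float | None = None,
    depletion: bool = True,
):
    """Forward FP saturation-binding curve.

    Without depletion the bound fraction of probe is ``P/(Kd + P)``; with
    depletion it is the exact 1:1 quadratic solution at finite probe
    concentration (the probe is the 'receptor' being titrated by protein).
    """
    if not kd > 0:
        raise ValueError("kd must be positive")
    p = np.asarray(protein_conc, dtype=float)
    if depletion:
        if probe_conc is None or probe_conc <= 0:
            raise ValueError("depletion form requires a positive probe_conc")
        # vectorised cancellation-free quadratic; same root as solve_single_site
        s = probe_conc + p + kd
        disc = np.maximum(s * s - 4.0 * probe_conc * p, 0.0)
        frac = 2.0 * p / (s + np.sqrt(disc))
    else:
        frac = p / (kd + p)
    return r0 + (rmax - r0) * frac


def four_param_logistic(conc, cp50: float, slope: float, floor: float, ceiling: float):
    """Four-parameter logistic in concentration (Hill form).

    Increases from ``floor`` at zero concentration to ``ceiling`` at
    saturation; the inflection on a log axis is at ``cp50``, where the
    response is midway between floor and ceiling.
    """
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (cp50 / np.maximum(c, 1e-300)) ** slope, np.inf)
    return floor + (ceiling - floor) / (1.0 + ratio)


@dataclass
class FitResult:
    """Point estimate with uncertainty for a titration fit.

    ``estimate`` is the Kd or CP50 in µM; ``ci_low``/``ci_high`` bound it at
    the stated confidence level; ``curve_params`` holds the remaining curve
    parameters (FP: r0, rmax; CAPA: floor, ceiling, slope).
    """

    estimate: float
    ci_low: float
    ci_high: float
    confidence: float
    curve_params: dict[str, float]
    residual_norm: float
    converged: bool
    saturating: bool = True
    stderr: float | None = None
    n_obs: int = 0
    method: str = ""
    warnings_: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"{self.method} fit ({self.n_obs} points)",
            "-" * 44,
            f"estimate      : {self.estimate:.4g} uM",
            f"{int(self.confidence * 100)}% CI        : [{self.ci_low:.4g}, {self.ci_high:.4g}] uM",
        ]
        if self.stderr is not None:
            lines.append(f"std. error    : {self.stderr:.3g} uM")
        for k, v in self.curve_params.items():
            lines.append(f"{k:<14}: {v:.4g}")
        lines.append(f"residual norm : {self.residual_norm:.3g}")
        lines.append(f"converged     : {self.converged}")
        if not self.saturating:
            lines.append("note          : apparent Kd > ~5 uM; curve does not "
                         "saturate and the point estimate is unreliable")
        for w in self.warnings_:
            lines.append(f"warning       : {w}")
        return "\n".join(lines)


def _fit_curve(x, y, model: Callable, p0, bounds) -> tuple[np.ndarray, bool]:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                model, x, y, p0=p0, bounds=bounds, maxfev=20000
            )
        return popt, True
    except (RuntimeError, ValueError):
        return np.asarray(p0, dtype=float), False


class FluorescencePolarizationModel:
    """Single-site FP binding model for a titration.

    Parameters
    ----------
    titration : Titration
        Protein concentration series with anisotropy-change responses.
    depletion : bool
        Use the ligand-depletion quadratic (default) or the hyperbola.
    probe_concentration : float, optional
        Labeled probe concentration (µM); overrides the titration's value.
    """

    def __init__(
        self,
        titration: Titration,
        depletion: bool = True,
        probe_concentration: float | None = None,
    ):
        self.titration = titration
        self.depletion = depletion
        self.probe_concentration = (
            probe_concentration
            if probe_concentration is not None
            else titration.probe_concentration
        )
        if self.depletion and not (self.probe_concentration and self.probe_concentration > 0):
            raise ValueError("depletion fit requires a positive probe concentration")

    # deterministic, derivative-free start values
    def _start(self, x, y):
        r0 = float(np.min(y))
        rmax = float(np.max(y))
        half = r0 + 0.5 * (rmax - r0)
        kd0 = float(x[np.argmin(np.abs(y - half))])
        if kd0 <= 0:
            kd0 = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
        return kd0, r0, rmax

    def _model(self):
        def f(x, log_kd, r0, rmax):
            return fp_forward(
                x, 10.0 ** log_kd, r0, rmax,
                probe_conc=self.probe_concentration, depletion=self.depletion,
            )
        return f

    def fit(
        self,
        confidence: float = 0.95,
        ci_method: str = "bootstrap",
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> FitResult:
        """Nonlinear least squares over (Kd, r0, rmax).

        ``ci_method`` is ``"bootstrap"`` (parametric: Gaussian noise at the
        residual scale, refit, percentile interval) or ``"curvature"``
        (asymptotic normal interval on log10 Kd from the Jacobian).
        """
        x = self.titration.concentrations
        y = self.titration.responses
        if np.ptp(y) <= 0:
            raise FitError("responses are flat; nothing to fit")
        kd0, r0, rmax = self._start(x, y)
        f = self._model()
        p0 = (np.log10(kd0), r0, rmax)
        bounds = ([-9, -np.inf, -np.inf], [9, np.inf, np.inf])
        popt, ok = _fit_curve(x, y, f, p0, bounds)
        yhat = f(x, *popt)
        resid = y - yhat
        rnorm = float(np.sqrt(np.sum(resid**2)))
        kd = float(10.0 ** popt[0])
        curve = {"r0": float(popt[1]), "rmax": float(popt[2])}
        warn: list[str] = []

        ci_low = ci_high = kd
        stderr = None
        if ok:
            if ci_method == "bootstrap":
                sigma = float(np.std(resid, ddof=3)) if len(y) > 3 else float(np.std(resid))
                rng = np.random.default_rng(seed)
                boots = []
                for _ in range(n_boot):
                    yb = yhat + rng.normal(0.0, sigma, size=yhat.shape)
                    pb, okb = _fit_curve(x, yb, f, popt, bounds)
                    if okb:
                        boots.append(10.0 ** pb[0])
                if len(boots) >= max(20, n_boot // 2):
                    a = 0.5 * (1.0 - confidence)
                    ci_low, ci_high = np.quantile(boots, [a, 1.0 - a])
                    stderr = float(np.std(boots, ddof=1))
                else:
                    ok = False
                    warn.append("bootstrap refits largely failed")
            elif ci_method == "curvature":
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        _, pcov = optimize.curve_fit(
                            f, x, y, p0=popt, bounds=bounds, maxfev=20000
                        )
                    se_log = float(np.sqrt(pcov[0, 0]))
                    z = stats.norm.ppf(0.5 * (1.0 + confidence))
                    ci_low = 10.0 ** (popt[0] - z * se_log)
                    ci_high = 10.0 ** (popt[0] + z * se_log)
                    stderr = kd * np.log(10.0) * se_log
                except (RuntimeError, ValueError):
                    warn.append("curvature CI unavailable")
            else:
                raise ValueError("ci_method must be 'bootstrap' or 'curvature'")
        return FitResult(
            estimate=kd,
            ci_low=float(min(ci_low, kd)),
            ci_high=float(max(ci_high, kd)),
            confidence=confidence,
            curve_params=curve,
            residual_norm=rnorm,
            converged=ok,
            saturating=kd <= NON_SATURATING_KD,
            stderr=stderr,
            n_obs=len(y),
            method="FP single-site Kd"
            + (" (depletion)" if self.depletion else " (hyperbola)"),
            warnings_=warn,
        )


class PenetrationModel:
    """CAPA dose–response model: four-parameter logistic, CP50 at inflection.

    With replicate curves present, each replicate is fitted independently;
    the reported CP50 is their mean and the uncertainty is the standard
    error across the independent curve fits, matching how replicated
    penetration assays are conventionally summarised.
    """

    def __init__(self, titration: Titration):
        self.titration = titration
        if len(np.unique(titration.concentrations)) < 6:
            raise ValueError("CAPA fit needs at least 6 distinct concentrations")
        if np.any(titration.responses < -0.2) or np.any(titration.responses > 1.2):
            raise ValueError("CAPA responses must be normalized penetration fractions")

    @staticmethod
    def _model(x, log_cp50, slope, floor, ceiling):
        return four_param_logistic(x, 10.0 ** log_cp50, slope, floor, ceiling)

    def _fit_one(self, x, y):
        half = np.min(y) + 0.5 * np.ptp(y)
        cp0 = float(x[np.argmin(np.abs(y - half))])
        if cp0 <= 0:
            cp0 = float(np.median(x[x > 0]))
        p0 = (np.log10(cp0), 1.0, float(np.min(y)), float(np.max(y)))
        bounds = ([-9, 0.05, -0.5, -0.5], [9, 20, 1.5, 1.5])
        popt, ok = _fit_curve(x, y, self._model, p0, bounds)
        return popt, ok

    def fit(self, confidence: float = 0.95) -> FitResult:
        tit = self.titration
        fits = []
        warn: list[str] = []
        for _, rep in tit.replicates():
            order = np.argsort(rep.concentrations)
            x, y = rep.concentrations[order], rep.responses[order]
            # penetration should rise with concentration; flag gross violations
            if np.corrcoef(np.log10(np.maximum(x, 1e-12)), y)[0, 1] < 0:
                warn.append("response decreases with concentration in a replicate")
            popt, ok = self._fit_one(x, y)
            if ok:
                fits.append(popt)
        if not fits:
            return FitResult(
                estimate=np.nan, ci_low=np.nan, ci_high=np.nan, confidence=confidence,
                curve_params={}, residual_norm=np.nan, converged=False,
                n_obs=len(tit.responses), method="CAPA CP50", warnings_=warn,
            )
        cp50s = np.array([10.0 ** p[0] for p in fits])
        est = float(np.mean(cp50s))
        pmean = np.mean(fits, axis=0)
        yhat = self._model(tit.concentrations, *pmean)
        rnorm = float(np.sqrt(np.sum((tit.responses - yhat) ** 2)))
        if len(cp50s) >= 2:
            stderr = float(np.std(cp50s, ddof=1) / np.sqrt(len(cp50s)))
            tcrit = stats.t.ppf(0.5 * (1.0 + confidence), df=len(cp50s) - 1)
            ci_low, ci_high = est - tcrit * stderr, est + tcrit * stderr
        else:
            stderr = None
            ci_low = ci_high = est
            warn.append("single replicate: no between-fit standard error")
        return FitResult(
            estimate=est,
            ci_low=float(max(ci_low, 0.0)),
            ci_high=float(ci_high),
            confidence=confidence,
            curve_params={
                "slope": float(pmean[1]),
                "floor": float(pmean[2]),
                "ceiling": float(pmean[3]),
            },
            residual_norm=rnorm,
            converged=True,
            stderr=stderr,
            n_obs=len(tit.responses),
            method="CAPA CP50",
            warnings_=warn,
        )


def fit_kd(
    titration: Titration,
    depletion: bool = True,
    confidence: float = 0.95,
    probe_concentration: float | None = None,
    **fit_kwargs,
) -> FitResult:
    """Fit a single-site Kd to an FP titration. See FluorescencePolarizationModel."""
    model = FluorescencePolarizationModel(
        titration, depletion=depletion, probe_concentration=probe_concentration
    )
    return model.fit(confidence=confidence, **fit_kwargs)


def fit_cp50(titration: Titration, confidence: float = 0.95) -> FitResult:
    """Fit a CAPA CP50 to a penetration dose–response. See PenetrationModel."""
    return PenetrationModel(titration).fit(confidence=confidence)


def selectivity_ratio(kd_range_a, kd_range_b) -> float:
    """Ratio of arithmetic midpoints of two Kd ranges.

    Quantifies binding selectivity when each affinity is reported as a
    range: e.g. midpoints of 0.39–0.52 µM over 0.030–0.080 µM give ~8,
    the H3K9me2 : LIG1K126me2 selectivity of the UHRF1 TTD.
    """
    (a_lo, a_hi), (b_lo, b_hi) = kd_range_a, kd_range_b
    for lo, hi in ((a_lo, a_hi), (b_lo, b_hi)):
        if not (lo > 0 and hi > 0):
            raise ValueError("Kd ranges must be positive")
        if lo > hi:
            raise ValueError("range lower bound exceeds upper bound")
    return (0.5 * (a_lo + a_hi)) / (0.5 * (b_lo + b_hi))


def normalize_capa(raw_fluorescence, no_peptide_anchor: float, full_block_anchor: float):
    """Convert raw CAPA fluorescence to penetration fraction in [0, 1].

    Fluorescence is inversely related to penetration: with no peptide the
    reporter is fully labeled (maximal fluorescence, zero penetration);
    at a saturating control the reporter is fully blocked (minimal
    fluorescence, full penetration).
    """
    f = np.asarray(raw_fluorescence, dtype=float)
    span = no_peptide_anchor - full_block_anchor
    if span <= 0:
        raise ValueError("no-peptide anchor must exceed the full-block anchor")
    return np.clip((no_peptide_anchor - f) / span, 0.0, 1.0)
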