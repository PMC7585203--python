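"""Differential DNA methylation on beta-value matrices.

Beta values are per-CpG methylation fractions in [0, 1].  The analysis
asks whether a treatment shifts the methylome globally: probes highly
methylated in the control (β > 0.8) are selected, per-probe differences
Δβ = treated − control are computed (negative Δβ = hypomethylation in the
treated sample), and the Δβ distribution is summarised by its mean,
median and a fine histogram.  The shift call is a deliberately simple
distributional rule — the mean effect against a floor, with a bootstrap
CI reported either way — rather than per-probe significance testing,
because the scientific claim is about the bulk distribution.

The statsmodels-style entry point is :class:`DifferentialMethylation`,
whose ``fit()`` returns a results object wrapping the same primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "DeltaBetaSummary",
    "ShiftCall",
    "DifferentialMethylation",
    "DifferentialMethylationResults",
    "filter_high_methylation",
    "delta_beta",
    "summarize_delta",
    "density_bins",
    "call_global_shift",
]

DEFAULT_FILTER_THRESHOLD = 0.8
DEFAULT_EFFECT_FLOOR = 0.05
DEFAULT_HIST_BINS = 1000
DEFAULT_DENSITY_BINS = 500


@dataclass
class BetaMatrix:
    """Probe × sample methylation-fraction matrix.

    ``frame`` is indexed by probe id with one column per sample; NaN marks
    missing probes.  All non-missing values must lie in [0, 1].
    """

    frame: pd.DataFrame

    def __post_init__(self):
        vals = self.frame.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path) -> "BetaMatrix":
        return cls(pd.read_csv(path, index_col="probe_id", comment="#"))

    @property
    def probe_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def sample_labels(self) -> list[str]:
        return list(self.frame.columns)

    def column(self, label: str) -> pd.Series:
        return self.frame[label]


def filter_high_methylation(
    control: pd.Series, threshold: float = DEFAULT_FILTER_THRESHOLD
) -> pd.Index:
    """Probes with control beta strictly above the threshold.

    Missing control values are excluded.  The strict ``>`` matches the
    convention of selecting confidently methylated probes before asking
    whether they lose methylation.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = control > threshold  # NaN compares False
    return control.index[mask.fillna(False)]


def delta_beta(control: pd.Series, treated: pd.Series, probes: pd.Index) -> pd.Series:
    """Per-probe Δβ = treated − control over a probe set.

    Negative values mean the treated sample is hypomethylated.  Probes
    missing in either column are dropped; the count is recorded in
    ``result.attrs['n_dropped']``.
    """
    sub_c = control.reindex(probes)
    sub_t = treated.reindex(probes)
    delta = sub_t - sub_c
    n_dropped = int(delta.isna().sum())
    delta = delta.dropna()
    delta.name = "delta_beta"
    delta.attrs["n_dropped"] = n_dropped
    return delta


@dataclass
class DeltaBetaSummary:
    """Summary of a Δβ distribution: n, moments and a fine histogram."""

    n_probes: int
    mean_delta: float
    median_delta: float
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD
    deltas: np.ndarray | None = field(default=None, repr=False)

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def summarize_delta(
    deltas: pd.Series | np.ndarray,
    n_bins: int = DEFAULT_HIST_BINS,
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD,
) -> DeltaBetaSummary:
    """Mean, median and an equal-width histogram of Δβ over [−1, 1]."""
    d = np.asarray(deltas, dtype=float)
    d = d[~np.isnan(d)]
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    if d.size == 0:
        return DeltaBetaSummary(
            n_probes=0, mean_delta=np.nan, median_delta=np.nan,
            bin_edges=edges, counts=np.zeros(n_bins, dtype=int),
            filter_threshold=filter_threshold, deltas=d,
        )
    counts, _ = np.histogram(d, bins=edges)
    return DeltaBetaSummary(
        n_probes=int(d.size),
        mean_delta=float(np.mean(d)),
        median_delta=float(np.median(d)),
        bin_edges=edges,
        counts=counts,
        filter_threshold=filter_threshold,
        deltas=d,
    )


def density_bins(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    n_bins: int = DEFAULT_DENSITY_BINS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D square-bin counts of paired betas over the unit square.

    Pairs with a missing member are dropped.  Returns (counts, x_edges,
    y_edges); counts sum to the number of complete pairs.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = ~(np.isnan(xv) | np.isnan(yv))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, xe, ye = np.histogram2d(xv[ok], yv[ok], bins=[edges, edges])
    return counts, xe, ye


@dataclass
class ShiftCall:
    """Verdict of the global-shift decision rule."""

    verdict: str  # "shift" | "no-shift" | "indeterminate"
    mean_delta: float
    ci_low: float
    ci_high: float
    effect_floor: float
    n_probes: int

    @property
    def is_shift(self) -> bool:
        return self.verdict == "shift"


def call_global_shift(
    summary: DeltaBetaSummary,
    effect_floor: float = DEFAULT_EFFECT_FLOOR,
    min_n: int = 100,
    n_boot: int = 500,
    confidence: float = 0.95,
    seed: int | None = None,
) -> ShiftCall:
    """Call a global methylation shift from a Δβ summary.

    Verdict is "shift" iff |mean Δβ| ≥ ``effect_floor``; a bootstrap CI of
    the mean is reported regardless so borderline calls are transparent.
    Requires the summary to carry its delta vector.
    """
    if summary.deltas is None:
        raise ValueError("summary must retain its delta vector for the shift call")
    d = summary.deltas
    if d.size < min_n:
        return ShiftCall("indeterminate", float(np.nan), np.nan, np.nan,
                         effect_floor, int(d.size))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boot_means = d[idx].mean(axis=1)
    a = 0.5 * (1.0 - confidence)
    lo, hi = np.quantile(boot_means, [a, 1.0 - a])
    mean = float(np.mean(d))
    verdict = "shift" if abs(mean) >= effect_floor else "no-shift"
    return ShiftCall(verdict, mean, float(lo), float(hi), effect_floor, int(d.size))


class DifferentialMethylation:
    """Global differential-methylation model between two samples.

    Parameters
    ----------
    data : BetaMatrix
        Probe × sample beta values.
    control, treated : str
        Sample column labels.
    threshold : float
        Control-beta filter; only probes with control β > threshold enter
        the Δβ distribution.
    """

    def __init__(
        self,
        data: BetaMatrix,
        control: str,
        treated: str,
        threshold: float = DEFAULT_FILTER_THRESHOLD,
    ):
        self.data = data
        self.control = control
        self.treated = treated
        self.threshold = threshold
        for col in (control, treated):
            if col not in data.sample_labels:
                raise KeyError(f"sample column not found: {col}")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, control: str, treated: str, **kw):
        return cls(BetaMatrix(frame), control, treated, **kw)

    def fit(
        self,
        n_bins: int = DEFAULT_HIST_BINS,
        effect_floor: float = DEFAULT_EFFECT_FLOOR,
        min_n: int = 100,
        n_boot: int = 500,
        seed: int | None = None,
    ) -> "DifferentialMethylationResults":
        control = self.data.column(self.control)
        treated = self.data.column(self.treated)
        probes = filter_high_methylation(control, self.threshold)
        deltas = delta_beta(control, treated, probes)
        summary = summarize_delta(deltas, n_bins=n_bins, filter_threshold=self.threshold)
        call = ShiftCall("indeterminate", summary.mean_delta, np.nan, np.nan,
                         effect_floor, summary.n_probes)
        if summary.n_probes > 0:
            call = call_global_shift(
                summary, effect_floor=effect_floor, min_n=min_n,
                n_boot=n_boot, seed=seed,
            )
        return DifferentialMethylationResults(
            model=self, summary_stats=summary, shift_call=call,
            n_dropped=deltas.attrs.get("n_dropped", 0),
        )


@dataclass
class DifferentialMethylationResults:
    """Fitted Δβ distribution and shift verdict for one comparison."""

    model: DifferentialMethylation
    summary_stats: DeltaBetaSummary
    shift_call: ShiftCall
    n_dropped: int = 0

    @property
    def mean_delta(self) -> float:
        return self.summary_stats.mean_delta

    @property
    def median_delta(self) -> float:
        return self.summary_stats.median_delta

    @property
    def n_probes(self) -> int:
        return self.summary_stats.n_probes

    def summary(self) -> str:
        s = self.summary_stats
        c = self.shift_call
        lines = [
            "Differential methylation (beta values)",
            "-" * 44,
            f"comparison    : {self.model.treated} - {self.model.control}",
            f"filter        : control beta > {self.model.threshold}",
            f"probes (n)    : {s.n_probes}"
            + (f"  [{self.n_dropped} dropped incomplete]" if self.n_dropped else ""),
            f"mean delta    : {s.mean_delta:+.4f}",
            f"median delta  : {s.median_delta:+.4f}",
            f"bootstrap CI  : [{c.ci_low:+.4f}, {c.ci_high:+.4f}]",
            f"effect floor  : {c.effect_floor}",
            f"verdict       : {c.verdict}",
        ]
        return "\n".join(lines)

    def plot_histogram(self, ax=None):
        """Δβ histogram (1000 fine bins by default), as the figures plot it."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summary_stats
        centers = 0.5 * (s.bin_edges[:-1] + s.bin_edges[1:])
        ax.bar(centers, s.counts, width=np.diff(s.bin_edges), color="0.3")
        ax.set_xlabel(r"$\Delta\beta$ (treated $-$ control)")
        ax.set_ylabel("probes")
        ax.set_xlim(-1, 1)
        return ax
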