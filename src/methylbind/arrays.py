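"""Reader-domain and peptide microarray quantification.

Arrays print each GST-tagged reader domain (or each peptide) as replicate
spots; after scanning, the per-spot intensities are aggregated, normalized
within each probe dataset to the brightest signal, and ranked.  Two
conventions from replicated array practice are encoded here:

* spread — duplicates report the half-range; three or more replicates
  report the standard error of the mean;
* saturation — normalized signals above ~0.7 cannot be ordered reliably
  (probing at saturating peptide concentration plus print variability),
  so entities above the threshold form one tied class at the top of the
  ranking rather than an ordered list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "NormalizedProfile",
    "aggregate_replicates",
    "normalize_to_brightest",
    "flag_saturation",
    "rank_entities",
    "quantify",
]

SATURATION_THRESHOLD = 0.7


@dataclass
class IntensityMatrix:
    """Entity × replicate spot intensities for one hybridized probe.

    ``values`` holds raw fluorescence (arbitrary units, ≥ 0; NaN marks a
    missing spot); rows are reader domains or peptides, columns replicates.
    """

    values: np.ndarray
    entity_labels: list[str]
    probe_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D entity x replicate grid")
        if len(self.entity_labels) != self.values.shape[0]:
            raise ValueError("entity_labels must match the number of rows")
        if np.any(self.values[~np.isnan(self.values)] < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long_dataframe(cls, df: pd.DataFrame, probe: str | None = None):
        """Build from long-form ``entity, replicate, probe, intensity`` rows."""
        if probe is not None:
            df = df[df["probe"] == probe]
        wide = df.pivot_table(
            index="entity", columns="replicate", values="intensity", aggfunc="first"
        )
        return cls(
            values=wide.to_numpy(),
            entity_labels=list(wide.index.astype(str)),
            probe_label=probe if probe is not None else str(df["probe"].iloc[0]),
        )

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, ent in enumerate(self.entity_labels):
            for j in range(self.n_replicates):
                v = self.values[i, j]
                if not np.isnan(v):
                    rows.append(
                        {"entity": ent, "replicate": j, "probe": self.probe_label,
                         "intensity": v}
                    )
        return pd.DataFrame(rows)


@dataclass
class NormalizedProfile:
    """Aggregated, brightest-normalized signal profile for one probe."""

    probe_label: str
    entity_labels: list[str]
    mean_signal: np.ndarray
    spread: np.ndarray
    normalized: np.ndarray
    saturated: np.ndarray
    saturation_threshold: float = SATURATION_THRESHOLD
    degenerate: bool = False
    excluded: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe": self.probe_label,
                "entity": self.entity_labels,
                "mean": self.mean_signal,
                "spread": self.spread,
                "normalized": self.normalized,
                "saturated": self.saturated,
            }
        )


def aggregate_replicates(matrix: IntensityMatrix) -> pd.DataFrame:
    """Per-entity mean and spread across replicate spots.

    Spread is the half-range for ≤ 2 valid replicates and the SEM
    (sample SD / sqrt(n)) for ≥ 3; entities with no valid replicate are
    excluded and listed in the ``excluded`` column of the attrs.
    """
    means, spreads, ns, keep, excluded = [], [], [], [], []
    for i, ent in enumerate(matrix.entity_labels):
        row = matrix.values[i]
        valid = row[~np.isnan(row)]
        if valid.size == 0:
            excluded.append(ent)
            continue
        keep.append(ent)
        means.append(float(np.mean(valid)))
        ns.append(int(valid.size))
        if valid.size <= 2:
            spreads.append(float((valid.max() - valid.min()) / 2.0))
        else:
            spreads.append(float(np.std(valid, ddof=1) / np.sqrt(valid.size)))
    out = pd.DataFrame(
        {"entity": keep, "mean": means, "spread": spreads, "n_valid": ns}
    )
    out.attrs["excluded"] = excluded
    return out


def normalize_to_brightest(means: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale signals to the brightest entity within the probe dataset.

    Returns the normalized vector and a flag that is True when all signals
    are zero (normalization degenerate; zeros returned unchanged).
    """
    m = np.asarray(means, dtype=float)
    if np.any(m < 0):
        raise ValueError("signals must be non-negative")
    peak = m.max() if m.size else 0.0
    if peak == 0:
        return np.zeros_like(m), True
    return m / peak, False


def flag_saturation(normalized: np.ndarray, threshold: float = SATURATION_THRESHOLD) -> np.ndarray:
    """Mark entities whose normalized signal exceeds the saturation threshold.

    Flagged entities are mutually indistinguishable: at saturating probe
    concentration their signal differences reflect print variability, not
    affinity.
    """
    n = np.asarray(normalized, dtype=float)
    return n > threshold


def quantify(
    matrix: IntensityMatrix, saturation_threshold: float = SATURATION_THRESHOLD
) -> NormalizedProfile:
    """Aggregate replicates, normalize to brightest and flag saturation."""
    agg = aggregate_replicates(matrix)
    normalized, degenerate = normalize_to_brightest(agg["mean"].to_numpy())
    return NormalizedProfile(
        probe_label=matrix.probe_label,
        entity_labels=list(agg["entity"]),
        mean_signal=agg["mean"].to_numpy(),
        spread=agg["spread"].to_numpy(),
        normalized=normalized,
        saturated=flag_saturation(normalized, saturation_threshold),
        saturation_threshold=saturation_threshold,
        degenerate=degenerate,
        excluded=agg.attrs["excluded"],
    )


def rank_entities(profile: NormalizedProfile) -> pd.DataFrame:
    """Rank entities by normalized signal, with a tied saturated class.

    All saturated entities share rank 1 (reported as a set via the
    ``tied_class`` flag); the remainder are ordered by descending
    normalized signal.
    """
    df = profile.to_dataframe()
    sat = df[df["saturated"]].copy()
    rest = df[~df["saturated"]].sort_values("normalized", ascending=False).copy()
    sat["rank"] = 1
    sat["tied_class"] = len(sat) > 1
    rest["rank"] = np.arange(len(rest)) + (2 if len(sat) else 1)
    rest["tied_class"] = False
    ranked = pd.concat([sat.sort_values("normalized", ascending=False), rest])
    return ranked.reset_index(drop=True)
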