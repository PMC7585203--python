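"""Competitive binding equilibria for a single-site methyllysine reader.

A reader protein (UHRF1, through its tandem Tudor domain) partitions between
N competing methylated ligands — in the motivating system, histone H3K9me2
and the non-histone substrate LIG1K126me2.  The model is pure mass balance
with 1:1 exclusive binding::

    R_t = R_f + sum_i C_i          (receptor balance)
    L_i_t = L_i_f + C_i            (one balance per ligand)
    C_i = R_f * L_i_f / Kd_i       (definition of each dissociation constant)

Eliminating the complexes reduces the system to one scalar equation in the
free receptor concentration ``r``::

    r * (1 + sum_i L_i_t / (Kd_i + r)) = R_t

whose left side is strictly increasing in ``r``, so a unique root lies in
``[0, R_t]`` and bracketed root-finding is guaranteed to converge.

Concentrations are in µM throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "BindingSystem",
    "EquilibriumState",
    "StoichiometryScenario",
    "SweepResult",
    "solve_single_site",
    "solve_competitive",
    "predict_partition",
    "excess_limit_ratio",
    "sweep_scenarios",
]

#: residual tolerance for the scalar solve (µM)
RESIDUAL_TOL = 1e-12
MAX_ITER = 200


class DomainError(ValueError):
    """Raised when inputs violate the model's physical domain."""


class ConvergenceError(RuntimeError):
    """Raised when the equilibrium solve fails to reach tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations and dissociation constants of a competitive system.

    Parameters
    ----------
    receptor_total : float
        Total reader concentration (µM).
    ligand_totals : sequence of float
        Total concentration of each competing ligand (µM).
    kds : sequence of float
        Dissociation constant of each ligand (µM), parallel to
        ``ligand_totals``.  The association constant is ``1/Kd``.
    labels : sequence of str, optional
        Ligand identifiers; defaults to ``ligand_1 .. ligand_N``.
    """

    receptor_total: float
    ligand_totals: tuple[float, ...]
    kds: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "ligand_totals", tuple(float(x) for x in self.ligand_totals))
        object.__setattr__(self, "kds", tuple(float(k) for k in self.kds))
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"ligand_{i + 1}" for i in range(len(self.ligand_totals)))
            )
        else:
            object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.ligand_totals) != len(self.kds) or len(self.ligand_totals) < 1:
            raise DomainError("ligand_totals and kds must have equal length >= 1")
        if len(self.labels) != len(self.ligand_totals):
            raise DomainError("labels must parallel ligand_totals")
        if self.receptor_total < 0 or any(l < 0 for l in self.ligand_totals):
            raise DomainError("concentrations must be non-negative")
        if any(not (k > 0) for k in self.kds):
            raise DomainError("dissociation constants must be positive")

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_totals)


@dataclass(frozen=True)
class EquilibriumState:
    """Free and complexed species concentrations at equilibrium (µM)."""

    receptor_total: float
    receptor_free: float
    ligand_totals: tuple[float, ...]
    ligand_free: tuple[float, ...]
    complexes: tuple[float, ...]
    labels: tuple[str, ...]

    @property
    def occupancy_fractions(self) -> tuple[float, ...]:
        """Share of total receptor bound to each ligand."""
        if self.receptor_total == 0:
            return tuple(0.0 for _ in self.complexes)
        return tuple(c / self.receptor_total for c in self.complexes)

    @property
    def free_fraction(self) -> float:
        if self.receptor_total == 0:
            return 1.0
        return self.receptor_free / self.receptor_total

    def occupancy(self, label: str) -> float:
        return self.occupancy_fractions[self.labels.index(label)]

    def as_dict(self) -> dict[str, float]:
        d = {"receptor_total": self.receptor_total, "receptor_free": self.receptor_free,
             "free_fraction": self.free_fraction}
        for lab, lt, lf, c, occ in zip(
            self.labels, self.ligand_totals, self.ligand_free, self.complexes,
            self.occupancy_fractions,
        ):
            d[f"{lab}_total"] = lt
            d[f"{lab}_free"] = lf
            d[f"{lab}_complex"] = c
            d[f"{lab}_occupancy"] = occ
        return d


def _state_from_receptor_free(system: BindingSystem, r: float) -> EquilibriumState:
    complexes = tuple(r * lt / (kd + r) for lt, kd in zip(system.ligand_totals, system.kds))
    # ligand_free via Kd/(Kd+r) avoids cancellation when the ligand is nearly depleted
    ligand_free = tuple(lt * kd / (kd + r) for lt, kd in zip(system.ligand_totals, system.kds))
    return EquilibriumState(
        receptor_total=system.receptor_total,
        receptor_free=r,
        ligand_totals=system.ligand_totals,
        ligand_free=ligand_free,
        complexes=complexes,
        labels=system.labels,
    )


def solve_single_site(receptor_total: float, ligand_total: float, kd: float) -> EquilibriumState:
    """Closed-form 1:1 equilibrium for a single receptor–ligand pair.

    The complex concentration is the smaller root of the binding quadratic,

    ``C = ((R + L + Kd) - sqrt((R + L + Kd)^2 - 4 R L)) / 2``,

    evaluated in the cancellation-free form ``2RL / (S + sqrt(S^2 - 4RL))``.
    """
    if receptor_total < 0 or ligand_total < 0:
        raise DomainError("concentrations must be non-negative")
    if not kd > 0:
        raise DomainError("kd must be positive")
    s = receptor_total + ligand_total + kd
    disc = s * s - 4.0 * receptor_total * ligand_total
    denom = s + math.sqrt(max(disc, 0.0))
    complex_ = 2.0 * receptor_total * ligand_total / denom if denom > 0 else 0.0
    return EquilibriumState(
        receptor_total=receptor_total,
        receptor_free=receptor_total - complex_,
        ligand_totals=(ligand_total,),
        ligand_free=(ligand_total - complex_,),
        complexes=(complex_,),
        labels=("ligand_1",),
    )


def solve_competitive(
    system: BindingSystem,
    tol: float = RESIDUAL_TOL,
    max_iter: int = MAX_ITER,
) -> EquilibriumState:
    """Solve the N-ligand competitive equilibrium.

    Reduces the mass balances to the scalar equation
    ``r (1 + sum_i L_i_t/(Kd_i + r)) = R_t`` for the free receptor ``r`` and
    finds the unique root in ``[0, R_t]`` by safeguarded bracketing.
    """
    r_t = system.receptor_total
    if r_t == 0.0:
        return _state_from_receptor_free(system, 0.0)

    lig = np.asarray(system.ligand_totals)
    kds = np.asarray(system.kds)

    # solve in x = r / R_t on [0, 1] so bracketing accuracy is relative,
    # independent of the absolute concentration scale
    def residual(x: float) -> float:
        return x * (1.0 + float(np.sum(lig / (kds + x * r_t)))) - 1.0

    f_hi = residual(1.0)
    if f_hi == 0.0:  # all ligand totals zero: receptor stays free
        return _state_from_receptor_free(system, r_t)
    try:
        x = brentq(residual, 0.0, 1.0, xtol=1e-16, rtol=8.9e-16, maxiter=max_iter)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise ConvergenceError(f"equilibrium solve failed: {exc}") from exc
    res = residual(x)
    if abs(res) > max(tol / max(r_t, 1e-300), 1e-9):
        raise ConvergenceError("equilibrium solve did not reach tolerance", residual=res * r_t)
    return _state_from_receptor_free(system, x * r_t)


@dataclass(frozen=True)
class StoichiometryScenario:
    """Cellular stoichiometry scenario for the reader partition prediction.

    Defaults encode the published cellular estimates: equimolar UHRF1 and
    LIG1, a 1000-fold molar excess of histone H3 over LIG1, 35 % of H3
    di-methylated at K9 and 50 % of LIG1 di-methylated at K126, with measured
    dissociation constants of 0.19 µM (H3K9me2) and 0.041 µM (LIG1K126me2).
    Only ratios are known from proteomics, so ``absolute_scale`` pins the
    LIG1 total concentration (µM); the partition prediction is insensitive
    to it over orders of magnitude.
    """

    uhrf1_to_lig1_ratio: float = 1.0
    h3_to_lig1_ratio: float = 1000.0
    h3_me2_fraction: float = 0.35
    lig1_me2_fraction: float = 0.50
    kd_h3: float = 0.19
    kd_lig1: float = 0.041
    absolute_scale: float = 1.0

    def __post_init__(self):
        for name in ("h3_me2_fraction", "lig1_me2_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1]")
        for name in ("uhrf1_to_lig1_ratio", "h3_to_lig1_ratio", "absolute_scale"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if not (self.kd_h3 > 0 and self.kd_lig1 > 0):
            raise DomainError("dissociation constants must be positive")

    def to_system(self) -> BindingSystem:
        return BindingSystem(
            receptor_total=self.uhrf1_to_lig1_ratio * self.absolute_scale,
            ligand_totals=(
                self.h3_to_lig1_ratio * self.h3_me2_fraction * self.absolute_scale,
                self.lig1_me2_fraction * self.absolute_scale,
            ),
            kds=(self.kd_h3, self.kd_lig1),
            labels=("H3K9me2", "LIG1K126me2"),
        )

    @property
    def methyl_abundance_ratio(self) -> float:
        """Molar excess of H3K9me2 over LIG1K126me2 implied by the scenario."""
        return self.h3_to_lig1_ratio * self.h3_me2_fraction / self.lig1_me2_fraction


def predict_partition(scenario: StoichiometryScenario | None = None) -> EquilibriumState:
    """Equilibrium partition of the reader between H3K9me2 and LIG1K126me2.

    With default parameters the model predicts ~99 % of the reader bound to
    H3K9me2 and <1 % to LIG1K126me2: the histone mark's sheer abundance
    outweighs the ~5-fold tighter LIG1 interaction.
    """
    scenario = scenario or StoichiometryScenario()
    return solve_competitive(scenario.to_system())


def excess_limit_ratio(ligand_totals: Sequence[float], kds: Sequence[float]) -> np.ndarray:
    """Occupancy shares among bound receptor in the no-depletion limit.

    When every ligand remains effectively at its total concentration, ligand
    i's share of the bound receptor is ``(L_i/Kd_i) / sum_j (L_j/Kd_j)``.
    """
    lig = np.asarray(ligand_totals, dtype=float)
    kds_ = np.asarray(kds, dtype=float)
    if lig.shape != kds_.shape:
        raise DomainError("ligand_totals and kds must have matching length")
    if np.any(lig < 0) or np.any(kds_ <= 0):
        raise DomainError("require ligand_totals >= 0 and kds > 0")
    w = lig / kds_
    total = w.sum()
    if total == 0:
        raise DomainError("all ligand totals are zero; shares undefined")
    return w / total


@dataclass
class SweepResult:
    """Parameter sweep of the partition prediction."""

    table: pd.DataFrame
    envelope: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        if self.envelope is None:
            occ_cols = [c for c in self.table.columns if c.endswith("_occupancy")]
            self.envelope = self.table[occ_cols].agg(["min", "max"])


_SCENARIO_PARAMS = (
    "uhrf1_to_lig1_ratio",
    "h3_to_lig1_ratio",
    "h3_me2_fraction",
    "lig1_me2_fraction",
    "kd_h3",
    "kd_lig1",
    "absolute_scale",
)


def sweep_scenarios(
    base: StoichiometryScenario,
    ranges: dict[str, tuple[float, float]],
    grid_size: int = 25,
    mode: str = "product",
    log_params: Sequence[str] = ("absolute_scale", "kd_h3", "kd_lig1"),
) -> SweepResult:
    """Sweep scenario parameters and tabulate the resulting partitions.

    Parameters
    ----------
    base : StoichiometryScenario
        Parameters held fixed where not swept.
    ranges : dict
        Map of parameter name to ``(lo, hi)`` interval.  A degenerate
        interval ``(a, a)`` yields a single grid point.
    grid_size : int
        Points per swept axis.
    mode : {"product", "per_axis"}
        Cartesian product of all axes, or each axis swept separately with
        the others at their base values.
    log_params : sequence of str
        Parameters gridded logarithmically (must be positive).

    Returns
    -------
    SweepResult
        ``table`` has one row per scenario with all parameters, species
        concentrations and occupancy fractions; ``envelope`` holds the
        min/max of each occupancy fraction across the sweep (the prediction
        band).
    """
    if not ranges:
        raise DomainError("ranges must name at least one parameter")
    for p in ranges:
        if p not in _SCENARIO_PARAMS:
            raise DomainError(f"unknown scenario parameter: {p}")
    if grid_size < 1:
        raise DomainError("grid_size must be >= 1")

    def axis(p: str) -> np.ndarray:
        lo, hi = ranges[p]
        if lo > hi:
            raise DomainError(f"empty range for {p}: ({lo}, {hi})")
        if lo == hi or grid_size == 1:
            return np.array([lo])
        if p in log_params and lo > 0:
            return np.geomspace(lo, hi, grid_size)
        return np.linspace(lo, hi, grid_size)

    params = list(ranges)
    rows = []
    if mode == "product":
        combos = itertools.product(*(axis(p) for p in params))
        combo_params = [params] * 1  # all params vary together
        for values in combos:
            rows.append(dict(zip(params, values)))
    elif mode == "per_axis":
        for p in params:
            for v in axis(p):
                rows.append({p: v})
    else:
        raise DomainError("mode must be 'product' or 'per_axis'")

    records = []
    for overrides in rows:
        scen = StoichiometryScenario(
            **{p: overrides.get(p, getattr(base, p)) for p in _SCENARIO_PARAMS}
        )
        state = predict_partition(scen)
        rec = {p: getattr(scen, p) for p in _SCENARIO_PARAMS}
        rec["methyl_abundance_ratio"] = scen.methyl_abundance_ratio
        rec.update(state.as_dict())
        records.append(rec)
    return SweepResult(table=pd.DataFrame.from_records(records))
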