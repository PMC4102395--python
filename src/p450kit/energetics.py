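"""Reaction-coordinate scanning and ensemble barrier statistics.

Adiabatic mapping: at each target value of a geometric reaction
coordinate, the system is energy-minimised under a stiff harmonic
restraint, seeded from the previous converged geometry along the leg.
The reported energy at each point is the physical backend energy with
the restraint term excluded; the barrier is the difference between the
highest and lowest points of the profile (transition state minus
reactant complex).

An ensemble of barriers from independently prepared starting structures
is summarised by its arithmetic mean, sample standard deviation, and a
Boltzmann-weighted average

    dE_bw = -kT * ln[ (1/N) * sum_i exp(-dEi / kT) ],

which is dominated by the lowest barriers — the ones most
representative of the reactive conformations of the enzyme.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .constants import KB_KCAL
from .core import GeometryError, Structure
from .qmmm import RestraintSpec

# An energy backend maps a flat position vector to (energy kcal/mol,
# gradient); it must be deterministic for identical inputs.
EnergyBackend = Callable[[np.ndarray], tuple[float, np.ndarray]]


class Harmonic1D:
    """V(r) = a * (r - r0)^2 — a one-dimensional analytic backend."""

    def __init__(self, r0: float = 2.0, a: float = 1.0):
        self.r0, self.a = r0, a

    def __call__(self, x: np.ndarray):
        r = float(np.asarray(x).ravel()[0])
        return self.a * (r - self.r0) ** 2, np.array([2 * self.a * (r - self.r0)])


class DoubleWell1D:
    """V(r) = a*(r-c1)^2*(r-c2)^2 + slope*r — an asymmetric double well."""

    def __init__(self, c1: float = 1.2, c2: float = 2.6, a: float = 4.0, slope: float = 0.0):
        self.c1, self.c2, self.a, self.slope = c1, c2, a, slope

    def __call__(self, x: np.ndarray):
        r = float(np.asarray(x).ravel()[0])
        u, v = r - self.c1, r - self.c2
        e = self.a * u * u * v * v + self.slope * r
        g = self.a * (2 * u * v * v + 2 * u * u * v) + self.slope
        return e, np.array([g])


class ScalarCoordinate:
    """Reaction coordinate = the single position component itself."""

    def value(self, x: np.ndarray) -> float:
        return float(np.asarray(x).ravel()[0])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(np.asarray(x, float).ravel())
        g[0] = 1.0
        return g


class DistanceCoordinate:
    """Reaction coordinate = |x_i - x_j| for a flat (n*3,) position vector."""

    def __init__(self, i: int, j: int):
        self.i, self.j = i, j

    def value(self, x: np.ndarray) -> float:
        x = np.asarray(x, float).reshape(-1, 3)
        return float(np.linalg.norm(x[self.i] - x[self.j]))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        xr = np.asarray(x, float).reshape(-1, 3)
        d = xr[self.i] - xr[self.j]
        r = np.linalg.norm(d)
        g = np.zeros_like(xr)
        if r > 0:
            g[self.i] = d / r
            g[self.j] = -d / r
        return g.ravel()


@dataclasses.dataclass
class ReactionProfile:
    r: np.ndarray  # coordinate values, Å, sorted ascending
    energies: np.ndarray  # backend energy (restraint excluded), kcal/mol

    @property
    def reactant_index(self) -> int:
        return int(np.argmin(self.energies))

    @property
    def ts_index(self) -> int:
        return int(np.argmax(self.energies))

    @property
    def barrier(self) -> float:
        """TS minus reactant energy: max(E) - min(E) over the profile."""
        return float(self.energies[self.ts_index] - self.energies[self.reactant_index])

    @property
    def ts_coordinate(self) -> float:
        return float(self.r[self.ts_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_A": self.r, "E_kcal": self.energies})


class ScanConvergenceError(RuntimeError):
    def __init__(self, r: float, message: str):
        super().__init__(f"restrained minimisation failed at r = {r} Å: {message}")
        self.r = r


def run_scan(
    backend: EnergyBackend,
    restraints: tuple[Sequence[RestraintSpec], Sequence[RestraintSpec]],
    x0: np.ndarray | None = None,
    coordinate=None,
    gtol: float = 1e-3,
    max_iter: int = 500,
) -> ReactionProfile:
    """Adiabatic scan of ``backend`` over the restraint targets.

    ``restraints`` is the (ascending, descending) pair produced by
    ``qmmm.scan_restraints``; each leg starts from the shared start
    point and every minimisation is seeded from the previous converged
    geometry of its leg. Convergence: max gradient component of the
    restrained energy <= ``gtol`` kcal/mol/Å.
    """
    if coordinate is None:
        coordinate = ScalarCoordinate()
    up, down = restraints
    if not up or not down:
        raise ValueError("run_scan: both scan legs must be non-empty")
    start = up[0].target
    if x0 is None:
        x0 = np.array([start])
    x0 = np.asarray(x0, dtype=float).ravel()

    results: dict[float, float] = {}

    def minimise_leg(leg: Sequence[RestraintSpec], seed: np.ndarray) -> np.ndarray:
        x = seed.copy()
        for spec in leg:
            target, k = spec.target, spec.force_constant

            def objective(xx):
                e, g = backend(xx)
                r = coordinate.value(xx)
                dr = r - target
                return (
                    e + k * dr * dr,
                    np.asarray(g, float).ravel() + 2 * k * dr * coordinate.gradient(xx),
                )

            res = minimize(
                objective, x, jac=True, method="L-BFGS-B",
                options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14},
            )
            grad_inf = float(np.max(np.abs(res.jac)))
            if grad_inf > 10 * gtol and not res.success:
                raise ScanConvergenceError(target, res.message)
            x = np.asarray(res.x, float)
            e_phys, _ = backend(x)  # restraint term excluded from the profile
            results[round(target, 6)] = float(e_phys)
        return x

    minimise_leg(up, x0)
    minimise_leg(down, x0)

    r = np.array(sorted(results))
    e = np.array([results[v] for v in r])
    return ReactionProfile(r, e)


@dataclasses.dataclass
class BarrierSet:
    """An ensemble of activation barriers and its Table-style aggregates."""

    barriers: np.ndarray  # kcal/mol
    temperature: float  # K
    mean: float
    sample_sd: float | None  # n-1 denominator; None for a single barrier
    boltzmann_weighted: float

    def to_frame(self, label: str = "barriers") -> pd.DataFrame:
        rows = {f"p{i + 1}": b for i, b in enumerate(self.barriers)}
        rows["Ave"] = self.mean
        rows["Boltzmann-weighted Ave"] = self.boltzmann_weighted
        rows["St. Dev."] = np.nan if self.sample_sd is None else self.sample_sd
        return pd.DataFrame({label: rows})


def barrier_stats(barriers: Sequence[float], temperature: float = 300.0) -> BarrierSet:
    """Mean, sample SD and Boltzmann-weighted average of an ensemble.

    The Boltzmann weight uses kT = 0.0019872 * T kcal/mol and the
    log-sum-exp form, so the result always lies between min(barriers)
    and the arithmetic mean, approaching the former as T -> 0 and the
    latter as T -> infinity.
    """
    b = np.asarray(list(barriers), dtype=float)
    if b.size == 0:
        raise ValueError("barrier_stats: empty barrier list")
    if temperature <= 0:
        raise ValueError("barrier_stats: temperature must be positive")
    kt = KB_KCAL * temperature
    bw = -kt * (logsumexp(-b / kt) - np.log(b.size))
    sd = float(b.std(ddof=1)) if b.size > 1 else None
    return BarrierSet(b, temperature, float(b.mean()), sd, float(bw))


@dataclasses.dataclass
class FragmentPopulation:
    """Per-fragment sums of Mulliken spin densities and charges."""

    spin: dict[str, float]
    charge: dict[str, float]

    @property
    def total_spin(self) -> float:
        return float(sum(self.spin.values()))

    @property
    def total_charge(self) -> float:
        return float(sum(self.charge.values()))


def aggregate_mulliken(
    table: pd.DataFrame, fragment_map: dict[int, str]
) -> FragmentPopulation:
    """Sum per-atom Mulliken spin densities and charges by fragment.

    ``table`` needs columns ``serial``, ``spin``, ``charge``; every
    serial must be assigned to exactly one fragment. Fragment totals
    conserve the per-atom totals exactly.
    """
    spin: dict[str, float] = {}
    charge: dict[str, float] = {}
    for _, row in table.iterrows():
        serial = int(row["serial"])
        frag = fragment_map.get(serial)
        if frag is None:
            raise KeyError(f"atom serial {serial} not assigned to any fragment")
        spin[frag] = spin.get(frag, 0.0) + float(row["spin"])
        charge[frag] = charge.get(frag, 0.0) + float(row["charge"])
    return FragmentPopulation(spin, charge)


def aggregate_mulliken_ensemble(
    tables: Sequence[pd.DataFrame], fragment_map: dict[int, str]
) -> pd.DataFrame:
    """Fragment means and sample SDs across an ensemble of snapshots."""
    if not tables:
        raise ValueError("empty ensemble")
    pops = [aggregate_mulliken(t, fragment_map) for t in tables]
    frags = list(pops[0].spin)
    rows = []
    for frag in frags:
        s = np.array([p.spin.get(frag, 0.0) for p in pops])
        c = np.array([p.charge.get(frag, 0.0) for p in pops])
        rows.append({
            "fragment": frag,
            "spin_mean": s.mean(),
            "spin_sd": s.std(ddof=1) if len(pops) > 1 else np.nan,
            "charge_mean": c.mean(),
            "charge_sd": c.std(ddof=1) if len(pops) > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("fragment")


def fe_s_distance_report(
    structures: Sequence[Structure],
    fe_name: str = "FE",
    s_name: str = "SG",
) -> tuple[float, float | None]:
    """Mean and sample SD of the Fe-Sγ distance across optimised structures.

    The Fe-S bond length tracks the share of unpaired spin on the
    proximal sulfur; its spread across snapshots measures how much the
    axial ligation varies in the ensemble. SD is None for a single
    structure.
    """
    dists = []
    for k, s in enumerate(structures):
        fe = [i for i, a in enumerate(s.atoms) if a.name == fe_name]
        sg = [i for i, a in enumerate(s.atoms) if a.name == s_name]
        if not fe or not sg:
            missing = fe_name if not fe else s_name
            raise GeometryError(f"structure {k + 1}: atom {missing} missing")
        dists.append(float(np.linalg.norm(s.atoms[fe[0]].pos - s.atoms[sg[0]].pos)))
    d = np.array(dists)
    if d.size == 0:
        raise ValueError("fe_s_distance_report: no structures supplied")
    sd = float(d.std(ddof=1)) if d.size > 1 else None
    return float(d.mean()), sd
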