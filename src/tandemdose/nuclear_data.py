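"""Radionuclide decay data, branched decay-chain kinetics, and dose constants.

This module models per-nuclide emission spectra (as mean energies and yields),
branched decay chains as directed acyclic graphs, the Bateman closed-form
solution for chain activities, and the conversion of energy released per
disintegration into an equilibrium dose constant in Gy·g/(μCi·h).

Decay data ship with the package as a plain CSV compiled from evaluated
nuclear data (NNDC/ENSDF, ICRP-107-style); see :func:`bundled_decay_data_path`.
"""

from __future__ import annotations

import enum
import functools
import math
import re
from collections import defaultdict
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEV_TO_J",
    "BQ_PER_UCI",
    "KBQ_PER_UCI",
    "GY_G_PER_UCI_H_PER_MEV",
    "DecayDataError",
    "ChainStructureError",
    "DecayDataValidationError",
    "EmissionKind",
    "EmissionFilter",
    "Emission",
    "Nuclide",
    "DecayChain",
    "DoseConstant",
    "normalize_nuclide_name",
    "bundled_decay_data_path",
    "load_decay_data",
    "default_chains",
    "energy_per_decay",
    "chain_energy_per_decay",
    "dose_constant",
    "chain_dose_constant",
    "bateman_activities",
    "cumulative_decays",
    "equilibrium_time",
]

MEV_TO_J = 1.602176634e-13
BQ_PER_UCI = 3.7e4
KBQ_PER_UCI = 37.0
#: Dose constant for 1 MeV released per disintegration:
#: J/MeV × decays/(s·μCi) × s/h ÷ J/(Gy·g) = Gy·g/(μCi·h) per MeV.
GY_G_PER_UCI_H_PER_MEV = MEV_TO_J * BQ_PER_UCI * 3600.0 / 1e-3

_HALF_LIFE_UNITS_H = {"s": 1.0 / 3600.0, "min": 1.0 / 60.0, "h": 1.0, "d": 24.0}
_BRANCHING_TOL = 1e-6


class DecayDataError(ValueError):
    """Base class for decay-data problems."""


class ChainStructureError(DecayDataError):
    """Chain graph is malformed (missing daughter, cycle, no termination)."""


class DecayDataValidationError(DecayDataError):
    """Row-level data violate an invariant (branching sum, unknown kind...)."""


class EmissionKind(str, enum.Enum):
    ALPHA = "alpha"
    BETA_MEAN = "beta_mean"
    CONVERSION_ELECTRON = "conversion_electron"
    AUGER = "auger"
    GAMMA = "gamma"
    XRAY = "xray"


class EmissionFilter(str, enum.Enum):
    """Which emission kinds enter an energy-per-decay sum.

    ``reference`` (alphas + mean betas, photons excluded) reproduces the
    conventional locally-absorbed self-dose constants for mm-scale sources;
    ``charged_all`` additionally counts conversion and Auger electrons and is
    documented as deviating from the reference constants.
    """

    REFERENCE = "reference"
    CHARGED_ALL = "charged_all"
    BETA_ONLY = "beta_only"
    ALPHA_ONLY = "alpha_only"
    PHOTONS_ONLY = "photons_only"
    ALL = "all"


_FILTER_KINDS: dict[EmissionFilter, frozenset[EmissionKind]] = {
    EmissionFilter.REFERENCE: frozenset({EmissionKind.ALPHA, EmissionKind.BETA_MEAN}),
    EmissionFilter.CHARGED_ALL: frozenset(
        {
            EmissionKind.ALPHA,
            EmissionKind.BETA_MEAN,
            EmissionKind.CONVERSION_ELECTRON,
            EmissionKind.AUGER,
        }
    ),
    EmissionFilter.BETA_ONLY: frozenset({EmissionKind.BETA_MEAN}),
    EmissionFilter.ALPHA_ONLY: frozenset({EmissionKind.ALPHA}),
    EmissionFilter.PHOTONS_ONLY: frozenset({EmissionKind.GAMMA, EmissionKind.XRAY}),
    EmissionFilter.ALL: frozenset(EmissionKind),
}


@dataclass(frozen=True)
class Emission:
    """A single emission line: mean energy (MeV) and yield per disintegration."""

    kind: EmissionKind
    energy_mev: float
    yield_: float

    def __post_init__(self) -> None:
        if not isinstance(self.kind, EmissionKind):
            object.__setattr__(self, "kind", EmissionKind(self.kind))
        if not self.energy_mev > 0:
            raise DecayDataValidationError(f"emission energy must be > 0, got {self.energy_mev}")
        if self.yield_ < 0:
            raise DecayDataValidationError(f"emission yield must be >= 0, got {self.yield_}")


@dataclass(frozen=True)
class Nuclide:
    """A nuclide with half-life (hours; ``None`` for stable), emissions and decay modes."""

    name: str
    half_life_h: float | None
    emissions: tuple[Emission, ...] = ()
    decay_modes: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.half_life_h is not None and not self.half_life_h > 0:
            raise DecayDataValidationError(
                f"{self.name}: half-life must be > 0 (or None for stable)"
            )
        if self.decay_modes:
            if self.half_life_h is None:
                raise DecayDataValidationError(f"{self.name}: stable nuclide cannot decay")
            total = sum(f for _, f in self.decay_modes)
            if abs(total - 1.0) > _BRANCHING_TOL:
                raise DecayDataValidationError(
                    f"{self.name}: branching fractions sum to {total:.6g}, expected 1"
                )

    @property
    def is_stable(self) -> bool:
        return self.half_life_h is None

    @property
    def lambda_per_h(self) -> float:
        """Decay constant in 1/h (0 for a stable nuclide)."""
        if self.half_life_h is None:
            return 0.0
        return math.log(2.0) / self.half_life_h


@dataclass(frozen=True)
class DoseConstant:
    """Equilibrium dose constant in Gy·g/(μCi·h) with its derivation settings."""

    value: float
    emission_filter: EmissionFilter
    yield_cutoff: float
    nuclide_or_chain: str


class DecayChain:
    """Branched decay chain rooted at ``parent``, validated as a terminating DAG."""

    def __init__(self, parent: str, nuclides: Mapping[str, Nuclide]):
        if parent not in nuclides:
            raise ChainStructureError(f"parent {parent!r} not in nuclide set")
        self.parent = parent
        self._all = dict(nuclides)
        self._members = self._toposort()
        self.nuclides: dict[str, Nuclide] = {n: self._all[n] for n in self._members}
        self._branch_prob = self._branch_probabilities()

    # -- structure -----------------------------------------------------------

    def _toposort(self) -> list[str]:
        """Reachable members in topological (feeder-before-fed) order."""
        reachable: set[str] = set()
        stack = [self.parent]
        while stack:
            name = stack.pop()
            if name in reachable:
                continue
            reachable.add(name)
            nuc = self._all.get(name)
            if nuc is None:
                raise ChainStructureError(f"daughter {name!r} referenced but not defined")
            for daughter, _ in nuc.decay_modes:
                stack.append(daughter)
        # Kahn's algorithm on the reachable subgraph.
        indeg: dict[str, int] = {n: 0 for n in reachable}
        for n in reachable:
            for d, _ in self._all[n].decay_modes:
                indeg[d] += 1
        order = [n for n in reachable if indeg[n] == 0]
        if order != [self.parent] and self.parent not in order:
            raise ChainStructureError(f"{self.parent}: parent is fed by a chain member (cycle)")
        queue = list(order)
        out: list[str] = []
        while queue:
            n = queue.pop(0)
            out.append(n)
            for d, _ in self._all[n].decay_modes:
                indeg[d] -= 1
                if indeg[d] == 0:
                    queue.append(d)
        if len(out) != len(reachable):
            raise ChainStructureError(f"{self.parent}: decay graph contains a cycle")
        for n in out:
            if not self._all[n].decay_modes and not self._all[n].is_stable:
                # Radioactive dead-end: allowed only if declared terminal on purpose;
                # treat as terminating (its activity still decays away).
                pass
        return out

    def _branch_probabilities(self) -> dict[str, float]:
        prob: dict[str, float] = defaultdict(float)
        prob[self.parent] = 1.0
        for name in self._members:
            for daughter, frac in self.nuclides[name].decay_modes:
                prob[daughter] += prob[name] * frac
        return dict(prob)

    @property
    def members(self) -> list[str]:
        """Member names, parent first, topologically ordered."""
        return list(self._members)

    def branch_probability(self, member: str) -> float:
        """Cumulative probability that a parent decay eventually reaches ``member``."""
        if member not in self.nuclides:
            raise KeyError(f"{member!r} is not a member of the {self.parent} chain")
        return self._branch_prob[member]

    def __contains__(self, member: str) -> bool:
        return member in self.nuclides

    def __repr__(self) -> str:  # pragma: no cover
        return f"DecayChain({self.parent}, members={self._members})"


# -- name handling ----------------------------------------------------------

_NAME_RE_NUM_FIRST = re.compile(r"^(\d+)[-_ ]?([A-Za-z]{1,3})$")
_NAME_RE_SYM_FIRST = re.compile(r"^([A-Za-z]{1,3})[-_ ]?(\d+)$")


def normalize_nuclide_name(name: str) -> str:
    """Normalize nuclide spellings (``225Ac``, ``ac225``, ``Ac-225``) to ``Ac-225``."""
    s = name.strip()
    m = _NAME_RE_NUM_FIRST.match(s)
    if m:
        mass, sym = m.group(1), m.group(2)
    else:
        m = _NAME_RE_SYM_FIRST.match(s)
        if not m:
            raise ValueError(f"cannot parse nuclide name {name!r}")
        sym, mass = m.group(1), m.group(2)
    return f"{sym.capitalize()}-{int(mass)}"


# -- loading -----------------------------------------------------------------


def bundled_decay_data_path() -> str:
    """Filesystem path of the decay-data CSV shipped with the package."""
    return str(resources.files("tandemdose.data").joinpath("decay_data.csv"))


def load_decay_data(source: str | None = None) -> dict[str, DecayChain]:
    """Read a decay-data table and return a chain rooted at every radioactive nuclide.

    The table holds one decay branch or one emission per row with columns
    ``nuclide, half_life, half_life_unit, daughter, branching, emission,
    energy_mev, yield, source``.  Unknown emission kinds and branching sums
    away from 1 are rejected; a daughter referenced but never defined raises
    :class:`ChainStructureError`.
    """
    path = source or bundled_decay_data_path()
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    # "yield" is a Python keyword; rename so itertuples exposes the column.
    df = df.rename(columns={"yield": "yield_"})
    required = {"nuclide", "half_life", "half_life_unit", "daughter", "branching",
                "emission", "energy_mev", "yield_"}
    missing = required - set(df.columns)
    if missing:
        raise DecayDataValidationError(f"decay table missing columns: {sorted(missing)}")

    half_lives: dict[str, float | None] = {}
    emissions: dict[str, list[Emission]] = defaultdict(list)
    modes: dict[str, list[tuple[str, float]]] = defaultdict(list)

    for row in df.itertuples(index=False):
        name = row.nuclide.strip()
        if not name:
            raise DecayDataValidationError("row with empty nuclide name")
        if row.half_life.strip():
            unit = row.half_life_unit.strip().lower()
            if unit not in _HALF_LIFE_UNITS_H:
                raise DecayDataValidationError(f"{name}: unknown half-life unit {unit!r}")
            hl = float(row.half_life) * _HALF_LIFE_UNITS_H[unit]
        else:
            hl = None
        if name in half_lives:
            prev = half_lives[name]
            if (prev is None) != (hl is None) or (
                prev is not None and hl is not None and abs(prev - hl) > 1e-9 * prev
            ):
                raise DecayDataValidationError(f"{name}: inconsistent half-life across rows")
        else:
            half_lives[name] = hl

        if row.daughter.strip():
            modes[name].append((row.daughter.strip(), float(row.branching)))
        if row.emission.strip():
            kind = row.emission.strip()
            try:
                ekind = EmissionKind(kind)
            except ValueError as exc:
                raise DecayDataValidationError(f"{name}: unknown emission kind {kind!r}") from exc
            emissions[name].append(Emission(ekind, float(row.energy_mev), float(row.yield_)))

    nuclides = {
        name: Nuclide(
            name=name,
            half_life_h=half_lives[name],
            emissions=tuple(emissions.get(name, ())),
            decay_modes=tuple(modes.get(name, ())),
        )
        for name in half_lives
    }
    return {
        name: DecayChain(name, nuclides)
        for name, nuc in nuclides.items()
        if not nuc.is_stable
    }


@functools.lru_cache(maxsize=1)
def default_chains() -> dict[str, DecayChain]:
    """Chains from the bundled decay-data fixture (cached)."""
    return load_decay_data()


# -- energy per decay and dose constants ------------------------------------


def energy_per_decay(
    nuclide: Nuclide,
    emission_filter: EmissionFilter | str = EmissionFilter.REFERENCE,
    yield_cutoff: float = 0.01,
) -> float:
    """Yield-weighted energy (MeV) per disintegration over the filtered emissions.

    Emissions with yield below ``yield_cutoff`` are ignored.
    """
    if not 0.0 <= yield_cutoff < 1.0:
        raise ValueError(f"yield_cutoff must be in [0, 1), got {yield_cutoff}")
    kinds = _FILTER_KINDS[EmissionFilter(emission_filter)]
    return sum(
        e.energy_mev * e.yield_
        for e in nuclide.emissions
        if e.kind in kinds and e.yield_ >= yield_cutoff
    )


def chain_energy_per_decay(
    chain: DecayChain,
    emission_filter: EmissionFilter | str = EmissionFilter.REFERENCE,
    yield_cutoff: float = 0.01,
) -> float:
    """Energy (MeV) released per parent disintegration at secular equilibrium.

    Each member contributes its own energy per decay scaled by the cumulative
    branch probability from the parent.
    """
    return sum(
        chain.branch_probability(name)
        * energy_per_decay(chain.nuclides[name], emission_filter, yield_cutoff)
        for name in chain.members
    )


def dose_constant(
    energy_mev: float,
    emission_filter: EmissionFilter | str = EmissionFilter.REFERENCE,
    yield_cutoff: float = 0.01,
    nuclide_or_chain: str = "",
) -> DoseConstant:
    """Convert MeV per disintegration to a dose constant in Gy·g/(μCi·h)."""
    if energy_mev < 0:
        raise ValueError(f"energy must be >= 0, got {energy_mev}")
    return DoseConstant(
        value=energy_mev * GY_G_PER_UCI_H_PER_MEV,
        emission_filter=EmissionFilter(emission_filter),
        yield_cutoff=yield_cutoff,
        nuclide_or_chain=nuclide_or_chain,
    )


def chain_dose_constant(
    chain: DecayChain,
    emission_filter: EmissionFilter | str = EmissionFilter.REFERENCE,
    yield_cutoff: float = 0.01,
) -> DoseConstant:
    """Dose constant for a whole chain at secular equilibrium."""
    e = chain_energy_per_decay(chain, emission_filter, yield_cutoff)
    return dose_constant(e, emission_filter, yield_cutoff, nuclide_or_chain=chain.parent)


# -- Bateman kinetics --------------------------------------------------------


def _bateman_number_coefficients(chain: DecayChain) -> dict[str, dict[float, float]]:
    """Exponential-term coefficients of N_i(t) for unit initial *parent activity*.

    Returns ``{member: {rate: coeff}}`` with ``N_i(t) = sum coeff * exp(-rate*t)``
    and ``N_parent(0) = 1/lambda_parent`` so the parent activity starts at 1.
    Degenerate (equal) decay constants along a feeding path are not supported.
    """
    lam_p = chain.nuclides[chain.parent].lambda_per_h
    coeffs: dict[str, dict[float, float]] = {chain.parent: {lam_p: 1.0 / lam_p}}
    feeders: dict[str, list[tuple[str, float]]] = defaultdict(list)
    for name in chain.members:
        for daughter, frac in chain.nuclides[name].decay_modes:
            feeders[daughter].append((name, frac))

    for name in chain.members[1:]:
        nuc = chain.nuclides[name]
        if nuc.is_stable:
            continue
        lam = nuc.lambda_per_h
        terms: dict[float, float] = defaultdict(float)
        for parent_name, frac in feeders[name]:
            for rate, c in coeffs[parent_name].items():
                src = frac * chain.nuclides[parent_name].lambda_per_h * c
                denom = lam - rate
                if abs(denom) <= 1e-12 * lam:
                    raise DecayDataError(
                        f"degenerate decay constants ({name} vs rate {rate}/h): "
                        "the closed-form Bateman solution used here requires distinct rates"
                    )
                terms[rate] += src / denom
        terms[lam] -= sum(terms.values())  # enforce N(0) = 0
        coeffs[name] = dict(terms)
    return coeffs


def bateman_activities(chain: DecayChain, t_grid_h: Sequence[float]) -> pd.DataFrame:
    """Activities of every radioactive member vs time, for unit parent activity at t=0.

    ``t_grid_h`` must be nonnegative and nondecreasing.  The returned frame is
    indexed by time (hours) with one column per radioactive member; values are
    activities relative to the initial parent activity.
    """
    t = np.asarray(t_grid_h, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid_h must be a non-empty 1-D sequence")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("t_grid_h must be nonnegative and nondecreasing")
    coeffs = _bateman_number_coefficients(chain)
    out: dict[str, np.ndarray] = {}
    for name in chain.members:
        nuc = chain.nuclides[name]
        if nuc.is_stable:
            continue
        lam = nuc.lambda_per_h
        acts = np.zeros_like(t)
        for rate, c in coeffs[name].items():
            acts += lam * c * np.exp(-rate * t)
        out[name] = np.maximum(acts, 0.0)  # clip roundoff-negative values
    return pd.DataFrame(out, index=pd.Index(t, name="t_h"))


def cumulative_decays(chain: DecayChain, member: str) -> float:
    """Integral of a member's activity over [0, inf) for unit initial parent activity.

    Equals the member's cumulative branch probability divided by the parent
    decay constant (total decays conservation).
    """
    if member not in chain:
        raise KeyError(f"{member!r} not in chain {chain.parent}")
    coeffs = _bateman_number_coefficients(chain)
    lam = chain.nuclides[member].lambda_per_h
    if lam == 0.0:
        raise ValueError(f"{member} is stable: activity integral undefined")
    return float(sum(lam * c / rate for rate, c in coeffs[member].items()))


def equilibrium_time(
    chain: DecayChain,
    member: str,
    tolerance: float = 0.01,
    t_max_h: float = 48.0,
    dt_h: float = 0.01,
) -> float:
    """Hours until ``member``/parent activity stays within ``tolerance`` of its asymptote.

    The asymptote is the transient-equilibrium ratio set by the slowest
    surviving exponential (the parent's, for a long-lived parent).  Returns 0
    for the parent itself; raises ``KeyError`` for a non-member.
    """
    if member not in chain:
        raise KeyError(f"{member!r} not in chain {chain.parent}")
    if not 0.0 < tolerance < 1.0:
        raise ValueError("tolerance must be in (0, 1)")
    if member == chain.parent:
        return 0.0
    coeffs = _bateman_number_coefficients(chain)
    lam_p = chain.nuclides[chain.parent].lambda_per_h
    lam_m = chain.nuclides[member].lambda_per_h
    asymptote = lam_m * coeffs[member].get(lam_p, 0.0)
    if asymptote <= 0:
        raise DecayDataError(f"{member}: no transient-equilibrium asymptote with the parent")
    t = np.arange(dt_h, t_max_h + dt_h, dt_h)
    ratio = np.zeros_like(t)
    for rate, c in coeffs[member].items():
        ratio += lam_m * c * np.exp(-rate * t)
    ratio /= np.exp(-lam_p * t)  # parent activity
    outside = np.abs(ratio / asymptote - 1.0) > tolerance
    if outside[-1]:
        return math.inf
    last_bad = np.nonzero(outside)[0]
    if last_bad.size == 0:
        return float(t[0])
    return float(t[last_bad[-1] + 1])
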