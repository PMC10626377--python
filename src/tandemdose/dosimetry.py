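"""Tumor self-dose per injected activity, equal-dose activity matching, tandem design.

Self-dose assumes an absorbed fraction of 1.0 for the filtered (locally
deposited) radiation and ignores cross-dose from neighboring organs.  Internal
bookkeeping is Gy / kBq / h; μCi and cGy/kBq appear only at the presentation
boundary (1 μCi = 37 kBq exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .nuclear_data import (
    DecayChain,
    DoseConstant,
    EmissionFilter,
    KBQ_PER_UCI,
    chain_dose_constant,
    normalize_nuclide_name,
)
from .tac_fitting import (
    CumulatedActivity,
    TimeActivityCurve,
    cumulated_activity,
    fit_model,
    select_model,
)

__all__ = [
    "AbsorbedDoseResult",
    "ActivityPrescription",
    "absorbed_dose_gy",
    "self_dose",
    "match_activity",
    "tandem_prescription",
    "round_activity_kbq",
    "tumor_dose_from_uptake",
]


@dataclass(frozen=True)
class AbsorbedDoseResult:
    """Tumor self-dose for a prescription: per-activity rate and total dose."""

    dose_per_injected_activity_cgy_per_kbq: float
    total_dose_gy: float
    tumor_mass_g: float
    injected_kbq: float
    dose_constant_used: DoseConstant
    cumulated_activity_used: CumulatedActivity


@dataclass(frozen=True)
class ActivityPrescription:
    """Injected-activity prescription: (nuclide, kBq) components, mono or tandem."""

    components: tuple[tuple[str, float], ...]
    label: str = "mono"

    def __post_init__(self) -> None:
        if self.label not in ("mono", "tandem"):
            raise ValueError(f"label must be 'mono' or 'tandem', got {self.label!r}")
        if any(kbq <= 0 for _, kbq in self.components):
            raise ValueError("component activities must be > 0")
        if self.label == "tandem" and len(self.components) < 2:
            raise ValueError("a tandem prescription needs >= 2 components")

    def rounded_components(self) -> tuple[tuple[str, float], ...]:
        """Components quantized for reporting (see :func:`round_activity_kbq`)."""
        return tuple((n, round_activity_kbq(kbq)) for n, kbq in self.components)


def absorbed_dose_gy(cumulated_uci_h: float, delta: DoseConstant, mass_g: float) -> float:
    """Dose (Gy) = Ã [μCi·h] × Δ [Gy·g/(μCi·h)] / mass [g]."""
    if not mass_g > 0:
        raise ValueError(f"mass_g must be > 0, got {mass_g}")
    if cumulated_uci_h < 0:
        raise ValueError("cumulated activity must be >= 0")
    return cumulated_uci_h * delta.value / mass_g


def self_dose(
    cumulated: CumulatedActivity,
    delta: DoseConstant,
    tumor_mass_g: float,
    injected_kbq: float,
) -> AbsorbedDoseResult:
    """Tumor self-dose from a cumulated activity expressed in %IA·h.

    The fractional cumulated activity (%IA·h / 100, i.e. kBq·h per injected
    kBq) is scaled to the prescription, converted to μCi·h, and multiplied by
    the dose constant over the tumor mass.  The per-activity rate is reported
    in cGy/kBq.
    """
    if not injected_kbq > 0:
        raise ValueError(f"injected_kbq must be > 0, got {injected_kbq}")
    total_uci_h = (cumulated.value / 100.0) * injected_kbq / KBQ_PER_UCI
    total_gy = absorbed_dose_gy(total_uci_h, delta, tumor_mass_g)
    return AbsorbedDoseResult(
        dose_per_injected_activity_cgy_per_kbq=100.0 * total_gy / injected_kbq,
        total_dose_gy=total_gy,
        tumor_mass_g=tumor_mass_g,
        injected_kbq=injected_kbq,
        dose_constant_used=delta,
        cumulated_activity_used=cumulated,
    )


def match_activity(
    reference_kbq: float,
    reference_dose_per_kbq: float,
    target_dose_per_kbq: float,
) -> float:
    """Activity of the target nuclide delivering the reference tumor dose.

    Exact algebra: returned × target rate = reference × reference rate.
    """
    if not reference_kbq > 0:
        raise ValueError("reference_kbq must be > 0")
    if not (reference_dose_per_kbq > 0 and target_dose_per_kbq > 0):
        raise ValueError("dose-per-activity rates must be > 0")
    return reference_kbq * reference_dose_per_kbq / target_dose_per_kbq


def round_activity_kbq(kbq: float) -> float:
    """Quantize a prescription activity for reporting, rounding halves down.

    Activities of at least 1 MBq are reported to integer MBq; smaller ones to
    integer kBq.  The half-down rule makes 17.5 MBq report as 17 MBq.
    """
    quantum = 1000.0 if kbq >= 1000.0 else 1.0
    return math.ceil(kbq / quantum - 0.5) * quantum


def tandem_prescription(
    mono_prescriptions: Sequence[ActivityPrescription | tuple[str, float]],
    fractions: Sequence[float],
) -> ActivityPrescription:
    """Scale each mono prescription by its fraction and combine into a tandem.

    ``mono_prescriptions`` may be single-component prescriptions or bare
    ``(nuclide, kbq)`` pairs.  Raw (unrounded) activities are retained on the
    result; use :meth:`ActivityPrescription.rounded_components` for reporting.
    A single component at fraction 1.0 is returned unchanged as mono.
    """
    comps: list[tuple[str, float]] = []
    for p in mono_prescriptions:
        if isinstance(p, ActivityPrescription):
            if len(p.components) != 1:
                raise ValueError("mono prescriptions must have exactly one component")
            comps.append(p.components[0])
        else:
            name, kbq = p
            comps.append((normalize_nuclide_name(name), float(kbq)))
    if len(comps) != len(fractions):
        raise ValueError(
            f"{len(comps)} components but {len(fractions)} fractions"
        )
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must be in (0, 1]")
    scaled = tuple((n, kbq * f) for (n, kbq), f in zip(comps, fractions))
    if len(scaled) == 1:
        return ActivityPrescription(scaled, label="mono")
    return ActivityPrescription(scaled, label="tandem")


def tumor_dose_from_uptake(
    uptake,
    chain: DecayChain,
    tumor_mass_g: float,
    injected_kbq: float,
    organ: str = "tumor",
    emission_filter: EmissionFilter | str = EmissionFilter.REFERENCE,
    yield_cutoff: float = 0.01,
    models: Sequence[str] = ("mono_exp", "bi_exp"),
) -> AbsorbedDoseResult:
    """Full dosimetry stage: uptake summary table -> tumor self-dose.

    ``uptake`` is a summary frame as produced by
    :func:`tandemdose.biodistribution.summarize_uptake`.  The organ's mean %IA
    series is fitted with each candidate model, the minimum-AICc fit is
    selected, the cumulated activity is computed with physical decay re-applied
    (the %IA data are decay-corrected), and the chain dose constant in
    ``reference`` mode converts it to absorbed dose.
    """
    sub = uptake[uptake["organ"] == organ].sort_values("time_pi_h")
    if sub.empty:
        raise ValueError(f"no rows for organ {organ!r} in the uptake table")
    tac = TimeActivityCurve(
        times=sub["time_pi_h"].to_numpy(dtype=float),
        values=sub["mean_pct_ia"].to_numpy(dtype=float),
        sds=sub["sd_pct_ia"].to_numpy(dtype=float),
        n_per_point=sub["n"].to_numpy(dtype=float),
    )
    fits = [fit_model(tac, m) for m in models]
    best = select_model(fits)
    lam_phys = chain.nuclides[chain.parent].lambda_per_h
    cum = cumulated_activity(best, physical_lambda=lam_phys, data_is_decay_corrected=True)
    delta = chain_dose_constant(chain, emission_filter, yield_cutoff)
    return self_dose(cum, delta, tumor_mass_g, injected_kbq)
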