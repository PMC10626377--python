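"""Synthetic cohorts with the statistical structure the analysis pipeline assumes.

Two generators are provided:

* ``simulate_biodistribution`` — per-animal organ uptake around bi-exponential
  truth curves with relative (proportional) normal noise truncated at zero;
* ``simulate_trial`` — per-mouse exponential radiance growth with lognormal
  inter-mouse heterogeneity in the starting burden.  Death is mechanistic
  (the radiance crossing a threshold), so burden series and survival times are
  internally consistent, and the arm growth rate is calibrated in closed form
  so the configured median survival is hit exactly in distribution.

A single integer seed fans out to independent substreams per stage, so any
stage can be regenerated on its own and the full bundle is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import biodistribution as bd
from . import efficacy as eff
from .nuclear_data import DecayChain, default_chains, normalize_nuclide_name

__all__ = [
    "BiexpTruth",
    "SimConfig",
    "biexp_through_points",
    "simulate_biodistribution",
    "simulate_trial",
    "end_to_end_fixture",
    "FixtureBundle",
]

_STREAMS = {
    "biodist-Lu-177": 1,
    "biodist-Ac-225": 2,
    "trial-3wk": 3,
    "trial-5wk": 4,
}


@dataclass(frozen=True)
class BiexpTruth:
    """Ground-truth bi-exponential organ kinetics in %IA/g."""

    a1: float
    lambda1: float
    a2: float
    lambda2: float

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2) <= 0:
            raise ValueError("truth rates must be > 0")
        if min(self.a1, self.a2) < 0:
            raise ValueError("truth amplitudes must be >= 0")

    def __call__(self, t_h: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_h, dtype=float)
        return self.a1 * np.exp(-self.lambda1 * t) + self.a2 * np.exp(-self.lambda2 * t)


def biexp_through_points(
    t_a: float,
    v_a: float,
    t_b: float,
    v_b: float,
    fast_amp: float = 0.0,
    fast_rate: float = 0.5,
) -> BiexpTruth:
    """Bi-exponential truth passing exactly through two (time, value) setpoints.

    The fast component (``fast_amp``·exp(−``fast_rate``·t)) is fixed; the slow
    component is solved so the total curve hits both setpoints.
    """
    if not t_b > t_a >= 0:
        raise ValueError("need t_b > t_a >= 0")
    ra = v_a - fast_amp * math.exp(-fast_rate * t_a)
    rb = v_b - fast_amp * math.exp(-fast_rate * t_b)
    if ra <= 0 or rb <= 0 or ra <= rb:
        raise ValueError("setpoints not reachable with a decaying slow component")
    lam2 = math.log(ra / rb) / (t_b - t_a)
    a2 = ra * math.exp(lam2 * t_a)
    return BiexpTruth(a1=fast_amp, lambda1=fast_rate, a2=a2, lambda2=lam2)


def _default_organ_kinetics() -> dict[str, dict[str, BiexpTruth]]:
    # Setpoints (in %IA/g) match the generator's target summary statistics:
    # tumor 14.4/14.1 at 4 h and 6.3/9.3 at 168 h, kidney 13.3/25.9 at 1 h.
    return {
        "Lu-177": {
            "tumor": biexp_through_points(4, 14.4, 168, 6.3, fast_amp=2.0, fast_rate=0.5),
            "kidneys": biexp_through_points(1, 13.3, 168, 1.2),
            "liver": biexp_through_points(1, 1.0, 168, 0.3),
            "submandibular_salivary_glands": biexp_through_points(1, 0.45, 168, 0.05),
            "intestines": biexp_through_points(1, 1.6, 168, 0.2),
        },
        "Ac-225": {
            "tumor": biexp_through_points(4, 14.1, 168, 9.3, fast_amp=2.0, fast_rate=0.5),
            "kidneys": biexp_through_points(1, 25.9, 168, 1.5),
            "liver": biexp_through_points(1, 1.2, 168, 0.4),
            "submandibular_salivary_glands": biexp_through_points(1, 0.45, 168, 0.05),
            "intestines": biexp_through_points(1, 1.8, 168, 0.25),
        },
    }


#: Median survival setpoints (weeks) per treatment cohort and arm.
DEFAULT_SURVIVAL_MEDIANS = {
    "3wk": {"NT": 8.3, "Lu": 9.4, "Ac": 15.3, "tandem": 14.1},
    "5wk": {"NT": 7.9, "Lu": 10.3, "Ac": 14.6, "tandem": 13.2},
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic-cohort generators (deterministic given seed)."""

    seed: int = 0
    # biodistribution stage
    n_per_timepoint: int = 5
    timepoints_h: tuple[float, ...] = (1.0, 4.0, 24.0, 48.0, 168.0)
    organ_kinetics: Mapping[str, Mapping[str, BiexpTruth]] = field(
        default_factory=_default_organ_kinetics
    )
    noise_rel_sd: float = 0.2
    organ_masses_g: Mapping[str, float] = field(
        default_factory=lambda: {
            "tumor": 0.3,
            "kidneys": 0.4,
            "liver": 1.3,
            "submandibular_salivary_glands": 0.1,
            "intestines": 1.5,
        }
    )
    injected_kbq: Mapping[str, float] = field(
        default_factory=lambda: {"Lu-177": 30_000.0, "Ac-225": 40.0}
    )
    count_delay_h: Mapping[str, float] = field(
        default_factory=lambda: {"Lu-177": 0.0, "Ac-225": 24.0}
    )
    # trial stage
    n_per_arm: int = 10
    baseline_radiance: float = 1.0e6
    death_threshold: float = 5.0e9
    radiance_lognorm_sd: float = 0.5
    survival_medians_wk: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SURVIVAL_MEDIANS.items()}
    )
    arm_growth_rates: Mapping[str, Mapping[str, float]] | None = None
    followup_wk: float = 25.0

    def __post_init__(self) -> None:
        if self.n_per_timepoint < 1 or self.n_per_arm < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.noise_rel_sd < 0:
            raise ValueError("noise_rel_sd must be >= 0")
        if self.death_threshold <= self.baseline_radiance:
            raise ValueError("death_threshold must exceed baseline_radiance")
        for cohort in self.survival_medians_wk.values():
            if any(m <= 0 for m in cohort.values()):
                raise ValueError("survival medians must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream generator for a named stage."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown stream {stream!r}")
        return np.random.default_rng(np.random.SeedSequence([self.seed, _STREAMS[stream]]))

    def growth_rate(self, cohort: str, arm: str) -> float:
        """Per-week exponential growth rate; calibrated so the configured
        median survival is the distributional median of the threshold-crossing
        time (growth = ln(threshold/baseline) / median)."""
        if self.arm_growth_rates is not None:
            return float(self.arm_growth_rates[cohort][arm])
        median = self.survival_medians_wk[cohort][arm]
        return math.log(self.death_threshold / self.baseline_radiance) / median


def simulate_biodistribution(config: SimConfig, nuclide: str) -> list[bd.BiodistSample]:
    """Draw per-animal biodistribution samples for one nuclide.

    Each value is truth(t) × max(0, 1 + ε) with ε ~ Normal(0, relative SD);
    counted activities are back-computed so that quantification with the
    matching decay correction reproduces the drawn %IA/g exactly.
    """
    name = normalize_nuclide_name(nuclide)
    if name not in config.organ_kinetics:
        raise KeyError(f"no organ kinetics configured for {name}")
    chain = default_chains()[name]
    half_life_h = chain.nuclides[name].half_life_h
    rng = config.rng(f"biodist-{name}")
    injected = config.injected_kbq[name]
    delay = config.count_delay_h.get(name, 0.0)
    samples: list[bd.BiodistSample] = []
    for organ, truth in config.organ_kinetics[name].items():
        mass = config.organ_masses_g[organ]
        for t in config.timepoints_h:
            base = float(truth(t))
            for i in range(config.n_per_timepoint):
                factor = max(0.0, 1.0 + rng.normal(0.0, config.noise_rel_sd)) \
                    if config.noise_rel_sd > 0 else 1.0
                pct_ia_per_g = base * factor
                pct_ia = pct_ia_per_g * mass
                count_time = t + delay
                measured = (pct_ia / 100.0) * injected * 2.0 ** (-count_time / half_life_h)
                samples.append(
                    bd.BiodistSample(
                        animal_id=f"{name}-t{t:g}-m{i + 1}",
                        organ=organ,
                        time_pi_h=t,
                        measured_activity_kbq=measured,
                        count_time_h=count_time,
                        sample_mass_g=mass,
                        injected_activity_kbq=injected,
                    )
                )
    return samples


def simulate_trial(
    config: SimConfig, cohort: str = "3wk"
) -> tuple[list[eff.BLISeries], list[eff.SurvivalRecord]]:
    """Simulate the 4-arm trial for one treatment cohort.

    Radiance grows exponentially per mouse from a lognormal starting burden;
    a mouse dies when its (continuous-time) radiance crosses the death
    threshold, at a time recorded to 0.1 wk.  Mice alive at the follow-up
    cutoff are right-censored at their last observation.  Zero growth means
    the threshold is never crossed: all mice are censored.
    """
    if cohort not in config.survival_medians_wk:
        raise KeyError(f"unknown cohort {cohort!r}")
    rng = config.rng(f"trial-{cohort}")
    series: list[eff.BLISeries] = []
    records: list[eff.SurvivalRecord] = []
    log_thr = math.log(config.death_threshold)
    for arm in config.survival_medians_wk[cohort]:
        g = config.growth_rate(cohort, arm)
        for i in range(config.n_per_arm):
            log_r0 = math.log(config.baseline_radiance) + rng.normal(
                0.0, config.radiance_lognorm_sd
            )
            if g > 0:
                t_death = (log_thr - log_r0) / g
                t_death = max(0.1, round(t_death, 1))
            else:
                t_death = math.inf
            mouse = f"{cohort}-{arm}-{i + 1}"
            if t_death <= config.followup_wk:
                records.append(eff.SurvivalRecord(mouse, arm, t_death, 1))
                last_week = int(t_death)
            else:
                records.append(
                    eff.SurvivalRecord(mouse, arm, config.followup_wk, 0)
                )
                last_week = int(config.followup_wk)
            weeks = np.arange(0.0, last_week + 1.0)
            radiance = np.exp(log_r0 + g * weeks)
            series.append(eff.BLISeries(mouse, arm, weeks, radiance))
    return series, records


@dataclass(frozen=True)
class FixtureBundle:
    """Deterministic end-to-end input bundle (all tables are plain DataFrames)."""

    config: SimConfig
    decay_table: pd.DataFrame
    lu_samples: list[bd.BiodistSample]
    ac_samples: list[bd.BiodistSample]
    lu_uptake: pd.DataFrame
    ac_uptake: pd.DataFrame
    bli: dict[str, list[eff.BLISeries]]
    survival: dict[str, list[eff.SurvivalRecord]]

    def tables(self) -> dict[str, pd.DataFrame]:
        def samples_df(samples):
            return pd.DataFrame(
                [[getattr(s, c) for c in bd.SAMPLE_COLUMNS] for s in samples],
                columns=bd.SAMPLE_COLUMNS,
            )

        def bli_df(series_set):
            rows = [
                (s.mouse_id, s.arm, float(w), float(r))
                for s in series_set
                for w, r in zip(s.weeks, s.radiance)
            ]
            return pd.DataFrame(rows, columns=eff.BLI_COLUMNS)

        def surv_df(records):
            return pd.DataFrame(
                [(r.mouse_id, r.arm, r.time_wk, r.event) for r in records],
                columns=eff.SURVIVAL_COLUMNS,
            )

        out = {
            "decay_data": self.decay_table,
            "biodist_lu177": samples_df(self.lu_samples),
            "biodist_ac225": samples_df(self.ac_samples),
            "uptake_lu177": self.lu_uptake,
            "uptake_ac225": self.ac_uptake,
        }
        for cohort in self.bli:
            out[f"bli_{cohort}"] = bli_df(self.bli[cohort])
            out[f"survival_{cohort}"] = surv_df(self.survival[cohort])
        return out

    def write_csvs(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in self.tables().items():
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        return paths

    def content_hash(self) -> str:
        """SHA-256 over all serialized tables (byte-identical given the seed)."""
        h = hashlib.sha256()
        for name, df in sorted(self.tables().items()):
            h.update(name.encode())
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()


def end_to_end_fixture(config: SimConfig) -> FixtureBundle:
    """Generate the complete deterministic input bundle for integration tests."""
    from .nuclear_data import bundled_decay_data_path

    decay = pd.read_csv(bundled_decay_data_path(), comment="#")
    chains = default_chains()
    lu = simulate_biodistribution(config, "Lu-177")
    ac = simulate_biodistribution(config, "Ac-225")
    lu_up = bd.summarize_uptake(lu, chains["Lu-177"].nuclides["Lu-177"])
    ac_up = bd.summarize_uptake(ac, chains["Ac-225"].nuclides["Ac-225"])
    bli = {}
    survival = {}
    for cohort in config.survival_medians_wk:
        s, r = simulate_trial(config, cohort)
        bli[cohort] = s
        survival[cohort] = r
    return FixtureBundle(
        config=config,
        decay_table=decay,
        lu_samples=lu,
        ac_samples=ac,
        lu_uptake=lu_up,
        ac_uptake=ac_up,
        bli=bli,
        survival=survival,
    )
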