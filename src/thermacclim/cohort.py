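"""Synthetic cohorts reproducing the heat-challenge trial's structure.

The source trial housed 45 finishing pigs (5 treatment groups x 9
animals, 3 replicates) across three consecutive 15-d periods.  Each
period comprised a 3-d prechallenge, a 5-d heat challenge (32 degC) and
a 7-d recovery, with groups rotating between a thermoneutral (T) and a
heated (H) room.  This module regenerates that design stochastically:
daily feed intake and core temperature follow the two-threshold mean
function with a per-animal Gaussian intercept and Gaussian residual
noise, using the published parameter presets, so every downstream stage
(fitting, pipeline summaries) can be exercised without animal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import TrajectoryDataset, VarianceComponents
from .model import AcclimationParams, evaluate, evaluate_sharp

__all__ = [
    "Preset",
    "StudyDesign",
    "StudyConfig",
    "StudyDataset",
    "preset_from_table3",
    "available_presets",
    "simulate_trajectories",
    "simulate_study",
]

METABOLIC_EXPONENT = 0.60

# Published parameter presets: (y0, v1, v2, td1, td2, SEs..., sigma_r2,
# sigma_e2, adj R2, n animals).  The first block is the by-period
# analysis (heat-challenged groups pooled within period); the second is
# the HHH group refitted separately per period to quantify acclimation
# across repeated challenges.  Variances and R2 are shared within a fit
# and repeated on every row of that fit.
_ROW = (
    "group", "period", "y0", "v1", "v2", "td1", "td2",
    "se_y0", "se_v1", "se_v2", "se_td1", "se_td2",
    "sigma_r2", "sigma_e2", "adj_r2", "n_animals",
)

_TABLE3 = {
    # ADFI, g/d/kg^0.60 — by period
    "ADFI/P1":      ("TTH&HHH", "P1", 179, -39.1, 5.34, 0.01, 7.97, 14.6, 0.8, 0.84, 0.35, 1.04, 300, 331, 0.65, 18),
    "ADFI/P2/THT":  ("THT", "P2", 158, -45.6, 6.50, 0.27, 7.26, 10.4, 10.9, 1.14, 0.26, 0.86, 249, 245, 0.67, 9),
    "ADFI/P2/HHH":  ("HHH", "P2", 162, -54.5, 4.72, 0.13, 9.30, 14.5, 14.9, 0.80, 0.28, 1.13, 249, 245, 0.67, 9),
    "ADFI/P3/TTH":  ("TTH", "P3", 165, -36.3, 11.50, 1.03, 5.97, 7.7, 7.1, 2.23, 0.31, 0.24, 295, 304, 0.68, 9),
    "ADFI/P3/HHH":  ("HHH", "P3", 159, -44.3, 5.99, 0.27, 7.76, 11.4, 12.9, 1.62, 0.32, 1.42, 295, 304, 0.68, 9),
    # T_core, degC — by period
    "Tcore/P1":     ("TTH&HHH", "P1", 39.3, 0.48, -0.30, 1.46, 6.30, 0.05, 0.04, 0.02, 0.13, 0.20, 0.038, 0.036, 0.87, 18),
    "Tcore/P2/THT": ("THT", "P2", 39.2, 0.36, -0.39, 2.06, 5.67, 0.12, 0.07, 0.05, 0.30, 0.24, 0.057, 0.100, 0.86, 9),
    "Tcore/P2/HHH": ("HHH", "P2", 39.0, 0.50, -0.34, 1.43, 6.42, 0.12, 0.07, 0.03, 0.20, 0.38, 0.057, 0.100, 0.86, 9),
    "Tcore/P3/TTH": ("TTH", "P3", 39.1, 0.41, -0.25, 1.34, 6.13, 0.11, 0.07, 0.03, 0.27, 0.35, 0.051, 0.087, 0.83, 9),
    "Tcore/P3/HHH": ("HHH", "P3", 38.7, 0.42, -0.29, 1.68, 6.33, 0.12, 0.08, 0.04, 0.35, 0.32, 0.051, 0.087, 0.83, 9),
    # HHH group across periods (repeated-challenge acclimation)
    "ADFI/HHH/P1":  ("HHH", "P1", 177, -39.1, 5.35, 0.00, 7.98, 14.8, 15.4, 0.82, 0.36, 1.08, 324, 324, 0.70, 9),
    "ADFI/HHH/P2":  ("HHH", "P2", 160, -49.8, 5.49, 0.20, 7.99, 9.2, 10.2, 0.78, 0.21, 0.77, 324, 324, 0.70, 9),
    "ADFI/HHH/P3":  ("HHH", "P3", 163, -38.5, 8.63, 0.71, 6.41, 6.1, 7.2, 1.41, 0.26, 0.59, 324, 324, 0.70, 9),
    "Tcore/HHH/P1": ("HHH", "P1", 39.4, 0.48, -0.30, 1.45, 6.30, 0.06, 0.05, 0.02, 0.16, 0.23, 0.054, 0.102, 0.85, 9),
    "Tcore/HHH/P2": ("HHH", "P2", 39.1, 0.44, -0.35, 1.63, 5.98, 0.07, 0.05, 0.03, 0.18, 0.21, 0.054, 0.102, 0.85, 9),
    "Tcore/HHH/P3": ("HHH", "P3", 38.9, 0.42, -0.27, 1.50, 6.25, 0.07, 0.05, 0.02, 0.19, 0.23, 0.054, 0.102, 0.85, 9),
}


@dataclass(frozen=True)
class Preset:
    """One published parameter set: mean function + variance components."""

    label: str
    variable: str  # "ADFI" (g/d/kg^0.60) or "Tcore" (degC)
    group: str
    period: str
    params: AcclimationParams
    variance: VarianceComponents
    se: dict[str, float]
    adj_r2: float
    n_animals: int
    day_grid: tuple[float, ...] = tuple(float(d) for d in range(-1, 11))


def available_presets() -> list[str]:
    return sorted(_TABLE3)


def preset_from_table3(label: str, r1: float = 0.25, r2: float = 0.25) -> Preset:
    """Look up a published parameter preset by label (e.g. ``"Tcore/P1"``)."""
    if label not in _TABLE3:
        raise KeyError(
            f"unknown preset {label!r}; available: {', '.join(available_presets())}"
        )
    row = dict(zip(_ROW, _TABLE3[label]))
    return Preset(
        label=label,
        variable=label.split("/")[0],
        group=row["group"],
        period=row["period"],
        params=AcclimationParams(
            row["y0"], row["v1"], row["v2"], row["td1"], row["td2"], r1=r1, r2=r2
        ),
        variance=VarianceComponents(row["sigma_r2"], row["sigma_e2"]),
        se={k[3:]: row[k] for k in ("se_y0", "se_v1", "se_v2", "se_td1", "se_td2")},
        adj_r2=row["adj_r2"],
        n_animals=row["n_animals"],
    )


def simulate_trajectories(
    preset: Preset,
    n_animals: int | None = None,
    day_grid=None,
    seed: int | None = None,
    animal_prefix: str = "pig",
) -> TrajectoryDataset:
    """Draw one cohort from y_ij = Y(d_j) + b_i + e_ij.

    ``b_i ~ N(0, sigma_r2)`` per animal, ``e_ij ~ N(0, sigma_e2)`` per
    observation; reproducible for a given ``seed`` (mandatory).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    n = int(n_animals if n_animals is not None else preset.n_animals)
    days = np.asarray(day_grid if day_grid is not None else preset.day_grid, dtype=float)
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, np.sqrt(preset.variance.sigma_r2), size=n)
    eps = rng.normal(0.0, np.sqrt(preset.variance.sigma_e2), size=(n, len(days)))
    mu = evaluate(preset.params, days)
    values = mu[None, :] + b[:, None] + eps
    frame = pd.DataFrame(
        {
            "animal_id": np.repeat([f"{animal_prefix}{i:03d}" for i in range(n)], len(days)),
            "group": preset.group,
            "day": np.tile(days, n),
            "value": values.ravel(),
        }
    )
    variable = "ADFI_g_d_kg060" if preset.variable == "ADFI" else "Tcore_C"
    return TrajectoryDataset(frame, variable=variable, period=preset.period)


# room occupancy per group and period (T thermoneutral, H heated)
_ROOMS = {
    "TTT": ("T", "T", "T"),
    "HTT": ("H", "T", "T"),
    "THT": ("T", "H", "T"),
    "TTH": ("T", "T", "H"),
    "HHH": ("H", "H", "H"),
}

# preset labels used for a challenged (H-room) group in each period
_CHALLENGE_PRESETS = {
    ("HTT", "P1"): ("ADFI/P1", "Tcore/P1"),
    ("HHH", "P1"): ("ADFI/P1", "Tcore/P1"),
    ("THT", "P2"): ("ADFI/P2/THT", "Tcore/P2/THT"),
    ("HHH", "P2"): ("ADFI/P2/HHH", "Tcore/P2/HHH"),
    ("TTH", "P3"): ("ADFI/P3/TTH", "Tcore/P3/TTH"),
    ("HHH", "P3"): ("ADFI/P3/HHH", "Tcore/P3/HHH"),
}

# period baseline (prechallenge) ADFI presets, used for thermoneutral levels
_PERIOD_BASELINE = {"P1": "ADFI/P1", "P2": "ADFI/P2/THT", "P3": "ADFI/P3/TTH"}

PERIODS = ("P1", "P2", "P3")
PERIOD_LENGTH = 15  # days; relative day index -3..11, weigh day 12 = next -3
WEIGH_DAYS = (-3, 0, 5)


@dataclass(frozen=True)
class StudyDesign:
    """Group x period room assignment and cohort sizes."""

    rooms: dict[str, tuple[str, str, str]] = field(default_factory=lambda: dict(_ROOMS))
    n_per_group: int = 9
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for g, r in self.rooms.items():
            if len(r) != len(PERIODS) or any(x not in ("T", "H") for x in r):
                raise ValueError(f"invalid room assignment for group {g}: {r}")

    @property
    def groups(self) -> list[str]:
        return list(self.rooms)

    def room(self, group: str, period: str) -> str:
        return self.rooms[group][PERIODS.index(period)]


@dataclass(frozen=True)
class StudyConfig:
    """Tunables of the whole-study generator (units in the field names)."""

    bw0_mean_kg: float = 68.6
    bw0_sd_kg: float = 4.3
    growth_rate_kg_d: float = 1.2
    growth_rate_sd_kg_d: float = 0.08
    bw_weigh_noise_var_kg2: float = 0.5  # gut fill / scale noise at weighing
    tcore_baseline_C: float = 39.0  # thermoneutral daily mean at experiment start
    tcore_drift_C_d: float = -0.01  # slow age-related decline under thermoneutrality
    couple_gain_to_intake: bool = True
    r1: float = 0.25
    r2: float = 0.25


@dataclass
class StudyDataset:
    """Full simulated trial in long format.

    ``records`` columns: animal_id, group, replicate, period, day,
    variable (ADFI_g_d | ADFI_g_d_kg060 | Tcore_C | BW_kg), value.
    """

    records: pd.DataFrame
    animals: pd.DataFrame
    design: StudyDesign
    config: StudyConfig
    seed: int


def _baseline_adfi(period: str, r1: float, r2: float) -> float:
    """Thermoneutral metabolic-scale intake: the prechallenge plateau Y(-1)."""
    p = preset_from_table3(_PERIOD_BASELINE[period], r1=r1, r2=r2).params
    return float(evaluate_sharp(p, -1.0))


def simulate_study(
    design: StudyDesign | None = None,
    config: StudyConfig | None = None,
    seed: int | None = None,
) -> StudyDataset:
    """Simulate the 5-group x 3-period trial day by day.

    Feed intake is generated on the metabolic scale (g/d/kg^0.60) and
    multiplied back by BW^0.60 to emit raw g/d, so the pipeline's
    scaling step is exercised nontrivially.  Challenged group-periods
    follow their published trajectory preset (days clipped to the
    fitted window -1..10); thermoneutral periods sit flat at the
    prechallenge intake level and drift linearly in core temperature.
    Body weight grows linearly, modulated by relative intake, with
    weighing noise added only at weigh days.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    design = design or StudyDesign()
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)

    ref_adfi = preset_from_table3("ADFI/P1", config.r1, config.r2)
    ref_tcore = preset_from_table3("Tcore/P1", config.r1, config.r2)

    rows = []
    animal_rows = []
    rel_days = np.arange(-3, 12)  # 15 feeding days per period
    for group in design.groups:
        for j in range(design.n_per_group):
            replicate = j % design.n_replicates + 1
            aid = f"{group}_{j:02d}"
            bw0 = rng.normal(config.bw0_mean_kg, config.bw0_sd_kg)
            rate = rng.normal(config.growth_rate_kg_d, config.growth_rate_sd_kg_d)
            b_feed = rng.normal(0.0, np.sqrt(ref_adfi.variance.sigma_r2))
            b_tcore = rng.normal(0.0, np.sqrt(ref_tcore.variance.sigma_r2))
            animal_rows.append((aid, group, replicate, bw0, rate, b_feed, b_tcore))

            bw = bw0  # true BW at experiment day 0 (= P1 day -3)
            for pi, period in enumerate(PERIODS):
                challenged = design.room(group, period) == "H"
                labels = _CHALLENGE_PRESETS.get((group, period))
                adfi_base = _baseline_adfi(period, config.r1, config.r2)
                if challenged:
                    pa = preset_from_table3(labels[0], config.r1, config.r2)
                    pt = preset_from_table3(labels[1], config.r1, config.r2)
                for d in rel_days:
                    t_exp = pi * PERIOD_LENGTH + (d + 3)
                    dc = float(np.clip(d, -1, 10))
                    if challenged:
                        mu_adfi = evaluate(pa.params, dc)
                        mu_tcore = evaluate(pt.params, dc)
                        se_adfi = np.sqrt(pa.variance.sigma_e2)
                        se_tcore = np.sqrt(pt.variance.sigma_e2)
                    else:
                        mu_adfi = adfi_base
                        mu_tcore = config.tcore_baseline_C + config.tcore_drift_C_d * t_exp
                        se_adfi = np.sqrt(ref_adfi.variance.sigma_e2)
                        se_tcore = np.sqrt(ref_tcore.variance.sigma_e2)
                    adfi_met = mu_adfi + b_feed + rng.normal(0.0, se_adfi)
                    tcore = mu_tcore + b_tcore + rng.normal(0.0, se_tcore)
                    if d in WEIGH_DAYS:
                        noise = rng.normal(0.0, np.sqrt(config.bw_weigh_noise_var_kg2))
                        rows.append((aid, group, replicate, period, float(d), "BW_kg", bw + noise))
                        if d == -3 and pi > 0:
                            # same weighing closes the previous period (its day 12)
                            rows.append(
                                (aid, group, replicate, PERIODS[pi - 1], 12.0, "BW_kg", bw + noise)
                            )
                    feed_g_d = adfi_met * bw**METABOLIC_EXPONENT
                    rows.append((aid, group, replicate, period, float(d), "ADFI_g_d_kg060", adfi_met))
                    rows.append((aid, group, replicate, period, float(d), "ADFI_g_d", feed_g_d))
                    rows.append((aid, group, replicate, period, float(d), "Tcore_C", tcore))
                    gain = rate
                    if config.couple_gain_to_intake:
                        gain = rate * mu_adfi / adfi_base
                    bw += gain
            noise = rng.normal(0.0, np.sqrt(config.bw_weigh_noise_var_kg2))
            rows.append((aid, group, replicate, "P3", 12.0, "BW_kg", bw + noise))

    records = pd.DataFrame(
        rows,
        columns=["animal_id", "group", "replicate", "period", "day", "variable", "value"],
    )
    animals = pd.DataFrame(
        animal_rows,
        columns=["animal_id", "group", "replicate", "bw0_kg", "growth_rate_kg_d",
                 "b_feed", "b_tcore"],
    )
    return StudyDataset(records, animals, design, config, int(seed))
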