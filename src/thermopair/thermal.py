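"""Estimation of insect thermal requirements from rearing experiments.

Over the ecologically relevant temperature range the developmental rate of
insects and mites (the reciprocal of development time in days) increases
approximately linearly with temperature,

    rate(T) = a + b*T = (T - LDT) / SET,

so the x-intercept of the fitted line is the lower developmental threshold
LDT = -a/b (°C, the temperature at which development ceases) and the
reciprocal slope is the sum of effective temperatures SET = 1/b (day-degrees
D° above LDT needed to complete the stage).

The module fits this line per species/stage/population by ordinary least
squares, converts coefficients to (LDT, SET) with delta-method standard
errors, averages estimates across independently studied populations after a
robust (median/MAD) outlier screen, and selects a single per-species value
with egg-to-adult development preferred over single stages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from statistics import mean
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import EstimationError, ValidationError

logger = logging.getLogger(__name__)

#: Recognised developmental stages; free-form stages use the ``other:<label>`` form.
STAGES = frozenset({"egg", "larva", "pupa", "nymph", "egg_to_adult"})

#: Consistency factor making the MAD an unbiased sigma estimate under normality.
MAD_SCALE = 1.4826


def _check_stage(stage: str) -> str:
    if stage in STAGES or stage.startswith("other:"):
        return stage
    raise ValidationError(
        f"unknown stage {stage!r}; expected one of {sorted(STAGES)} or 'other:<label>'"
    )


@dataclass(frozen=True)
class DevelopmentObservation:
    """One laboratory rearing record at constant temperature."""

    species_id: str
    population_id: str
    study_id: str
    stage: str
    temperature: float  # °C
    development_time: float  # days

    def __post_init__(self) -> None:
        _check_stage(self.stage)
        if not math.isfinite(self.temperature):
            raise ValidationError(f"{self.species_id}: temperature must be finite")
        if not (math.isfinite(self.development_time) and self.development_time > 0):
            raise ValidationError(
                f"{self.species_id}: development_time must be positive and finite, "
                f"got {self.development_time}"
            )

    @property
    def rate(self) -> float:
        """Developmental rate in day^-1."""
        return 1.0 / self.development_time


@dataclass(frozen=True)
class RateRegression:
    """OLS fit of developmental rate on temperature for one species/stage."""

    species_id: str
    stage: str
    intercept_a: float  # day^-1
    slope_b: float  # day^-1 °C^-1
    se_a: float
    se_b: float
    cov_ab: float
    r_squared: float
    n_points: int
    temperature_range: tuple[float, float]


@dataclass(frozen=True)
class ThermalRequirement:
    """Per-species (or per-population) lower threshold and thermal sum."""

    species_id: str
    stage: str
    ldt: float  # °C
    set_dd: float  # day-degrees above LDT
    se_ldt: float | None = None
    se_set: float | None = None
    n_sources: int = 1
    source: str = "single_study"  # or "population_mean"

    def __post_init__(self) -> None:
        _check_stage(self.stage)
        if not self.set_dd > 0:
            raise ValidationError(
                f"{self.species_id}: SET must be positive, got {self.set_dd}"
            )

    def rate_at(self, temperature: float) -> float:
        """Linear development rate at ``temperature``; 0 at or below the LDT."""
        return max(0.0, (temperature - self.ldt) / self.set_dd)

    def development_time_at(self, temperature: float) -> float:
        """Predicted development time (days) at a temperature above the LDT."""
        if temperature <= self.ldt:
            raise ValidationError(
                f"no development at {temperature} °C (LDT = {self.ldt} °C)"
            )
        return self.set_dd / (temperature - self.ldt)


def fit_rate_regression(
    observations: Sequence[DevelopmentObservation],
    *,
    min_temperatures: int = 3,
    on_means: bool = False,
) -> RateRegression:
    """Fit rate = a + b*T by OLS for a single species and stage.

    Parameters
    ----------
    observations
        Rearing records sharing ``species_id`` and ``stage``.
    min_temperatures
        Minimum number of distinct rearing temperatures; two points would fit
        any line exactly, so the default demands three.
    on_means
        Regress on per-temperature mean rates instead of individual replicate
        rates, for reproducing studies that published treatment means only.
    """
    if not observations:
        raise EstimationError("no observations supplied")
    species = {o.species_id for o in observations}
    stages = {o.stage for o in observations}
    if len(species) != 1 or len(stages) != 1:
        raise ValidationError(
            f"observations mix species/stages: {sorted(species)} / {sorted(stages)}"
        )
    (species_id,), (stage,) = species, stages

    temps = np.array([o.temperature for o in observations], dtype=float)
    rates = np.array([o.rate for o in observations], dtype=float)
    n_distinct = np.unique(temps).size
    if n_distinct < min_temperatures:
        raise EstimationError(
            f"{species_id}/{stage}: only {n_distinct} distinct temperatures "
            f"(need ≥ {min_temperatures})"
        )
    if on_means:
        frame = pd.DataFrame({"t": temps, "r": rates}).groupby("t", as_index=False).mean()
        temps, rates = frame["t"].to_numpy(), frame["r"].to_numpy()

    X = sm.add_constant(temps)
    res = sm.OLS(rates, X).fit()
    cov = res.cov_params()
    return RateRegression(
        species_id=species_id,
        stage=stage,
        intercept_a=float(res.params[0]),
        slope_b=float(res.params[1]),
        se_a=float(res.bse[0]),
        se_b=float(res.bse[1]),
        cov_ab=float(np.asarray(cov)[0, 1]),
        r_squared=float(np.clip(res.rsquared, 0.0, 1.0)),
        n_points=int(temps.size),
        temperature_range=(float(temps.min()), float(temps.max())),
    )


def derive_thermal_constants(fit: RateRegression) -> ThermalRequirement:
    """Convert a rate regression into (LDT, SET) with delta-method SEs.

    LDT = -a/b and SET = 1/b. First-order propagation gives

        Var(LDT) = Var(a)/b² + a² Var(b)/b⁴ - 2 a Cov(a,b)/b³
        Var(SET) = Var(b)/b⁴
    """
    a, b = fit.intercept_a, fit.slope_b
    if b <= 0:
        raise EstimationError(
            f"{fit.species_id}/{fit.stage}: no positive thermal response "
            f"(slope = {b:g})"
        )
    var_a, var_b, cov = fit.se_a**2, fit.se_b**2, fit.cov_ab
    var_ldt = var_a / b**2 + a**2 * var_b / b**4 - 2 * a * cov / b**3
    var_set = var_b / b**4
    return ThermalRequirement(
        species_id=fit.species_id,
        stage=fit.stage,
        ldt=-a / b,
        set_dd=1.0 / b,
        se_ldt=math.sqrt(max(var_ldt, 0.0)),
        se_set=math.sqrt(max(var_set, 0.0)),
        n_sources=1,
        source="single_study",
    )


def _mad_mask(values: np.ndarray, k: float) -> np.ndarray:
    """True for values within k scaled-MADs of the median."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return np.abs(values - med) <= k * MAD_SCALE * mad


def aggregate_populations(
    estimates: Sequence[ThermalRequirement],
    outlier_k: float = 3.0,
    *,
    joint: bool = False,
) -> ThermalRequirement:
    """Average per-population estimates for one species/stage.

    Estimates whose LDT or SET deviates from the cross-population median by
    more than ``outlier_k`` scaled median absolute deviations are discarded
    (and logged) before taking the unweighted arithmetic mean — a quantified
    stand-in for manual screening of doubtful literature values.  With
    ``joint=True`` a population flagged on either trait is dropped entirely;
    the default screens LDT and SET independently.
    """
    if not estimates:
        raise EstimationError("no estimates to aggregate")
    if outlier_k <= 0:
        raise ValidationError("outlier_k must be positive")
    species = {e.species_id for e in estimates}
    stages = {e.stage for e in estimates}
    if len(species) != 1 or len(stages) != 1:
        raise ValidationError("estimates mix species or stages")
    if len(estimates) == 1:
        return estimates[0]

    ldts = np.array([e.ldt for e in estimates])
    sets = np.array([e.set_dd for e in estimates])
    keep_ldt = _mad_mask(ldts, outlier_k)
    keep_set = _mad_mask(sets, outlier_k)
    for e, ok_l, ok_s in zip(estimates, keep_ldt, keep_set):
        if not (ok_l and ok_s):
            logger.info(
                "outlier discarded for %s/%s: ldt=%.3g set=%.3g (ldt_ok=%s set_ok=%s)",
                e.species_id, e.stage, e.ldt, e.set_dd, ok_l, ok_s,
            )
    if joint:
        keep_ldt = keep_set = keep_ldt & keep_set
    assert keep_ldt.any() and keep_set.any(), "median-based screen cannot empty the set"

    ldt_keep = ldts[keep_ldt]
    set_keep = sets[keep_set]
    # with per-trait screening the survivor sets can differ; report the
    # conservative (smaller) count
    n = int(min(ldt_keep.size, set_keep.size))
    return ThermalRequirement(
        species_id=next(iter(species)),
        stage=next(iter(stages)),
        ldt=float(ldt_keep.mean()),
        set_dd=float(set_keep.mean()),
        se_ldt=float(ldt_keep.std(ddof=1) / math.sqrt(ldt_keep.size))
        if ldt_keep.size > 1 else None,
        se_set=float(set_keep.std(ddof=1) / math.sqrt(set_keep.size))
        if set_keep.size > 1 else None,
        n_sources=n,
        source="population_mean",
    )


def select_stage_values(estimates: Sequence[ThermalRequirement]) -> ThermalRequirement:
    """Pick one per-species value from stage-specific estimates.

    SET: total (egg-to-adult) development is preferred; with only one stage
    available that stage is used; several partial stages without egg-to-adult
    would require an explicit choice and raise.  LDT: egg-to-adult preferred,
    otherwise the mean of stage-specific LDTs — all stages of a population
    are assumed to share the same threshold.
    """
    if not estimates:
        raise EstimationError("no stage estimates supplied")
    species = {e.species_id for e in estimates}
    if len(species) != 1:
        raise ValidationError("estimates mix species")
    by_stage = {e.stage: e for e in estimates}
    if len(by_stage) != len(estimates):
        raise ValidationError("duplicate stage estimates; aggregate populations first")

    if "egg_to_adult" in by_stage:
        return by_stage["egg_to_adult"]
    if len(estimates) == 1:
        return estimates[0]
    # Several partial stages: LDTs average, but stage SETs are not additive
    # without knowing stage coverage — demand an explicit choice for SET.
    raise EstimationError(
        f"{next(iter(species))}: multiple partial stages "
        f"({sorted(by_stage)}) without egg_to_adult; select a stage explicitly "
        "or use stage_ldt_mean() for the threshold"
    )


def stage_ldt_mean(estimates: Sequence[ThermalRequirement]) -> float:
    """Mean LDT across stage-specific estimates of one species."""
    if not estimates:
        raise EstimationError("no stage estimates supplied")
    return mean(e.ldt for e in estimates)


def estimate_thermal_requirements(
    observations: Iterable[DevelopmentObservation],
    *,
    min_temperatures: int = 3,
    outlier_k: float = 3.0,
    on_means: bool = False,
) -> list[ThermalRequirement]:
    """End-to-end estimation: fit per population/study, aggregate, select stage.

    Species whose data never support a fit (too few temperatures, or no
    positive thermal response) are logged and omitted, mirroring the
    exclusion of unusable literature records.
    """
    frame_keys: dict[tuple, list[DevelopmentObservation]] = {}
    for obs in observations:
        key = (obs.species_id, obs.stage, obs.population_id, obs.study_id)
        frame_keys.setdefault(key, []).append(obs)

    per_species_stage: dict[tuple[str, str], list[ThermalRequirement]] = {}
    for (species_id, stage, _pop, _study), group in frame_keys.items():
        try:
            fit = fit_rate_regression(
                group, min_temperatures=min_temperatures, on_means=on_means
            )
            tr = derive_thermal_constants(fit)
        except (EstimationError, ValidationError) as exc:
            logger.warning("skipping %s/%s: %s", species_id, stage, exc)
            continue
        per_species_stage.setdefault((species_id, stage), []).append(tr)

    per_species: dict[str, list[ThermalRequirement]] = {}
    for (species_id, stage), ests in per_species_stage.items():
        agg = aggregate_populations(ests, outlier_k=outlier_k)
        per_species.setdefault(species_id, []).append(agg)

    out: list[ThermalRequirement] = []
    for species_id, stage_ests in sorted(per_species.items()):
        try:
            chosen = select_stage_values(stage_ests)
        except EstimationError:
            # Several partial stages: average the LDTs (shared-threshold
            # assumption) and keep the SET of the longest-duration stage,
            # flagged via the stage label.
            ldt = stage_ldt_mean(stage_ests)
            longest = max(stage_ests, key=lambda e: e.set_dd)
            chosen = replace(longest, ldt=ldt)
            logger.info(
                "%s: no egg_to_adult stage; LDT averaged over %d stages, "
                "SET taken from %s", species_id, len(stage_ests), longest.stage,
            )
        out.append(chosen)
    return out
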