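"""Zero-order ¹⁵N pool-dilution estimation and per-ion plant N uptake.

The model
---------
A labelled soil N pool (NH₄⁺ or NO₃⁻) of size ``M`` (µg N g⁻¹ dry soil) and
atom% excess ``a`` receives unlabelled (background-abundance) influx at a
constant gross production rate ``f`` and loses N at a constant gross
consumption rate ``c``, both µg N g⁻¹ d⁻¹ (zero-order kinetics: fluxes do
not depend on pool size). Then

    M(τ) = m₀ + (f − c)·τ
    a(τ) = a₀ · (M(τ)/m₀)^(−f/(f−c))          (a₀·e^(−f·τ/m₀) when f = c)

because production dilutes the pool while consumption removes N at the
pool's current enrichment. Inverting the two-point observation
(m₀, a₀) at the first harvest and (m_t, a_t) at the second gives

    f = (m₀ − m_t)/Δt · ln(a₀/a_t) / ln(m₀/m_t)     (m_t ≠ m₀)
    f = m₀/Δt · ln(a₀/a_t)                          (m_t → m₀ limit)
    c = f − (m_t − m₀)/Δt

Plant uptake of *total* N (not just tracer) from the labelled pool follows
the pool-dilution uptake procedure: the gain in plant ¹⁵N excess between the
two destructive harvests, divided by the time-weighted mean atom% excess of
the source pool over the same window, ā = (1/Δt)∫a(τ)dτ, evaluated in
closed form from the fitted (f, c).

Estimates are never clamped: negative rates or uptakes are returned with
diagnostic flags so that downstream statistics see unbiased values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .data_model import LABEL_TO_ION, PairMap
from .errors import EstimationError, ValidationError
from .isotope import N15_NATURAL_ABUNDANCE

_ION_TO_SOIL_COL = {"NH4": "soil_nh4_ug_g", "NO3": "soil_no3_ug_g"}


@dataclass(frozen=True)
class PoolObservation:
    """Two-point observation of one labelled soil pool.

    Attributes
    ----------
    m0, a0 : float
        Pool size (µg N g⁻¹ dry soil) and atom% excess at the first harvest.
    mt, at : float
        The same quantities at the second harvest.
    dt : float
        Days between the harvests.
    """

    m0: float
    a0: float
    mt: float
    at: float
    dt: float

    def __post_init__(self) -> None:
        if self.m0 <= 0 or self.mt <= 0:
            raise ValidationError(f"pool sizes must be > 0 (m0={self.m0}, "
                                  f"mt={self.mt})")
        if self.dt <= 0:
            raise ValidationError(f"dt={self.dt} must be > 0")


@dataclass
class GrossRateEstimate:
    """Gross production/consumption and mean pool enrichment for one pool."""

    production: float
    consumption: float
    mean_excess: float
    flags: list[str] = field(default_factory=list)


@dataclass
class UptakeEstimate:
    """Per-ion plant N uptake for one harvest pair and species."""

    ion: str
    n_uptake_total: float          # mg N per plant over the window
    per_capita_rate: float         # mg N g⁻¹ plant dry mass d⁻¹
    plant_excess_t1: float         # mg ¹⁵N excess at t₁
    plant_excess_t14: float        # mg ¹⁵N excess at t₁₄
    flags: list[str] = field(default_factory=list)


def _log1p_over_x(x: float) -> float:
    """log(1+x)/x, stable through x = 0."""
    if abs(x) < 1e-8:
        return 1.0 - x / 2.0 + x * x / 3.0
    return math.log1p(x) / x


def gross_rates(obs: PoolObservation) -> GrossRateEstimate:
    """Estimate gross production and consumption from a two-point observation.

    Returns a :class:`GrossRateEstimate` whose ``mean_excess`` is the
    closed-form time-weighted mean enrichment (see :func:`mean_pool_excess`).
    Negative production (enrichment rose between harvests) is flagged, not
    clamped. Raises :class:`EstimationError` for unlabelled or completely
    diluted pools (a₀ ≤ 0 or a_t ≤ 0) where the logarithms are undefined.
    """
    if obs.a0 <= 0:
        raise EstimationError(f"pool not labelled: a0={obs.a0} <= 0")
    if obs.at <= 0:
        raise EstimationError(f"complete dilution: at={obs.at} <= 0")

    flags: list[str] = []
    dilution = math.log(obs.a0 / obs.at)
    if abs(obs.mt - obs.m0) <= 1e-9 * obs.m0:
        f = obs.m0 / obs.dt * dilution
        flags.append("constant_pool_limit")
    else:
        f = ((obs.m0 - obs.mt) / obs.dt) * dilution / math.log(obs.m0 / obs.mt)
    c = f - (obs.mt - obs.m0) / obs.dt
    if obs.mt > obs.m0:
        flags.append("pool_grew")
    elif obs.mt < obs.m0:
        flags.append("pool_shrank")
    if f < 0:
        flags.append("negative_production")
    est = GrossRateEstimate(production=f, consumption=c, mean_excess=math.nan,
                            flags=flags)
    est.mean_excess = mean_pool_excess(obs, est)
    return est


def mean_pool_excess(obs: PoolObservation, rates: GrossRateEstimate) -> float:
    """Time-weighted mean atom% excess ā over [0, Δt] under the fitted model.

    With k = (f−c)/m₀ and p = f/(f−c), the closed form

        ā = a₀·[(1 + kΔt)^(1−p) − 1] / (kΔt·(1−p))

    is evaluated through the algebraically equivalent, uniformly stable
    expression ā = a₀·expm1(−q·r)/(−q) with q = cΔt/m₀ and
    r = log1p(kΔt)/(kΔt), which passes continuously through the f = c,
    c = 0 and f = 0 limits. Raises :class:`EstimationError` if the modelled
    pool is exhausted within the window.
    """
    return _mean_excess_closed_form(rates.production, rates.consumption,
                                    obs.m0, obs.a0, obs.dt)


def _mean_excess_closed_form(f: float, c: float, m0: float, a0: float,
                             dt: float) -> float:
    kdt = (f - c) * dt / m0
    if 1.0 + kdt <= 0.0:
        raise EstimationError(
            f"modelled pool crosses zero within the window (f={f}, c={c}, "
            f"m0={m0}, dt={dt})")
    r = _log1p_over_x(kdt)
    q = c * dt / m0
    if abs(q) < 1e-10:
        # expm1(-q r)/(-q) -> r as q -> 0
        return a0 * r * (1.0 - q * r / 2.0)
    return a0 * math.expm1(-q * r) / (-q)


def pool_excess_at(f: float, c: float, m0: float, a0: float, t: float) -> float:
    """Atom% excess a(t) of the modelled pool, stable through f = c."""
    kt = (f - c) * t / m0
    if 1.0 + kt <= 0.0:
        raise EstimationError("pool size non-positive at requested time")
    return a0 * math.exp(-(f * t / m0) * _log1p_over_x(kt))


def excess_integral(f: float, c: float, m0: float, a0: float,
                    t0: float, t1: float) -> float:
    """∫ₜ₀^ₜ₁ a(τ) dτ for the zero-order model started at (m₀, a₀) at τ=0.

    Advances the model state to t₀ analytically, then applies the closed-form
    mean over [t₀, t₁]. Used by the forward simulator, so that noiseless
    simulation and estimation share the same exact kinetics.
    """
    if t1 < t0:
        raise ValidationError(f"t1={t1} < t0={t0}")
    if t1 == t0:
        return 0.0
    m_t0 = m0 + (f - c) * t0
    if m_t0 <= 0:
        raise EstimationError("pool size non-positive at interval start")
    a_t0 = pool_excess_at(f, c, m0, a0, t0)
    return _mean_excess_closed_form(f, c, m_t0, a_t0, t1 - t0) * (t1 - t0)


def plant_excess_mg(plant_n_mg: float, plant_atom_pct: float,
                    background: float = N15_NATURAL_ABUNDANCE) -> float:
    """Plant ¹⁵N excess in mg: N content × atom% excess / 100."""
    return plant_n_mg * (plant_atom_pct - background) / 100.0


def plant_uptake(n_t1_mg: float, atom_pct_t1: float,
                 n_t14_mg: float, atom_pct_t14: float,
                 mean_excess: float, dt: float,
                 biomass_t1_g: float, biomass_t14_g: float | None = None,
                 ion: str = "NH4", norm: str = "t1",
                 background: float = N15_NATURAL_ABUNDANCE) -> UptakeEstimate:
    """Uptake of total N from the labelled pool between the two harvests.

    The between-harvest increment of plant ¹⁵N excess is divided by the mean
    source-pool excess ā (as a fraction), so that uptake measures N, not
    merely tracer. The per-capita daily rate divides by Δt and by the
    biomass normaliser: t₁ biomass of the pair (default) or the geometric
    mean of the two harvest biomasses (``norm="geometric"``).
    """
    if mean_excess <= 0:
        raise ValidationError(f"mean_excess={mean_excess} must be > 0")
    if dt <= 0:
        raise ValidationError(f"dt={dt} must be > 0")
    e1 = plant_excess_mg(n_t1_mg, atom_pct_t1, background)
    e14 = plant_excess_mg(n_t14_mg, atom_pct_t14, background)
    total = (e14 - e1) / (mean_excess / 100.0)
    flags: list[str] = []
    if e14 < e1:
        flags.append("negative_uptake")
    if norm == "geometric":
        if biomass_t14_g is None or biomass_t14_g <= 0 or biomass_t1_g <= 0:
            raise ValidationError("geometric normalisation needs positive "
                                  "biomass at both harvests")
        denom = math.sqrt(biomass_t1_g * biomass_t14_g)
    elif norm == "t1":
        if biomass_t1_g <= 0:
            raise ValidationError(f"biomass_t1_g={biomass_t1_g} must be > 0")
        denom = biomass_t1_g
    else:
        raise ValidationError(f"unknown biomass normalisation {norm!r}")
    return UptakeEstimate(ion=ion, n_uptake_total=total,
                          per_capita_rate=total / (denom * dt),
                          plant_excess_t1=e1, plant_excess_t14=e14,
                          flags=flags)


@dataclass(frozen=True)
class PoolDilutionConfig:
    """Options for the rate/uptake pipelines.

    Attributes
    ----------
    background : float
        Natural-abundance reference, atom%.
    norm : str
        Biomass normaliser for per-capita rates: ``"t1"`` or ``"geometric"``.
    window : str
        Window for the mean source enrichment: ``"between_harvests"``
        (default; matches the destructive t₁/t₁₄ differencing) or
        ``"from_labelling"`` (extrapolates the fitted model back to the
        labelling time at τ = t₁ − harvest_day(t₁) ... i.e. day 0).
    """

    background: float = N15_NATURAL_ABUNDANCE
    norm: str = "t1"
    window: str = "between_harvests"


def _pot_level(df: pd.DataFrame) -> pd.DataFrame:
    return df.drop_duplicates("pot_id").set_index("pot_id")


def pool_observation_from_pair(df_pots: pd.DataFrame, t1_pot: str,
                               t14_pot: str, label: str,
                               background: float = N15_NATURAL_ABUNDANCE
                               ) -> PoolObservation:
    """Assemble the labelled pool's (m₀, a₀, m_t, a_t, Δt) from a pot pair."""
    ion = LABEL_TO_ION[label]
    col = _ION_TO_SOIL_COL[ion]
    r1, r14 = df_pots.loc[t1_pot], df_pots.loc[t14_pot]
    vals = [r1[col], r1["soil_pool_atom_pct"], r14[col],
            r14["soil_pool_atom_pct"], r1["harvest_day"], r14["harvest_day"]]
    if any(pd.isna(v) for v in vals):
        raise EstimationError(
            f"missing soil measurement in pair ({t1_pot}, {t14_pot})")
    return PoolObservation(
        m0=float(r1[col]), a0=float(r1["soil_pool_atom_pct"]) - background,
        mt=float(r14[col]), at=float(r14["soil_pool_atom_pct"]) - background,
        dt=float(r14["harvest_day"]) - float(r1["harvest_day"]))


def rates_pipeline(df: pd.DataFrame, pair_map: PairMap,
                   config: PoolDilutionConfig | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gross-rate estimates for every resolvable harvest pair.

    Returns ``(rates, failures)``: one row per harvest pair with the pool
    observation, fitted rates, mean enrichment and flags; failures lists
    pairs that could not be estimated, with reasons (never silently
    dropped).
    """
    config = config or PoolDilutionConfig()
    pots = _pot_level(df)
    rows, failures = [], []
    for cell, hp in sorted(pair_map.harvest_pairs.items()):
        site, block, rep, fert, comb, label = cell
        try:
            obs = pool_observation_from_pair(pots, hp.t1_pot_id, hp.t14_pot_id,
                                             label, config.background)
            est = gross_rates(obs)
        except (EstimationError, ValidationError) as exc:
            failures.append({"site": site, "block": block, "replicate": rep,
                             "fertiliser": fert, "combination": comb,
                             "label": label, "reason": str(exc)})
            continue
        rows.append({
            "site": site, "block": block, "replicate": rep,
            "fertiliser": fert, "combination": comb, "label": label,
            "ion": LABEL_TO_ION[label], "m0": obs.m0, "a0": obs.a0,
            "mt": obs.mt, "at": obs.at, "dt": obs.dt,
            "production": est.production, "consumption": est.consumption,
            "mean_excess": est.mean_excess, "flags": ";".join(est.flags),
        })
    return pd.DataFrame(rows), pd.DataFrame(failures)


def uptake_pipeline(df: pd.DataFrame, pair_map: PairMap,
                    config: PoolDilutionConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ion plant N uptake for every harvest pair and species.

    NH₄⁺ uptake comes from ¹⁵NH₄NO₃-labelled pairs and NO₃⁻ uptake from
    NH₄¹⁵NO₃-labelled pairs. Pairs whose aboveground biomass did not
    increase between harvests are excluded (the pool-dilution uptake
    procedure requires growth over the window); every exclusion or failure
    is recorded in the ledger returned alongside the estimates.
    """
    config = config or PoolDilutionConfig()
    pots = _pot_level(df)
    by_pot = {pid: grp.set_index("species")
              for pid, grp in df.groupby("pot_id", sort=False)}
    rows, ledger = [], []

    def _exclude(cell, species, reason):
        site, block, rep, fert, comb, label = cell
        ledger.append({"site": site, "block": block, "replicate": rep,
                       "fertiliser": fert, "combination": comb, "label": label,
                       "species": species, "reason": reason})

    for cell, hp in sorted(pair_map.harvest_pairs.items()):
        site, block, rep, fert, comb, label = cell
        ion = LABEL_TO_ION[label]
        try:
            obs = pool_observation_from_pair(pots, hp.t1_pot_id, hp.t14_pot_id,
                                             label, config.background)
            est = gross_rates(obs)
        except (EstimationError, ValidationError) as exc:
            _exclude(cell, "*", f"pool estimation failed: {exc}")
            continue
        if config.window == "from_labelling":
            t1_day = float(pots.loc[hp.t1_pot_id, "harvest_day"])
            horizon = t1_day + obs.dt
            m_at_label = obs.m0 - (est.production - est.consumption) * t1_day
            if m_at_label <= 0:
                _exclude(cell, "*", "pool extrapolates non-positive at labelling")
                continue
            a_at_label = obs.a0 / pool_excess_at(
                est.production, est.consumption, m_at_label, 1.0, t1_day)
            mean_excess = excess_integral(est.production, est.consumption,
                                          m_at_label, a_at_label,
                                          0.0, horizon) / horizon
        else:
            mean_excess = est.mean_excess
        if mean_excess <= 0:
            _exclude(cell, "*", "non-positive mean pool excess")
            continue

        t1_plants = by_pot[hp.t1_pot_id]
        t14_plants = by_pot[hp.t14_pot_id]
        for species in t1_plants.index:
            if species not in t14_plants.index:
                _exclude(cell, species, "species missing at t14")
                continue
            p1, p14 = t1_plants.loc[species], t14_plants.loc[species]
            needed = [p1["plant_biomass_g"], p14["plant_biomass_g"],
                      p1["plant_n_mg"], p14["plant_n_mg"],
                      p1["plant_atom_pct"], p14["plant_atom_pct"]]
            if any(pd.isna(v) for v in needed):
                _exclude(cell, species, "missing plant measurement")
                continue
            w1, w14 = float(p1["plant_biomass_g"]), float(p14["plant_biomass_g"])
            if w14 <= w1:
                _exclude(cell, species,
                         f"biomass did not increase (t1={w1:.4g} g, "
                         f"t14={w14:.4g} g)")
                continue
            try:
                upt = plant_uptake(
                    float(p1["plant_n_mg"]), float(p1["plant_atom_pct"]),
                    float(p14["plant_n_mg"]), float(p14["plant_atom_pct"]),
                    mean_excess, obs.dt, w1, w14, ion=ion, norm=config.norm,
                    background=config.background)
            except ValidationError as exc:
                _exclude(cell, species, str(exc))
                continue
            rows.append({
                "site": site, "block": block, "replicate": rep,
                "fertiliser": fert, "combination": comb, "label": label,
                "ion": ion, "species": species,
                "production": est.production, "consumption": est.consumption,
                "mean_excess": mean_excess,
                "plant_excess_t1_mg": upt.plant_excess_t1,
                "plant_excess_t14_mg": upt.plant_excess_t14,
                "n_uptake_total_mg": upt.n_uptake_total,
                "per_capita_rate_mg_g_d": upt.per_capita_rate,
                "biomass_t1_g": w1, "biomass_t14_g": w14, "dt": obs.dt,
                "flags": ";".join(est.flags + upt.flags),
            })
    return pd.DataFrame(rows), pd.DataFrame(
        ledger, columns=["site", "block", "replicate", "fertiliser",
                         "combination", "label", "species", "reason"])
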