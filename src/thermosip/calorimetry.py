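"""Calorimetric energetics of soil microbial glucose metabolism.

Converts isothermal-calorimeter power traces (uW per g dry soil) into
cumulative heats and computes the thermodynamic / metabolic indices used to
characterise community-level carbon use:

* thermodynamic efficiency index
  ``eta_eff = 1 - (Q_glucose - Q_control) / dH_glucose`` — the fraction of the
  energy added as glucose that is *not* dissipated as extra heat;
* thermal yield ``eta_co2 = dH_CO * n(CO2-C from glucose) / dH_glucose`` and
  its complement ``eta_soil = 1 - eta_co2`` — the split of glucose energy
  dissipated through oxidation to CO2 vs retained in the soil;
* calorespirometric ratio (mJ heat per ug CO2-C respired);
* metabolic quotient qCO2 (basal respiration per unit microbial biomass C).

Indices are reported unclamped: a negative efficiency is diagnostic (more heat
released than the substrate contained) and is preserved with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import simpson


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants of the energy bookkeeping.

    dH_glucose : heat content of the added glucose per g soil (J g-1); the
        default 18.05 corresponds to 500 ug glucose-C g-1 soil.
    dH_CO : heat released per mole of glucose-derived CO2-C (J mol-1 C);
        default 467200 = glucose combustion enthalpy 2,803,000 J mol-1 / 6 C.
    molar_mass_c : g mol-1.
    """

    dH_glucose: float = 18.05
    dH_CO: float = 467_200.0
    molar_mass_c: float = 12.011

    def __post_init__(self) -> None:
        if min(self.dH_glucose, self.dH_CO, self.molar_mass_c) <= 0:
            raise ValueError("all thermodynamic constants must be strictly positive")


@dataclass
class HeatSeries:
    """A power-vs-time record for one ampoule.

    time_h must be strictly increasing; power_uw is heat flow in uW per g dry
    soil. ``metadata`` carries management/crop/replicate/amendment labels.
    """

    unit_id: str
    time_h: np.ndarray
    power_uw: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.power_uw = np.asarray(self.power_uw, dtype=float)
        if self.time_h.shape != self.power_uw.shape or self.time_h.ndim != 1:
            raise ValueError("time and power must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError(f"{self.unit_id}: time must be strictly increasing")


def cumulative_heat(
    series: HeatSeries,
    window: tuple[float, float] | None = None,
    exclusion_h: float = 0.0,
    rule: str = "trapezoid",
) -> float:
    """Integrate power over a time window to cumulative heat (J g-1 soil).

    Parameters
    ----------
    window : (t0, t1) in hours; defaults to the full record.
    exclusion_h : length of the initial equilibration segment to discard;
        the excluded span is back-filled with the first retained power value
        (constant extrapolation), so the window length is unchanged.
    rule : "trapezoid" (default) or "simpson".

    Returns cumulative heat in J per g dry soil; negative integrals are
    physically dubious and raise a warning, not an error.
    """
    t = series.time_h
    p = series.power_uw
    if window is None:
        window = (float(t[0]), float(t[-1]))
    t0, t1 = map(float, window)
    if not (t[0] - 1e-9 <= t0 < t1 <= t[-1] + 1e-9):
        raise ValueError(f"window [{t0}, {t1}] outside recorded range [{t[0]}, {t[-1]}]")
    if exclusion_h < 0:
        raise ValueError("exclusion_h must be non-negative")
    mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    if mask.sum() < 2:
        raise ValueError("window must contain at least two samples")
    tw = t[mask]
    pw = p[mask].copy()
    if exclusion_h > 0:
        cut = t0 + exclusion_h
        keep = tw >= cut
        if not keep.any():
            raise ValueError("exclusion window removes the entire record")
        pw[~keep] = pw[keep][0]
    if rule == "trapezoid":
        integral_uw_h = float(np.trapezoid(pw, tw))
    elif rule == "simpson":
        integral_uw_h = float(simpson(pw, x=tw))
    else:
        raise ValueError(f"unknown integration rule {rule!r}")
    q = integral_uw_h * 3600.0 * 1e-6  # uW*h -> J
    if q < 0:
        warnings.warn(f"{series.unit_id}: negative cumulative heat ({q:.4g} J g-1)")
    return q


def thermodynamic_efficiency(
    q_glucose: float, q_control: float, constants: ThermoConstants = ThermoConstants()
) -> float:
    """Thermodynamic efficiency index: 1 - (Q_glucose - Q_control)/dH_glucose.

    Unclamped; values below 0 (net heat exceeding substrate energy) trigger a
    warning but are returned as-is.
    """
    eta = 1.0 - (q_glucose - q_control) / constants.dH_glucose
    if eta < 0:
        warnings.warn(f"eta_eff = {eta:.4g} < 0: net heat exceeds substrate energy")
    return eta


def thermal_yield(
    glucose_derived_co2c: float,
    constants: ThermoConstants = ThermoConstants(),
    mode: str = "as_written",
) -> tuple[float, float]:
    """Thermal yield of glucose-derived heat carried off as CO2.

    The caller supplies the CO2-C mass (ug C per g soil) whose oxidation is
    attributed to glucose; ``mode`` records which accounting produced it:
    ``"as_written"`` when primed and control CO2 have both been subtracted
    (i.e., strictly glucose-derived CO2-C, the default), ``"calibrated"`` when
    only the control has been subtracted. The formula itself is the same pure
    map of the supplied mass:

        eta_co2 = dH_CO * (mass / molar_mass_C) / dH_glucose
        eta_soil = 1 - eta_co2
    """
    if mode not in ("as_written", "calibrated"):
        raise ValueError("mode must be 'as_written' or 'calibrated'")
    if glucose_derived_co2c < 0:
        raise ValueError("glucose-derived CO2-C must be >= 0")
    moles = glucose_derived_co2c * 1e-6 / constants.molar_mass_c
    eta_co2 = constants.dH_CO * moles / constants.dH_glucose
    return eta_co2, 1.0 - eta_co2


def calorespirometric_ratio(q_j_per_g: float, co2c_ug_per_g: float) -> float:
    """Heat released per unit CO2-C respired, mJ per ug CO2-C."""
    if co2c_ug_per_g <= 0:
        raise ValueError("respired CO2-C must be strictly positive")
    return q_j_per_g * 1000.0 / co2c_ug_per_g


def metabolic_quotient(r_basal: float, mbc: float) -> float:
    """Metabolic quotient qCO2: basal respiration per unit microbial biomass C."""
    if mbc <= 0:
        raise ValueError("MBC must be strictly positive")
    return r_basal / mbc


def read_heat_curves(path, samples: pd.DataFrame | None = None) -> list[HeatSeries]:
    """Load ``heat_curves.tsv`` (unit_id, time_h, power_uW_per_g) into series.

    If a samples table is given, its metadata columns are attached by unit id.
    """
    df = pd.read_csv(path, sep="\t")
    meta = {}
    if samples is not None:
        meta = samples.set_index("unit_id").to_dict("index")
    out = []
    for uid, grp in df.groupby("unit_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            HeatSeries(
                unit_id=str(uid),
                time_h=grp["time_h"].to_numpy(),
                power_uw=grp["power_uW_per_g"].to_numpy(),
                metadata=dict(meta.get(uid, {})),
            )
        )
    return out


def indices_table(
    heat_series: list[HeatSeries],
    respiration: pd.DataFrame | None = None,
    mbc: pd.DataFrame | None = None,
    constants: ThermoConstants = ThermoConstants(),
    window: tuple[float, float] | None = None,
    exclusion_h: float = 0.0,
) -> pd.DataFrame:
    """Per-unit cumulative heats and, per soil unit, the derived indices.

    Pairs each glucose-amended ampoule with the water control of the same
    management/crop/replicate to compute eta_eff. If a respiration table
    (columns: management, crop, replicate, amendment, co2c plus optionally
    r_glucose) is supplied, calorespirometric ratios (both amendments) and,
    when ``r_glucose`` is present, thermal yields are added. If an MBC table
    (management, crop, replicate, mbc) is supplied, qCO2 is added.

    Returns one row per soil unit (management, crop, replicate) with columns
    q_control, q_glucose, eta_eff and whichever indices were computable.
    """
    rows = {}
    for s in heat_series:
        md = s.metadata
        key = (md.get("management"), md.get("crop"), md.get("replicate"))
        q = cumulative_heat(s, window=window, exclusion_h=exclusion_h)
        rows.setdefault(key, {})[md.get("amendment")] = q
    recs = []
    for (ms, crop, rep), qs in sorted(rows.items(), key=lambda kv: str(kv[0])):
        rec = {"management": ms, "crop": crop, "replicate": rep}
        rec["q_control"] = qs.get("water", np.nan)
        rec["q_glucose"] = qs.get("glucose", np.nan)
        if "water" in qs and "glucose" in qs:
            rec["eta_eff"] = thermodynamic_efficiency(qs["glucose"], qs["water"], constants)
        recs.append(rec)
    out = pd.DataFrame(recs)
    key_cols = ["management", "crop", "replicate"]
    if respiration is not None:
        resp = respiration.copy()
        piv = resp.pivot_table(index=key_cols, columns="amendment", values="co2c").rename(
            columns={"water": "r_basal", "glucose": "r_total"}
        )
        out = out.merge(piv.reset_index(), on=key_cols, how="left")
        out["caloresp_control"] = out["q_control"] * 1000.0 / out["r_basal"]
        out["caloresp_glucose"] = out["q_glucose"] * 1000.0 / out["r_total"]
        if "r_glucose" in resp.columns:
            rg = (
                resp.dropna(subset=["r_glucose"])
                .groupby(key_cols, as_index=False)["r_glucose"]
                .mean()
            )
            out = out.merge(rg, on=key_cols, how="left")
            yields = out["r_glucose"].map(
                lambda m: thermal_yield(m, constants) if np.isfinite(m) else (np.nan, np.nan)
            )
            out["eta_co2"] = [y[0] for y in yields]
            out["eta_soil"] = [y[1] for y in yields]
    if mbc is not None:
        out = out.merge(mbc[key_cols + ["mbc"]], on=key_cols, how="left")
        if "r_basal" in out.columns:
            out["qco2"] = out["r_basal"] / out["mbc"]
    return out
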