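"""Synthetic experiments with known ground truth.

Generates every input the pipeline consumes — calorimeter power traces,
flushed-headspace gas series, a soil chemistry table and SIP-fraction OTU
count tables — from an :class:`~thermosip.design.ExperimentDesign` and a
:class:`~thermosip.design.SyntheticTruth`, so parameter recovery can be tested
end-to-end without any external data.

Construction guarantees (before noise):

* each heat trace integrates (trapezoid, on its own grid) to the unit's true
  cumulative heat exactly;
* summed glucose-derived interval CO2-C equals fraction_respired x
  glucose_c_rate exactly, basal C accrues at a constant rate, primed C is a
  constant multiple of basal C, and interval atom fractions are the exact
  mass-weighted two-source mixtures;
* OTU table columns sum exactly to the sequencing depth.

All randomness flows from ``design.seed`` through named substreams, so
regenerating any one output is byte-identical regardless of which other
outputs are produced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calorimetry import HeatSeries
from .design import FRACTIONS, ExperimentDesign, SyntheticTruth, substream
from .isotope import GasSeries

# -- heat curves ------------------------------------------------------------


def _gamma_pulse(t_h: np.ndarray, shape: float, scale_h: float, duration_h: float) -> np.ndarray:
    """Unit-area (on the discrete grid) gamma-shaped pulse.

    Rejects parameter choices that put more than 1 % of the analytic pulse
    mass beyond the record, then renormalises the within-window discrete
    trapezoid to exactly 1 so target areas are hit by construction.
    """
    tail = stats.gamma.sf(duration_h, a=shape, scale=scale_h)
    if tail > 0.01:
        raise ValueError(
            f"gamma pulse (shape={shape}, scale={scale_h} h) leaves "
            f"{100 * tail:.2f}% of its mass beyond {duration_h} h (> 1% limit)"
        )
    pulse = stats.gamma.pdf(t_h, a=shape, scale=scale_h)
    area = np.trapezoid(pulse, t_h)
    return pulse / area


def simulate_heat_curves(
    design: ExperimentDesign,
    truth: SyntheticTruth,
    step_min: float = 1.0,
) -> list[HeatSeries]:
    """Power traces for every ampoule (uW per g dry soil, default 1-min steps).

    Water units dissipate their true cumulative heat at constant power;
    glucose units add a unimodal gamma pulse carrying the glucose-induced
    extra heat on top of the same basal power. Zero-mean Gaussian noise
    (``truth.power_noise_sd``) is added after the areas are fixed.
    """
    t = np.arange(0.0, design.duration_h + 1e-9, step_min / 60.0)
    duration_s = design.duration_h * 3600.0
    rng = substream(design.seed, "heat")
    out = []
    for unit in design.units():
        key = (unit["management"], unit["crop"])
        q_basal = truth.q_control[key]
        if q_basal <= 0:
            raise ValueError(f"target cumulative heat must be positive for {key}")
        basal_uw = q_basal / duration_s * 1e6
        power = np.full_like(t, basal_uw)
        if unit["amendment"] == "glucose":
            q_extra = truth.q_glucose[key] - q_basal
            if q_extra <= 0:
                raise ValueError(f"glucose Q must exceed control Q for {key}")
            pulse = _gamma_pulse(t, truth.pulse_shape, truth.pulse_scale_h, design.duration_h)
            power = power + q_extra / 3600.0 * 1e6 * pulse  # J/h -> uW
        if truth.power_noise_sd > 0:
            power = power + rng.normal(0.0, truth.power_noise_sd, size=t.shape)
        out.append(HeatSeries(unit_id=unit["unit_id"], time_h=t.copy(), power_uw=power,
                              metadata={k: v for k, v in unit.items() if k != "unit_id"}))
    return out


# -- gas series -------------------------------------------------------------


def simulate_gas_series(
    design: ExperimentDesign,
    truth: SyntheticTruth,
    n_blanks: int = 2,
) -> list[GasSeries]:
    """Flushed-headspace interval CO2-C masses and 13C abundances per jar.

    Glucose jars emit glucose-derived C following first-order depletion of the
    respirable glucose pool (renormalised so the within-window total equals
    fraction_respired x glucose_c_rate exactly), basal SOM-derived C at
    x_soil, and primed C = priming_coefficient x basal C, also at x_soil.
    Water jars emit basal C only; blank jars carry measurement noise only.
    """
    times = np.asarray(design.sampling_times_h, dtype=float)
    edges = np.concatenate([[0.0], times])
    dt = np.diff(edges)
    k = np.log(2.0) / truth.glucose_half_life_h
    depletion = 1.0 - np.exp(-k * edges)
    frac_per_interval = np.diff(depletion) / depletion[-1]
    rng = substream(design.seed, "gas")
    out = []
    for unit in design.units():
        key = (unit["management"], unit["crop"])
        basal_total = truth.basal_respiration[key]
        basal_i = basal_total * dt / dt.sum()
        if unit["amendment"] == "glucose":
            g_total = truth.fraction_respired[key] * design.glucose_c_rate
            glucose_i = g_total * frac_per_interval
            primed_i = truth.priming_coefficient[key] * basal_i
            som_i = basal_i + primed_i
            mass = glucose_i + som_i
            abund = (glucose_i * truth.x_glucose + som_i * truth.x_soil) / mass
        else:
            mass = basal_i.copy()
            abund = np.full_like(mass, truth.x_soil)
        if truth.co2_noise_sd > 0:
            mass = mass + rng.normal(0.0, truth.co2_noise_sd, size=mass.shape)
        if truth.abundance_noise_sd > 0:
            abund = abund + rng.normal(0.0, truth.abundance_noise_sd, size=abund.shape)
        out.append(GasSeries(jar_id=unit["unit_id"], time_h=times.copy(),
                             co2c=np.clip(mass, 0.0, None), atom_fraction=abund,
                             metadata={k_: v for k_, v in unit.items() if k_ != "unit_id"}))
    for b in range(1, n_blanks + 1):
        mass = (rng.normal(0.0, truth.co2_noise_sd, size=times.shape)
                if truth.co2_noise_sd > 0 else np.zeros_like(times))
        out.append(GasSeries(jar_id=f"blank-{b}", time_h=times.copy(),
                             co2c=np.clip(mass, 0.0, None),
                             atom_fraction=np.full_like(times, truth.x_soil),
                             metadata={"amendment": "blank"}))
    return out


# -- OTU tables -------------------------------------------------------------


def simulate_otu_table(
    design: ExperimentDesign,
    truth: SyntheticTruth,
    n_taxa: int = 500,
    depth: int = 25_000,
    concentration: float = 10_000.0,
    fractions: tuple[str, ...] = FRACTIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial OTU counts for every SIP fraction of every soil.

    One sample per (soil unit x fraction); the glucose-amended soils are the
    ones fractionated, so samples derive from the glucose units of the design.
    Planted glucose-utiliser taxa (``truth.enriched_taxa``, keyed by
    management system) have their expected relative abundance multiplied by
    ``2 ** truth.enrichment_log2fc`` in 13C-heavy samples of their system.
    Every column sums exactly to ``depth``.

    Returns ``(counts, samples)``: counts indexed by OTU id with a taxonomy
    column, and the per-sample metadata table.
    """
    if n_taxa < 10:
        raise ValueError("n_taxa must be >= 10")
    if depth < 100:
        raise ValueError("depth must be >= 100")
    otu_ids = [f"OTU{i:04d}" for i in range(1, n_taxa + 1)]
    enriched = {ms: set(ids) for ms, ids in dict(truth.enriched_taxa).items()}
    for ms, ids in enriched.items():
        missing = ids - set(otu_ids)
        if missing:
            raise ValueError(f"enriched taxa not in table: {sorted(missing)[:5]} ...")
    phyla = ("Proteobacteria", "Actinobacteria", "Firmicutes", "Bacteroidetes",
             "Acidobacteria", "Verrucomicrobia", "Chloroflexi", "Crenarchaeota")
    rng = substream(design.seed, "otu")
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_taxa)
    base /= base.sum()
    taxonomy = {oid: f"k__Bacteria; p__{phyla[i % len(phyla)]}; g__g{i:04d}"
                for i, oid in enumerate(otu_ids)}
    samples, columns = [], {}
    for unit in design.units():
        if unit["amendment"] != "glucose":
            continue
        for fraction in fractions:
            sid = f"{unit['management']}-{unit['crop']}-r{unit['replicate']}-{fraction}"
            expected = base.copy()
            if fraction == "13C-heavy":
                planted = enriched.get(unit["management"], set())
                if planted:
                    idx = [i for i, oid in enumerate(otu_ids) if oid in planted]
                    expected[idx] *= 2.0 ** truth.enrichment_log2fc
            expected /= expected.sum()
            p = rng.dirichlet(expected * concentration)
            counts = rng.multinomial(depth, p)
            columns[sid] = counts
            samples.append({"sample_id": sid, "management": unit["management"],
                            "crop": unit["crop"], "replicate": unit["replicate"],
                            "amendment": "glucose", "fraction": fraction})
    counts_df = pd.DataFrame(columns, index=pd.Index(otu_ids, name="otu_id"))
    counts_df.insert(0, "taxonomy", [taxonomy[o] for o in otu_ids])
    return counts_df, pd.DataFrame(samples)


# -- soil chemistry ---------------------------------------------------------

#: default per-treatment chemistry means (the field trial's published
#: treatment means): SOC %, DOC, NO3-N, PO4-P (ug g-1), pH, MBC (ug g-1),
#: BG, PHOX (umol g-1 h-1), and corresponding sds (SE * sqrt(n), n = 4).
DEFAULT_CHEMISTRY = {
    ("CON", "ANN"): {"SOC": 3.09, "DOC": 61.7, "NO3_N": 51.2, "PO4_P": 53.7,
                     "pH": 5.26, "MBC": 362.8, "BG": 1.66, "PHOX": 0.56},
    ("CON", "PER"): {"SOC": 2.73, "DOC": 61.3, "NO3_N": 53.3, "PO4_P": 65.5,
                     "pH": 5.03, "MBC": 254.2, "BG": 0.97, "PHOX": 0.52},
    ("ORG", "ANN"): {"SOC": 2.89, "DOC": 46.3, "NO3_N": 41.7, "PO4_P": 14.8,
                     "pH": 4.91, "MBC": 298.4, "BG": 1.10, "PHOX": 0.36},
    ("ORG", "PER"): {"SOC": 2.55, "DOC": 44.2, "NO3_N": 42.9, "PO4_P": 16.2,
                     "pH": 5.35, "MBC": 306.2, "BG": 0.98, "PHOX": 0.37},
}

DEFAULT_CHEMISTRY_SD = {
    ("CON", "ANN"): {"SOC": 0.60, "DOC": 20.2, "NO3_N": 14.2, "PO4_P": 14.4,
                     "pH": 0.28, "MBC": 65.8, "BG": 0.74, "PHOX": 0.10},
    ("CON", "PER"): {"SOC": 0.08, "DOC": 9.2, "NO3_N": 2.2, "PO4_P": 4.0,
                     "pH": 0.08, "MBC": 35.0, "BG": 0.44, "PHOX": 0.10},
    ("ORG", "ANN"): {"SOC": 0.58, "DOC": 6.8, "NO3_N": 2.2, "PO4_P": 2.6,
                     "pH": 0.30, "MBC": 35.2, "BG": 0.22, "PHOX": 0.22},
    ("ORG", "PER"): {"SOC": 0.40, "DOC": 6.6, "NO3_N": 5.6, "PO4_P": 2.2,
                     "pH": 0.32, "MBC": 43.2, "BG": 0.22, "PHOX": 0.22},
}

#: kec used to derive fumigation-extraction columns from MBC and DOC
KEC = 0.45


def simulate_soil_chemistry(
    design: ExperimentDesign,
    means: dict | None = None,
    sds: dict | None = None,
) -> pd.DataFrame:
    """One chemistry row per field unit: Gaussian draws around treatment means.

    Fumigation-extraction organic C columns are emitted alongside
    (``ec_unfumigated = DOC``, ``ec_fumigated = DOC + MBC * kec``) so the MBC
    computation can be exercised on raw extract values.
    """
    means = DEFAULT_CHEMISTRY if means is None else means
    sds = DEFAULT_CHEMISTRY_SD if sds is None else sds
    rng = substream(design.seed, "chemistry")
    rows = []
    for ms in design.management_systems:
        for crop in design.cropping_histories:
            mu = means[(ms, crop)]
            sd = sds[(ms, crop)]
            for rep in range(1, design.n_replicates + 1):
                row = {"management": ms, "crop": crop, "replicate": rep}
                for var, m in mu.items():
                    s = sd.get(var, 0.0)
                    if s < 0:
                        raise ValueError(f"sd for {var} must be >= 0")
                    row[var] = m + (rng.normal(0.0, s) if s > 0 else 0.0)
                row["ec_unfumigated"] = row["DOC"]
                row["ec_fumigated"] = row["DOC"] + row["MBC"] * KEC
                rows.append(row)
    return pd.DataFrame(rows)


# -- bundle -----------------------------------------------------------------


def _truth_manifest(design: ExperimentDesign, truth: SyntheticTruth) -> dict:
    key = lambda k: f"{k[0]}-{k[1]}"
    return {
        "seed": design.seed,
        "glucose_c_rate": design.glucose_c_rate,
        "q_control": {key(k): v for k, v in dict(truth.q_control).items()},
        "q_glucose": {key(k): v for k, v in dict(truth.q_glucose).items()},
        "basal_respiration": {key(k): v for k, v in dict(truth.basal_respiration).items()},
        "fraction_respired": {key(k): v for k, v in dict(truth.fraction_respired).items()},
        "priming_coefficient": {key(k): v for k, v in dict(truth.priming_coefficient).items()},
        "x_glucose": truth.x_glucose,
        "x_soil": truth.x_soil,
        "enriched_taxa": {ms: sorted(ids) for ms, ids in dict(truth.enriched_taxa).items()},
        "enrichment_log2fc": truth.enrichment_log2fc,
        "noise": {
            "power_sd": truth.power_noise_sd,
            "co2_sd": truth.co2_noise_sd,
            "abundance_sd": truth.abundance_noise_sd,
        },
    }


def simulate_experiment(
    design: ExperimentDesign,
    truth: SyntheticTruth | None = None,
    out_dir: str | Path | None = None,
    n_taxa: int = 500,
    depth: int = 25_000,
) -> dict:
    """Generate a complete experiment; optionally write it as a TSV bundle.

    Returns a dict of in-memory objects (heat, gas, chemistry, otu counts,
    samples, truth manifest). With ``out_dir`` the on-disk bundle contains
    ``heat_curves.tsv``, ``gas_samples.tsv``, ``chemistry.tsv``,
    ``otu_counts.tsv``, ``samples.tsv`` and ``truth.json``; a full pipeline
    run is possible from the bundle alone.
    """
    if truth is None:
        truth = SyntheticTruth()
    heat = simulate_heat_curves(design, truth)
    gas = simulate_gas_series(design, truth)
    chemistry = simulate_soil_chemistry(design)
    counts, otu_samples = simulate_otu_table(design, truth, n_taxa=n_taxa, depth=depth)
    units = pd.DataFrame(design.units())
    bundle = {
        "heat": heat,
        "gas": gas,
        "chemistry": chemistry,
        "otu_counts": counts,
        "otu_samples": otu_samples,
        "units": units,
        "truth": _truth_manifest(design, truth),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        heat_rows = pd.concat(
            [pd.DataFrame({"unit_id": s.unit_id, "time_h": s.time_h,
                           "power_uW_per_g": s.power_uw}) for s in heat],
            ignore_index=True,
        )
        heat_rows.to_csv(out / "heat_curves.tsv", sep="\t", index=False, float_format="%.10g")
        gas_rows = pd.concat(
            [pd.DataFrame({"jar_id": s.jar_id, "time_h": s.time_h,
                           "co2_c_ug_per_g_interval": s.co2c,
                           "atom_fraction_13c": s.atom_fraction}) for s in gas],
            ignore_index=True,
        )
        gas_rows.to_csv(out / "gas_samples.tsv", sep="\t", index=False, float_format="%.10g")
        chemistry.to_csv(out / "chemistry.tsv", sep="\t", index=False, float_format="%.10g")
        counts.to_csv(out / "otu_counts.tsv", sep="\t", float_format="%.10g")
        meta = pd.concat([units.rename(columns={"unit_id": "sample_id"}).assign(fraction="none"),
                          otu_samples], ignore_index=True)
        meta.to_csv(out / "samples.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(bundle["truth"], fh, indent=2, sort_keys=True)
    return bundle
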