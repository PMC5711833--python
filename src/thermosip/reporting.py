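"""Summary surfaces: treatment / pooled means ± SE, contrasts, report bundle.

Aggregation conventions matter in this analysis: fold-ratios computed from
pooled group means generally differ from the mean of per-replicate ratios, and
published summaries mix the two. Both are therefore always reported side by
side, and indices are computed both per replicate (then averaged) and from
mean inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import calorimetry, community, isotope


def treatment_summary(
    unit_table: pd.DataFrame,
    grouping: list[str],
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Means, standard errors (sd/sqrt(n)) and n per group.

    ``grouping=['management', 'crop']`` gives the individual-treatment level
    (n = replicates); ``grouping=['management']`` pools across cropping
    histories (n = 2 x replicates for a balanced design).
    """
    for g in grouping:
        if g not in unit_table.columns:
            raise ValueError(f"grouping variable {g!r} missing")
    if variables is None:
        variables = [
            c for c in unit_table.select_dtypes(include=[np.number]).columns
            if c not in grouping and c != "replicate"
        ]
    grouped = unit_table.groupby(grouping, sort=True)
    if any(size == 0 for size in grouped.size()):
        raise ValueError("empty group")
    rows = []
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(grouping, key))
        rec["n"] = len(sub)
        for v in variables:
            vals = sub[v].dropna()
            rec[f"{v}_mean"] = vals.mean()
            rec[f"{v}_se"] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append(rec)
    return pd.DataFrame(rows)


def contrast_ratios(
    unit_table: pd.DataFrame,
    variable: str,
    contrast: str,
    level_a: str,
    level_b: str,
    within: dict | None = None,
) -> dict:
    """Fold-ratio a/b and percent difference 100*(a-b)/b for one contrast.

    Computed two ways: from pooled group means (``ratio_of_means``) and as the
    mean of per-replicate ratios (``mean_of_ratios``, pairing replicates by
    the remaining design labels). ``within`` optionally restricts to a slice
    (e.g. ``{'amendment': 'glucose'}``).
    """
    df = unit_table
    if within:
        for k, v in within.items():
            df = df[df[k] == v]
    a = df[df[contrast] == level_a]
    b = df[df[contrast] == level_b]
    if a.empty or b.empty:
        raise ValueError(f"no samples for contrast {contrast}: {level_a} vs {level_b}")
    mean_a, mean_b = a[variable].mean(), b[variable].mean()
    if mean_b == 0:
        raise ValueError("zero denominator in contrast")
    out = {
        "variable": variable,
        "contrast": f"{level_a}/{level_b}",
        "ratio_of_means": mean_a / mean_b,
        "percent_difference_of_means": 100.0 * (mean_a - mean_b) / mean_b,
    }
    pair_keys = [c for c in ("management", "crop", "replicate") if c != contrast and c in df.columns]
    if pair_keys:
        merged = a.merge(b, on=pair_keys, suffixes=("_a", "_b"))
        va, vb = merged[f"{variable}_a"], merged[f"{variable}_b"]
        ok = vb != 0
        if ok.any():
            out["mean_of_ratios"] = float((va[ok] / vb[ok]).mean())
    return out


def run_pipeline(
    bundle_dir: str | Path,
    x_glucose: float = 0.195,
    constants: calorimetry.ThermoConstants = calorimetry.ThermoConstants(),
    rarefaction_depth: int | None = None,
    n_permutations: int = 499,
    seed: int = 0,
) -> dict:
    """Run every analysis stage on an on-disk synthetic (or real) bundle.

    Reads ``heat_curves.tsv``, ``gas_samples.tsv``, ``chemistry.tsv``,
    ``otu_counts.tsv`` and ``samples.tsv`` from ``bundle_dir`` and returns a
    dict of stage outputs: per-unit thermodynamic indices, the respiration
    partition, community analyses on the 13C fractions, and summary tables.
    """
    bundle = Path(bundle_dir)
    for fname in ("heat_curves.tsv", "gas_samples.tsv", "chemistry.tsv",
                  "otu_counts.tsv", "samples.tsv"):
        if not (bundle / fname).exists():
            raise FileNotFoundError(f"missing pipeline input: {bundle / fname}")
    samples = pd.read_csv(bundle / "samples.tsv", sep="\t")
    units = samples[samples["fraction"] == "none"].rename(columns={"sample_id": "unit_id"})
    heat = calorimetry.read_heat_curves(bundle / "heat_curves.tsv", samples=units)
    gas = isotope.read_gas_series(bundle / "gas_samples.tsv", samples=units)
    chemistry = pd.read_csv(bundle / "chemistry.tsv", sep="\t")
    counts = pd.read_csv(bundle / "otu_counts.tsv", sep="\t", index_col="otu_id")
    otu_samples = samples[samples["fraction"] != "none"]

    partition = isotope.partition_experiment(gas, x_glucose=x_glucose)

    key_cols = ["management", "crop", "replicate"]
    resp_rows = []
    for s in gas:
        if s.metadata.get("amendment") in ("glucose", "water"):
            resp_rows.append({**{k: s.metadata.get(k) for k in ("management", "crop",
                                                                "replicate", "amendment")},
                              "co2c": isotope.accumulate_intervals(s)})
    respiration = pd.DataFrame(resp_rows)
    respiration = respiration.merge(
        partition[key_cols + ["Rglucose"]].rename(columns={"Rglucose": "r_glucose"}),
        on=key_cols, how="left",
    )
    mbc = chemistry.copy()
    mbc["mbc"] = isotope.microbial_biomass_c(mbc["ec_fumigated"], mbc["ec_unfumigated"])
    indices = calorimetry.indices_table(
        heat, respiration=respiration, mbc=mbc[key_cols + ["mbc"]], constants=constants
    )

    # community stage on the 13C-heavy vs 13C-light contrast per management
    depth = rarefaction_depth
    numeric = counts.select_dtypes(include=[np.number])
    if depth is None:
        depth = int(min(community.DEFAULT_RAREFACTION_DEPTH, numeric.sum(axis=0).min()))
    rarefied = community.rarefy(counts, depth=depth, seed=seed)
    bc = community.bray_curtis(rarefied)
    ord_res = community.pcoa(bc, k=2)
    meta = otu_samples.set_index("sample_id")
    perm = community.permanova(bc, meta, terms=["fraction", "management"],
                               n_permutations=n_permutations, seed=seed)
    heavy = meta[meta["fraction"] == "13C-heavy"]
    enrichments = {}
    for ms in sorted(heavy["management"].unique()):
        ms_meta = meta[meta["management"] == ms]
        g1 = list(ms_meta[ms_meta["fraction"] == "13C-heavy"].index)
        g2 = list(ms_meta[ms_meta["fraction"] == "13C-light"].index)
        enrichments[ms] = community.enrichment_screen(
            rarefied, g1, g2, seed=seed, contrast=f"13C-heavy-vs-13C-light-{ms}"
        )

    # soil variables per heavy-fraction sample (unit-level values broadcast)
    soil_unit = chemistry.merge(
        partition[key_cols + ["Rt", "Rglucose", "RSOM", "Rprimed"]], on=key_cols, how="left"
    ).merge(indices[key_cols + ["eta_eff", "q_glucose", "q_control"]], on=key_cols, how="left")
    heavy_ids = list(heavy.index)
    soil_by_sample = (
        heavy.reset_index()[["sample_id"] + key_cols]
        .merge(soil_unit, on=key_cols, how="left")
        .set_index("sample_id")
        .loc[heavy_ids]
    )
    correlations = {
        ms: community.correlation_heatmap(res, rarefied, soil_by_sample, significant_only=False)
        for ms, res in enrichments.items()
    }

    return {
        "indices": indices,
        "partition": partition,
        "respiration": respiration,
        "chemistry": mbc,
        "rarefied_depth": depth,
        "braycurtis": bc,
        "pcoa": ord_res,
        "permanova": perm,
        "enrichment": enrichments,
        "correlations": correlations,
    }


def _frame_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def assemble_report(results: dict, out_dir: str | Path, config: dict | None = None) -> Path:
    """Write the report bundle: table analogues, contrasts, run metadata.

    Deterministic given identical inputs (stable ordering, fixed float
    formatting). Returns the report directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    indices = results["indices"]
    partition = results["partition"]
    chemistry = results["chemistry"]

    chem_vars = [c for c in ("SOC", "DOC", "NO3_N", "PO4_P", "pH", "mbc", "BG", "PHOX")
                 if c in chemistry.columns]
    table1 = pd.concat([
        treatment_summary(chemistry, ["management"], chem_vars),
        treatment_summary(chemistry, ["management", "crop"], chem_vars),
    ], ignore_index=True)
    _frame_tsv(table1, out / "table1.tsv")

    t2_vars = [c for c in ("r_basal", "q_control", "caloresp_control", "qco2",
                           "r_total", "q_glucose", "caloresp_glucose") if c in indices.columns]
    table2 = pd.concat([
        treatment_summary(indices, ["management"], t2_vars),
        treatment_summary(indices, ["management", "crop"], t2_vars),
    ], ignore_index=True)
    _frame_tsv(table2, out / "table2.tsv")

    t3_vars = [c for c in ("Rglucose", "RSOM", "Rprimed", "p_glucose_of_total",
                           "p_primed_of_total", "p_primed_of_som") if c in partition.columns]
    table3 = pd.concat([
        treatment_summary(partition, ["management"], t3_vars),
        treatment_summary(partition, ["management", "crop"], t3_vars),
    ], ignore_index=True)
    _frame_tsv(table3, out / "table3.tsv")

    t4_vars = [c for c in ("eta_eff", "eta_co2", "eta_soil") if c in indices.columns]
    table4 = pd.concat([
        treatment_summary(indices, ["management"], t4_vars),
        treatment_summary(indices, ["management", "crop"], t4_vars),
    ], ignore_index=True)
    _frame_tsv(table4, out / "table4.tsv")

    contrasts = []
    for ms in sorted(indices["management"].dropna().unique()):
        sub = indices[indices["management"] == ms]
        long = pd.concat([
            sub[["management", "crop", "replicate", "r_basal", "q_control"]]
            .rename(columns={"r_basal": "co2c", "q_control": "heat"}).assign(amendment="water"),
            sub[["management", "crop", "replicate", "r_total", "q_glucose"]]
            .rename(columns={"r_total": "co2c", "q_glucose": "heat"}).assign(amendment="glucose"),
        ], ignore_index=True)
        for var in ("co2c", "heat"):
            c = contrast_ratios(long, var, "amendment", "glucose", "water")
            c["group"] = ms
            contrasts.append(c)
    _frame_tsv(pd.DataFrame(contrasts), out / "contrasts.tsv")

    _frame_tsv(results["braycurtis"], out / "braycurtis.tsv", index=True)
    pco = results["pcoa"]
    _frame_tsv(pco.coordinates, out / "pcoa.tsv", index=True)
    _frame_tsv(results["permanova"].table, out / "permanova.tsv")
    enr = pd.concat(
        [res.table.assign(contrast=res.contrast) for res in results["enrichment"].values()]
    )
    _frame_tsv(enr, out / "enrichment.tsv", index=True)
    corr = pd.concat(
        [tbl.assign(group=ms) for ms, tbl in results["correlations"].items()]
    )
    _frame_tsv(corr, out / "correlations.tsv", index=True)
    _frame_tsv(indices, out / "indices.tsv")
    _frame_tsv(partition, out / "partition.tsv")

    config = dict(config or {})
    meta = {
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "rarefied_depth": results.get("rarefied_depth"),
        "permanova_permutations": results["permanova"].n_permutations,
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)

    lines = ["pipeline summary", "================"]
    pooled = treatment_summary(indices, ["management"], t4_vars)
    for _, row in pooled.iterrows():
        lines.append(
            f"{row['management']}: eta_eff = {row['eta_eff_mean']:.3f} "
            f"± {row['eta_eff_se']:.3f} (n={int(row['n'])})"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out
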