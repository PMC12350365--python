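"""Synthetic G2F-style dataset generator.

Emits the six tables of a hybrid maize trial network — trait records,
per-environment metadata, daily weather, soil profiles, crop-simulator
environmental covariates, and genotype call strings — at a configurable
reduced scale, together with the ground-truth record of every effect injected
into the yields. Downstream stages (imputation, encoding, feature
engineering, models) can therefore be tested against known answers without
any external download.

Yields follow an additive G×E×M construction::

    yield = baseline + state_effect + sum(locus_effect * dosage)
            + treatment_offset - planting_penalty + noise,   clipped at 0

so that regressions on the generated data recover the injected coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .config import DEFAULT_CALL_MIX, SyntheticConfig

WEATHER_FEATURES = [
    "temp_max", "temp_min", "temp_mean", "dewpoint", "rel_humidity",
    "precip", "solar_rad", "wind_speed", "wind_dir", "gdd",
    "evapotrans", "soil_temp", "vpd", "cloud_cover", "pressure",
    "photoperiod",
]

SOIL_FEATURES = [
    "ph", "om_pct", "p_ppm", "k_ppm", "ca_ppm", "mg_ppm", "na_ppm",
    "cec", "sand_pct", "silt_pct", "clay_pct", "no3_ppm", "nh4_ppm",
    "s_ppm", "zn_ppm", "fe_ppm", "mn_ppm", "cu_ppm", "b_ppm", "ec",
    "bulk_density", "buffer_ph", "total_n_pct",
]

#: Crop-simulator soil feature groups. All span 10 soil depths and 9
#: phenological stages except "Flow" (water flux between layers), which is
#: defined at the 9 layer interfaces.
ENVSIM_SOIL_GROUPS = [
    "SWSupplyDemand", "ESWRatio", "FlowUp", "NO3Leach",
    "SoilWater", "PlantAvailWater", "Flow",
]
ENVSIM_DEPTHS = 10
ENVSIM_FLOW_DEPTHS = 9
ENVSIM_STAGES = 9
ENVSIM_PHENO_FEATURES = ["sim_grain_yield", "sim_biomass", "sim_water_table", "sim_lai"]


@dataclass
class RawDataset:
    """The six generated tables plus the ground-truth effect record."""

    trait_table: pd.DataFrame
    metadata_table: pd.DataFrame
    weather_table: pd.DataFrame
    soil_table: pd.DataFrame
    envsim_table: pd.DataFrame
    genotype_table: pd.DataFrame
    truth: dict[str, Any] = field(default_factory=dict)

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "trait": self.trait_table,
            "metadata": self.metadata_table,
            "weather": self.weather_table,
            "soil": self.soil_table,
            "envsim": self.envsim_table,
            "genotype": self.genotype_table,
        }


def generate_genotype_calls(
    n_hybrids: int,
    n_loci: int,
    call_mix: dict[str, float] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    missing_marker: str = "./.",
    missing_loci: list[str] | None = None,
    hybrid_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw a hybrids x loci table of genotype call strings.

    Parameters
    ----------
    call_mix
        Probability per call string; defaults put <5% of mass on calls outside
        the four diploid biallelic ones.
    missing_rate
        Per-cell probability of the missing marker. If ``missing_loci`` is
        given, the rate applies only within those locus columns.
    """
    mix = dict(DEFAULT_CALL_MIX if call_mix is None else call_mix)
    probs = np.array(list(mix.values()), dtype=float)
    if (probs < 0).any():
        raise ValueError("call probabilities must be nonnegative")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"call probabilities must sum to 1, got {probs.sum():.6f}")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    calls = np.array(list(mix.keys()))
    idx = rng.choice(len(calls), size=(n_hybrids, n_loci), p=probs)
    data = calls[idx]

    loci = [f"locus_{j:04d}" for j in range(n_loci)]
    if missing_rate > 0:
        if missing_loci is None:
            mask = rng.random((n_hybrids, n_loci)) < missing_rate
        else:
            mask = np.zeros((n_hybrids, n_loci), dtype=bool)
            cols = [loci.index(c) for c in missing_loci]
            mask[:, cols] = rng.random((n_hybrids, len(cols))) < missing_rate
        data = np.where(mask, missing_marker, data)

    hybrids = hybrid_ids if hybrid_ids is not None else [f"P{2*i+1:03d}/P{2*i+2:03d}" for i in range(n_hybrids)]
    return pd.DataFrame(data, index=pd.Index(hybrids, name="Hybrid"), columns=loci)


def inject_yield(
    truth: dict[str, Any],
    design: pd.DataFrame,
    genotypes: pd.DataFrame,
    seed: int = 0,
) -> np.ndarray:
    """Compute yields for a trial design from the ground-truth effect record.

    ``design`` needs columns state, Hybrid, treatment and planting_doy;
    ``genotypes`` is the encoded dosage matrix indexed by hybrid. Unknown
    states or hybrids raise ``KeyError``.
    """
    rng = np.random.default_rng(seed)
    state_effects: dict[str, float] = truth["state_effects"]
    locus_effects: dict[str, float] = truth["locus_effects"]
    offsets: dict[str, float] = truth["treatment_offsets"]
    window_end = truth["planting_window"][1]
    penalty = truth["planting_penalty_per_day"]

    for st in design["state"].unique():
        if st not in state_effects:
            raise KeyError(f"unknown state in design: {st!r}")
    missing_hyb = set(design["Hybrid"]) - set(genotypes.index)
    if missing_hyb:
        raise KeyError(f"hybrids absent from genotype matrix: {sorted(missing_hyb)[:5]}")

    causal = list(locus_effects)
    beta = np.array([locus_effects[c] for c in causal])
    g = genotypes.loc[design["Hybrid"], causal].to_numpy(dtype=float) if causal else np.zeros((len(design), 0))
    genetic = g @ beta if causal else np.zeros(len(design))

    y = (
        truth["baseline_yield"]
        + design["state"].map(state_effects).to_numpy(dtype=float)
        + genetic
        + design["treatment"].map(offsets).fillna(0.0).to_numpy(dtype=float)
        - penalty * np.maximum(0, design["planting_doy"].to_numpy(dtype=float) - window_end)
        + rng.normal(0.0, truth["noise_sd"], size=len(design))
    )
    return np.clip(y, 0.0, None)


def _daily_weather(rng: np.random.Generator, env_rows: pd.DataFrame, n_days: int) -> pd.DataFrame:
    """Smooth seasonal daily series per environment, 16 features long-format."""
    frames = []
    doy = np.arange(1, n_days + 1)
    season = np.sin(2 * np.pi * (doy - 100) / 365.0)
    for _, row in env_rows.iterrows():
        base = rng.normal(0, 1, size=len(WEATHER_FEATURES))
        values = {}
        for k, feat in enumerate(WEATHER_FEATURES):
            scale = 10.0 if "temp" in feat else 3.0
            series = 15 + scale * season + base[k] + rng.normal(0, 0.8, size=n_days)
            if feat == "precip":
                series = np.maximum(0.0, series - 12)
            values[feat] = np.round(series, 3)
        frame = pd.DataFrame(values)
        frame.insert(0, "Env", row["Env"])
        dates = pd.to_datetime(f"{row['year']}-01-01") + pd.to_timedelta(doy - 1, unit="D")
        frame.insert(1, "date", dates.strftime("%Y-%m-%d"))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _soil_table(rng: np.random.Generator, env_rows: pd.DataFrame, missing_rate: float) -> pd.DataFrame:
    n = len(env_rows)
    data = {f: np.round(rng.normal(10, 3, size=n), 3) for f in SOIL_FEATURES}
    table = pd.DataFrame(data)
    table.insert(0, "Env", env_rows["Env"].to_numpy())
    if missing_rate > 0:
        mask = rng.random((n, len(SOIL_FEATURES))) < missing_rate
        vals = table[SOIL_FEATURES].to_numpy()
        vals[mask] = np.nan
        table[SOIL_FEATURES] = vals
    return table


def envsim_columns() -> tuple[list[str], list[str]]:
    """Column names of the crop-simulator table: (soil-group cols, phenology cols)."""
    soil_cols = []
    for grp in ENVSIM_SOIL_GROUPS:
        depths = ENVSIM_FLOW_DEPTHS if grp == "Flow" else ENVSIM_DEPTHS
        soil_cols += [f"{grp}_d{d+1}_s{s+1}" for d in range(depths) for s in range(ENVSIM_STAGES)]
    pheno_cols = [f"{f}_s{s+1}" for f in ENVSIM_PHENO_FEATURES for s in range(ENVSIM_STAGES)]
    return soil_cols, pheno_cols


def _envsim_table(
    rng: np.random.Generator,
    env_rows: pd.DataFrame,
    state_effects: dict[str, float],
    missing_rate: float,
) -> pd.DataFrame:
    """Random smooth depth x stage fields, weakly shifted by the state effect
    so the covariates carry genuine (if simple) yield signal."""
    soil_cols, pheno_cols = envsim_columns()
    n = len(env_rows)
    shift = env_rows["state"].map(state_effects).to_numpy(dtype=float)

    blocks = []
    for grp in ENVSIM_SOIL_GROUPS:
        depths = ENVSIM_FLOW_DEPTHS if grp == "Flow" else ENVSIM_DEPTHS
        d = np.arange(depths)[None, :, None]
        s = np.arange(ENVSIM_STAGES)[None, None, :]
        field_ = (
            5
            + 0.3 * shift[:, None, None]
            + np.sin(d / 3.0 + rng.normal(0, 0.5, size=(n, 1, 1)))
            + 0.2 * s
            + rng.normal(0, 0.3, size=(n, depths, ENVSIM_STAGES))
        )
        blocks.append(field_.reshape(n, -1))
    pheno = (
        8
        + 0.5 * shift[:, None]
        + rng.normal(0, 0.5, size=(n, len(pheno_cols)))
    )
    data = np.round(np.hstack(blocks + [pheno]), 3)
    if missing_rate > 0:
        mask = rng.random(data.shape) < missing_rate
        data[mask] = np.nan
    table = pd.DataFrame(data, columns=soil_cols + pheno_cols)
    table.insert(0, "Env", env_rows["Env"].to_numpy())
    return table


ISSUE_COMMENTS = {
    "no issues": "no issues observed this season",
    "drought": "severe drought stress in July",
    "storm": "hail storm damaged plots in June",
    "animal attack": "deer damage on border rows",
    "data issues": "harvest weights suspect, scale drift",
    "miscellaneous": "late fungicide application, minor lodging",
}


def generate_dataset(config: SyntheticConfig) -> RawDataset:
    """Generate the full six-table dataset with known injected effects."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2**31)]
    rng = np.random.default_rng(seeds[0])

    years = list(range(config.years[0], config.years[1] + 1))
    states = [f"ST{i+1:02d}" for i in range(config.n_states)]
    locations, loc_state = [], {}
    for i_state, st in enumerate(states):
        for j in range(config.envs_per_state):
            loc = f"LOC{i_state * config.envs_per_state + j + 1:02d}"
            locations.append(loc)
            loc_state[loc] = st

    env_rows = pd.DataFrame(
        [
            {"Env": f"{loc}_{yr}", "location": loc, "state": loc_state[loc], "year": yr}
            for loc in locations
            for yr in years
        ]
    )

    # --- genotypes -------------------------------------------------------
    loci = [f"locus_{j:04d}" for j in range(config.n_loci)]
    n_missing_loci = int(round(config.missing_rates.get("genotype_loci", 0.0) * config.n_loci))
    missing_prone = list(rng.choice(loci, size=n_missing_loci, replace=False)) if n_missing_loci else []
    genotype_table = generate_genotype_calls(
        config.n_hybrids,
        config.n_loci,
        missing_rate=0.85 if missing_prone else 0.0,
        seed=seeds[1],
        missing_marker=config.missing_marker,
        missing_loci=missing_prone,
    )
    from .genotype import encode_calls  # deferred: avoids cycle at import time

    dosages = encode_calls(genotype_table, missing_marker=config.missing_marker)
    complete_loci = [c for c in dosages.columns if not dosages[c].isna().any()]
    dosage_filled = dosages.fillna(0.0)

    # --- ground truth ----------------------------------------------------
    eff = config.effect_sizes
    state_effects = dict(zip(states, np.round(rng.normal(0, eff.state_sd, size=len(states)), 4)))
    n_causal = min(eff.n_causal_loci, len(complete_loci))
    causal = list(rng.choice(complete_loci, size=n_causal, replace=False))
    signs = np.where(np.arange(n_causal) % 2 == 0, 1.0, -1.0)
    locus_effects = {c: float(eff.locus_effect * s) for c, s in zip(causal, signs)}
    truth = {
        "baseline_yield": config.baseline_yield,
        "state_effects": state_effects,
        "locus_effects": locus_effects,
        "treatment_offsets": dict(eff.treatment_offsets),
        "planting_window": tuple(config.planting_window),
        "planting_penalty_per_day": eff.planting_penalty_per_day,
        "noise_sd": eff.noise_sd,
        "missing_prone_loci": missing_prone,
    }

    # --- trial design ----------------------------------------------------
    treatments = list(config.treatment_classes)
    probs = np.full(len(treatments), 0.5 / max(1, len(treatments) - 1))
    if "standard" in treatments:
        probs[treatments.index("standard")] = 0.5
    probs = probs / probs.sum()
    w0, w1 = config.planting_window

    design_rows = []
    hybrids = list(genotype_table.index)
    for _, env in env_rows.iterrows():
        tr = treatments[rng.choice(len(treatments), p=probs)]
        if tr == "late planting":
            doy = int(rng.integers(w1 + 10, w1 + 50))
        elif tr == "early planting":
            doy = int(rng.integers(max(1, w0 - 25), w0))
        else:
            doy = int(rng.integers(w0, w1 + 1))
        chosen = rng.choice(hybrids, size=min(config.hybrids_per_env, len(hybrids)), replace=False)
        for h in chosen:
            design_rows.append(
                {"Env": env["Env"], "location": env["location"], "state": env["state"],
                 "year": env["year"], "Hybrid": h, "treatment": tr, "planting_doy": doy}
            )
    design = pd.DataFrame(design_rows)
    design["yield"] = np.round(inject_yield(truth, design, dosage_filled, seed=seeds[2]), 4)

    trait_table = design[["Env", "Hybrid", "yield"]].copy()

    # --- metadata --------------------------------------------------------
    env_treat = design.drop_duplicates("Env")[["Env", "treatment", "planting_doy", "year"]]
    meta = env_rows.merge(env_treat[["Env", "treatment", "planting_doy"]], on="Env", how="left")
    start = pd.to_datetime(meta["year"].astype(str) + "-01-01")
    meta["planting_date"] = (start + pd.to_timedelta(meta["planting_doy"].fillna(w0) - 1, unit="D")).dt.strftime("%Y-%m-%d")
    issue_keys = list(ISSUE_COMMENTS)
    meta["issue_comment"] = [ISSUE_COMMENTS[issue_keys[i]] for i in rng.choice(len(issue_keys), size=len(meta))]
    meta_rate = config.missing_rates.get("metadata", 0.0)
    if meta_rate > 0:
        mask = rng.random(len(meta)) < meta_rate
        meta.loc[mask, "treatment"] = np.nan
    metadata_table = meta[["Env", "location", "state", "year", "treatment", "planting_date", "issue_comment"]]

    # --- environment tables ---------------------------------------------
    weather_table = _daily_weather(np.random.default_rng(seeds[3]), env_rows, config.n_days)
    soil_table = _soil_table(np.random.default_rng(seeds[4]), env_rows, config.missing_rates.get("soil", 0.0))
    envsim_table = _envsim_table(
        np.random.default_rng(seeds[5]), env_rows, state_effects, config.missing_rates.get("envsim", 0.0)
    )

    return RawDataset(
        trait_table=trait_table,
        metadata_table=metadata_table,
        weather_table=weather_table,
        soil_table=soil_table,
        envsim_table=envsim_table,
        genotype_table=genotype_table.reset_index(),
        truth=truth,
    )


def write_dataset(raw: RawDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the six tables as headered CSV files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in raw.tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        paths[name] = p
    return paths


def genotype_to_vcf(genotype_table: pd.DataFrame, path: str | Path, missing_marker: str = "./.") -> Path:
    """Write the call-string table as a minimal VCF whose GT field carries the calls.

    Loci become rows on a single synthetic contig; hybrids become sample
    columns. Only the GT subfield is meaningful.
    """
    table = genotype_table.set_index("Hybrid") if "Hybrid" in genotype_table.columns else genotype_table
    hybrids = list(table.index)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=synthetic_1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(hybrids) + "\n")
        for pos, locus in enumerate(table.columns, start=1):
            calls = ["." if c == missing_marker else str(c).replace("/", "|") for c in table[locus]]
            calls = [c.replace("|", "/") for c in calls]  # keep unphased convention
            fh.write(f"synthetic_1\t{pos}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")
    return path
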