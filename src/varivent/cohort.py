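"""Synthetic study cohorts and the end-to-end pipeline driver.

The cohort generator emulates the study design: one non-ventilated control
group (NV) plus four ventilated groups (n = 7 each) labelled by the nominal
CV of tidal volume (0, 15, 22.5, 30%). Cardiorespiratory variables are drawn
per animal from Gaussian group distributions at BASELINE and END with a
configurable within-animal correlation; morphometry samples and qPCR Ct
tables are generated from per-group targets. ``run_study`` chains
vtgen -> simulator -> mechanics -> morphometry -> qpcr -> stats and emits
report tables shaped like the study's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from varivent import morphometry, qpcr, stats
from varivent.mechanics import fit_equation_of_motion
from varivent.simulator import LungModel, simulate
from varivent.vtgen import VentilationPlan, generate_vt_sequence

__all__ = [
    "GroupSpec",
    "EchoRecord",
    "default_group_specs",
    "generate_cohort",
    "pat_pet_ratio",
    "run_study",
    "StageError",
]

TIMEPOINTS = ("BASELINE", "END")

#: variables that cannot be negative (draws are truncated at zero)
NONNEGATIVE_VARS = frozenset(
    {"VT", "CV_VT", "VE", "E", "R", "PEEP", "PaO2", "PaCO2", "HCO3", "HR", "MAP",
     "IVC", "RA", "RV_area", "PAT", "PET", "LV_area", "EF", "FS"}
)

# (BASELINE mean, BASELINE SD, END mean, END SD) per ventilated group;
# study summary values for respiratory, gas-exchange, and echo variables.
_VENT_DEFAULTS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "VV_0": {
        "VT": (6.0, 0.0, 6.0, 0.1),
        "CV_VT": (2.5, 1.9, 1.6, 0.3),
        "VE": (149.5, 2.9, 149.7, 2.1),
        "E": (3.2, 0.5, 3.6, 0.3),
        "R": (0.21, 0.04, 0.18, 0.01),
        "PEEP": (3.2, 0.3, 3.2, 0.3),
        "PaO2": (139, 37, 176, 21),
        "HR": (367, 75, 351, 67),
        "MAP": (116, 43, 129, 17),
        "RV_area": (0.34, 0.06, 0.28, 0.05),
        "PAT": (20.7, 8.6, 28.9, 9.8),
        "PET": (65.1, 18.9, 65.0, 16.7),
        "LV_area": (0.14, 0.04, 0.20, 0.05),
        "EF": (95.2, 3.9, 92.1, 5.4),
        "FS": (67.8, 9.2, 61.7, 12.3),
    },
    "VV_15": {
        "VT": (6.0, 0.0, 6.0, 0.0),
        "CV_VT": (1.2, 0.5, 15.4, 0.9),
        "VE": (150.4, 1.9, 153.1, 7.6),
        "E": (3.3, 0.4, 3.2, 0.3),
        "R": (0.20, 0.03, 0.18, 0.04),
        "PEEP": (3.2, 0.2, 3.2, 0.1),
        "PaO2": (134, 38, 191, 18),
        "HR": (351, 60, 357, 52),
        "MAP": (132, 17, 105, 24),
        "RV_area": (0.38, 0.07, 0.39, 0.11),
        "PAT": (22.3, 7.5, 33.3, 12.1),
        "PET": (69.0, 14.5, 61.6, 13.4),
        "LV_area": (0.12, 0.03, 0.13, 0.04),
        "EF": (95.1, 2.3, 89.5, 7.3),
        "FS": (66.4, 6.3, 54.4, 12.8),
    },
    "VV_22.5": {
        "VT": (6.0, 0.1, 6.0, 0.1),
        "CV_VT": (1.6, 0.7, 23.4, 1.3),
        "VE": (149.8, 2.3, 150.9, 3.6),
        "E": (3.2, 0.6, 2.8, 0.2),
        "R": (0.18, 0.02, 0.16, 0.01),
        "PEEP": (3.2, 0.2, 3.3, 0.3),
        "PaO2": (133, 34, 179, 26),
        "HR": (411, 66, 371, 60),
        "MAP": (133, 39, 106, 36),
        "RV_area": (0.34, 0.07, 0.33, 0.05),
        "PAT": (19.2, 5.4, 25.2, 5.5),
        "PET": (62.0, 8.5, 56.9, 9.3),
        "LV_area": (0.16, 0.08, 0.19, 0.10),
        "EF": (95.7, 3.4, 95.3, 1.9),
        "FS": (68.7, 9.2, 66.1, 5.2),
    },
    "VV_30": {
        "VT": (6.0, 0.1, 6.1, 0.1),
        "CV_VT": (1.4, 0.6, 28.8, 2.1),
        "VE": (149.9, 2.3, 151.8, 4.9),
        "E": (3.0, 0.6, 2.4, 0.2),
        "R": (0.19, 0.02, 0.17, 0.02),
        "PEEP": (3.0, 0.4, 3.1, 0.3),
        "PaO2": (134, 37, 173, 20),
        "HR": (348, 46, 319, 89),
        "MAP": (115, 26, 118, 22),
        "RV_area": (0.37, 0.07, 0.46, 0.12),
        "PAT": (22.6, 7.8, 17.3, 8.3),
        "PET": (68.8, 9.6, 58.1, 13.6),
        "LV_area": (0.13, 0.04, 0.16, 0.08),
        "EF": (93.2, 6.6, 87.9, 9.2),
        "FS": (64.4, 13.2, 55.9, 14.3),
    },
}

# (Lm mean um, Lm SD um, homogeneity-index target) per group
_MORPHO_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "NV": (96, 10, 0.66),
    "VV_0": (89, 13, 0.70),
    "VV_15": (89, 13, 0.78),
    "VV_22.5": (70, 6, 0.85),
    "VV_30": (88, 15, 0.76),
}

# mean ddCt shift vs NV per gene (negative = up-regulated); shaped to the
# qualitative expression pattern reported across groups
_DDCT_DEFAULTS: dict[str, dict[str, float]] = {
    "NV": {},
    "VV_0": {"CINC-1": -1.5, "IL-1b": -0.5},
    "VV_15": {"CINC-1": -1.3},
    "VV_22.5": {"IL-10": -1.2, "CC16": -1.0, "SP-C": -0.8},
    "VV_30": {"IL-6": -1.4, "CINC-1": -1.2, "SP-D": -1.3, "SP-C": -1.0},
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class GroupSpec:
    """Generation parameters for one study group."""

    name: str
    variables: dict = field(default_factory=dict)  # var -> (mB, sB, mE, sE)
    lm_mean: float = 90.0
    lm_sd: float = 12.0
    beta_inv_target: float = 0.75
    ddct_shifts: dict = field(default_factory=dict)  # gene -> mean ddCt vs NV
    nominal_cv_pct: float | None = None  # None for the non-ventilated group
    n_animals: int = 7

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        for var, (mb, sb, me, se) in self.variables.items():
            if sb < 0 or se < 0:
                raise ValueError(f"negative SD requested for {var!r}")
        if not 0 < self.beta_inv_target <= 1:
            raise ValueError("beta_inv_target must be in (0, 1]")

    @property
    def ventilated(self) -> bool:
        return self.nominal_cv_pct is not None


@dataclass(frozen=True)
class EchoRecord:
    """One echocardiographic assessment."""

    animal_id: str
    timepoint: str
    pat: float  # ms
    pet: float  # ms
    rv_area: float | None = None  # cm^2
    lv_area: float | None = None
    ef: float | None = None  # %
    fs: float | None = None
    ivc: float | None = None  # cm
    ra: float | None = None
    hr: float | None = None  # bpm
    map: float | None = None  # mmHg

    def __post_init__(self) -> None:
        if self.pat <= 0 or self.pet <= 0:
            raise ValueError("PAT and PET must be > 0")

    @property
    def pat_pet(self) -> float:
        return pat_pet_ratio(self)


def pat_pet_ratio(record) -> float:
    """Pulmonary acceleration-to-ejection time ratio PAT/PET."""
    pat = record.pat if hasattr(record, "pat") else record[0]
    pet = record.pet if hasattr(record, "pet") else record[1]
    if pet <= 0:
        raise ValueError(f"PET must be > 0, got {pet}")
    return pat / pet


def default_group_specs(n_animals: int = 7) -> list[GroupSpec]:
    """The five study groups with their tabulated summary statistics."""
    specs = [
        GroupSpec(
            name="NV",
            lm_mean=_MORPHO_DEFAULTS["NV"][0],
            lm_sd=_MORPHO_DEFAULTS["NV"][1],
            beta_inv_target=_MORPHO_DEFAULTS["NV"][2],
            ddct_shifts=_DDCT_DEFAULTS["NV"],
            n_animals=n_animals,
        )
    ]
    for name, cv in (("VV_0", 0.0), ("VV_15", 15.0), ("VV_22.5", 22.5), ("VV_30", 30.0)):
        lm_mean, lm_sd, binv = _MORPHO_DEFAULTS[name]
        specs.append(
            GroupSpec(
                name=name,
                variables=dict(_VENT_DEFAULTS[name]),
                lm_mean=lm_mean,
                lm_sd=lm_sd,
                beta_inv_target=binv,
                ddct_shifts=_DDCT_DEFAULTS[name],
                nominal_cv_pct=cv,
                n_animals=n_animals,
            )
        )
    return specs


def _diameter_cv_for_beta_inv(beta_inv: float) -> float:
    """Within-animal diameter CV whose gamma-sample homogeneity index is beta_inv.

    Uses the minimal-skew gamma family (skew = 2 cv), for which
    1/beta = (1 + cv^2) / (1 + 3 cv^2 + 2 cv^4).
    """
    if beta_inv >= 1.0:
        return 0.0
    f = lambda cv: (1 + cv**2) / (1 + 3 * cv**2 + 2 * cv**4) - beta_inv
    return float(brentq(f, 1e-6, 3.0))


def _draw_pair(rng, mb, sb, me, se, corr, nonneg):
    """Correlated (BASELINE, END) Gaussian draw, optionally truncated at 0."""
    cov = np.array([[sb**2, corr * sb * se], [corr * sb * se, se**2]])
    for _ in range(1000):
        b, e = rng.multivariate_normal([mb, me], cov)
        if not nonneg or (b >= 0 and e >= 0):
            return float(b), float(e)
    raise ValueError("could not draw non-negative values; check mean/SD request")


def generate_cohort(
    specs: list[GroupSpec] | None = None,
    seed: int = 0,
    baseline_end_corr: float = 0.7,
) -> pd.DataFrame:
    """Draw a full synthetic cohort as a long-format table.

    Columns: ``animal_id, group, timepoint, variable, value``. Ventilated
    groups carry all cardiorespiratory variables at both timepoints; the NV
    group contributes only morphometry and qPCR records (generated
    separately by :func:`run_study`), mirroring the study design.
    """
    if specs is None:
        specs = default_group_specs()
    if not specs:
        raise ValueError("need at least one group spec")
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        for i in range(spec.n_animals):
            animal = f"{spec.name}-{i + 1:02d}"
            for var, (mb, sb, me, se) in sorted(spec.variables.items()):
                b, e = _draw_pair(rng, mb, sb, me, se, baseline_end_corr, var in NONNEGATIVE_VARS)
                rows.append((animal, spec.name, "BASELINE", var, b))
                rows.append((animal, spec.name, "END", var, e))
    return pd.DataFrame(rows, columns=["animal_id", "group", "timepoint", "variable", "value"])


def _generate_morphometry(specs, seed):
    rng = np.random.default_rng(seed)
    samples = []
    for spec in specs:
        cv = _diameter_cv_for_beta_inv(spec.beta_inv_target)
        for i in range(spec.n_animals):
            mu_i = max(float(rng.normal(spec.lm_mean, spec.lm_sd)), 10.0)
            samples.append(
                morphometry.generate_airspace_sample(
                    mu_target=mu_i,
                    cv_target=cv,
                    skew_target=2 * cv,
                    n=20,
                    seed=int(rng.integers(2**31)),
                    animal_id=f"{spec.name}-{i + 1:02d}",
                    group=spec.name,
                )
            )
    return samples


def _generate_ct_records(specs, seed, replicate_sd=0.15, animal_sd=0.5):
    rng = np.random.default_rng(seed)
    records = []
    base_dct = {g: 5.0 + 0.5 * k for k, g in enumerate(sorted(set(qpcr.GENES) - {qpcr.REFERENCE_GENE}))}
    for spec in specs:
        for i in range(spec.n_animals):
            animal = f"{spec.name}-{i + 1:02d}"
            ref_ct = float(rng.normal(20.0, 0.3))
            records.append(
                qpcr.CtRecord(
                    animal_id=animal,
                    group=spec.name,
                    gene=qpcr.REFERENCE_GENE,
                    ct_values=tuple(ref_ct + rng.normal(0, replicate_sd, 3)),
                )
            )
            for gene, dct0 in base_dct.items():
                shift = spec.ddct_shifts.get(gene, 0.0)
                dct = dct0 + shift + float(rng.normal(0, animal_sd))
                target_ct = ref_ct + dct
                records.append(
                    qpcr.CtRecord(
                        animal_id=animal,
                        group=spec.name,
                        gene=gene,
                        ct_values=tuple(target_ct + rng.normal(0, replicate_sd, 3)),
                    )
                )
    return records


def _estimate_mechanics_for_cohort(table, specs, seed, n_breaths, noise_sd):
    """Replace tabulated E/R with estimates from simulated signals.

    For every ventilated animal and timepoint, the drawn (E, R) values are
    treated as ground truth, a tidal-volume sequence at the group's nominal
    CV is simulated, and the equation-of-motion estimates are written back.
    """
    rng = np.random.default_rng(seed)
    table = table.copy()
    idx = table.set_index(["animal_id", "timepoint", "variable"])["value"]
    for spec in specs:
        if not spec.ventilated:
            continue
        for i in range(spec.n_animals):
            animal = f"{spec.name}-{i + 1:02d}"
            for tp in TIMEPOINTS:
                cv = spec.nominal_cv_pct if tp == "END" else 0.0
                try:
                    e_true = float(idx[(animal, tp, "E")])
                    r_true = float(idx[(animal, tp, "R")])
                    peep = float(idx[(animal, tp, "PEEP")])
                except KeyError:
                    continue
                plan = VentilationPlan(
                    mean_vt=6.0,
                    cv_pct=cv,
                    n_breaths=n_breaths,
                    seed=int(rng.integers(2**31)),
                )
                seq = generate_vt_sequence(plan)
                model = LungModel(
                    E=e_true, R=r_true, p0=peep, noise_sd=noise_sd, seed=int(rng.integers(2**31))
                )
                signal = simulate(seq, model, plan, sampling_hz=200.0)
                fit = fit_equation_of_motion(signal)
                mask = (
                    (table["animal_id"] == animal)
                    & (table["timepoint"] == tp)
                    & (table["variable"].isin(["E", "R"]))
                )
                table.loc[mask & (table["variable"] == "E"), "value"] = fit.E_hat
                table.loc[mask & (table["variable"] == "R"), "value"] = fit.R_hat
    return table


def _summary_table(table, variables):
    """Mean +/- SD per group x timepoint, shaped like the study tables."""
    sub = table[table["variable"].isin(variables)]
    agg = (
        sub.groupby(["variable", "timepoint", "group"])["value"]
        .agg(["mean", "std"])
        .reset_index()
    )
    agg["mean_sd"] = agg.apply(lambda r: f"{r['mean']:.3g} ± {r['std']:.2g}", axis=1)
    return agg.pivot(index=["variable", "timepoint"], columns="group", values="mean_sd")


def run_study(config: dict | None = None, out_dir=None) -> dict:
    """Run the full synthetic study and return the report bundle.

    Config keys (all optional): ``seed``, ``n_animals``, ``stages`` (dict of
    booleans: mechanics, morphometry, qpcr, stats), ``n_breaths_sim``
    (breaths simulated per animal/timepoint for mechanics estimation),
    ``mechanics_noise_sd``, ``baseline_end_corr``, ``cohort_table`` (path to
    a user-supplied long-format CSV that replaces the synthetic cohort).

    Returns a dict of DataFrames and result dicts; if ``out_dir`` is given,
    CSV tables and a JSON of all comparisons are written there.
    """
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    n_animals = int(config.get("n_animals", 7))
    stages = {"mechanics": True, "morphometry": True, "qpcr": True, "stats": True}
    stages.update(config.get("stages", {}))
    n_breaths_sim = int(config.get("n_breaths_sim", 30))
    noise_sd = float(config.get("mechanics_noise_sd", 0.2))
    corr = float(config.get("baseline_end_corr", 0.7))

    specs = default_group_specs(n_animals=n_animals)
    bundle: dict = {"config": {"seed": seed, "n_animals": n_animals, "stages": stages}}

    try:
        if "cohort_table" in config:
            table = pd.read_csv(config["cohort_table"])
        else:
            table = generate_cohort(specs, seed=seed, baseline_end_corr=corr)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"cohort generation failed: {exc}") from exc

    if stages["mechanics"]:
        try:
            table = _estimate_mechanics_for_cohort(
                table, specs, seed=seed + 1, n_breaths=n_breaths_sim, noise_sd=noise_sd
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"mechanics stage failed: {exc}") from exc

    bundle["cohort"] = table
    resp_vars = ["VT", "CV_VT", "VE", "E", "R", "PEEP", "PaO2"]
    echo_vars = ["HR", "MAP", "RV_area", "PAT", "PET", "LV_area", "EF", "FS"]
    bundle["table1"] = _summary_table(table, resp_vars)
    bundle["table2"] = _summary_table(table, echo_vars)

    results: dict = {}
    if stages["morphometry"]:
        try:
            samples = _generate_morphometry(specs, seed=seed + 2)
            morpho = morphometry.morphometry_table(samples)
            bundle["table3"] = morpho
            if stages["stats"]:
                for col in ("lm", "d2", "beta_inv"):
                    grouped = [g[col].to_numpy() for _, g in morpho.groupby("group")]
                    labels = [name for name, _ in morpho.groupby("group")]
                    res = stats.one_way_anova(grouped, labels=labels)
                    results[f"morphometry_{col}"] = {
                        "F": res["F"],
                        "p": res["p"],
                        "pairwise": [c.to_dict() for c in res["pairwise"]],
                    }
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"morphometry stage failed: {exc}") from exc

    if stages["qpcr"]:
        try:
            records = _generate_ct_records(specs, seed=seed + 3)
            folds = qpcr.fold_change_table(records)
            bundle["fold_changes"] = folds
            if stages["stats"]:
                for gene, sub in folds.groupby("gene"):
                    grouped = [g["fold"].to_numpy() for _, g in sub.groupby("group")]
                    labels = [name for name, _ in sub.groupby("group")]
                    res = stats.kruskal_dunn(grouped, labels=labels)
                    results[f"qpcr_{gene}"] = {
                        "H": res["H"],
                        "p": res["p"],
                        "pairwise": [c.to_dict() for c in res["pairwise"]],
                    }
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"qpcr stage failed: {exc}") from exc

    if stages["stats"]:
        try:
            for dv in ("E", "R", "PAT", "PET", "RV_area", "PaO2"):
                res = stats.rm_anova_two_way(table, dv)
                results[f"rm_anova_{dv}"] = {
                    "anova": res["anova"],
                    "posthoc": [c.to_dict() for c in res["posthoc"]],
                }
            bundle["table4"] = stats.percent_change_table(
                table, variables=["E", "PAT", "PET", "RV_area", "PaO2"]
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stats stage failed: {exc}") from exc

    bundle["comparisons"] = results

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["cohort"].to_csv(out / "cohort.csv", index=False)
        bundle["table1"].to_csv(out / "table1.csv")
        bundle["table2"].to_csv(out / "table2.csv")
        if "table3" in bundle:
            bundle["table3"].to_csv(out / "table3.csv", index=False)
        if "table4" in bundle:
            bundle["table4"].to_csv(out / "table4.csv")
        if "fold_changes" in bundle:
            bundle["fold_changes"].to_csv(out / "fold_changes.csv", index=False)
        with open(out / "comparisons.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
    return bundle
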