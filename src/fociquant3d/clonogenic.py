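"""Clonogenic survival analysis.

A clonogenic assay plates known numbers of single cells, exposes them to a
dose series (ionizing radiation in Gy or a drug in µM) and counts the
colonies of at least 50 cells.  Plating efficiency (PE) is the colony
fraction under control conditions; relative survival at dose D is the colony
fraction at D divided by PE, so S(0) = 1 by construction.  Within an
experiment each dose is plated at two cell densities whose survival
estimates are averaged with equal weight; curves aggregate experiments as
mean ± SEM, and genotypes are compared per dose with a one-tailed paired
Student t-test (pairing by experiment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stats import two_sample_t

REQUIRED_COLUMNS = {"experiment", "dose", "cells_plated", "colonies"}


def plating_efficiency(colonies: float, cells_plated: float) -> float:
    """Fraction of plated single cells that formed a >= 50-cell colony."""
    if cells_plated <= 0:
        raise ValueError("cells_plated must be positive")
    if colonies < 0 or colonies > cells_plated:
        raise ValueError("colonies must be in [0, cells_plated]")
    return colonies / cells_plated


@dataclass
class SurvivalCurve:
    genotype: str
    agent: str
    #: per-experiment survival estimates: columns experiment, dose, survival
    per_experiment: pd.DataFrame
    #: aggregated curve: columns dose, mean_survival, sem_survival, n
    summary: pd.DataFrame
    #: plating efficiency per experiment id
    plating_efficiency: dict


def _validate_table(table: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"colony table missing columns {sorted(missing)}")
    if (table["dose"] < 0).any():
        raise ValueError("doses must be >= 0")
    if (table["colonies"] > table["cells_plated"]).any():
        raise ValueError("colonies cannot exceed cells_plated")


def relative_survival(table: pd.DataFrame) -> SurvivalCurve:
    """Dose-response survival relative to the untreated control.

    Within each experiment the plating efficiency is the mean dose-0 colony
    fraction over the plated densities; survival per dose is the mean over
    densities of (colony fraction)/PE.  Experiments are aggregated by mean ±
    SEM per dose.  Survival is invariant under proportional rescaling of all
    counts, and S(0) = 1 exactly.
    """
    _validate_table(table)
    genotype = str(table["genotype"].iloc[0]) if "genotype" in table else ""
    agent = str(table["agent"].iloc[0]) if "agent" in table else ""
    rows = []
    pes: dict = {}
    for exp_id, grp in table.groupby("experiment"):
        ctrl = grp[grp["dose"] == 0]
        if ctrl.empty:
            raise ValueError(f"experiment {exp_id!r} lacks a dose-0 control")
        pe = float((ctrl["colonies"] / ctrl["cells_plated"]).mean())
        if pe <= 0:
            raise ValueError(f"experiment {exp_id!r} has zero plating efficiency")
        pes[exp_id] = pe
        for dose, dgrp in grp.groupby("dose"):
            # mean colony fraction over densities divided once by PE: equal to
            # the mean of per-density survival ratios, and exactly 1 at dose 0
            s = float((dgrp["colonies"] / dgrp["cells_plated"]).mean() / pe)
            rows.append({"experiment": exp_id, "dose": float(dose), "survival": s})
    per_exp = pd.DataFrame(rows)
    agg = (
        per_exp.groupby("dose")["survival"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_survival", "sem": "sem_survival", "count": "n"})
    )
    return SurvivalCurve(genotype, agent, per_exp, agg, pes)


def compare_survival(
    curve_a: SurvivalCurve,
    curve_b: SurvivalCurve,
    alternative: str = "greater",
    include_dose0: bool = False,
) -> pd.DataFrame:
    """Per-dose one-tailed paired Student t-test between two survival curves.

    Experiments are paired by id across the two curves.  The default
    ``alternative='greater'`` tests whether curve A survives better than
    curve B at each dose (the direction is a config flag, not a result).
    """
    a = curve_a.per_experiment.pivot(index="experiment", columns="dose",
                                     values="survival")
    b = curve_b.per_experiment.pivot(index="experiment", columns="dose",
                                     values="survival")
    common_exp = a.index.intersection(b.index)
    if len(common_exp) < 2:
        raise ValueError("need >= 2 paired experiments")
    doses = sorted(set(a.columns) & set(b.columns))
    rows = []
    for dose in doses:
        if dose == 0 and not include_dose0:
            continue
        res = two_sample_t(
            a.loc[common_exp, dose], b.loc[common_exp, dose],
            tails=1, paired=True, alternative=alternative,
        )
        rows.append(
            {"dose": dose, "statistic": res.statistic, "df": res.df, "p": res.p}
        )
    return pd.DataFrame(rows)


def fit_lq(curve: SurvivalCurve) -> tuple[float, float]:
    """Least-squares linear-quadratic fit S(D) = exp(-αD - βD²).

    An extension beyond the raw curves; fitted on the per-experiment survival
    points with non-negativity bounds.
    """
    d = curve.per_experiment["dose"].to_numpy(float)
    s = curve.per_experiment["survival"].to_numpy(float)

    def model(dd, alpha, beta):
        return np.exp(-alpha * dd - beta * dd**2)

    popt, _ = curve_fit(model, d, s, p0=(0.1, 0.01),
                        bounds=([0.0, 0.0], [10.0, 10.0]), maxfev=10000)
    return float(popt[0]), float(popt[1])


def expected_survival(alpha: float, beta: float, dose: float) -> float:
    """Closed-form LQ survival exp(-αD - βD²)."""
    return math.exp(-alpha * dose - beta * dose**2)
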