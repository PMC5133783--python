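"""Orchestration: figure-level experiments on synthetic data.

``run_foci_experiment`` reproduces the structure of the imaging figures
(mean ± SEM γH2AX foci per selected cell and SMC6-positive fraction per
time point, with WT-vs-null t-tests at both the cell level and the
experiment level).  ``run_full_demo`` exercises every stage end to end on
freshly generated synthetic data.  All randomness flows from a single master
seed through spawned child seeds, so reports rerun bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonogenic, crispr, foci, synthetic
from .cellcycle import colcemid_depletion, division_stats, phase_fractions
from .imaging import make_gaussian_psf, richardson_lucy
from .stats import holm, two_sample_t

#: Sampling time points after damage induction used for quantitative imaging.
DEFAULT_TIMEPOINTS = ("0min", "30min", "3h", "6h")
#: Order-of-magnitude WT mean γH2AX foci per nucleus at each time point
#: (damage appears immediately and is progressively resolved).
DEFAULT_FOCI_MEANS = {"0min": 14.0, "30min": 11.0, "3h": 7.0, "6h": 4.0}


@dataclass
class ExperimentConfig:
    """Stage toggles and parameters for a foci experiment."""

    seed: int = 0
    n_experiments: int = 3
    timepoints: tuple = DEFAULT_TIMEPOINTS
    foci_means: dict = field(default_factory=lambda: dict(DEFAULT_FOCI_MEANS))
    null_foci_fold: float = 1.0  # >1 emulates an etoposide-like excess in the null line
    coloc_prob: float = 0.5
    treatment: str = "IR"
    n_nuclei_per_stack: int = 6
    stack_shape: tuple = (42, 256, 384)
    nucleus_radii_um: tuple = (1.6, 2.8, 2.8)
    noise: bool = True
    deconvolve: bool = False
    deconvolve_max_iter: int = 40
    psf_sigma_xy_um: float = 0.1
    psf_sigma_z_um: float = 0.3
    min_voxels_gh2ax: int = foci.MIN_VOXELS_GH2AX
    min_voxels_smc6: int = foci.MIN_VOXELS_SMC6
    threshold_method: str = "mean_sd"
    k_sd: float = 3.0
    selection_min_smc6: int = foci.SELECTION_MIN_SMC6

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(d["timepoints"])
        d["stack_shape"] = list(d["stack_shape"])
        d["nucleus_radii_um"] = list(d["nucleus_radii_um"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        if "timepoints" in kwargs:
            kwargs["timepoints"] = tuple(kwargs["timepoints"])
        if "stack_shape" in kwargs:
            kwargs["stack_shape"] = tuple(kwargs["stack_shape"])
        if "nucleus_radii_um" in kwargs:
            kwargs["nucleus_radii_um"] = tuple(kwargs["nucleus_radii_um"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _analyze_stack(stack, config: ExperimentConfig):
    data = stack.data
    if config.deconvolve:
        psf = make_gaussian_psf(
            config.psf_sigma_xy_um, config.psf_sigma_z_um, stack.voxel_size_nm
        )
        data = data.copy()
        for ci, snr in ((1, 10.0), (2, 12.0)):
            data[ci] = richardson_lucy(
                data[ci], psf, max_iter=config.deconvolve_max_iter, snr=snr
            )
    mask = foci.segment_nuclei(data[0])
    gh = foci.detect_foci(
        data[1], mask, config.min_voxels_gh2ax, channel_name="gH2AX",
        threshold_method=config.threshold_method, k_sd=config.k_sd,
        voxel_size_nm=stack.voxel_size_nm,
    )
    smc = foci.detect_foci(
        data[2], mask, config.min_voxels_smc6, channel_name="SMC6",
        threshold_method=config.threshold_method, k_sd=config.k_sd,
        voxel_size_nm=stack.voxel_size_nm,
    )
    return foci.per_cell_records(mask, gh, smc, config.selection_min_smc6)


def run_foci_experiment(config: ExperimentConfig) -> dict:
    """Per-time-point condition summaries plus WT-vs-null tests.

    Each of ``n_experiments`` biological replicates contributes one phantom
    stack per genotype and time point.  Cell-level tests pool cells across
    experiments (two-tailed unpaired Student t on per-cell γH2AX counts);
    experiment-level tests compare the per-experiment means (n =
    n_experiments per genotype).  A Holm-adjusted column accompanies the raw
    per-time-point cell-level p-values.
    """
    ss = np.random.SeedSequence(config.seed)
    genotypes = {"WT": 1.0, "null": config.null_foci_fold}
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "timepoints": {},
    }
    cell_ps = []
    for tp in config.timepoints:
        mean_foci = config.foci_means[tp]
        tp_entry: dict = {}
        cells: dict[str, list] = {g: [] for g in genotypes}
        exp_means: dict[str, list] = {g: [] for g in genotypes}
        for genotype, fold in genotypes.items():
            for _ in range(config.n_experiments):
                child = ss.spawn(1)[0]
                params = synthetic.FociPhantomParams(
                    stack_shape=config.stack_shape,
                    n_nuclei=config.n_nuclei_per_stack,
                    nucleus_radii_um=config.nucleus_radii_um,
                    n_gh2ax_per_nucleus=("poisson", mean_foci * fold),
                    coloc_prob=config.coloc_prob,
                    noise=config.noise,
                    seed=child,
                )
                stack, _ = synthetic.gen_foci_stack(params)
                records = _analyze_stack(stack, config)
                selected = [r for r in records if r.selected]
                cells[genotype].extend(selected)
                if selected:
                    exp_means[genotype].append(
                        float(np.mean([r.n_gh2ax for r in selected]))
                    )
            summary = foci.summarize_condition(
                cells[genotype], genotype=genotype, treatment=config.treatment,
                timepoint=tp,
            )
            tp_entry[genotype] = dataclasses.asdict(summary)
        wt_counts = [r.n_gh2ax for r in cells["WT"]]
        null_counts = [r.n_gh2ax for r in cells["null"]]
        cell_t = two_sample_t(null_counts, wt_counts, tails=2, paired=False)
        tp_entry["cell_level"] = {"t": cell_t.statistic, "df": cell_t.df,
                                  "p": cell_t.p, "n": [len(null_counts), len(wt_counts)]}
        cell_ps.append(cell_t.p)
        if min(len(exp_means["WT"]), len(exp_means["null"])) >= 2:
            exp_t = two_sample_t(exp_means["null"], exp_means["WT"],
                                 tails=2, paired=False)
            tp_entry["experiment_level"] = {
                "t": exp_t.statistic, "df": exp_t.df, "p": exp_t.p,
                "n": [len(exp_means["null"]), len(exp_means["WT"])],
            }
        wt_fr = [r.frac_smc6_positive for r in cells["WT"]
                 if r.frac_smc6_positive is not None]
        null_fr = [r.frac_smc6_positive for r in cells["null"]
                   if r.frac_smc6_positive is not None]
        if len(wt_fr) >= 2 and len(null_fr) >= 2:
            fr_t = two_sample_t(null_fr, wt_fr, tails=2, paired=False)
            tp_entry["cell_level_frac"] = {"t": fr_t.statistic, "p": fr_t.p}
        report["timepoints"][tp] = tp_entry
    adj = holm(cell_ps)
    for tp, p_adj in zip(config.timepoints, adj):
        report["timepoints"][tp]["cell_level"]["p_holm"] = float(p_adj)
    return report


def _save_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def run_full_demo(master_seed: int = 0, out_dir=None, verbose: bool = False) -> dict:
    """Run every stage on freshly generated synthetic data.

    Stages: phantom imaging experiment (4 time points, 3 replicate
    experiments, 2 genotypes), a deconvolution on/off robustness check on one
    stack, clonogenic curves for an etoposide-like agent, colcemid
    depletion and division-interval statistics, and the Surveyor arithmetic
    on a synthetic edited-locus template.  Completes in a few minutes on one
    CPU at the default sizes.
    """
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.spawn(6)
    out = Path(out_dir) if out_dir is not None else None
    report: dict = {"master_seed": master_seed}

    def log(msg):
        if verbose:
            print(msg, flush=True)

    # --- imaging experiment -------------------------------------------------
    log("foci experiment ...")
    config = ExperimentConfig(seed=int(seeds[0].generate_state(1)[0] % 2**31),
                              null_foci_fold=1.5, treatment="etoposide")
    foci_report = run_foci_experiment(config)
    report["foci_experiment"] = foci_report

    # --- deconvolution robustness -------------------------------------------
    log("deconvolution check ...")
    params = synthetic.FociPhantomParams(
        stack_shape=(42, 224, 336), n_nuclei=6, seed=seeds[1]
    )
    stack, _ = synthetic.gen_foci_stack(params)
    cfg_off = ExperimentConfig(deconvolve=False)
    cfg_on = ExperimentConfig(deconvolve=True)
    n_off = sum(r.n_gh2ax for r in _analyze_stack(stack, cfg_off))
    n_on = sum(r.n_gh2ax for r in _analyze_stack(stack, cfg_on))
    rel_diff = abs(n_on - n_off) / max(n_off, 1)
    report["deconvolution_check"] = {
        "total_foci_raw": n_off, "total_foci_deconvolved": n_on,
        "relative_difference": rel_diff,
    }
    assert rel_diff <= 0.10, "deconvolution changed foci counts by more than 10%"

    # --- clonogenic ----------------------------------------------------------
    log("clonogenic ...")
    doses = [0.0, 7.5, 15.0, 30.0]
    plated = [200, 400, 800, 1600]
    t_wt = synthetic.gen_colony_counts(
        pe=0.75, alpha=0.05, beta=0.002, doses=doses, n_plated=plated,
        replicates=3, seed=seeds[2], genotype="WT", agent="etoposide",
    )
    t_null = synthetic.gen_colony_counts(
        pe=0.25, alpha=0.15, beta=0.004, doses=doses, n_plated=plated,
        replicates=3, seed=seeds[2].spawn(1)[0], genotype="null",
        agent="etoposide",
    )
    curve_wt = clonogenic.relative_survival(t_wt)
    curve_null = clonogenic.relative_survival(t_null)
    comparison = clonogenic.compare_survival(curve_wt, curve_null)
    assert (curve_wt.per_experiment.query("dose == 0")["survival"] == 1).all()
    report["clonogenic"] = {
        "pe_wt": float(np.mean(list(curve_wt.plating_efficiency.values()))),
        "pe_null": float(np.mean(list(curve_null.plating_efficiency.values()))),
        "wt_curve": curve_wt.summary.to_dict("records"),
        "null_curve": curve_null.summary.to_dict("records"),
        "paired_one_tailed_p": comparison.to_dict("records"),
    }

    # --- cell cycle ----------------------------------------------------------
    log("cell cycle ...")
    series_wt = synthetic.gen_colcemid_series(residual=0.02, seed=seeds[3],
                                              genotype="WT")
    series_null = synthetic.gen_colcemid_series(residual=0.16,
                                                seed=seeds[3].spawn(1)[0],
                                                genotype="null")
    fit_wt = colcemid_depletion(series_wt)
    fit_null = colcemid_depletion(series_null)
    pf = phase_fractions(series_wt[0])
    tracks_wt, tracks_null = synthetic.gen_division_tracks(seed=seeds[4])
    dstats = division_stats(tracks_wt, tracks_null)
    report["cellcycle"] = {
        "t0_phase_fractions": {"f_g01": pf.f_g01, "f_s": pf.f_s, "f_g2m": pf.f_g2m},
        "colcemid_residual_wt": fit_wt.residual_fraction,
        "colcemid_residual_null": fit_null.residual_fraction,
        "division_fold_change": dstats.fold_change,
        "division_p": dstats.test.p,
    }

    # --- CRISPR verification -------------------------------------------------
    log("crispr ...")
    template = synthetic.make_edited_template(seed=seeds[5])
    # representative Surveyor band intensities (synthetic densitometry)
    bands = {crispr.NSMCE2_SG1: (685.6, 157.2, 157.2),
             crispr.NSMCE2_SG2: (695.6, 152.2, 152.2)}
    surveyor = crispr.surveyor_report(
        template, [crispr.NSMCE2_SG1, crispr.NSMCE2_SG2],
        crispr.SURVEYOR_FWD_PRIMER, crispr.SURVEYOR_REV_PRIMER,
        band_intensities=bands,
    )
    report["crispr"] = surveyor
    assert surveyor["amplicon_length_bp"] == 417

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        _save_json(report, out / "demo_report.json")
        curve_wt.per_experiment.to_csv(out / "survival_wt.csv", index=False)
        curve_null.per_experiment.to_csv(out / "survival_null.csv", index=False)
        fit_null.table.to_csv(out / "colcemid_null.csv", index=False)
        _plot_demo(curve_wt, curve_null, fit_wt, fit_null, out)
    return report


def _plot_demo(curve_wt, curve_null, fit_wt, fit_null, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for curve, label in ((curve_wt, "WT"), (curve_null, "null")):
        axes[0].errorbar(curve.summary["dose"], curve.summary["mean_survival"],
                         yerr=curve.summary["sem_survival"], marker="o",
                         label=label)
    axes[0].set_yscale("log")
    axes[0].set_xlabel("dose")
    axes[0].set_ylabel("relative survival")
    axes[0].legend()
    for fit, label in ((fit_wt, "WT"), (fit_null, "null")):
        axes[1].plot(fit.table["time_h"], fit.table["f_g01"], marker="o",
                     label=f"{label} (r={fit.residual_fraction:.2f})")
    axes[1].set_xlabel("colcemid (h)")
    axes[1].set_ylabel("G0/1 fraction")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(out / "demo_summary.png", dpi=120)
    plt.close(fig)
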