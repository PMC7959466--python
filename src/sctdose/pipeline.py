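"""End-to-end orchestration of the validation workflow on synthetic cases.

Per case: generate a head phantom, produce a pseudo-CT (degrade-CT
surrogate by default, or the trained GAN), compute HU-class and DRR RMSE,
build the initial analytic SRT dose and a synthetic dose whose perturbation
magnitude is tied to the pseudo-CT HU error, run the gamma analyses and DVH
endpoint extraction, and aggregate the cohort with paired statistics. The
whole study is a pure function of its configuration (fixed master seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dosimetry, image_compare, stats
from .gamma import GammaCriteria, compute_gamma
from .grids import StructureRole, write_nifti
from .synthetic import (
    PerturbationSpec,
    PhantomSpec,
    Prescription,
    degrade_ct,
    make_head_phantom,
    make_srt_dose,
    perturb_dose,
)

__all__ = ["StudyConfig", "ComparisonReport", "run_study", "render_report", "default_criteria"]


def default_criteria() -> list[GammaCriteria]:
    """local+global × {2%/2 mm, 2%/1 mm, 1%/1 mm}, 10% threshold."""
    out = []
    for mode in ("local", "global"):
        for tol, dta in ((2.0, 2.0), (2.0, 1.0), (1.0, 1.0)):
            out.append(GammaCriteria(tol, dta, 0.10, mode))
    return out


@dataclass
class StudyConfig:
    """Study-level configuration.

    The degrade-CT surrogate perturbs each initial dose map by a world-space
    shift of ``shift_mm_per_hu × RMSE_soft`` millimetres, a dose rescaling of
    ``1 + scale_per_hu × RMSE_soft`` and additive Gaussian noise — a stand-in
    for a dose recalculation on the pseudo-CT whose error is known exactly.
    """

    n_cases: int = 10
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    criteria: list = field(default_factory=default_criteria)
    vx_thresholds_gy: tuple = (10.0, 18.0, 21.0)
    degrade_bias_hu: float = 10.0
    degrade_noise_hu: float = 10.0
    shift_mm_per_hu: float = 0.02
    scale_per_hu: float = 5e-4
    dose_noise_sd_gy: float = 0.05
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("StudyConfig: at least one case required")
        if not self.criteria:
            raise ValueError("StudyConfig: criteria list must be nonempty")


@dataclass
class ComparisonReport:
    """Aggregated per-case metrics and cohort statistics."""

    hu_rmse: pd.DataFrame  # per case: bone, soft-tissue, DRR RMSE
    gamma_per_case: pd.DataFrame  # per case x criteria passing rates
    gamma_summary: pd.DataFrame  # cohort mean/median/SD per criteria
    endpoint_table: pd.DataFrame  # per endpoint: initial, synthetic, diffs, p
    constraints: pd.DataFrame  # OAR constraint check on the initial dose
    dvh_curves: dict = field(default_factory=dict)  # case -> {label: DvhCurve}
    gamma_slices: dict = field(default_factory=dict)  # case -> central gamma slice

    def to_json(self) -> str:
        payload = {
            "hu_rmse": self.hu_rmse.to_dict(orient="list"),
            "gamma_per_case": self.gamma_per_case.to_dict(orient="list"),
            "gamma_summary": self.gamma_summary.to_dict(orient="list"),
            "endpoint_table": self.endpoint_table.to_dict(orient="list"),
            "constraints": self.constraints.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)


def _case_prescription(i: int) -> Prescription:
    return Prescription.pd2() if i % 2 else Prescription.pd1()


def _case_phantom_spec(base: PhantomSpec, i: int, seed: int) -> PhantomSpec:
    """Vary lesion size and position between cases, deterministically.

    Centers are drawn inside a shrunken copy of the brain ellipsoid so the
    lesion sphere always fits within the brain whatever the phantom size.
    """
    rng = np.random.default_rng(seed)
    radius = float(rng.uniform(6.0, 11.0))
    brain_radii = np.array(base.head_radii) - base.skull_thickness - 4.0
    while True:  # rejection-sample a direction in the unit ball
        u = rng.uniform(-1.0, 1.0, 3)
        if (u**2).sum() <= 1.0:
            break
    center = tuple(0.9 * u * np.maximum(brain_radii - radius - 2.0, 0.0))
    return dataclasses.replace(
        base, lesion_centers=(center,), lesion_radii=(radius,), seed=seed
    )


def run_study(config: StudyConfig) -> ComparisonReport:
    """Run the full validation workflow; deterministic given the master seed."""
    seeds = np.random.SeedSequence(config.master_seed).generate_state(4 * config.n_cases)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    hu_rows, gamma_rows, ep_records, con_rows = [], [], [], []
    dvh_curves, gamma_slices = {}, {}
    failures = []

    for i in range(config.n_cases):
        s_phantom, s_degrade, s_perturb, s_dir = (int(x) for x in seeds[4 * i : 4 * i + 4])
        try:
            spec = _case_phantom_spec(config.phantom, i, s_phantom)
            prescription = _case_prescription(i)
            ct, mri, structures = make_head_phantom(spec)
            pseudo = degrade_ct(ct, config.degrade_bias_hu, config.degrade_noise_hu, s_degrade)

            classes = image_compare.classify_hu(ct)
            rmse_bone = image_compare.rmse(pseudo, ct, classes.bone)
            rmse_soft = image_compare.rmse(pseudo, ct, classes.soft_tissue)
            rmse_drr = image_compare.drr_rmse(ct, pseudo)
            hu_rows.append(
                {"case": i, "rmse_bone_hu": rmse_bone, "rmse_soft_hu": rmse_soft,
                 "rmse_drr_hu_mm": rmse_drr}
            )

            initial = make_srt_dose(structures, prescription, ct, label="initial")
            rng_dir = np.random.default_rng(s_dir)
            direction = rng_dir.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = tuple(direction * config.shift_mm_per_hu * rmse_soft)
            synthetic = perturb_dose(
                initial,
                PerturbationSpec(
                    shift_mm=shift,
                    dose_scale=1.0 + config.scale_per_hu * rmse_soft,
                    noise_sd_gy=config.dose_noise_sd_gy,
                    seed=s_perturb,
                ),
            )

            for crit in config.criteria:
                res = compute_gamma(initial, synthetic, crit)
                gamma_rows.append(
                    {"case": i, "mode": crit.mode, "dose_tol_percent": crit.dose_tol_percent,
                     "dta_mm": crit.dta_mm, "criteria": crit.label,
                     "passing_rate": res.passing_rate,
                     "evaluated_count": res.evaluated_count,
                     "pass": res.passing_rate >= crit.pass_rate_goal}
                )
                if crit.mode == "local" and crit.dose_tol_percent == 2 and crit.dta_mm == 2:
                    gamma_slices[i] = res.gamma_map[res.gamma_map.shape[0] // 2]

            ptv = next(s for s in structures if s.role == StructureRole.PTV)
            brain = next(s for s in structures if s.name == "brain")
            for label, dose in (("initial", initial), ("synthetic", synthetic)):
                ep = dosimetry.endpoints(dose, ptv, config.vx_thresholds_gy)
                idx = dosimetry.plan_indices(dose, ptv, prescription)
                ep_records.append(
                    {"case": i, "dose": label, "Dmin": ep.dmin_gy, "Dmax": ep.dmax_gy,
                     "Dmean": ep.dmean_gy, "D2": ep.d2_gy, "D50": ep.d50_gy,
                     "D98": ep.d98_gy, "HI1": idx.hi1, "HI2": idx.hi2, "HI3": idx.hi3,
                     "CI": idx.conformity_index, "GI": idx.gradient_index,
                     "PIV_cm3": idx.piv_cm3, "HalfPIV_cm3": idx.half_piv_cm3}
                )
                dvh_curves.setdefault(i, {})[label] = dosimetry.compute_dvh(dose, ptv)

            for r in dosimetry.check_oar_constraints(initial, structures):
                con_rows.append(
                    {"case": i, "constraint_structure": r.constraint.structure,
                     "structure": r.structure_name, "metric": r.constraint.metric,
                     "x_gy": r.constraint.x_gy, "threshold": r.constraint.threshold,
                     "unit": r.constraint.unit, "tier": r.constraint.tier,
                     "observed": r.observed,
                     "status": "not evaluable" if r.passed is None
                     else ("pass" if r.passed else "fail")}
                )

            if out_dir:
                case_dir = out_dir / f"case_{i:03d}"
                case_dir.mkdir(exist_ok=True)
                write_nifti(ct, case_dir / "ct.nii.gz")
                write_nifti(mri, case_dir / "mri.nii.gz")
                write_nifti(pseudo, case_dir / "pseudo_ct.nii.gz")
                write_nifti(initial, case_dir / "dose_initial.nii.gz")
                write_nifti(synthetic, case_dir / "dose_synthetic.nii.gz")
                for s in structures:
                    write_nifti(s, case_dir / f"{s.name}.{s.role.value.lower()}.nii.gz")
                manifest = {
                    "case": i, "seed_phantom": s_phantom, "seed_degrade": s_degrade,
                    "seed_perturb": s_perturb,
                    "prescription": dataclasses.asdict(prescription),
                    "phantom": {k: v for k, v in dataclasses.asdict(spec).items()},
                }
                (case_dir / "manifest.json").write_text(
                    json.dumps(manifest, indent=2, sort_keys=True, default=str)
                )
        except Exception as exc:  # record and continue with the remaining cases
            failures.append({"case": i, "error": str(exc)})

    hu_rmse = pd.DataFrame(hu_rows)
    gamma_per_case = pd.DataFrame(gamma_rows)
    gamma_summary = (
        gamma_per_case.groupby(["mode", "dose_tol_percent", "dta_mm"], as_index=False)
        .agg(mean=("passing_rate", "mean"), median=("passing_rate", "median"),
             sd=("passing_rate", "std"), n=("passing_rate", "size"))
        if len(gamma_per_case)
        else pd.DataFrame(columns=["mode", "dose_tol_percent", "dta_mm",
                                   "mean", "median", "sd", "n"])
    )

    ep_df = pd.DataFrame(ep_records)
    endpoint_rows = []
    if len(ep_df):
        initial_df = ep_df[ep_df["dose"] == "initial"].set_index("case")
        synth_df = ep_df[ep_df["dose"] == "synthetic"].set_index("case")
        for col in ("Dmin", "Dmax", "Dmean", "D2", "D50", "D98",
                    "HI1", "HI2", "HI3", "CI", "GI", "PIV_cm3", "HalfPIV_cm3"):
            a = initial_df[col].to_numpy()
            b = synth_df[col].to_numpy()
            row = {"endpoint": col,
                   "initial_mean": float(a.mean()), "initial_sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
                   "synthetic_mean": float(b.mean()), "synthetic_sd": float(b.std(ddof=1)) if b.size > 1 else 0.0,
                   "mean_abs_difference": float(np.abs(b - a).mean()),
                   "mean_difference": float((b - a).mean())}
            if a.size >= 2:
                series = stats.PairedSeries(tuple(initial_df.index), a, b)
                t_res = stats.t_test_two_sided(series, paired=True)
                row["p"] = t_res.p
                row["degenerate"] = t_res.degenerate
            else:
                row["p"] = float("nan")
                row["degenerate"] = True
            endpoint_rows.append(row)
    endpoint_table = pd.DataFrame(endpoint_rows)

    report = ComparisonReport(
        hu_rmse=hu_rmse,
        gamma_per_case=gamma_per_case,
        gamma_summary=gamma_summary,
        endpoint_table=endpoint_table,
        constraints=pd.DataFrame(con_rows),
        dvh_curves=dvh_curves,
        gamma_slices=gamma_slices,
    )
    if failures:
        report.constraints.attrs["failures"] = failures
    if out_dir:
        (out_dir / "report.json").write_text(report.to_json())
    return report


def render_report(report: ComparisonReport, out_dir) -> list:
    """Write CSV tables, per-case DVH overlays and gamma-map slice figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"render_report: cannot write to {out_dir}: {exc}") from exc

    written = []
    tables = {
        "hu_rmse.csv": report.hu_rmse,
        "gamma_per_case.csv": report.gamma_per_case,
        "gamma_summary.csv": report.gamma_summary,
        "endpoint_table.csv": report.endpoint_table,
        "constraints.csv": report.constraints,
    }
    schemas = {
        "hu_rmse.csv": ["case", "rmse_bone_hu", "rmse_soft_hu", "rmse_drr_hu_mm"],
        "gamma_per_case.csv": ["case", "mode", "dose_tol_percent", "dta_mm",
                               "criteria", "passing_rate", "evaluated_count", "pass"],
        "gamma_summary.csv": ["mode", "dose_tol_percent", "dta_mm",
                              "mean", "median", "sd", "n"],
        "endpoint_table.csv": ["endpoint", "initial_mean", "initial_sd",
                               "synthetic_mean", "synthetic_sd",
                               "mean_abs_difference", "mean_difference",
                               "p", "degenerate"],
        "constraints.csv": ["case", "constraint_structure", "structure", "metric",
                            "x_gy", "threshold", "unit", "tier", "observed", "status"],
    }
    for name, df in tables.items():
        if df.empty:
            df = pd.DataFrame(columns=schemas[name])
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    for case, curves in report.dvh_curves.items():
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for label, curve in curves.items():
            ax.plot(curve.dose_bins, 100.0 * curve.cumulative_volume_fraction,
                    label=label)
        ax.set_xlabel("Dose (Gy)")
        ax.set_ylabel("Volume (%)")
        ax.set_title(f"Case {case}: PTV DVH")
        ax.legend()
        path = out_dir / f"dvh_case_{case:03d}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    for case, gslice in report.gamma_slices.items():
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(gslice, vmin=0, vmax=2, cmap="coolwarm")
        fig.colorbar(im, ax=ax, label="gamma")
        ax.set_title(f"Case {case}: local 2%/2 mm gamma (central slice)")
        path = out_dir / f"gamma_case_{case:03d}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
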