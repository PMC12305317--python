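"""End-to-end dual-target experiment: model object, results object, runner.

:class:`DualTargetExperiment` bundles a head model, a cohort (given or
sampled), and a coil; :meth:`DualTargetExperiment.fit` runs the full
analysis — spatial statistics of the three targeting methods, per-subject
E-field metrics with the coil over each target, LOI-parallel vs
LOI-perpendicular orientation comparison, and the 0-150 degree orientation
sweep with functional/anatomical ratio profiles — and returns a
:class:`DualTargetResults` carrying the tables, statistics, a ``summary()``
and plotting helpers.  ``run_experiment`` adds the file-writing layer used
by the command-line interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .cohort import (CohortSpec, TargetSet, cohort_to_frame, frame_to_cohort,
                     sample_cohort, write_cohort_csv)
from .coil import (CoilModel, build_sweep, coil_dipoles, initial_pose,
                   loi_orientations, rotate_pose)
from .engine import efield_sphere, normalize_to_m1
from .geometry import HeadGeometry, generate_head
from .roi import (Roi, define_roi, e_perp, e_roi, orientation_histogram,
                  ratio_profile)
from .spatial import (closest_point_on_mesh, dispersion, pair_distances,
                      project_to_cortex, scalp_entry, surface_normal_at)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "DualTargetExperiment", "DualTargetResults",
           "run_experiment", "m1_reference_field"]

#: Synthetic-space direction of the hand-knob motor cortex reference site.
M1_DIRECTION = np.array([-34.19, -14.33, 66.83]) / np.linalg.norm(
    [-34.19, -14.33, 66.83])

TARGET_TYPES = ("functional", "anatomical", "f3")


@dataclass
class RunConfig:
    """Flat configuration for an end-to-end run (units: mm, A/us)."""

    n_subjects: int = 30
    mesh_density: int = 5
    perturbation_amplitude: float = 1.5
    didt_m1: float = 1.0
    didt_dlpfc: float = 0.8
    roi_radius_mm: float = 10.0
    coil_wing_radius_mm: float = 35.0
    coil_wing_separation_mm: float = 70.0
    coil_dipoles_per_wing: int = 16
    coil_standoff_mm: float = 0.0
    seed: int = 0
    output_dir: str = "tmsfield_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def m1_reference_field(head: HeadGeometry, coil: CoilModel, didt: float = 1.0,
                       standoff: float = 0.0) -> float:
    """Field strength (V/m) at the motor-cortex analog, initial orientation.

    The coil sits at the scalp point over the M1 direction with the
    initial clinical orientation and the motor-threshold slew rate
    (1 A/us); the reference is the field magnitude at the nearest cortical
    projection of that scalp site.
    """
    probe = head.center + M1_DIRECTION * head.layer_radii["scalp"]
    scalp_pt, _, _ = closest_point_on_mesh(probe[None, :], head.scalp_mesh)
    scalp_pt = scalp_pt[0]
    normal = surface_normal_at(scalp_pt, head.scalp_mesh)
    pose = initial_pose(scalp_pt, normal)
    cortical = project_to_cortex(scalp_pt, head.cortex_mesh)
    fmap = efield_sphere(coil_dipoles(coil, pose, standoff), cortical[None, :],
                         didt, head.center)
    return float(fmap.magnitudes()[0])


class DualTargetExperiment:
    """Dual-target TMS E-field model on a synthetic head.

    Parameters
    ----------
    head : HeadGeometry, optional
        Generated from ``config`` when omitted.
    cohort : list of TargetSet, optional
        Pre-existing targets; sampled from ``cohort_spec`` when omitted.
    cohort_spec : CohortSpec, optional
    coil : CoilModel, optional
    config : RunConfig, optional
        Supplies head/coil/stimulation defaults not given explicitly.
    """

    def __init__(self, head: HeadGeometry | None = None,
                 cohort: list[TargetSet] | None = None,
                 cohort_spec: CohortSpec | None = None,
                 coil: CoilModel | None = None,
                 config: RunConfig | None = None):
        self.config = config or RunConfig()
        cfg = self.config
        self.head = head if head is not None else generate_head(
            mesh_density=cfg.mesh_density,
            perturbation_amplitude=cfg.perturbation_amplitude, seed=cfg.seed)
        self.cohort_spec = cohort_spec or CohortSpec(
            n_subjects=cfg.n_subjects, rng_seed=cfg.seed)
        self.cohort = cohort
        self.coil = coil or CoilModel(
            wing_radius=cfg.coil_wing_radius_mm,
            wing_separation=cfg.coil_wing_separation_mm,
            dipoles_per_wing=cfg.coil_dipoles_per_wing)

    @classmethod
    def from_config(cls, config: RunConfig) -> "DualTargetExperiment":
        return cls(config=config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, head: HeadGeometry,
                       **kwargs) -> "DualTargetExperiment":
        """Build from a long-format cohort target table (see cohort module)."""
        return cls(head=head, cohort=frame_to_cohort(df), **kwargs)

    # ------------------------------------------------------------------
    def _evaluator(self, m1_ref: float):
        cfg = self.config

        def evaluate(pose, points):
            dip = coil_dipoles(self.coil, pose, cfg.coil_standoff_mm)
            fmap = efield_sphere(dip, points, cfg.didt_dlpfc, self.head.center)
            return normalize_to_m1(fmap, m1_ref)

        return evaluate

    def fit(self) -> "DualTargetResults":
        """Run the full analysis; deterministic for a fixed config/seed."""
        cfg = self.config
        head = self.head
        cohort = self.cohort if self.cohort is not None else sample_cohort(
            head, self.cohort_spec)
        m1_ref = m1_reference_field(head, self.coil, didt=cfg.didt_m1,
                                    standoff=cfg.coil_standoff_mm)
        evaluate = self._evaluator(m1_ref)

        # --- spatial statistics of the three targeting methods -----------
        points = {t: np.array([getattr(s, t).cortical_point for s in cohort])
                  for t in TARGET_TYPES}
        dispersions = {t: dispersion(points[t], t) for t in TARGET_TYPES}
        disp_groups = [dispersions[t].per_subject_distance for t in TARGET_TYPES]
        disp_anova = st.one_way_anova(disp_groups, list(TARGET_TYPES))
        disp_lsd = st.lsd_posthoc(disp_groups, list(TARGET_TYPES))
        pairs = pair_distances(cohort)
        pair_anova = st.one_way_anova([p.per_subject_distance for p in pairs],
                                      ["-".join(p.pair) for p in pairs])

        # --- per-subject field metrics -----------------------------------
        metric_rows, pose_rows, profiles, failures = [], [], [], 0
        voxel_counts = {t: [] for t in TARGET_TYPES}
        volumes = {t: [] for t in TARGET_TYPES}
        for subj in cohort:
            try:
                rois = {t: define_roi(getattr(subj, t).cortical_point,
                                      head.cortex_mesh, cfg.roi_radius_mm)
                        for t in TARGET_TYPES}
                for t in TARGET_TYPES:
                    voxel_counts[t].append(rois[t].voxel_count)
                    volumes[t].append(rois[t].volume_mm3)

                # coil over each target, initial orientation, measure all sites
                for coil_t in TARGET_TYPES:
                    entry = getattr(subj, coil_t).scalp_point
                    normal = surface_normal_at(entry, head.scalp_mesh)
                    pose = initial_pose(entry, normal)
                    self._record_pose(pose_rows, subj.subject_id, coil_t,
                                      "initial", pose)
                    pts = np.vstack([rois[t].sample_points for t in TARGET_TYPES])
                    fmap = evaluate(pose, pts)
                    for meas_t in TARGET_TYPES:
                        metric_rows.append(self._metric_row(
                            subj.subject_id, coil_t, "initial", 0.0, meas_t,
                            rois[meas_t], fmap))

                # LOI orientations and sweep, coil over the functional target
                entry = subj.functional.scalp_point
                normal = surface_normal_at(entry, head.scalp_mesh)
                base = initial_pose(entry, normal)
                par, perp, _ = loi_orientations(subj.functional.cortical_point,
                                                subj.anatomical.cortical_point,
                                                base)
                pts = np.vstack([rois["functional"].sample_points,
                                 rois["anatomical"].sample_points])
                for label, pose in (("parallel", par), ("perpendicular", perp)):
                    self._record_pose(pose_rows, subj.subject_id, "functional",
                                      label, pose)
                    fmap = evaluate(pose, pts)
                    for meas_t in ("functional", "anatomical"):
                        metric_rows.append(self._metric_row(
                            subj.subject_id, "functional", label,
                            pose.rotation_deg, meas_t, rois[meas_t], fmap))

                sweep = build_sweep(base, subj.functional.cortical_point)
                for ang, pose in zip(sweep.angles_deg, sweep.poses):
                    self._record_pose(pose_rows, subj.subject_id, "functional",
                                      f"sweep_{int(ang)}", pose)
                    fmap = evaluate(pose, pts)
                    for meas_t in ("functional", "anatomical"):
                        metric_rows.append(self._metric_row(
                            subj.subject_id, "functional", "sweep", ang,
                            meas_t, rois[meas_t], fmap))
                profiles.append(ratio_profile(subj.subject_id, sweep, evaluate,
                                              rois["functional"],
                                              rois["anatomical"]))
            except Exception:
                failures += 1
                logger.exception("subject %s failed; skipped", subj.subject_id)
        if failures > 0.1 * len(cohort):
            raise RuntimeError(f"{failures}/{len(cohort)} subjects failed")

        metrics = pd.DataFrame(metric_rows)
        poses = pd.DataFrame(pose_rows)
        results = DualTargetResults(
            experiment=self, cohort=cohort, m1_reference=m1_ref,
            dispersions=dispersions, dispersion_anova=disp_anova,
            dispersion_lsd=disp_lsd, pair_summaries=pairs,
            pair_anova=pair_anova, voxel_counts=voxel_counts, volumes=volumes,
            metrics=metrics, poses=poses, profiles=profiles,
            n_failed=failures)
        results._finalize()
        return results

    # ------------------------------------------------------------------
    @staticmethod
    def _metric_row(sid, coil_t, strategy, angle, meas_t, roi: Roi, fmap):
        return {
            "subject_id": sid, "coil_target": coil_t, "orientation": strategy,
            "orientation_deg": float(angle), "measured_target": meas_t,
            "e_roi": e_roi(roi, fmap), "e_perp": e_perp(roi, fmap),
            "voxel_count": roi.voxel_count,
        }

    @staticmethod
    def _record_pose(rows, sid, coil_t, label, pose):
        rows.append({
            "subject_id": sid, "coil_target": coil_t, "orientation": label,
            "center_x": pose.center[0], "center_y": pose.center[1],
            "center_z": pose.center[2],
            "normal_x": pose.contact_normal[0],
            "normal_y": pose.contact_normal[1],
            "normal_z": pose.contact_normal[2],
            "handle_x": pose.handle_dir[0], "handle_y": pose.handle_dir[1],
            "handle_z": pose.handle_dir[2],
            "rotation_deg": pose.rotation_deg,
        })


@dataclass
class DualTargetResults:
    """Fitted results: tables, statistics, summary and plots."""

    experiment: DualTargetExperiment
    cohort: list
    m1_reference: float
    dispersions: dict
    dispersion_anova: st.StatResult
    dispersion_lsd: list
    pair_summaries: list
    pair_anova: st.StatResult
    voxel_counts: dict
    volumes: dict
    metrics: pd.DataFrame
    poses: pd.DataFrame
    profiles: list
    n_failed: int
    stats: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def _orientation_values(self, orientation: str, target: str,
                            column: str) -> np.ndarray:
        m = self.metrics
        sel = m[(m["orientation"] == orientation)
                & (m["coil_target"] == "functional")
                & (m["measured_target"] == target)]
        return sel.sort_values("subject_id")[column].to_numpy()

    def _finalize(self) -> None:
        """Derive the cohort-level statistics from the metric table."""
        s: dict = {}
        disp = self.dispersions
        s["dispersion_mean_mm"] = {t: disp[t].mean_mm for t in TARGET_TYPES}
        s["dispersion_fold_change"] = st.ratio(disp["functional"].mean_mm,
                                               disp["anatomical"].mean_mm)
        s["dispersion_anova_F"] = self.dispersion_anova.value
        s["dispersion_anova_eta2"] = self.dispersion_anova.eta2
        s["pair_mean_mm"] = {"-".join(p.pair): p.mean_mm
                             for p in self.pair_summaries}
        s["volume_mean_mm3"] = {t: float(np.mean(self.volumes[t]))
                                for t in TARGET_TYPES}
        vol_anova = st.one_way_anova([np.asarray(self.volumes[t], float)
                                      for t in TARGET_TYPES])
        s["volume_anova_F"], s["volume_anova_p"] = vol_anova.value, vol_anova.p

        # own-target field with the coil over each target (equal-depth null)
        own = {}
        m = self.metrics
        for t in TARGET_TYPES:
            sel = m[(m["orientation"] == "initial") & (m["coil_target"] == t)
                    & (m["measured_target"] == t)]
            own[t] = sel["e_roi"].to_numpy()
        s["own_target_e_roi_mean"] = {t: float(v.mean()) for t, v in own.items()}
        own_anova = st.one_way_anova(list(own.values()), list(TARGET_TYPES))
        s["own_target_anova_F"], s["own_target_anova_p"] = (own_anova.value,
                                                            own_anova.p)

        # neighbor comparison at the initial orientation, coil over functional
        for col in ("e_roi", "e_perp"):
            f0 = self._orientation_values("initial", "functional", col)
            a0 = self._orientation_values("initial", "anatomical", col)
            s[f"initial_functional_{col}"] = float(f0.mean())
            s[f"initial_anatomical_{col}"] = float(a0.mean())
            s[f"initial_neighbor_t_{col}"] = st.t_test(f0, a0, paired=True).value
            s[f"initial_neighbor_p_{col}"] = st.t_test(f0, a0, paired=True).p

        # LOI parallel vs perpendicular
        for col in ("e_roi", "e_perp"):
            fp = self._orientation_values("parallel", "functional", col)
            ap = self._orientation_values("parallel", "anatomical", col)
            fq = self._orientation_values("perpendicular", "functional", col)
            aq = self._orientation_values("perpendicular", "anatomical", col)
            gs = {k: st.GroupSummary.from_data(k, v) for k, v in
                  (("fp", fp), ("ap", ap), ("fq", fq), ("aq", aq))}
            s[f"parallel_functional_{col}"] = gs["fp"].mean
            s[f"parallel_anatomical_{col}"] = gs["ap"].mean
            s[f"perpendicular_functional_{col}"] = gs["fq"].mean
            s[f"perpendicular_anatomical_{col}"] = gs["aq"].mean
            s[f"ratio_parallel_{col}"] = st.ratio(gs["fp"].mean, gs["ap"].mean)
            s[f"ratio_perpendicular_{col}"] = st.ratio(gs["fq"].mean,
                                                       gs["aq"].mean)
            s[f"cohens_d_parallel_{col}"] = st.cohens_d_pooled(gs["fp"], gs["ap"])
            s[f"cohens_d_perpendicular_{col}"] = st.cohens_d_pooled(gs["fq"],
                                                                    gs["aq"])
            s[f"functional_drop_pct_{col}"] = st.percent_change(gs["fp"].mean,
                                                                gs["fq"].mean)
            s[f"anatomical_drop_pct_{col}"] = st.percent_change(gs["ap"].mean,
                                                                gs["aq"].mean)
            s[f"t_perpendicular_{col}"] = st.t_test(fq, aq, paired=True).value

        # sweep ratio extrema and histograms
        if self.profiles:
            rmax = np.array([p.ratio_e_roi.max() for p in self.profiles])
            rmin = np.array([p.ratio_e_roi.min() for p in self.profiles])
            s["max_ratio_mean"], s["min_ratio_mean"] = (float(rmax.mean()),
                                                        float(rmin.mean()))
            s["ratio_extrema_t"] = st.t_test(rmax, rmin, paired=True).value
            s["ratio_extrema_p"] = st.t_test(rmax, rmin, paired=True).p
            hmax, hmin = orientation_histogram(self.profiles, "e_roi")
            pmax, pmin = orientation_histogram(self.profiles, "e_perp")
            s["histogram_e_roi"] = {"max": hmax, "min": hmin}
            s["histogram_e_perp"] = {"max": pmax, "min": pmin}
        self.stats = s

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable cohort summary."""
        from statsmodels.iolib.table import SimpleTable

        s = self.stats
        lines = ["Dual-target TMS E-field experiment",
                 f"subjects: {len(self.cohort)} (failed: {self.n_failed}); "
                 f"M1 reference: {self.m1_reference:.4g} V/m", ""]
        disp_rows = [[t, f"{self.dispersions[t].mean_mm:.2f}",
                      f"{self.dispersions[t].sd_mm:.2f}",
                      f"{np.mean(self.voxel_counts[t]):.1f}",
                      f"{s['volume_mean_mm3'][t]:.0f}"] for t in TARGET_TYPES]
        lines.append(str(SimpleTable(
            disp_rows, headers=["target", "dispersion mm", "sd", "voxels",
                                "volume mm3"],
            title=f"Targeting dispersion (ANOVA F={s['dispersion_anova_F']:.2f}, "
                  f"eta2={s['dispersion_anova_eta2']:.2f}; fold change "
                  f"{s['dispersion_fold_change']:.2f})")))
        pair_rows = [["-".join(p.pair), f"{p.mean_mm:.2f}", f"{p.sd_mm:.2f}"]
                     for p in self.pair_summaries]
        lines.append(str(SimpleTable(pair_rows,
                                     headers=["pair", "mean mm", "sd"],
                                     title="Inter-target distances")))
        field_rows = []
        for label in ("initial", "parallel", "perpendicular"):
            key = label if label != "initial" else "initial"
            field_rows.append([
                label,
                f"{s[f'{key}_functional_e_roi']:.3f}",
                f"{s[f'{key}_anatomical_e_roi']:.3f}",
                f"{s[f'{key}_functional_e_roi'] / s[f'{key}_anatomical_e_roi']:.2f}",
                f"{s[f'{key}_functional_e_perp']:.3f}",
                f"{s[f'{key}_anatomical_e_perp']:.3f}",
            ])
        lines.append(str(SimpleTable(
            field_rows,
            headers=["orientation", "E_ROI func", "E_ROI anat", "ratio",
                     "E_perp func", "E_perp anat"],
            title="Coil over the functional target")))
        lines.append(
            f"parallel->perpendicular drop: functional "
            f"{s['functional_drop_pct_e_roi']:+.2f}%, anatomical "
            f"{s['anatomical_drop_pct_e_roi']:+.2f}% (E_ROI)")
        if "max_ratio_mean" in s:
            lines.append(
                f"sweep ratio extrema: max {s['max_ratio_mean']:.2f}, "
                f"min {s['min_ratio_mean']:.2f} "
                f"(paired t={s['ratio_extrema_t']:.2f})")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, outdir) -> None:
        """Write the report bundle (CSV/JSON/text) into ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(self.cohort, out / "cohort.csv")
        self.poses.to_csv(out / "poses.csv", index=False)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        stats_serializable = json.loads(json.dumps(self.stats, default=float))
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_serializable, fh, indent=2)
        hist = {k: self.stats[k] for k in ("histogram_e_roi", "histogram_e_perp")
                if k in self.stats}
        with open(out / "histograms.json", "w") as fh:
            json.dump(json.loads(json.dumps(hist, default=float)), fh, indent=2)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        self.experiment.config.to_yaml(out / "config.yaml")

    # ------------------------------------------------------------------
    def plot_ratio_profiles(self, ax=None, metric: str = "e_roi"):
        """Per-subject functional/anatomical ratio vs orientation angle."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        attr = "ratio_e_roi" if metric == "e_roi" else "ratio_e_perp"
        for p in self.profiles:
            ax.plot(p.angles_deg, getattr(p, attr), color="0.6", alpha=0.5)
        mean = np.mean([getattr(p, attr) for p in self.profiles], axis=0)
        ax.plot(self.profiles[0].angles_deg, mean, color="C3", lw=2,
                label="cohort mean")
        ax.set_xlabel("coil orientation (deg)")
        ax.set_ylabel(f"functional/anatomical {metric} ratio")
        ax.legend()
        return ax

    def plot_orientation_histogram(self, ax=None, metric: str = "e_roi"):
        """Percent of subjects with max/min ratio at each orientation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.stats[f"histogram_{metric}"]
        angles = sorted(hist["max"].keys())
        width = 10.0
        ax.bar([a - width / 2 for a in angles],
               [hist["max"][a] for a in angles], width=width, label="max")
        ax.bar([a + width / 2 for a in angles],
               [hist["min"][a] for a in angles], width=width, label="min")
        ax.set_xlabel("coil orientation (deg)")
        ax.set_ylabel("% of subjects")
        ax.legend()
        return ax

    def plot_dispersion(self, ax=None):
        """Per-target distances to the cohort centroid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = [self.dispersions[t].per_subject_distance for t in TARGET_TYPES]
        ax.boxplot(data, tick_labels=list(TARGET_TYPES))
        ax.set_ylabel("distance to centroid (mm)")
        return ax


def run_experiment(config: RunConfig) -> DualTargetResults:
    """Run the configured experiment and write its report bundle."""
    exp = DualTargetExperiment.from_config(config)
    results = exp.fit()
    results.save(config.output_dir)
    return results
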