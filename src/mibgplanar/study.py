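"""End-to-end in-silico reproducibility study.

Simulates a cohort of heart-failure phantoms, has simulated observers draw
ROIs (one experienced observer measuring twice for the intra-observer design,
a second experienced observer for the inter-observer design, and a
higher-jitter "inexperienced" observer), quantifies every study under the
manual-polygon and the fixed-size oval/circular cardiac ROIs, and summarises
agreement with ICCs (with 95 % CI and qualitative class) and Bland-Altman
limits — including the very-low delayed H/M subgroup and the
fixed-vs-manual-ROI comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import (
    ObserverModel,
    PhantomConfig,
    default_config_sampler,
    generate_phantom,
    simulate_observer,
)
from .quant import quantify_study
from .reliability import (
    LOW_DELAYED_HM_THRESHOLD,
    ObserverMeasurementTable,
    bland_altman,
    filter_low_delayed_hm,
    icc_two_way_mixed,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "write_report", "read_measurements"]

SCHEMA_VERSION = 1

MEASURANDS = ("hm_early", "hm_delayed", "wr_m1_pct", "wr_m2_pct")

#: observer sessions: the first experienced observer measures twice
#: (intra-observer design), a second experienced observer once
#: (inter-observer), and an inexperienced observer once.
SESSIONS = ("exp1_m1", "exp1_m2", "exp2", "inexp")

#: (name, session A, session B, ICC measures) -- single measures for the
#: intra-observer repeat, average measures for between-observer comparisons
COMPARISONS = (
    ("intra", "exp1_m1", "exp1_m2", "single"),
    ("inter", "exp1_m1", "exp2", "average"),
    ("experience", "exp1_m1", "inexp", "average"),
)

MEASUREMENT_COLUMNS = [
    "subject", "session", "roi_mode",
    "H_e", "M_e", "H_l", "M_l",
    "hm_early", "hm_delayed", "wr_m1_pct", "wr_m2_pct",
]


@dataclass
class StudyConfig:
    n_subjects: int = 70
    seed: int = 0
    phantom_base: PhantomConfig = field(default_factory=lambda: PhantomConfig(noise="poisson"))
    experienced_model: ObserverModel = field(default_factory=ObserverModel)
    inexperienced_model: ObserverModel = field(
        default_factory=lambda: ObserverModel(
            vertex_jitter_sd_px=3.0, roi_shift_sd_px=3.0, axis_angle_jitter_deg=8.0
        )
    )
    roi_modes: tuple[str, ...] = ("polygon", "oval", "circle")
    independent_rois_per_phase: bool = True
    subgroup_threshold: float = LOW_DELAYED_HM_THRESHOLD

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("study needs at least 2 subjects")
        if not self.roi_modes:
            raise ValueError("at least one cardiac ROI mode required")
        if "polygon" not in self.roi_modes:
            raise ValueError("the manual polygon ROI mode is the reference and must be included")


@dataclass
class StudyReport:
    """All result tables of one simulated study (CSV/JSON serialisable)."""

    config_summary: dict
    measurements: pd.DataFrame
    observer_agreement: pd.DataFrame  # per measurand x comparison (Table-2 shape)
    subgroup_agreement: pd.DataFrame  # low delayed H/M subgroup (Table-3 shape)
    roi_mode_agreement: pd.DataFrame  # fixed-size vs manual cardiac ROI (Table-4 shape)
    bland_altman_points: pd.DataFrame
    subgroup_n: int
    truth: pd.DataFrame


def _session_table(meas: pd.DataFrame, sessions: tuple[str, str], measurand: str) -> np.ndarray:
    sub = meas[(meas.roi_mode == "polygon") & (meas.session.isin(sessions))]
    wide = sub.pivot(index="subject", columns="session", values=measurand)[list(sessions)]
    # complete-case requirement: drop subjects where a session's measurand is
    # undefined (e.g. non-positive background-corrected uptake for WR method 2)
    return wide.dropna().to_numpy()


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full simulated reproducibility study; deterministic by seed."""
    ss = np.random.SeedSequence(config.seed)
    seed_cohort, *seed_sessions = ss.spawn(1 + len(SESSIONS))

    sampler = default_config_sampler(base=config.phantom_base)
    rng_cohort = np.random.default_rng(seed_cohort)
    subjects = [generate_phantom(sampler(rng_cohort)) for _ in range(config.n_subjects)]

    models = {
        "exp1_m1": config.experienced_model,
        "exp1_m2": config.experienced_model,  # same observer, independent redraw
        "exp2": config.experienced_model,
        "inexp": config.inexperienced_model,
    }
    session_rngs = {name: np.random.default_rng(s) for name, s in zip(SESSIONS, seed_sessions)}

    rows = []
    truth_rows = []
    spacing = config.phantom_base.pixel_spacing_mm
    for sid, (early, delayed, truth) in enumerate(subjects):
        truth_rows.append(
            {
                "subject": sid,
                "true_early_hm": truth.true_early_hm,
                "true_delayed_hm": truth.true_delayed_hm,
                "true_wr_m1": truth.true_wr_m1,
                "true_wr_m2": truth.true_wr_m2,
            }
        )
        for session in SESSIONS:
            rng = session_rngs[session]
            rois_e = simulate_observer(truth, models[session], rng=rng)
            rois_l = (
                simulate_observer(truth, models[session], rng=rng)
                if config.independent_rois_per_phase
                else rois_e
            )
            modes = config.roi_modes if session == "exp1_m1" else ("polygon",)
            for mode in modes:
                m = quantify_study(
                    early, delayed, rois_e, cardiac=mode, roi_set_delayed=rois_l,
                    on_degenerate_wr2="nan",
                )
                rows.append(
                    {
                        "subject": sid,
                        "session": session,
                        "roi_mode": mode,
                        "H_e": m.H_e,
                        "M_e": m.M_e,
                        "H_l": m.H_l,
                        "M_l": m.M_l,
                        "hm_early": m.hm_early,
                        "hm_delayed": m.hm_delayed,
                        "wr_m1_pct": m.wr_m1_pct,
                        "wr_m2_pct": m.wr_m2_pct,
                    }
                )
    meas = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    truth_df = pd.DataFrame(truth_rows)

    # --- observer agreement per measurand (Table-2 shape) ------------------
    agreement_rows = []
    ba_points = []
    for name, sa, sb, measures in COMPARISONS:
        for measurand in MEASURANDS:
            values = _session_table(meas, (sa, sb), measurand)
            table = ObserverMeasurementTable(values, measurand=measurand, rater_labels=(sa, sb))
            icc = icc_two_way_mixed(table, measures=measures, definition="consistency")
            ba = bland_altman(values[:, 0], values[:, 1])
            agreement_rows.append(
                {
                    "comparison": name,
                    "measurand": measurand,
                    "session_a": sa,
                    "session_b": sb,
                    "mean_a": values[:, 0].mean(),
                    "sd_a": values[:, 0].std(ddof=1),
                    "mean_b": values[:, 1].mean(),
                    "sd_b": values[:, 1].std(ddof=1),
                    "icc": icc.icc,
                    "icc_ci_low": icc.ci_low,
                    "icc_ci_high": icc.ci_high,
                    "icc_measures": measures,
                    "icc_class": icc.qualitative_class,
                    "ba_mean_diff": ba.mean_diff,
                    "ba_loa_low": ba.loa_low,
                    "ba_loa_high": ba.loa_high,
                }
            )
            ba_points.append(
                pd.DataFrame(
                    {
                        "comparison": name,
                        "measurand": measurand,
                        "pair_mean": ba.pair_means,
                        "difference": ba.differences,
                    }
                )
            )
    observer_agreement = pd.DataFrame(agreement_rows)

    # --- low delayed H/M subgroup (Table-3 shape) ---------------------------
    ref = (
        meas[(meas.session == "exp1_m1") & (meas.roi_mode == "polygon")]
        .set_index("subject")["hm_delayed"]
        .rename("hm_delayed_ref")
        .reset_index()
    )
    subgroup_subjects = filter_low_delayed_hm(
        ref, threshold=config.subgroup_threshold, reference_column="hm_delayed_ref"
    )["subject"]
    sub_rows = []
    for name, sa, sb, measures in COMPARISONS[:2]:  # intra + inter, delayed H/M
        values = _session_table(
            meas[meas.subject.isin(subgroup_subjects)], (sa, sb), "hm_delayed"
        )
        row = {"comparison": name, "n_subgroup": values.shape[0]}
        if values.shape[0] >= 2:
            table = ObserverMeasurementTable(values, measurand="hm_delayed")
            icc = icc_two_way_mixed(table, measures=measures, definition="consistency")
            row.update(
                {
                    "mean_a": values[:, 0].mean(),
                    "sd_a": values[:, 0].std(ddof=1),
                    "mean_b": values[:, 1].mean(),
                    "sd_b": values[:, 1].std(ddof=1),
                    "icc": icc.icc,
                    "icc_ci_low": icc.ci_low,
                    "icc_ci_high": icc.ci_high,
                    "icc_class": icc.qualitative_class,
                }
            )
        else:
            # too few severe-denervation subjects to estimate agreement
            row.update({k: np.nan for k in (
                "mean_a", "sd_a", "mean_b", "sd_b",
                "icc", "icc_ci_low", "icc_ci_high",
            )})
            row["icc_class"] = "not_computable"
        sub_rows.append(row)
    subgroup_agreement = pd.DataFrame(sub_rows)

    # --- fixed-size vs manual cardiac ROI (Table-4 shape) -------------------
    ref_sess = meas[meas.session == "exp1_m1"]
    poly = ref_sess[ref_sess.roi_mode == "polygon"].set_index("subject")
    mode_rows = []
    for mode in config.roi_modes:
        cur = ref_sess[ref_sess.roi_mode == mode].set_index("subject")
        row = {
            "roi_mode": mode,
            "mean_counts_per_mm2": (cur["H_l"] / spacing**2).mean(),
            "sd_counts_per_mm2": (cur["H_l"] / spacing**2).std(ddof=1),
            "hm_delayed_mean": cur["hm_delayed"].mean(),
            "hm_delayed_sd": cur["hm_delayed"].std(ddof=1),
        }
        if mode != "polygon":
            pair = np.column_stack([poly["hm_delayed"], cur["hm_delayed"]])
            icc = icc_two_way_mixed(
                ObserverMeasurementTable(pair, measurand="hm_delayed"),
                measures="average",
                definition="consistency",
            )
            ba_hm = bland_altman(cur["hm_delayed"].to_numpy(), poly["hm_delayed"].to_numpy())
            ba_counts = bland_altman(cur["H_l"].to_numpy(), poly["H_l"].to_numpy())
            row.update(
                {
                    "icc_vs_polygon": icc.icc,
                    "icc_ci_low": icc.ci_low,
                    "icc_ci_high": icc.ci_high,
                    "icc_class": icc.qualitative_class,
                    "ba_hm_mean_diff": ba_hm.mean_diff,
                    "ba_hm_loa_low": ba_hm.loa_low,
                    "ba_hm_loa_high": ba_hm.loa_high,
                    "ba_counts_mean_diff": ba_counts.mean_diff,
                    "ba_counts_loa_low": ba_counts.loa_low,
                    "ba_counts_loa_high": ba_counts.loa_high,
                }
            )
        mode_rows.append(row)
    roi_mode_agreement = pd.DataFrame(mode_rows)

    config_summary = {
        "schema_version": SCHEMA_VERSION,
        "n_subjects": config.n_subjects,
        "seed": config.seed,
        "noise": config.phantom_base.noise,
        "matrix_size": config.phantom_base.matrix_size,
        "pixel_spacing_mm": spacing,
        "experienced_model": vars(config.experienced_model).copy(),
        "inexperienced_model": vars(config.inexperienced_model).copy(),
        "roi_modes": list(config.roi_modes),
        "independent_rois_per_phase": config.independent_rois_per_phase,
        "subgroup_threshold": config.subgroup_threshold,
    }
    return StudyReport(
        config_summary=config_summary,
        measurements=meas,
        observer_agreement=observer_agreement,
        subgroup_agreement=subgroup_agreement,
        roi_mode_agreement=roi_mode_agreement,
        bland_altman_points=pd.concat(ba_points, ignore_index=True),
        subgroup_n=int(len(subgroup_subjects)),
        truth=truth_df,
    )


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write the report suite (CSV tables + JSON summary) to ``out_dir``.

    All tables are rendered before any file is written, so a failure never
    leaves a partial report behind.
    """
    payload = {
        "config": report.config_summary,
        "subgroup_n": report.subgroup_n,
        "observer_agreement": report.observer_agreement.to_dict(orient="records"),
        "subgroup_agreement": report.subgroup_agreement.to_dict(orient="records"),
        "roi_mode_agreement": report.roi_mode_agreement.to_dict(orient="records"),
    }
    fmt = "%.17g"  # round-trips float64 exactly
    rendered = {
        "table2.csv": report.observer_agreement.to_csv(index=False, float_format=fmt),
        "table3.csv": report.subgroup_agreement.to_csv(index=False, float_format=fmt),
        "table4.csv": report.roi_mode_agreement.to_csv(index=False, float_format=fmt),
        "measurements.csv": report.measurements.to_csv(index=False, float_format=fmt),
        "truth.csv": report.truth.to_csv(index=False, float_format=fmt),
        "bland_altman_points.csv": report.bland_altman_points.to_csv(index=False, float_format=fmt),
        "report.json": json.dumps(payload, indent=1),
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, text in rendered.items():
        (out / name).write_text(text)


def read_measurements(
    csv_path: str | Path,
    measurand: str,
    sessions: tuple[str, ...] = ("exp1_m1", "exp2"),
    roi_mode: str = "polygon",
) -> ObserverMeasurementTable:
    """Load a measurements.csv back into a subjects x raters table."""
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for col in ("subject", "session", "roi_mode", measurand):
        if col not in df.columns:
            raise ValueError(f"measurements file is missing column {col!r}")
    sub = df[(df.roi_mode == roi_mode) & (df.session.isin(sessions))]
    if sub.empty:
        raise ValueError("no measurements match the requested sessions/ROI mode")
    wide = sub.pivot(index="subject", columns="session", values=measurand)
    missing = [s for s in sessions if s not in wide.columns]
    if missing:
        raise ValueError(f"sessions absent from measurements file: {missing}")
    return ObserverMeasurementTable(
        wide[list(sessions)].to_numpy(), measurand=measurand, rater_labels=tuple(sessions)
    )
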