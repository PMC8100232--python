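"""Orchestration: phantom -> tensor -> ALPS, and cohort -> statistics -> report.

The two flows mirror the study design:

* :func:`run_alps_pipeline` fits tensors per subject, extracts the fiber-ROI
  axis diffusivities per hemisphere for each observer's ROI set, computes
  the per-observer ALPS indices and averages the observers.
* :func:`run_group_comparison` runs, separately for right-side and
  left-side tumor cohorts (each against the same normal controls), an
  age/sex-adjusted ANCOVA on each ALPS response with three Bonferroni
  pairwise contrasts — a 12-contrast grid.
* :func:`run_correlation_analysis` takes the PTBE+ subset, correlates PTBE
  volume with the seven candidate factors (age, sex, grade, Ki-67,
  location, tumor volume, tumor-side ALPS), screens them with VIFs, and
  fits the stepwise multivariable regression.

Descriptive volume bins use half-open [low, high) intervals with 0 as its
own edema bin, making each binning a partition.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alps as alps_mod
from . import stats as stats_mod
from . import tensor as tensor_mod
from .phantom import (GROUP_CONTROL, GROUP_NO_PTBE, GROUP_PTBE,
                      cohort_from_csv)

__all__ = [
    "StudyConfig",
    "setup_logging",
    "run_alps_pipeline",
    "run_group_comparison",
    "run_correlation_analysis",
    "descriptive_summary",
    "ipsilateral_alps",
    "write_report",
    "TUMOR_VOLUME_BINS",
    "EDEMA_VOLUME_BINS",
]

logger = logging.getLogger("dtialps")

GROUP_ORDER = [GROUP_NO_PTBE, GROUP_PTBE, GROUP_CONTROL]

#: Half-open [low, high) tumor-volume bins (cm^3), as printed labels.
TUMOR_VOLUME_BINS = [("1-8", 1.0, 8.0), ("8-27", 8.0, 27.0),
                     ("27-64", 27.0, 64.0), ("64-125", 64.0, 125.0),
                     (">125", 125.0, float("inf"))]

#: Edema bins: exactly 0 is its own bin, then half-open intervals.
EDEMA_VOLUME_BINS = [("1-27", 0.0, 27.0), ("27-64", 27.0, 64.0),
                     ("64-125", 64.0, 125.0), (">125", 125.0, float("inf"))]

CANDIDATE_COLUMNS = ["age", "sex", "tumor_grade", "ki67", "location",
                     "tumor_volume", "alps_ipsi"]


@dataclass
class StudyConfig:
    """Paths, analysis switches, thresholds and seeds for a full run."""

    output_dir: Path = Path("results")
    cohort_csv: Path | None = None
    subjects: list = dc_field(default_factory=list)  # ALPS-flow input descriptors
    sides: tuple[str, ...] = ("right", "left")
    responses: tuple[str, ...] = ("alps_right", "alps_left")
    alpha: float = 0.05
    stepwise_entry_p: float = 0.05
    stepwise_removal_p: float = 0.10
    seed: int = 0
    log_level: str = "INFO"
    plots: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.output_dir = Path(self.output_dir)
        if self.cohort_csv is not None:
            self.cohort_csv = Path(self.cohort_csv)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sides", "responses"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def setup_logging(level: str = "INFO", logfile=None) -> logging.Logger:
    """Log to stderr and optionally to a run-log file."""
    logger.setLevel(getattr(logging, level.upper()))
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    logger.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger


# ---------------------------------------------------------------------------
# ALPS flow
# ---------------------------------------------------------------------------

def _subject_alps_rows(subject: dict) -> list[dict]:
    """Fit one subject's DWI and return per-observer/per-hemisphere rows.

    ``subject`` keys: subject_id, dwi, bval, bvec, labels, and optionally
    labels_obs2 (second observer's ROI set) and flip (bvec sign flips).
    """
    sid = subject["subject_id"]
    dwi, voxel_size = tensor_mod.load_dwi(subject["dwi"])
    scheme = tensor_mod.load_scheme(subject["bval"], subject["bvec"],
                                    flip=tuple(subject.get("flip",
                                                           (False,) * 3)))
    field = tensor_mod.fit_tensor(dwi, scheme, voxel_size=voxel_size)
    label_paths = [subject["labels"]]
    if subject.get("labels_obs2"):
        label_paths.append(subject["labels_obs2"])

    rows: list[dict] = []
    for hemi in ("right", "left"):
        per_observer = []
        for obs, lpath in enumerate(label_paths, start=1):
            labels = tensor_mod.load_labels(lpath)
            proj, assoc = _roi_pair(labels, hemi)
            d = alps_mod.extract_axis_diffusivities(field, proj, assoc)
            res = alps_mod.single_observer_result(sid, hemi, d)
            per_observer.append((obs, d, res))
            rows.append(_alps_row(sid, hemi, str(obs), d, res.index))
        final = per_observer[0][2]
        if len(per_observer) == 2:
            final = alps_mod.average_observers(per_observer[0][2],
                                               per_observer[1][2])
        mean_d = _mean_diffusivities([d for _, d, _ in per_observer])
        rows.append(_alps_row(sid, hemi, "mean", mean_d, final.index))
    return rows


def _roi_pair(labels, hemisphere):
    from .phantom import phantom_roi_pair
    return phantom_roi_pair(labels, hemisphere)


def _mean_diffusivities(ds) -> alps_mod.AxisDiffusivities:
    return alps_mod.AxisDiffusivities(
        d_xproj=float(np.mean([d.d_xproj for d in ds])),
        d_yproj=float(np.mean([d.d_yproj for d in ds])),
        d_xassoc=float(np.mean([d.d_xassoc for d in ds])),
        d_zassoc=float(np.mean([d.d_zassoc for d in ds])),
    )


def _alps_row(sid, hemi, observer, d, index) -> dict:
    return {"subject_id": sid, "side": hemi, "observer": observer,
            "d_xproj": d.d_xproj, "d_yproj": d.d_yproj,
            "d_xassoc": d.d_xassoc, "d_zassoc": d.d_zassoc, "index": index}


def run_alps_pipeline(subjects: list[dict], out_csv=None) -> pd.DataFrame:
    """Fit tensors and compute per-subject, per-hemisphere ALPS indices.

    Per-subject failures are logged and skipped; the run fails only if no
    subject succeeds. Returns the per-observer + observer-mean table and
    optionally writes it as CSV.
    """
    all_rows: list[dict] = []
    n_ok = 0
    for subject in subjects:
        sid = subject.get("subject_id", "?")
        try:
            rows = _subject_alps_rows(subject)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            logger.error("subject %s skipped: %s", sid, exc)
            continue
        logger.info("subject %s: %d ALPS rows", sid, len(rows))
        all_rows.extend(rows)
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("ALPS pipeline failed for every subject")
    df = pd.DataFrame(all_rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


# ---------------------------------------------------------------------------
# Statistics flow
# ---------------------------------------------------------------------------

def run_group_comparison(cohort: pd.DataFrame,
                         config: StudyConfig | None = None) -> pd.DataFrame:
    """Table-2-style grid of age/sex-adjusted Bonferroni pairwise contrasts.

    For each requested tumor side the side's two patient groups are pooled
    with the controls; each ALPS response column gets one ANCOVA with three
    pairwise contrasts. Sides with a missing group are skipped with a
    warning.
    """
    config = config or StudyConfig()
    records = []
    for side in config.sides:
        sub = cohort[(cohort["tumor_side"] == side)
                     | (cohort["group"] == GROUP_CONTROL)]
        present = set(sub["group"])
        if not set(GROUP_ORDER) <= present:
            logger.warning("side %s skipped: groups missing (%s)", side,
                           sorted(set(GROUP_ORDER) - present))
            continue
        for response in config.responses:
            res = stats_mod.ancova_pairwise(
                sub, response=response, group_col="group",
                covariates=("age", "sex"), alpha=config.alpha,
                group_order=GROUP_ORDER)
            for c in res.contrasts:
                records.append({
                    "tumor_side": side, "response": response,
                    "group_a": c.group_a, "group_b": c.group_b,
                    "adj_diff": c.diff, "p_raw": c.p_raw, "p_adj": c.p_adj,
                    "ci_low": c.ci_low, "ci_high": c.ci_high,
                    "omnibus_p": res.omnibus_p,
                    "n_a": res.group_sizes[c.group_a],
                    "n_b": res.group_sizes[c.group_b],
                })
            logger.info("side %s response %s: omnibus p = %.4g", side,
                        response, res.omnibus_p)
    return pd.DataFrame(records)


def ipsilateral_alps(cohort: pd.DataFrame) -> pd.Series:
    """ALPS index on the tumor side (NaN for controls)."""
    side = cohort["tumor_side"].to_numpy()
    out = np.where(side == "right", cohort["alps_right"],
                   np.where(side == "left", cohort["alps_left"], np.nan))
    return pd.Series(out, index=cohort.index, name="alps_ipsi")


def run_correlation_analysis(cohort: pd.DataFrame,
                             config: StudyConfig | None = None):
    """PTBE-volume correlates in the PTBE+ subset.

    Returns ``(correlations, vifs, regression)``: seven Pearson
    correlations of PTBE volume against age, sex, grade, Ki-67, location,
    tumor volume and tumor-side ALPS; the VIF screen over the same
    candidates; and the stepwise multivariable regression.
    """
    config = config or StudyConfig()
    sub = cohort[cohort["group"] == GROUP_PTBE].copy()
    if len(sub) < 10:
        raise ValueError(
            f"PTBE+ subset has {len(sub)} rows; at least 10 are required")
    sub["alps_ipsi"] = ipsilateral_alps(sub)
    X = stats_mod.encode_binary_covariates(sub[CANDIDATE_COLUMNS])
    y = sub["ptbe_volume"].to_numpy(dtype=float)

    corr_rows = []
    for col in CANDIDATE_COLUMNS:
        res = stats_mod.pearson(X[col], y)
        corr_rows.append({"factor": col, "r": res.r, "p": res.p_value,
                          "n": res.n})
    correlations = pd.DataFrame(corr_rows)
    vifs = stats_mod.vif(X)
    regression = stats_mod.stepwise_regression(
        X, y, entry_p=config.stepwise_entry_p,
        removal_p=config.stepwise_removal_p)
    logger.info("stepwise selected: %s (R^2 = %.3f)", regression.selected,
                regression.r_squared)
    return correlations, vifs, regression


# ---------------------------------------------------------------------------
# Descriptives and report
# ---------------------------------------------------------------------------

def _bin_counts(values: np.ndarray, bins) -> dict:
    counts = {}
    for label, lo, hi in bins:
        counts[label] = int(np.sum((values >= lo) & (values < hi)))
    return counts


def descriptive_summary(cohort: pd.DataFrame) -> dict:
    """Table-1-style descriptive counts for the patient rows of a cohort."""
    pat = cohort[cohort["group"] != GROUP_CONTROL]
    tumor = pat["tumor_volume"].to_numpy(dtype=float)
    edema = pat["ptbe_volume"].to_numpy(dtype=float)
    edema_bins = {"0": int(np.sum(edema == 0.0))}
    nonzero = edema[edema > 0.0]
    first_label, _, first_hi = EDEMA_VOLUME_BINS[0]
    edema_bins[first_label] = int(np.sum(nonzero < first_hi))
    for label, lo, hi in EDEMA_VOLUME_BINS[1:]:
        edema_bins[label] = int(np.sum((nonzero >= lo) & (nonzero < hi)))
    out = {
        "n_patients": int(len(pat)),
        "n_controls": int((cohort["group"] == GROUP_CONTROL).sum()),
        "mean_age": float(pat["age"].mean()),
        "sex": pat["sex"].value_counts().to_dict(),
        "tumor_side": pat["tumor_side"].value_counts().to_dict(),
        "tumor_grade": pat["tumor_grade"].value_counts().to_dict(),
        "location": pat["location"].value_counts().to_dict(),
        "tumor_volume_bins": _bin_counts(tumor, TUMOR_VOLUME_BINS),
        "edema_volume_bins": edema_bins,
        "n_ptbe_present": int(np.sum(edema > 0.0)),
        "ptbe_absent_fraction": float(np.mean(edema == 0.0)),
    }
    if "site" in pat.columns:
        out["site"] = pat["site"].value_counts().to_dict()
    return out


def _plot_report(cohort: pd.DataFrame, outdir: Path, config: StudyConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for side, response in (("right", "alps_right"), ("left", "alps_left")):
        sub = cohort[(cohort["tumor_side"] == side)
                     | (cohort["group"] == GROUP_CONTROL)]
        data = [sub.loc[sub["group"] == g, response].to_numpy()
                for g in GROUP_ORDER]
        if any(len(d) == 0 for d in data):
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.boxplot(data, tick_labels=["PTBE-", "PTBE+", "normal"])
        ax.set_ylabel(f"{side} ALPS index")
        ax.set_title(f"{side}-side meningiomas vs controls")
        fig.tight_layout()
        fig.savefig(outdir / f"alps_{side}_boxplot.png", dpi=120)
        plt.close(fig)

    ptbe = cohort[cohort["group"] == GROUP_PTBE].copy()
    if len(ptbe) >= 3:
        x = ipsilateral_alps(ptbe).to_numpy()
        y = ptbe["ptbe_volume"].to_numpy()
        res = stats_mod.pearson(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(x, y, s=16)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, slope * xs + intercept, color="firebrick")
        ax.set_xlabel("ALPS index ipsilateral to tumor")
        ax.set_ylabel("PTBE volume (cm^3)")
        ax.set_title(f"r = {res.r:.3f}, p = {res.p_value:.2g}")
        fig.tight_layout()
        fig.savefig(outdir / "ptbe_vs_alps_scatter.png", dpi=120)
        plt.close(fig)


def write_report(cohort: pd.DataFrame, config: StudyConfig) -> dict:
    """Run the full statistics flow and write CSV/JSON (optionally PNG) outputs.

    Outputs under ``config.output_dir``: ``descriptives.json``,
    ``group_contrasts.csv``, ``correlations.csv``, ``stepwise.json`` and a
    combined ``report.json``. Byte-identical across runs for a fixed config
    and cohort.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    desc = descriptive_summary(cohort)
    grid = run_group_comparison(cohort, config)
    correlations, vifs, regression = run_correlation_analysis(cohort, config)

    grid.to_csv(outdir / "group_contrasts.csv", index=False)
    correlations.to_csv(outdir / "correlations.csv", index=False)
    stepwise_doc = {
        "selected": list(regression.selected),
        "coefficients": regression.coefficients,
        "std_coefficients": regression.std_coefficients,
        "p_values": regression.p_values,
        "r_squared": regression.r_squared,
        "entry_p": regression.entry_p,
        "removal_p": regression.removal_p,
        "vifs": {k: (None if not np.isfinite(v) else float(v))
                 for k, v in vifs.items()},
        "trace": [list(t) for t in regression.trace],
    }
    report = {"descriptives": desc,
              "group_contrasts": grid.to_dict(orient="records"),
              "correlations": correlations.to_dict(orient="records"),
              "stepwise": stepwise_doc,
              "alpha": config.alpha, "seed": config.seed}
    with open(outdir / "descriptives.json", "w") as fh:
        json.dump(desc, fh, indent=1, sort_keys=True)
    with open(outdir / "stepwise.json", "w") as fh:
        json.dump(stepwise_doc, fh, indent=1, sort_keys=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    if config.plots:
        _plot_report(cohort, outdir, config)
    logger.info("report written to %s", outdir)
    return report


def load_cohort(config: StudyConfig) -> pd.DataFrame:
    if config.cohort_csv is None:
        raise ValueError("config.cohort_csv is not set")
    return cohort_from_csv(config.cohort_csv)
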