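"""Plate-level orchestration and group statistics.

Runs the per-well analyses (contraction trace -> peaks -> Hooke's-law force
estimate for movies; 3D quantification for stacks) across a 96-well layout,
aggregates one metrics row per well, and provides the assay's comparisons:
a rank-based two-group test (Mann-Whitney U, configurable to Welch's t) and
Dunnett's many-to-one procedure for dose-response series, with group means
+/- SEM as reported alongside the figures of such assays.

A failing well is flagged in its own row and never aborts the plate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import hci, synthetic
from .force import ForceParameters, peak_specific_force
from .piv import PivConfig, contraction_trace, detect_peaks

__all__ = [
    "GroupComparison",
    "load_layout",
    "run_plate",
    "compare_groups",
    "dose_response",
]

SIGNIFICANCE_TIERS = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class GroupComparison:
    """Result of one metric's comparison between groups."""

    metric: str
    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sems: tuple[float, float]
    test: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    warnings: list[str] = field(default_factory=list)

    def stars(self) -> str:
        """Significance stars at the conventional tiers (report output only)."""
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return "*" * sum(p < tier for tier in SIGNIFICANCE_TIERS)


def load_layout(path: Path) -> pd.DataFrame:
    """Read and validate a plate-layout CSV (well, condition[, dose, files])."""
    layout = pd.read_csv(path)
    if "well" not in layout or "condition" not in layout:
        raise ValueError("layout needs 'well' and 'condition' columns")
    wells = [synthetic.validate_well_id(w) for w in layout["well"]]
    if len(set(wells)) != len(wells):
        raise ValueError("duplicate well ids in layout")
    return layout


def run_plate(
    layout: pd.DataFrame,
    data_dir: Path,
    piv_config: PivConfig = PivConfig(),
    seg_configs: dict[str, hci.SegmentationConfig] | None = None,
    sheet_thickness_um: float = 30.0,
    min_prominence_um_s: float = 0.0,
) -> pd.DataFrame:
    """Analyse every well of a plate; one metrics row per well.

    ``layout`` may carry explicit ``movie``/``stack`` file columns; otherwise
    files are resolved from ``data_dir/manifest.csv`` as written by
    :func:`myoscreen.synthetic.make_plate`.  Failures are isolated per well
    (status == 'failed', error message recorded, all metric columns NaN).
    """
    if len(layout) == 0:
        raise ValueError("empty layout")
    data_dir = Path(data_dir)
    files: dict[tuple[str, str], str] = {}
    manifest_path = data_dir / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        for rec in manifest.to_dict("records"):
            files[(rec["well"], rec["kind"])] = rec["file"]

    rows = []
    for rec in layout.to_dict("records"):
        well = rec["well"]
        row: dict = dict(
            well=well, condition=rec["condition"],
            dose=rec.get("dose", np.nan), status="ok", error="",
        )
        movie_file = rec.get("movie") or files.get((well, "movie"))
        stack_file = rec.get("stack") or files.get((well, "stack"))
        try:
            if movie_file:
                row.update(_analyse_movie(
                    data_dir / movie_file, piv_config,
                    sheet_thickness_um, min_prominence_um_s,
                ))
            if stack_file:
                row.update(_analyse_stack(data_dir / stack_file, seg_configs))
        except Exception as exc:  # fault isolation: flag, keep going
            row["status"] = "failed"
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def _analyse_movie(
    path: Path, piv_config: PivConfig,
    sheet_thickness_um: float, min_prominence_um_s: float,
) -> dict:
    movie, meta = synthetic.read_movie(path)
    trace = contraction_trace(
        movie, piv_config,
        frame_rate_hz=meta["frame_rate_hz"],
        pixel_size_um=meta["pixel_size_um"],
    )
    trace = detect_peaks(trace, min_prominence=min_prominence_um_s)
    params = ForceParameters.for_movie(
        movie.shape[1], movie.shape[2],
        pixel_size_um=meta["pixel_size_um"],
        frame_rate_hz=meta["frame_rate_hz"],
        finest_window_px=piv_config.window_sizes_px[-1],
        sheet_thickness_um=sheet_thickness_um,
    )
    est = peak_specific_force(trace, params)
    return dict(
        n_peaks=len(trace.peak_indices),
        peak_time_s=est.time_s,
        peak_speed_um_s=float(np.nanmax(trace.mean_speed_um_s)),
        peak_abs_vx_um_s=est.v_x_um_s,
        peak_abs_vy_um_s=est.v_y_um_s,
        d_um=est.d_combined_um,
        eps_x=est.eps_x, eps_y=est.eps_y,
        sigma_x_kpa=est.sigma_x_kpa, sigma_y_kpa=est.sigma_y_kpa,
        specific_force_kn_m2=est.specific_force_kn_m2,
        f_x_nn=est.f_x_nn, f_y_nn=est.f_y_nn, f_nn=est.f_combined_nn,
    )


def _analyse_stack(
    path: Path, seg_configs: dict[str, hci.SegmentationConfig] | None
) -> dict:
    stack, meta = synthetic.read_stack(path)
    channel_map = {n: i for i, n in enumerate(meta["channels"])}
    metrics, _ = hci.well_metrics(
        stack, tuple(meta["voxel_size_zyx_um"]),
        channel_map=channel_map, configs=seg_configs,
    )
    return metrics.as_dict()


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _group_values(metrics: pd.DataFrame, metric: str, label: str) -> np.ndarray:
    sel = metrics[(metrics["condition"] == label)
                  & (metrics.get("status", "ok") == "ok")]
    vals = sel[metric].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]  # listwise exclusion of missing metrics


def compare_groups(
    metrics: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    method: str = "mannwhitney",
) -> GroupComparison:
    """Two-sided two-sample comparison of one metric between two conditions.

    Default is the Mann-Whitney U test (the conventional nonparametric
    two-sample test); ``method='welch'`` switches to Welch's t.  Degenerate
    all-tied data reports p = 1 with a warning record.
    """
    a = _group_values(metrics, metric, group_a)
    b = _group_values(metrics, metric, group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 wells with this metric")
    notes: list[str] = []
    if np.ptp(np.concatenate([a, b])) == 0:
        notes.append("degenerate all-tied data")
        stat, p = 0.0, 1.0
        test = method
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p, test = float(res.statistic), float(res.pvalue), "mannwhitney-u"
    elif method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p, test = float(res.statistic), float(res.pvalue), "welch-t"
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        metric=metric,
        groups=(group_a, group_b),
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        sems=(float(stats.sem(a)), float(stats.sem(b))),
        test=test,
        statistic=stat,
        p_value=p,
        warnings=notes,
    )


def dose_response(
    metrics: pd.DataFrame,
    metric: str,
    control_label: str,
    dose_labels: dict[str, float],
) -> tuple[list[GroupComparison], bool]:
    """Each dose vs control via Dunnett's many-to-one procedure.

    ``dose_labels`` maps condition labels to numeric doses; input order is
    irrelevant (sorted by dose internally).  Returns the per-dose comparisons
    (with Dunnett-adjusted p-values) and a trend flag: whether the group
    means are monotone in dose, anchored at the control.  With a single dose
    the comparison falls back to :func:`compare_groups` with a warning.
    """
    if not dose_labels:
        raise ValueError("no dose groups given")
    ordered = sorted(dose_labels.items(), key=lambda kv: kv[1])
    control = _group_values(metrics, metric, control_label)
    if len(control) < 2:
        raise ValueError("control group needs >= 2 wells")
    samples = []
    for label, _ in ordered:
        vals = _group_values(metrics, metric, label)
        if len(vals) < 2:
            raise ValueError(f"group {label!r} needs >= 2 wells")
        samples.append(vals)

    if len(ordered) == 1:
        warnings.warn("single dose level: falling back to two-group test")
        comp = compare_groups(metrics, metric, ordered[0][0], control_label)
        comp.warnings.append("single dose: no many-to-one adjustment")
        comps = [comp]
    else:
        # fixed rng: Dunnett's p integrates a multivariate t numerically,
        # and plate outputs must be bit-reproducible
        res = stats.dunnett(*samples, control=control, rng=0)
        comps = []
        for k, (label, _) in enumerate(ordered):
            vals = samples[k]
            comps.append(GroupComparison(
                metric=metric,
                groups=(label, control_label),
                n=(len(vals), len(control)),
                means=(float(vals.mean()), float(control.mean())),
                sems=(float(stats.sem(vals)), float(stats.sem(control))),
                test="dunnett",
                statistic=float(res.statistic[k]),
                p_value=float(res.pvalue[k]),
                p_adjusted=float(res.pvalue[k]),  # Dunnett p is family-adjusted
            ))

    means = [float(control.mean())] + [float(s.mean()) for s in samples]
    diffs = np.diff(means)
    trend = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    return comps, trend


def comparisons_to_frame(comps: list[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons into a report table."""
    rows = []
    for c in comps:
        rows.append(dict(
            metric=c.metric, group=c.groups[0], reference=c.groups[1],
            n_group=c.n[0], n_reference=c.n[1],
            mean_group=c.means[0], mean_reference=c.means[1],
            sem_group=c.sems[0], sem_reference=c.sems[1],
            test=c.test, statistic=c.statistic, p_value=c.p_value,
            p_adjusted=c.p_adjusted, stars=c.stars(),
        ))
    return pd.DataFrame(rows)
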