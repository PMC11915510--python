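"""Nucleolus-to-nucleoplasm ratio tracking and divergence-onset statistics.

A treatment time-lapse is reduced to one ratio per nucleolus per frame: the
mean fluorescence over the nucleolus pixels divided by the mean over its
parent nucleoplasm (nucleus minus nucleoli).  The ratio is therefore
invariant to any global linear rescaling of a frame.  Group divergence over
time is assessed with a two-way repeated-measures (split-plot) ANOVA — time
within subjects, treatment group between subjects — followed by per-frame
Tukey-HSD group contrasts; the onset is the earliest frame whose adjusted
p-value clears alpha.

Nucleoli are found as dark, compact objects in the nucleus-masked phase
contrast image with a deterministic heuristic (inverted phase, per-nucleus
Otsu with a bimodality gate); externally trained pixel classifiers can be
substituted through :func:`nucleoquant.nuclei.load_external_labels`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.stats import studentized_range, tukey_hsd

from .errors import ContractError
from .nuclei import LabelMask, nucleoplasm_mask

RATIO_COLUMNS = ["cell_id", "nucleolus_id", "frame", "time_min", "ratio", "group"]


# -- nucleolus detection from phase contrast ----------------------------------


def _otsu_with_separability(values: np.ndarray) -> tuple[float, float]:
    """Otsu threshold plus the between-class/total variance ratio (0..1)."""
    hist, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    total = w.sum()
    if total == 0:
        return float(values.mean()), 0.0
    p = w / total
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    denom = omega * (1.0 - omega)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b2 = np.where(denom > 0, (mu_t * omega - mu) ** 2 / denom, 0.0)
    k = int(np.argmax(sigma_b2))
    total_var = float(((centers - mu_t) ** 2 * p).sum())
    eta = float(sigma_b2[k] / total_var) if total_var > 0 else 0.0
    return float(centers[k]), eta


def detect_nucleoli_phase(
    phase_img: np.ndarray,
    nucleus_mask: LabelMask,
    min_area: int = 20,
    smooth_sigma: float = 1.0,
    separability_min: float = 0.6,
) -> tuple[LabelMask, dict[int, int]]:
    """Segment nucleoli as dark compact bodies inside each nucleus.

    The phase image is smoothed and inverted; inside each nucleus an Otsu
    split of the inverted intensities marks the nucleolus.  Nuclei whose
    intensity histogram is not clearly bimodal (Otsu separability below
    ``separability_min``) are recorded with no nucleolus rather than split on
    noise.  Returns the nucleolus label mask and a nucleolus -> parent nucleus
    map.
    """
    phase = np.asarray(phase_img, dtype=float)
    if phase.shape != nucleus_mask.labels.shape:
        raise ContractError("phase image and nucleus mask shapes differ")
    inv = -ndi.gaussian_filter(phase, smooth_sigma)

    out = np.zeros(phase.shape, dtype=np.int32)
    parent: dict[int, int] = {}
    next_label = 1
    for nid in nucleus_mask.ids:
        sel = nucleus_mask.labels == nid
        vals = inv[sel]
        if vals.max() == vals.min():
            continue  # uniform: no nucleolus, ratio will be missing
        thr, eta = _otsu_with_separability(vals)
        if eta < separability_min:
            continue
        cand = np.zeros(phase.shape, dtype=bool)
        cand[sel] = inv[sel] > thr
        lab, n = ndi.label(cand, structure=ndi.generate_binary_structure(2, 1))
        for j in range(1, n + 1):
            obj = lab == j
            if obj.sum() >= min_area:
                out[obj] = next_label
                parent[next_label] = int(nid)
                next_label += 1
    return LabelMask(out), parent


# -- trajectory quality filtering ---------------------------------------------


def exclude_objects(objects: pd.DataFrame, rules: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop whole-cell trajectories violating feature bounds.

    ``objects`` holds one row per (cell_id, frame) with feature columns such
    as ``area``, ``eccentricity`` and ``mean_intensity``.  Supported rules:

    - ``max_area_drop``: fractional area collapse between consecutive frames
      (e.g. 0.4 flags dying/dividing cells);
    - ``min_area`` / ``max_area``;
    - ``max_eccentricity``;
    - ``min_intensity`` / ``max_intensity``.

    A violating cell is removed for *all* frames, so the surviving cells'
    measurements are untouched.  Returns (filtered table, exclusion log).
    """
    known = {
        "max_area_drop",
        "min_area",
        "max_area",
        "max_eccentricity",
        "min_intensity",
        "max_intensity",
    }
    unknown = set(rules) - known
    if unknown:
        raise ContractError(f"unknown exclusion rules {sorted(unknown)}")

    log = []
    bad: set = set()
    for cid, sub in objects.groupby("cell_id"):
        sub = sub.sort_values("frame")
        reasons = []
        if "max_area_drop" in rules and len(sub) > 1:
            a = sub["area"].to_numpy(dtype=float)
            drop = 1.0 - a[1:] / np.maximum(a[:-1], 1e-12)
            if np.nanmax(drop) > rules["max_area_drop"]:
                reasons.append("area_collapse")
        if "min_area" in rules and (sub["area"] < rules["min_area"]).any():
            reasons.append("area_below_min")
        if "max_area" in rules and (sub["area"] > rules["max_area"]).any():
            reasons.append("area_above_max")
        if (
            "max_eccentricity" in rules
            and "eccentricity" in sub
            and (sub["eccentricity"] > rules["max_eccentricity"]).any()
        ):
            reasons.append("eccentricity")
        if (
            "min_intensity" in rules
            and "mean_intensity" in sub
            and (sub["mean_intensity"] < rules["min_intensity"]).any()
        ):
            reasons.append("intensity_below_min")
        if (
            "max_intensity" in rules
            and "mean_intensity" in sub
            and (sub["mean_intensity"] > rules["max_intensity"]).any()
        ):
            reasons.append("intensity_above_max")
        if reasons:
            bad.add(cid)
            log.append({"cell_id": cid, "reason": "+".join(reasons)})

    filtered = objects[~objects["cell_id"].isin(bad)].copy()
    if filtered.empty and not objects.empty:
        warnings.warn("all cells excluded by the configured rules", stacklevel=2)
    return filtered, pd.DataFrame(log, columns=["cell_id", "reason"])


# -- per-frame ratios with overlap tracking -----------------------------------


def _link_by_overlap(prev: np.ndarray, curr: np.ndarray, track_of_prev: dict[int, int],
                     next_track: int) -> tuple[dict[int, int], int]:
    """Assign current labels to track ids by maximum pixel overlap with the
    previous frame; ties go to the larger overlap then the lower label."""
    track_of_curr: dict[int, int] = {}
    curr_ids = np.unique(curr[curr > 0])
    claimed: dict[int, tuple[int, int]] = {}  # track -> (overlap, curr label)
    for cid in curr_ids:
        sel = curr == cid
        overl = prev[sel]
        overl = overl[overl > 0]
        if overl.size:
            counts = np.bincount(overl)
            best_prev = int(counts.argmax())  # argmax returns lowest on ties
            best_ov = int(counts.max())
            trk = track_of_prev.get(best_prev)
            if trk is not None:
                old = claimed.get(trk)
                if old is None or best_ov > old[0]:
                    if old is not None:
                        track_of_curr[old[1]] = -1  # displaced, reassign below
                    claimed[trk] = (best_ov, int(cid))
                    track_of_curr[int(cid)] = trk
                    continue
        track_of_curr[int(cid)] = -1
    for cid, trk in track_of_curr.items():
        if trk == -1:
            track_of_curr[cid] = next_track
            next_track += 1
    return track_of_curr, next_track


def ratio_timeseries(
    fluor_frames: np.ndarray,
    nuclei_frames: list[LabelMask],
    nucleoli_frames: list[LabelMask],
    group: str = "control",
    frame_interval_min: float = 5.0,
) -> pd.DataFrame:
    """Per-nucleolus nucleolus/nucleoplasm intensity ratios over a time-lapse.

    ``fluor_frames`` is a ``(t, y, x)`` array; the mask lists give one
    :class:`LabelMask` per frame.  Nucleolus (and nucleus) identity across
    frames is established by maximum mask overlap with the previous frame.
    Frames where a nucleus has an empty nucleoplasm yield a missing ratio.
    """
    fluor = np.asarray(fluor_frames, dtype=float)
    if fluor.ndim != 3:
        raise ContractError("fluor_frames must be (t, y, x)")
    n_frames = fluor.shape[0]
    if not (len(nuclei_frames) == len(nucleoli_frames) == n_frames):
        raise ContractError("one mask per frame is required")

    rows = []
    nuc_tracks: dict[int, int] = {}
    nol_tracks: dict[int, int] = {}
    next_nuc = next_nol = 1
    for f in range(n_frames):
        nuclei = nuclei_frames[f]
        nols = nucleoli_frames[f]
        if f == 0:
            nuc_tracks = {int(i): None for i in nuclei.ids}
            for i in nuclei.ids:
                nuc_tracks[int(i)] = next_nuc
                next_nuc += 1
            nol_tracks = {}
            for i in nols.ids:
                nol_tracks[int(i)] = next_nol
                next_nol += 1
        else:
            nuc_tracks, next_nuc = _link_by_overlap(
                nuclei_frames[f - 1].labels, nuclei.labels, prev_nuc_tracks, next_nuc
            )
            nol_tracks, next_nol = _link_by_overlap(
                nucleoli_frames[f - 1].labels, nols.labels, prev_nol_tracks, next_nol
            )
        prev_nuc_tracks, prev_nol_tracks = nuc_tracks, nol_tracks

        nucleoplasm = nucleoplasm_mask(nuclei, nols)
        img = fluor[f]
        for nol_id in nols.ids:
            nol_id = int(nol_id)
            sel = nols.labels == nol_id
            owners = nuclei.labels[sel]
            owners = owners[owners > 0]
            if owners.size == 0:
                continue
            parent = int(np.bincount(owners).argmax())
            np_sel = nucleoplasm.labels == parent
            ratio = (
                float(img[sel].mean() / img[np_sel].mean())
                if np_sel.any() and img[np_sel].mean() != 0
                else np.nan
            )
            rows.append(
                {
                    "cell_id": nuc_tracks.get(parent, parent),
                    "nucleolus_id": nol_tracks[nol_id],
                    "frame": f,
                    "time_min": f * frame_interval_min,
                    "ratio": ratio,
                    "group": group,
                }
            )
    return pd.DataFrame(rows, columns=RATIO_COLUMNS)


# -- repeated-measures ANOVA and onset ----------------------------------------


@dataclass
class OnsetResult:
    """Two-way repeated-measures ANOVA output with per-frame contrasts.

    ``first_significant`` is the earliest frame whose Tukey-adjusted group
    contrast clears alpha, reported only when the interaction or group main
    effect itself is significant.
    """

    anova: pd.DataFrame
    per_frame: pd.DataFrame
    first_significant: int | None
    alpha: float
    n_subjects: int
    n_dropped: int
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)


def rm_anova_onset(
    series: pd.DataFrame,
    alpha: float = 0.05,
    correction: bool = False,
    posthoc: str = "cells",
) -> OnsetResult:
    """Locate the first frame at which treatment groups diverge.

    Subjects are nucleoli with complete tracks (rows for every frame);
    incomplete tracks are dropped and counted.  The ANOVA is the standard
    split-plot design (within factor: frame; between factor: group) computed
    with ``pingouin.mixed_anova``; ``correction=True`` applies the
    Greenhouse-Geisser epsilon to the within-subject p-values.

    Post hoc, the group contrast at each frame is adjusted with the Tukey
    HSD studentized-range statistic.  With ``posthoc="cells"`` (default) the
    Tukey family is *all* frame-by-group cell means — the adjustment that
    makes "the earliest significant timepoint" meaningful, since an
    unadjusted 5% level would fire on roughly one pre-onset frame in twenty
    by chance alone.  ``posthoc="per_frame"`` restricts the family to the
    groups within each frame (a plain Tukey HSD per frame).
    """
    import pingouin as pg

    df = series.dropna(subset=["ratio"]).copy()
    if df.empty:
        raise ContractError("empty ratio table")
    df["subject"] = (
        df["group"].astype(str)
        + "/"
        + df["cell_id"].astype(str)
        + "/"
        + df["nucleolus_id"].astype(str)
    )
    frames = np.sort(df["frame"].unique())
    if len(frames) < 2:
        raise ContractError("need >= 2 frames")

    wide = df.pivot_table(index="subject", columns="frame", values="ratio")
    complete = wide.dropna(axis=0).index
    n_dropped = len(wide) - len(complete)
    df = df[df["subject"].isin(complete)]
    groups = df.groupby("subject")["group"].first()
    group_levels = np.sort(groups.unique())
    if len(group_levels) < 2:
        raise ContractError("need >= 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ContractError(f"every group needs >= 2 complete subjects; got {dict(sizes)}")

    notes: list[str] = []
    if n_dropped:
        notes.append(f"dropped {n_dropped} incomplete subject track(s)")

    # degenerate noiseless data: the F statistic is 0/0
    resid_var = df.groupby(["group", "frame"])["ratio"].var(ddof=1)
    if np.allclose(resid_var.fillna(0.0), 0.0):
        warnings.warn("zero residual variance: test statistics undefined", stacklevel=2)
        per_frame = pd.DataFrame(
            {"frame": frames, "p_tukey": np.nan, "diff": 0.0}
        )
        return OnsetResult(
            anova=pd.DataFrame(),
            per_frame=per_frame,
            first_significant=None,
            alpha=alpha,
            n_subjects=len(complete),
            n_dropped=n_dropped,
            degenerate=True,
            notes=notes + ["degenerate: no residual variance"],
        )

    aov = pg.mixed_anova(
        data=df,
        dv="ratio",
        within="frame",
        between="group",
        subject="subject",
        correction=correction,
    )
    def _col(*names: str) -> str | None:
        return next((n for n in names if n in aov.columns), None)

    p_unc_col = _col("p_unc", "p-unc")
    p_gg_col = _col("p_GG_corr", "p-GG-corr") if correction else None

    def _p(source: str) -> float:
        row = aov[aov["Source"] == source]
        if row.empty:
            return np.nan
        col = p_gg_col if (p_gg_col and source != "group") else p_unc_col
        val = row.iloc[0][col]
        return float(val) if np.isfinite(val) else np.nan

    p_interaction = _p("Interaction")
    p_group = _p("group")

    if posthoc not in ("cells", "per_frame"):
        raise ContractError("posthoc must be 'cells' or 'per_frame'")
    per_rows = []
    if posthoc == "cells":
        # Tukey-Kramer over the full family of frame x group cell means,
        # pooled within-cell error
        cell = df.groupby(["group", "frame"])["ratio"].agg(["mean", "var", "count"])
        df_err = int((cell["count"] - 1).sum())
        mse = float(
            ((cell["count"] - 1) * cell["var"].fillna(0.0)).sum() / df_err
        )
        k_means = len(cell)
        for f in frames:
            stats = [cell.loc[(g, f)] for g in group_levels]
            pvals = []
            for i in range(len(stats)):
                for j in range(i + 1, len(stats)):
                    se = math.sqrt(
                        mse / 2.0 * (1.0 / stats[i]["count"] + 1.0 / stats[j]["count"])
                    )
                    q = abs(stats[i]["mean"] - stats[j]["mean"]) / se
                    pvals.append(float(studentized_range.sf(q, k_means, df_err)))
            means = [float(s["mean"]) for s in stats]
            per_rows.append(
                {
                    "frame": int(f),
                    "p_tukey": float(min(pvals)),
                    "diff": float(means[-1] - means[0]),
                    **{f"mean_{g}": m for g, m in zip(group_levels, means)},
                }
            )
    else:
        for f in frames:
            sub = df[df["frame"] == f]
            samples = [
                sub.loc[sub["group"] == g, "ratio"].to_numpy() for g in group_levels
            ]
            res = tukey_hsd(*samples)
            pvals = [
                res.pvalue[i, j]
                for i in range(len(samples))
                for j in range(i + 1, len(samples))
            ]
            means = [s.mean() for s in samples]
            per_rows.append(
                {
                    "frame": int(f),
                    "p_tukey": float(min(pvals)),
                    "diff": float(means[-1] - means[0]),
                    **{f"mean_{g}": float(m) for g, m in zip(group_levels, means)},
                }
            )
    per_frame = pd.DataFrame(per_rows)

    first = None
    gate = (np.isfinite(p_interaction) and p_interaction < alpha) or (
        np.isfinite(p_group) and p_group < alpha
    )
    if gate:
        sig = per_frame[per_frame["p_tukey"] < alpha]
        if not sig.empty:
            first = int(sig["frame"].iloc[0])

    return OnsetResult(
        anova=aov,
        per_frame=per_frame,
        first_significant=first,
        alpha=alpha,
        n_subjects=len(complete),
        n_dropped=n_dropped,
        notes=notes,
    )
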