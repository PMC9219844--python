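"""Feature-level metabolomics statistics: retention-time alignment across
runs, technical-replicate averaging, Welch tests on log2 intensities, BH-FDR
adjustment, and the signed fold-change display convention.

The model is the standard one for untargeted LC-MS intensity data: feature
intensities are treated as log-normal, so group comparison is a Welch
(unequal-variance) two-sided t-test on log2(intensity + pseudo) with a
pseudo-intensity guarding against zeros.  Multiplicity is controlled with
Benjamini-Hochberg across all tested features.  Fold-changes are reported
both as log2 differences and in the signed display convention in which a
k-fold decrease prints as -k (so |signed fold| >= 1 always).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "align_retention",
    "average_technical_replicates",
    "test_feature",
    "bh_adjust",
    "signed_fold_change",
    "differential_analysis",
    "DIFF_COLUMNS",
]

DIFF_COLUMNS = [
    "id",
    "mz",
    "rt",
    "signed_fold_change",
    "log2fc",
    "p_value",
    "q_value",
    "direction",
]


@dataclass
class FeatureTable:
    """A feature x sample intensity table with sample group assignments.

    ``data`` holds columns id, mz, rt and one intensity column per sample;
    ``sample_groups`` maps each sample to "control" or "treated";
    ``fraction`` names the extract fraction (pellet or conditioned media).
    """

    data: pd.DataFrame
    sample_groups: dict
    fraction: str = "pellet"

    def __post_init__(self) -> None:
        missing = [c for c in ("id", "mz", "rt") if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        if self.data["id"].duplicated().any():
            dupes = self.data.loc[self.data["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        for sample, group in self.sample_groups.items():
            if group not in ("control", "treated"):
                raise ValueError(f"sample {sample!r}: group must be control/treated, got {group!r}")
            if sample not in self.data.columns:
                raise ValueError(f"sample {sample!r} missing from feature table columns")

    @property
    def samples(self) -> list[str]:
        return [s for s in self.data.columns if s in self.sample_groups]

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups[s] == group]

    def to_tsv(self, features_path, samples_path, header_comment: Optional[str] = None) -> None:
        cols = ["id", "mz", "rt"] + self.samples
        with open(features_path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data[cols].to_csv(fh, sep="\t", index=False, lineterminator="\n")
        sheet = pd.DataFrame(
            {
                "sample": self.samples,
                "group": [self.sample_groups[s] for s in self.samples],
                "fraction": self.fraction,
            }
        )
        with open(samples_path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            sheet.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, features_path, samples_path) -> "FeatureTable":
        data = pd.read_csv(features_path, sep="\t", comment="#")
        sheet = pd.read_csv(samples_path, sep="\t", comment="#")
        groups = dict(zip(sheet["sample"], sheet["group"]))
        fraction = sheet["fraction"].iloc[0] if "fraction" in sheet.columns else "pellet"
        return cls(data=data, sample_groups=groups, fraction=fraction)


# ---------------------------------------------------------------------------
# Retention-time alignment ("peak groups" style)
# ---------------------------------------------------------------------------


def _cluster_by_mz(pooled: pd.DataFrame, mz_tol_ppm: float) -> np.ndarray:
    """Greedy gap clustering of pooled features on sorted m/z.

    Consecutive sorted m/z values join one cluster while the relative gap
    stays within the tolerance; a larger gap opens a new cluster.
    """
    order = np.argsort(pooled["mz"].to_numpy())
    mz_sorted = pooled["mz"].to_numpy()[order]
    labels_sorted = np.zeros(len(pooled), dtype=int)
    label = 0
    for i in range(1, len(mz_sorted)):
        if (mz_sorted[i] - mz_sorted[i - 1]) / mz_sorted[i - 1] * 1e6 > mz_tol_ppm:
            label += 1
        labels_sorted[i] = label
    labels = np.empty(len(pooled), dtype=int)
    labels[order] = labels_sorted
    return labels


def align_retention(
    runs: Sequence[tuple[str, pd.DataFrame]],
    mz_tol_ppm: float = 10.0,
    anchor_min_presence: float = 1.0,
    sample_groups: Optional[Mapping[str, str]] = None,
    fraction: str = "pellet",
) -> FeatureTable:
    """Align per-run feature lists on shared anchors and merge them.

    Each run is a (sample_id, DataFrame[id, mz, rt, intensity]) pair.
    Features are matched across runs by m/z (gap clustering at
    ``mz_tol_ppm``); clusters represented exactly once in at least
    ``anchor_min_presence`` of the runs serve as anchors.  The run whose
    anchor RTs sit closest to the cross-run anchor medians is the reference;
    every other run receives a monotone piecewise-linear RT map onto the
    reference anchors (linear interpolation between anchors, slope-1
    extrapolation with the edge offset outside the anchor range).

    Returns a merged FeatureTable with one intensity column per run and
    consensus (median) corrected RT and m/z per cluster.
    """
    if len(runs) < 2:
        raise ValueError("alignment requires at least two runs")
    frames = []
    for run_idx, (sample, df) in enumerate(runs):
        f = df[["id", "mz", "rt", "intensity"]].copy()
        f["run"] = run_idx
        f["sample"] = sample
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["cluster"] = _cluster_by_mz(pooled, mz_tol_ppm)

    n_runs = len(runs)
    min_runs = int(np.ceil(anchor_min_presence * n_runs))
    # anchors: clusters with exactly one member in >= min_runs runs and no run duplicated
    anchor_rt = {}  # cluster -> {run: rt}
    for cluster, block in pooled.groupby("cluster"):
        run_counts = block["run"].value_counts()
        if (run_counts == 1).all() and len(run_counts) >= min_runs:
            anchor_rt[cluster] = dict(zip(block["run"], block["rt"]))
    if not anchor_rt:
        raise ValueError(
            "no alignment anchors found across runs; try a larger m/z tolerance"
        )

    anchors = sorted(anchor_rt)
    med = np.array([np.median(list(anchor_rt[a].values())) for a in anchors])
    # reference run: minimal mean |rt - median| over anchors it participates in
    best_run, best_score = 0, np.inf
    for run_idx in range(n_runs):
        devs = [
            abs(anchor_rt[a][run_idx] - med[i])
            for i, a in enumerate(anchors)
            if run_idx in anchor_rt[a]
        ]
        score = np.mean(devs) if devs else np.inf
        if score < best_score - 1e-12:
            best_run, best_score = run_idx, score

    ref_points = {a: anchor_rt[a][best_run] for a in anchors if best_run in anchor_rt[a]}

    def make_map(run_idx: int):
        xs, ys = [], []
        for a in anchors:
            if run_idx in anchor_rt[a] and a in ref_points:
                xs.append(anchor_rt[a][run_idx])
                ys.append(ref_points[a])
        if not xs:
            return lambda rt: rt
        order = np.argsort(xs)
        xs_arr = np.asarray(xs)[order]
        ys_arr = np.maximum.accumulate(np.asarray(ys)[order])  # enforce monotone map

        def mapper(rt, xs_arr=xs_arr, ys_arr=ys_arr):
            rt = np.asarray(rt, dtype=float)
            out = np.interp(rt, xs_arr, ys_arr)
            below = rt < xs_arr[0]
            above = rt > xs_arr[-1]
            out = np.where(below, rt + (ys_arr[0] - xs_arr[0]), out)
            out = np.where(above, rt + (ys_arr[-1] - xs_arr[-1]), out)
            return out

        return mapper

    corrected = np.empty(len(pooled))
    for run_idx in range(n_runs):
        mask = pooled["run"] == run_idx
        corrected[mask.to_numpy()] = make_map(run_idx)(pooled.loc[mask, "rt"].to_numpy())
    pooled["rt_corrected"] = corrected

    # merge clusters into consensus features; at most one member per run is
    # kept per cluster (the member closest to the cluster median m/z), any
    # extras fall back to singleton features
    rows = []
    sample_names = [s for s, _ in runs]
    extra_rows = []
    for cluster, block in pooled.groupby("cluster"):
        keep_idx = []
        for run_idx, sub in block.groupby("run"):
            if len(sub) == 1:
                keep_idx.extend(sub.index)
            else:
                center = sub["mz"].median()
                nearest = (sub["mz"] - center).abs().idxmin()
                keep_idx.append(nearest)
                extra_rows.extend(i for i in sub.index if i != nearest)
        kept = block.loc[keep_idx]
        feat_id = kept["id"].mode().iloc[0]
        intensities = {s: 0.0 for s in sample_names}
        for _, r in kept.iterrows():
            intensities[r["sample"]] = r["intensity"]
        rows.append(
            {
                "id": feat_id,
                "mz": float(kept["mz"].median()),
                "rt": float(kept["rt_corrected"].median()),
                **intensities,
            }
        )
    for i in extra_rows:
        r = pooled.loc[i]
        intensities = {s: 0.0 for s in sample_names}
        intensities[r["sample"]] = r["intensity"]
        rows.append(
            {
                "id": f"{r['id']}__dup{i}",
                "mz": float(r["mz"]),
                "rt": float(r["rt_corrected"]),
                **intensities,
            }
        )
    data = pd.DataFrame(rows).sort_values(["mz", "rt"]).reset_index(drop=True)
    if data["id"].duplicated().any():
        # distinct m/z clusters can share a source id only if a run emitted the
        # same id twice; disambiguate deterministically
        counts: dict[str, int] = {}
        new_ids = []
        for fid in data["id"]:
            n = counts.get(fid, 0)
            new_ids.append(fid if n == 0 else f"{fid}__{n}")
            counts[fid] = n + 1
        data["id"] = new_ids
    groups = dict(sample_groups) if sample_groups else {s: "control" for s in sample_names}
    return FeatureTable(data=data, sample_groups=groups, fraction=fraction)


# ---------------------------------------------------------------------------
# Replicate averaging and per-feature testing
# ---------------------------------------------------------------------------


def average_technical_replicates(table: FeatureTable, tech_map: Mapping[str, str]) -> FeatureTable:
    """Arithmetic-mean technical replicates into one column per biological sample.

    ``tech_map`` maps each technical run/sample name to its biological sample
    id; singleton groups pass through unchanged.  Group labels must agree
    within each biological sample.
    """
    bio_samples: dict[str, list[str]] = {}
    for tech, bio in tech_map.items():
        bio_samples.setdefault(bio, []).append(tech)
    for bio, members in bio_samples.items():
        if not members:
            raise ValueError(f"biological sample {bio!r} has no technical replicates")
        labels = {table.sample_groups[m] for m in members}
        if len(labels) != 1:
            raise ValueError(f"biological sample {bio!r} mixes groups {labels}")
    data = table.data[["id", "mz", "rt"]].copy()
    groups = {}
    for bio in sorted(bio_samples):
        members = bio_samples[bio]
        data[bio] = table.data[members].mean(axis=1)
        groups[bio] = table.sample_groups[members[0]]
    return FeatureTable(data=data, sample_groups=groups, fraction=table.fraction)


def _welch_on_logs(control: np.ndarray, treated: np.ndarray, pseudo: float):
    """Shared core: Welch two-sided t on log2(x + pseudo), vectorized on axis 1.

    Rows where both groups are constant and equal return p = 1 by convention
    (no evidence either way); constant but unequal rows return p = 0.  Rows
    with fewer than two values in a group return p = NaN (flagged), the
    log2 fold-change is still defined.
    """
    lc = np.log2(control + pseudo)
    lt = np.log2(treated + pseudo)
    log2fc = lt.mean(axis=1) - lc.mean(axis=1)
    if control.shape[1] < 2 or treated.shape[1] < 2:
        return np.full(log2fc.shape, np.nan), log2fc
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(lt, lc, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_c = lc.var(axis=1, ddof=1)
    var_t = lt.var(axis=1, ddof=1)
    degenerate = (var_c == 0) & (var_t == 0)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(degenerate & (log2fc != 0), 0.0, p)
    return p, log2fc


def test_feature(control, treated, pseudo: float = 1.0) -> tuple[float, float]:
    """Welch two-sided t-test on log2(intensity + pseudo) for one feature.

    Returns (p_value, log2fc) where log2fc = mean log2(treated + pseudo) -
    mean log2(control + pseudo).  With fewer than two values in either group
    the p-value is NaN but the fold-change is still returned.
    """
    if pseudo <= 0:
        raise ValueError("pseudo-intensity must be positive")
    c = np.asarray(control, dtype=float).reshape(1, -1)
    t = np.asarray(treated, dtype=float).reshape(1, -1)
    if c.size == 0 or t.size == 0:
        raise ValueError("both groups need at least one intensity")
    p, log2fc = _welch_on_logs(c, t, pseudo)
    return float(p[0]), float(log2fc[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving with the usual monotonicity enforcement; NaN entries
    (features with undefined p) stay NaN and are excluded from the
    correction.  Values outside [0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def signed_fold_change(log2fc):
    """Display fold-change: +2^log2fc for increases, -2^(-log2fc) for decreases.

    A 5-fold decrease prints as -5; |result| >= 1 always and log2fc = 0 maps
    to +1.
    """
    arr = np.asarray(log2fc, dtype=float)
    ratio = np.exp2(arr)
    out = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    if np.isscalar(log2fc) or arr.ndim == 0:
        return float(out)
    return out


def differential_analysis(table: FeatureTable, pseudo: float = 1.0) -> pd.DataFrame:
    """Per-feature differential abundance over a grouped feature table.

    Output columns (fixed order): id, mz, rt, signed_fold_change, log2fc,
    p_value, q_value, direction.
    """
    control_cols = table.group_samples("control")
    treated_cols = table.group_samples("treated")
    if not control_cols or not treated_cols:
        raise ValueError("feature table needs samples in both groups")
    c = table.data[control_cols].to_numpy(dtype=float)
    t = table.data[treated_cols].to_numpy(dtype=float)
    if (c < 0).any() or (t < 0).any():
        raise ValueError("negative intensities")
    p, log2fc = _welch_on_logs(c, t, pseudo)
    out = pd.DataFrame(
        {
            "id": table.data["id"],
            "mz": table.data["mz"],
            "rt": table.data["rt"],
            "signed_fold_change": signed_fold_change(log2fc),
            "log2fc": log2fc,
            "p_value": p,
            "q_value": bh_adjust(p),
            "direction": np.where(log2fc < 0, "down", "up"),
        }
    )
    return out[DIFF_COLUMNS]
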