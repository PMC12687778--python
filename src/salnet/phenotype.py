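"""Functional-network involvement, SRS-subscore correlations, hemisphere
average/STD panels and control-group congruence.

These are the statistics that connect the saliency-correlation networks
back to phenotype: how many hub regions fall in each of the eight
functional networks (per tau threshold and averaged over the 0.1–0.6
sweep); which regions' saliency tracks each SRS subscore (Kendall tau at
p < 0.05 over the 150 cortical regions, tallied per hemisphere and lobe);
whether the per-region average and standard deviation of saliency are
proportional within/across hemispheres and severity groups (an 8x8 panel
grid); and how closely unscored controls resemble the low-severity group
region-by-region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    NETWORKS,
    SUBSCORES,
    ParcellationAtlas,
    RegionSaliencyMatrix,
    ValidationError,
)
from .corrnet import DEFAULT_THRESHOLDS, hub_ranking, kendall_tau

__all__ = [
    "NetworkInvolvement", "network_involvement", "averaged_involvement",
    "ScoreRegionTable", "score_region_correlations", "avg_std_grid",
    "control_congruence",
]


@dataclass
class NetworkInvolvement:
    """Counts and percentages of top regions per functional network."""

    counts: dict  # network -> count (float when averaged)
    total: float
    percentages: dict  # network -> percentage of total
    threshold: str

    def __post_init__(self) -> None:
        if self.total > 0:
            s = sum(self.percentages.values())
            if abs(s - 100.0) > 0.1:
                raise ValidationError(f"involvement percentages sum to {s}, not 100")
            if abs(sum(self.counts.values()) - self.total) > 1e-9:
                raise ValidationError("involvement counts do not sum to the total")


def network_involvement(top_regions: Sequence[int], atlas: ParcellationAtlas,
                        threshold_label: str = "") -> NetworkInvolvement:
    """Count top regions per functional network; percentages of the total.

    Regions mapped to no network (``none``) are excluded from the total.
    """
    net_of = atlas.region_attr("network")
    unknown = [r for r in top_regions if r not in net_of]
    if unknown:
        raise ValidationError(f"regions not in the atlas: {unknown}")
    counts = {n: 0 for n in NETWORKS}
    for r in top_regions:
        net = net_of[r]
        if net == "none" or (isinstance(net, float) and np.isnan(net)):
            continue
        if net not in counts:
            raise ValidationError(f"unknown network label {net!r} for region {r}")
        counts[net] += 1
    total = sum(counts.values())
    pct = {n: (100.0 * c / total if total else 0.0) for n, c in counts.items()}
    return NetworkInvolvement(counts=counts, total=float(total),
                              percentages=pct, threshold=threshold_label)


def averaged_involvement(matrix: RegionSaliencyMatrix, atlas: ParcellationAtlas,
                         thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                         top_n: int = 50, alpha: float = 0.01,
                         edges=None) -> NetworkInvolvement:
    """Involvement averaged over the tau-threshold sweep.

    Per-threshold counts and percentages are averaged arithmetically (the
    returned ``counts``/``percentages`` are those means side by side).
    """
    thresholds = tuple(thresholds)
    if not thresholds:
        raise ValidationError("at least one threshold is required")
    hubs = hub_ranking(matrix, edges=edges, thresholds=thresholds,
                       top_n=top_n, alpha=alpha)
    per = []
    for thr in thresholds:
        ids = [row["region_id"] for row in hubs["per_threshold"][thr]]
        per.append(network_involvement(ids, atlas, threshold_label=str(thr)))
    counts = {n: float(np.mean([p.counts[n] for p in per])) for n in NETWORKS}
    pcts = {n: float(np.mean([p.percentages[n] for p in per])) for n in NETWORKS}
    total = sum(counts.values())
    out = NetworkInvolvement.__new__(NetworkInvolvement)
    out.counts, out.total, out.percentages, out.threshold = counts, total, pcts, "averaged"
    return out


@dataclass
class ScoreRegionTable:
    """Significant (region, subscore) saliency correlations, Table-1 style."""

    rows: pd.DataFrame  # subscore, region_id, hemisphere, lobe, tau, p
    alpha: float

    def hemisphere_counts(self) -> dict:
        """Per subscore: (LH count, RH count) of significant regions."""
        out = {}
        for s in SUBSCORES:
            sub = self.rows[self.rows["subscore"] == s]
            out[s] = (int((sub["hemisphere"] == "L").sum()),
                      int((sub["hemisphere"] == "R").sum()))
        return out

    def lobe_counts(self) -> pd.DataFrame:
        return (self.rows.groupby(["subscore", "hemisphere", "lobe"])
                .size().rename("count").reset_index())


def score_region_correlations(matrix: RegionSaliencyMatrix, records,
                              alpha: float = 0.05,
                              cortical_only: bool = True) -> ScoreRegionTable:
    """Kendall tau of each SRS subscore against each region's saliency.

    Runs across scored (high + low) subjects only; the default scope is the
    150 cortical regions (both hemispheres).  Rows with p < alpha are
    retained.  A subscore constant across subjects is skipped with a
    warning.
    """
    by_id = {r.subject_id: r for r in records}
    keep = [i for i, sid in enumerate(matrix.subject_ids)
            if by_id[sid].group in ("high", "low")]
    if len(keep) < 3:
        raise ValidationError("need >= 3 scored subjects")
    if matrix.regions is None:
        raise ValidationError("matrix carries no region table")
    ids = matrix.region_ids
    if cortical_only:
        cort = set(matrix.regions.loc[matrix.regions["is_cortical"], "region_id"])
        ids = np.array([r for r in ids if r in cort])
    sub = matrix.subset_regions(ids)
    vals = sub.values[keep]
    meta = matrix.regions.set_index("region_id")
    n = len(keep)
    rows = []
    for s_name in SUBSCORES:
        scores = np.array([by_id[matrix.subject_ids[i]].subscores[s_name]
                           for i in keep], dtype=float)
        if np.ptp(scores) == 0:
            warnings.warn(f"subscore {s_name} is constant; skipped", UserWarning,
                          stacklevel=2)
            continue
        for j, rid in enumerate(ids):
            col = vals[:, j]
            if np.ptp(col) == 0:
                continue
            if n <= 9:
                tau, p = kendall_tau(col, scores)
            else:
                res = stats.kendalltau(col, scores, variant="b", method="asymptotic")
                tau, p = float(res.statistic), float(res.pvalue)
            if p < alpha or alpha >= 1.0:  # alpha=1 keeps the full table
                rows.append({"subscore": s_name, "region_id": int(rid),
                             "hemisphere": meta.loc[rid, "hemisphere"],
                             "lobe": meta.loc[rid, "lobe"],
                             "tau": tau, "p": p})
    df = pd.DataFrame(rows, columns=["subscore", "region_id", "hemisphere",
                                     "lobe", "tau", "p"])
    return ScoreRegionTable(rows=df, alpha=alpha)


def avg_std_grid(matrix: RegionSaliencyMatrix, records) -> dict:
    """The 8x8 {LH,RH} x {Avg,STD} x {High,Low} panel statistics.

    Each axis is a per-region vector over cortical regions of one
    hemisphere: the average (or standard deviation) of saliency across the
    subjects of one severity group.  Off-diagonal panels report Pearson r
    and the OLS slope of row-vs-column; diagonal panels report the
    Shapiro-Wilk normality statistic of the axis vector.
    """
    by_id = {r.subject_id: r for r in records}
    if matrix.regions is None:
        raise ValidationError("matrix carries no region table")
    vectors = {}
    for hemi in ("L", "R"):
        ids = matrix.regions.loc[
            matrix.regions["is_cortical"]
            & (matrix.regions["hemisphere"] == hemi), "region_id"]
        sub = matrix.subset_regions(ids.to_numpy())
        for grp in ("high", "low"):
            rows = np.array([i for i, sid in enumerate(matrix.subject_ids)
                             if by_id[sid].group == grp])
            if len(rows) < 2:
                raise ValidationError(
                    f"group {grp} has {len(rows)} subjects; STD needs >= 2"
                )
            block = sub.values[rows]
            vectors[(hemi, "Avg", grp)] = block.mean(axis=0)
            vectors[(hemi, "STD", grp)] = block.std(axis=0, ddof=1)
    axes = [(h, s, g) for h in ("L", "R") for s in ("Avg", "STD")
            for g in ("high", "low")]
    panels = {}
    for a in axes:
        for b in axes:
            if a == b:
                w, p = stats.shapiro(vectors[a])
                panels[(a, b)] = {"shapiro_w": float(w), "shapiro_p": float(p)}
            else:
                x, y = vectors[b], vectors[a]
                r, _ = stats.pearsonr(x, y)
                slope = float(np.polyfit(x, y, 1)[0])
                panels[(a, b)] = {"r": float(r), "slope": slope}
    return {"axes": axes, "vectors": vectors, "panels": panels}


def control_congruence(matrix: RegionSaliencyMatrix,
                       groups: Optional[Sequence[str]] = None) -> dict:
    """Cross-region linear association of control vs low-severity means.

    Computes the per-region mean saliency within each of the two groups and
    returns Pearson r plus the OLS slope/intercept of control on low.
    """
    groups = list(groups) if groups is not None else list(matrix.groups)
    ctrl = np.array([g == "control" for g in groups])
    low = np.array([g == "low" for g in groups])
    if not ctrl.any() or not low.any():
        raise ValidationError("control congruence needs both groups present")
    m_ctrl = matrix.values[ctrl].mean(axis=0)
    m_low = matrix.values[low].mean(axis=0)
    r, _ = stats.pearsonr(m_low, m_ctrl)
    slope, intercept = np.polyfit(m_low, m_ctrl, 1)
    return {"r": float(r), "slope": float(slope), "intercept": float(intercept),
            "n_regions": int(matrix.values.shape[1])}
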