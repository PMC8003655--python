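"""Evaluation metrics and group statistics.

Per-case Dice overlap, tumor volume in mL, heteroscedasticity-robust
group comparison (Welch's ANOVA with Games-Howell post-hoc pairs),
Pearson correlation, and Z-score histogram profiles that relate a
case's intensity distribution to its tumor VOI.

Statistics are always computed per case and then aggregated (grouped
mean +/- sample SD), never pooled voxelwise. A Dice of two *empty*
masks is an error rather than 1.0: tumor-free cases must be handled
explicitly by the caller, otherwise they would silently inflate means.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .volio import Volume4Ch, VoiMask, support_mask

__all__ = [
    "EvalRecord",
    "HistogramProfile",
    "dice",
    "tumor_volume_ml",
    "welch_anova",
    "games_howell",
    "pearson_r",
    "histogram_profile",
    "aggregate",
    "records_to_frame",
    "write_records",
    "read_records",
]

MODEL_TYPES = ("source", "target", "finetuned")


@dataclass(frozen=True)
class EvalRecord:
    """One case's evaluation result for one model."""

    case_id: str
    facility_id: str
    model_type: str
    dice: float
    tumor_volume_ml: float
    metadata_label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError(f"dice must be in [0, 1], got {self.dice}")
        if self.tumor_volume_ml < 0:
            raise ValueError("tumor_volume_ml must be nonnegative")


@dataclass
class HistogramProfile:
    """Z-score histograms of one normalized case.

    ``channel_counts``: per-channel counts over the in-brain support
    (out-of-range values are clipped into the edge bins so counts always
    sum to the support size). ``voi_counts``: counts of the chosen
    channel restricted to the VOI. ``voi_median_z`` is NaN (and
    ``voi_defined`` False) for an empty VOI.
    """

    bin_edges: np.ndarray
    channel_counts: np.ndarray  # (4, n_bins)
    voi_counts: np.ndarray  # (n_bins,)
    voi_channel: int
    voi_fraction: float
    voi_median_z: float
    voi_defined: bool


def dice(a: VoiMask, b: VoiMask) -> float:
    """Overlap 2|A ∩ B| / (|A| + |B|); symmetric, 1.0 for identical masks."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        raise ValueError("Dice of two empty masks is undefined (0/0)")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def tumor_volume_ml(mask: VoiMask) -> float:
    """Nonzero-voxel count x voxel volume (mm^3) / 1000."""
    return mask.voxel_count * float(np.prod(mask.spacing)) / 1000.0


def _check_groups(groups):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if g.std(ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance")
    return arrays


def _long_frame(arrays, labels=None):
    labels = labels if labels is not None else [str(i) for i in range(len(arrays))]
    return pd.DataFrame(
        {
            "value": np.concatenate(arrays),
            "group": np.concatenate([[l] * len(g) for l, g in zip(labels, arrays)]),
        }
    )


def welch_anova(groups) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns ``(F, df1, df2, p)`` with the Welch-Satterthwaite
    denominator degrees of freedom.
    """
    arrays = _check_groups(groups)
    res = pg.welch_anova(dv="value", between="group", data=_long_frame(arrays))
    row = res.iloc[0]
    return float(row["F"]), float(row["ddof1"]), float(row["ddof2"]), float(row["p_unc"])


def games_howell(groups, labels=None) -> pd.DataFrame:
    """Games-Howell post-hoc pairwise comparisons.

    ``groups`` may be a dict label -> values or a sequence of lists.
    Returns a DataFrame with columns (group_a, group_b, mean_diff,
    p_adj); p-values come from the studentized-range distribution with
    k groups and Welch-Satterthwaite pairwise df.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        arrays = _check_groups(groups.values())
    else:
        arrays = _check_groups(groups)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(arrays))]
    res = pg.pairwise_gameshowell(dv="value", between="group", data=_long_frame(arrays, labels))
    out = res.rename(columns={"A": "group_a", "B": "group_b", "diff": "mean_diff", "pval": "p_adj"})
    return out[["group_a", "group_b", "mean_diff", "p_adj"]].reset_index(drop=True)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("inputs must have nonzero variance")
    return float(sps.pearsonr(x, y).statistic)


def histogram_profile(vol: Volume4Ch, voi: VoiMask, channel: int = 1,
                      bins: np.ndarray | None = None) -> HistogramProfile:
    """Z-score histogram profile of a normalized volume against its VOI.

    ``vol`` must already be Z-score normalized. Default bins: 60 uniform
    bins over Z in [-3, 3]; values outside the range are clipped into
    the edge bins so the counts conserve the support voxel count.
    """
    if voi.shape != vol.shape:
        raise ValueError("VOI shape does not match volume")
    edges = np.linspace(-3.0, 3.0, 61) if bins is None else np.asarray(bins, dtype=float)
    sup = support_mask(vol)
    n_sup = int(sup.sum())
    lo = (edges[0] + edges[1]) / 2
    hi = (edges[-2] + edges[-1]) / 2

    def counts(values):
        return np.histogram(np.clip(values, lo, hi), bins=edges)[0]

    channel_counts = np.stack([counts(vol.data[c][sup]) for c in range(4)])
    voi_sel = voi.data.astype(bool) & sup
    n_voi = int(voi_sel.sum())
    if n_voi:
        zvals = vol.data[channel][voi_sel]
        voi_counts = counts(zvals)
        median = float(np.median(zvals))
    else:
        voi_counts = np.zeros(len(edges) - 1, dtype=np.int64)
        median = float("nan")
    return HistogramProfile(
        bin_edges=edges,
        channel_counts=channel_counts,
        voi_counts=voi_counts,
        voi_channel=channel,
        voi_fraction=n_voi / n_sup if n_sup else 0.0,
        voi_median_z=median,
        voi_defined=bool(n_voi),
    )


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def aggregate(records, by: str = "model_type") -> pd.DataFrame:
    """Grouped mean +/- sample SD of Dice with counts.

    ``by`` is one of facility_id, model_type, metadata_label. Groups are
    ordered by sorted key; a single-record group reports SD 0.
    """
    frame = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if frame.empty:
        raise ValueError("no records to aggregate")
    if by not in ("facility_id", "model_type", "metadata_label"):
        raise ValueError(f"cannot aggregate by {by!r}")
    rows = []
    for key in sorted(frame[by].unique()):
        vals = frame.loc[frame[by] == key, "dice"].to_numpy()
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append({by: key, "mean_dice": float(vals.mean()), "sd_dice": sd, "n": len(vals)})
    return pd.DataFrame(rows)


def write_records(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.10g")


def read_records(path) -> list[EvalRecord]:
    frame = pd.read_csv(path, keep_default_na=False)
    return [EvalRecord(**{k: row[k] for k in EvalRecord.__dataclass_fields__}) for _, row in frame.iterrows()]
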