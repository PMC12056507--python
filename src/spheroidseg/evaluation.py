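"""Segmentation accuracy metrics and interobserver statistics.

Per image, a predicted pixel set P is compared against the manually
segmented target T through:

* JCD, the Jaccard distance ``1 − |P∩T| / |P∪T|`` — the relative area
  error of the segmentation (0 = perfect overlap, 1 = disjoint);
* RDD / RCD, the relative deviation ``|c_P − c_T| / c_T`` of the mean
  diameter / circularity;
* Δr, the average radial error: the thickness of a circular layer,
  around a circle with the target's area, whose area equals the
  mismatched area ``|P∪T| − |P∩T|``.  Surplus and missing areas do not
  compensate, so Δr is deliberately conservative.

Dataset-level bookkeeping follows the case taxonomy for rare
artifacts: a prediction whose largest component is disjoint from the
target (JCD = 1) is *invalid* and counts toward the invalid spheroid
fraction (ISF), with RDD and RCD also set to 1; a prediction with
extra components beyond a valid largest spheroid is *ambiguous* and
counts toward the ambiguous spheroid fraction (ASF).  ISF and ASF are
reported with the binomial standard error sqrt(p(1−p)/n).

Interobserver agreement across raters is assessed on per-image
pairwise JCD tables with the Friedman rank test (tie-corrected,
chi-square asymptotics) and Dunn–Bonferroni pairwise post hoc tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .masks import PolyChain, label_components, largest_component, mask_overlap, trace_contour
from .morphometrics import circularity as _circularity
from .morphometrics import diameter as _diameter
from .postprocess import SegmentationResult

__all__ = [
    "EvalRecord",
    "EvalSummary",
    "jcd",
    "relative_deviation",
    "delta_r",
    "evaluate_image",
    "summarize",
    "interobserver_matrix",
    "friedman_test",
    "dunn_bonferroni",
]


@dataclass(frozen=True)
class EvalRecord:
    jcd: float
    iou: float
    rdd: float
    rcd: float
    delta_r_px: float
    delta_r_um: float
    invalid: bool
    ambiguous: bool
    d_target_px: float
    d_pred_px: float
    circ_target: float
    circ_pred: float


@dataclass(frozen=True)
class EvalSummary:
    n: int
    mean: dict
    sd: dict
    median: dict
    isf: float
    isf_se: float
    asf: float
    asf_se: float


def _check_shapes(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=bool)
    t = np.asarray(t, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not t.any():
        raise ValueError("target mask must be non-empty")
    return p, t


def jcd(p: np.ndarray, t: np.ndarray) -> float:
    """Jaccard distance 1 − |P∩T|/|P∪T|; empty P against non-empty T → 1."""
    p, t = _check_shapes(p, t)
    inter, union = mask_overlap(p, t)
    if union == 0:  # both empty; unreachable since t is non-empty
        return 0.0
    return 1.0 - inter / union


def relative_deviation(c_pred: float, c_target: float) -> float:
    """Relative deviation |c_P − c_T| / c_T of a scalar characteristic."""
    if c_target <= 0:
        raise ValueError("target characteristic must be positive")
    return abs(c_pred - c_target) / c_target


def delta_r(p: np.ndarray, t: np.ndarray, pixel_size: float = 1.0) -> tuple[float, float]:
    """Average radial error Δr, returned as ``(px, µm)``.

    Δr = sqrt((|P∪T| − |P∩T|)/π + d_T²/4) − d_T/2, with d_T the mean
    target diameter: the thickness the mismatched area would have if
    spread as an annulus around a circle of the target's area.
    """
    p, t = _check_shapes(p, t)
    inter, union = mask_overlap(p, t)
    d_t = _diameter(t)
    mismatch = union - inter
    dr = math.sqrt(mismatch / math.pi + d_t**2 / 4.0) - d_t / 2.0
    return dr, dr * pixel_size


def evaluate_image(
    pred: SegmentationResult, target: np.ndarray, pixel_size: float = 1.0
) -> EvalRecord:
    """Full per-image metric bundle with the rare-artifact case rules.

    The JCD (and Δr) are computed on the largest predicted component.
    JCD = 1 marks the prediction invalid: RDD and RCD are set to 1 and
    Δr is computed against the empty prediction.  Extra components
    alongside a valid largest one mark the image ambiguous.
    """
    target = np.asarray(target, dtype=bool)
    if not target.any():
        raise ValueError("target mask must be non-empty")
    if pred.spheroid_mask.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")

    d_t = _diameter(target)
    t_contour = trace_contour(largest_component(label_components(target))[0])
    circ_t, _ = _circularity(target, t_contour)

    j = jcd(pred.spheroid_mask, target)
    invalid = j == 1.0
    ambiguous = bool(pred.ambiguous) and not invalid

    if invalid:
        empty = np.zeros_like(target)
        dr_px, dr_um = delta_r(empty, target, pixel_size)
        return EvalRecord(
            jcd=1.0,
            iou=0.0,
            rdd=1.0,
            rcd=1.0,
            delta_r_px=dr_px,
            delta_r_um=dr_um,
            invalid=True,
            ambiguous=False,
            d_target_px=d_t,
            d_pred_px=_diameter(pred.spheroid_mask),
            circ_target=circ_t,
            circ_pred=float("nan"),
        )

    d_p = _diameter(pred.spheroid_mask)
    circ_p, _ = _circularity(pred.spheroid_mask, pred.contour)
    dr_px, dr_um = delta_r(pred.spheroid_mask, target, pixel_size)
    return EvalRecord(
        jcd=j,
        iou=1.0 - j,
        rdd=relative_deviation(d_p, d_t),
        rcd=relative_deviation(circ_p, circ_t),
        delta_r_px=dr_px,
        delta_r_um=dr_um,
        invalid=False,
        ambiguous=ambiguous,
        d_target_px=d_t,
        d_pred_px=d_p,
        circ_target=circ_t,
        circ_pred=circ_p,
    )


_SUMMARY_METRICS = ("jcd", "rdd", "rcd", "delta_r_px", "delta_r_um")


def summarize(records: Sequence[EvalRecord]) -> EvalSummary:
    """Dataset-level aggregation: mean/SD/median per metric, ISF/ASF ± SE.

    Standard deviations are population SDs over the record set (zero
    for a single record); ISF/ASF standard errors come from the
    binomial distribution, SE = sqrt(p(1−p)/n).
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    n = len(records)
    mean, sd, median = {}, {}, {}
    for m in _SUMMARY_METRICS:
        vals = np.array([getattr(r, m) for r in records], dtype=float)
        mean[m] = float(vals.mean())
        sd[m] = float(vals.std(ddof=0))
        median[m] = float(np.median(vals))
    isf = sum(r.invalid for r in records) / n
    asf = sum(r.ambiguous for r in records) / n
    return EvalSummary(
        n=n,
        mean=mean,
        sd=sd,
        median=median,
        isf=isf,
        isf_se=math.sqrt(isf * (1 - isf) / n),
        asf=asf,
        asf_se=math.sqrt(asf * (1 - asf) / n),
    )


def interobserver_matrix(
    masks_by_rater: Mapping[str, Sequence[np.ndarray]],
) -> pd.DataFrame:
    """Pairwise JCD table: one row per image, one column per rater pair.

    All raters must have segmented the same image list with non-empty
    masks.  Columns are the unordered pairs ``"A~B"`` in lexicographic
    order; with R raters there are R(R−1)/2 of them.
    """
    raters = sorted(masks_by_rater)
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    counts = {r: len(masks_by_rater[r]) for r in raters}
    if len(set(counts.values())) != 1:
        raise ValueError(f"raters segmented differing image counts: {counts}")
    n_images = counts[raters[0]]
    for r in raters:
        for m in masks_by_rater[r]:
            if not np.asarray(m).any():
                raise ValueError(f"rater {r} has an empty mask")
    pairs = list(itertools.combinations(raters, 2))
    data = {
        f"{a}~{b}": [
            jcd(masks_by_rater[a][i], masks_by_rater[b][i]) for i in range(n_images)
        ]
        for a, b in pairs
    }
    return pd.DataFrame(data)


def friedman_test(table: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over a blocks × groups table.

    Within each block (row) the k group values are ranked (ties get
    mean ranks); the tie-corrected chi-square statistic

        χ²_F = [12/(n·k·(k+1)) · Σ R_j² − 3n(k+1)] / C,
        C = 1 − Σ(t³ − t) / (n·k·(k² − 1)),

    is referred to the chi-square distribution with k − 1 degrees of
    freedom.  A table where every block is constant has no rank
    information; the statistic is 0 with p = 1.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D (blocks x groups)")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 groups")
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    rank_sums = ranks.sum(axis=0)
    uncorrected = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (
        k + 1
    )
    # tie correction: sum of (t^3 - t) over tie groups of every block
    tie_sum = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:  # every block fully tied
        return 0.0, 1.0
    statistic = uncorrected / correction
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), p


def dunn_bonferroni(
    table: np.ndarray, group_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Dunn's pairwise post hoc test with Bonferroni correction.

    Mean-rank differences are standardized by sqrt(k(k+1)/(6n)); the
    two-sided normal p-value is multiplied by the number of pairs and
    clipped at 1.  Returns a DataFrame with one row per unordered pair
    (columns: group_a, group_b, z, p_unadjusted, p_adjusted).
    """
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    if group_names is None:
        group_names = [f"g{j}" for j in range(k)]
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append(
            {
                "group_a": group_names[i],
                "group_b": group_names[j],
                "z": z,
                "p_unadjusted": min(p_raw, 1.0),
                "p_adjusted": min(p_raw * len(pairs), 1.0),
            }
        )
    return pd.DataFrame(rows)
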