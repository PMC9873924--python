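"""Landmark-anchored zone assignment and zone-differential statistics.

Spots are partitioned into three equal tertile zones by landmark expression
(periportal marker high, pericentral marker high, intermediate); module
scores are compared between the two marker zones with a two-sided Wilcoxon
rank-sum test (volcano table); distance-resolved zonation profiles average
module scores over the top-decile marker spots and their first and second
hexagonal neighbour rings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal
from statsmodels.stats.multitest import multipletests

from .geometry import SpotGeometry, ring_neighbors
from .scoring import NormalizedMatrix


class Tertile(str, Enum):
    ALB_HIGH = "ALB_HIGH"
    CYP_HIGH = "CYP_HIGH"
    INTERMEDIATE = "INTERMEDIATE"


#: ring-membership class labels, serialised exactly as written here
RING_CLASSES = ("ALB_TOP", "ALB_R1", "ALB_R2", "CYP_TOP", "CYP_R1", "CYP_R2")


@dataclass(frozen=True)
class ZoneConfig:
    """Landmark genes anchoring the zones and the top-spot fraction."""

    portal_marker: str = "Alb"
    central_marker: str = "Cyp2e1"
    top_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.portal_marker == self.central_marker:
            raise ValueError("portal and central markers must differ")
        if not 0 < self.top_fraction < 0.5:
            raise ValueError("top_fraction must be in (0, 0.5)")


def _ranking(values: np.ndarray, spot_ids: Sequence[str]) -> list[int]:
    """Indices sorted by value descending, ties broken by spot id ascending."""
    return sorted(range(len(spot_ids)), key=lambda i: (-values[i], spot_ids[i]))


def assign_tertiles(norm: NormalizedMatrix, config: ZoneConfig) -> pd.Series:
    """Partition spots into three near-equal zones anchored on the markers.

    Each marker class targets ``t = n // 3`` spots taken from the top of that
    marker's ranking (descending value, ties by spot id).  A spot claimed by
    both top lists goes to the class in which it ranks better (tie -> the
    portal class); the losing class backfills from its next-ranked spots.
    Remaining spots are labelled intermediate.
    """
    n = len(norm.spot_ids)
    if n < 3:
        raise ValueError("need at least 3 spots for a tertile partition")
    portal = norm.gene_values(config.portal_marker)
    central = norm.gene_values(config.central_marker)
    t = n // 3
    alb_order = _ranking(portal, norm.spot_ids)
    cyp_order = _ranking(central, norm.spot_ids)
    alb_rank = {i: r for r, i in enumerate(alb_order)}
    cyp_rank = {i: r for r, i in enumerate(cyp_order)}
    alb: set[int] = set()
    cyp: set[int] = set()
    ia = ic = 0
    while len(alb) < t or len(cyp) < t:
        cand_a = cand_c = None
        if len(alb) < t:
            while alb_order[ia] in alb or alb_order[ia] in cyp:
                ia += 1
            cand_a = alb_order[ia]
        if len(cyp) < t:
            while cyp_order[ic] in alb or cyp_order[ic] in cyp:
                ic += 1
            cand_c = cyp_order[ic]
        if cand_a is not None and cand_a == cand_c:
            # claimed by both: better within-sample rank wins, tie -> portal
            if alb_rank[cand_a] <= cyp_rank[cand_a]:
                alb.add(cand_a)
            else:
                cyp.add(cand_a)
        else:
            if cand_a is not None:
                alb.add(cand_a)
            if cand_c is not None and cand_c not in alb:
                cyp.add(cand_c)
    labels = []
    for i in range(n):
        if i in alb:
            labels.append(Tertile.ALB_HIGH.value)
        elif i in cyp:
            labels.append(Tertile.CYP_HIGH.value)
        else:
            labels.append(Tertile.INTERMEDIATE.value)
    return pd.Series(labels, index=list(norm.spot_ids), name="zone")


def _top_spots(values: np.ndarray, spot_ids: Sequence[str], fraction: float) -> list[str]:
    k = math.ceil(fraction * len(spot_ids))
    order = _ranking(values, spot_ids)
    return [spot_ids[i] for i in order[:k]]


def ring_membership(
    norm: NormalizedMatrix,
    geometry: SpotGeometry,
    config: ZoneConfig,
) -> dict[str, frozenset[str]]:
    """Top-decile marker spots and their first/second neighbour rings.

    Within each marker family the classes are disjoint with precedence
    TOP > R1 > R2; the two families are computed independently and may
    overlap.
    """
    out: dict[str, frozenset[str]] = {}
    for marker, prefix in (
        (config.portal_marker, "ALB"),
        (config.central_marker, "CYP"),
    ):
        values = norm.gene_values(marker)
        top = _top_spots(values, norm.spot_ids, config.top_fraction)
        top_set = frozenset(top)
        r1: set[str] = set()
        r2: set[str] = set()
        for s in top:
            rings = ring_neighbors(geometry, s)
            r1 |= rings.ring1
            r2 |= rings.ring2
        r1 -= top_set
        r2 -= top_set | r1
        out[f"{prefix}_TOP"] = top_set
        out[f"{prefix}_R1"] = frozenset(r1)
        out[f"{prefix}_R2"] = frozenset(r2)
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 12


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses exact enumeration of the rank-sum distribution when the pooled size
    is at most 12 and there are no ties; otherwise a normal approximation
    with tie correction and continuity correction, matching the classical
    two-sample procedure.  If every pooled value is identical the p-value
    is 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    n = n1 + n2
    has_ties = len(np.unique(pooled)) < n
    if n <= _EXACT_LIMIT and not has_ties:
        order = np.argsort(pooled)
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        w = ranks[:n1].sum()
        total = math.comb(n, n1)
        n_le = n_ge = 0
        for comb in combinations(range(1, n + 1), n1):
            s = sum(comb)
            if s <= w:
                n_le += 1
            if s >= w:
                n_ge += 1
        return min(1.0, 2.0 * min(n_le, n_ge) / total)
    # normal approximation with average ranks, tie and continuity correction
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j + 1)  # average of ranks i+1..j
        i = j
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = w - mu
    z -= math.copysign(0.5, z) if z != 0 else 0.0
    z /= math.sqrt(var)
    return min(1.0, 2.0 * _normal.sf(abs(z)))


def zone_volcano(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Zone-differential statistics per gene set.

    ``delta`` is the mean module score in the portal-marker zone minus the
    mean in the central-marker zone; ``p`` is the two-sided Wilcoxon rank-sum
    p-value.  Raw p-values drive the volcano; a Benjamini-Hochberg column is
    emitted additionally but not used for selection.
    """
    labels = labels.reindex(scores.index)
    alb = scores.loc[labels == Tertile.ALB_HIGH.value]
    cyp = scores.loc[labels == Tertile.CYP_HIGH.value]
    if alb.empty or cyp.empty:
        raise ValueError("both marker zones must be non-empty")
    rows = []
    for name in scores.columns:
        xa = alb[name].to_numpy()
        xc = cyp[name].to_numpy()
        p = wilcoxon_rank_sum(xa, xc)
        rows.append(
            {
                "set": name,
                "delta": float(xa.mean() - xc.mean()),
                "p": p,
                "minus_log10_p": -math.log10(p),
            }
        )
    out = pd.DataFrame(rows)
    out["bh_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# zonation profiles
# ---------------------------------------------------------------------------


def zonation_profile(
    scores: pd.DataFrame,
    membership: Mapping[str, frozenset[str]],
    sample_id: str,
) -> pd.DataFrame:
    """Mean module score per ring class for one sample.

    Returns one row per (set, class); an empty class yields a missing (NaN)
    mean, never a silent 0.
    """
    rows = []
    for name in scores.columns:
        for cls in RING_CLASSES:
            spots = [s for s in membership.get(cls, frozenset()) if s in scores.index]
            mean = float(scores.loc[spots, name].mean()) if spots else float("nan")
            rows.append({"set": name, "sample": sample_id, "class": cls, "mean": mean})
    return pd.DataFrame(rows)


def select_top_range(profiles: pd.DataFrame, k: int = 200) -> list[str]:
    """Sets with the largest range of class means across samples and classes.

    The range per set is max - min over all its (sample, class) means,
    missing entries excluded; ties on range are broken by set name
    ascending.  Returns at most ``k`` names.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranges = (
        profiles.dropna(subset=["mean"])
        .groupby("set")["mean"]
        .agg(lambda v: v.max() - v.min())
    )
    ordered = sorted(ranges.index, key=lambda s: (-ranges[s], s))
    return ordered[:k]


def normalize_profile_rows(profiles: pd.DataFrame, mode: str = "zscore") -> pd.DataFrame:
    """Add a per-set normalised column across all (sample, class) means.

    ``zscore`` uses the sample standard deviation (ddof=1); a constant row
    normalises to zeros.  ``minmax`` rescales to [0, 1] instead.
    """
    if mode not in {"zscore", "minmax"}:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    out = profiles.copy()
    normalized = np.full(len(out), np.nan)
    for _, idx in out.groupby("set").groups.items():
        vals = out.loc[idx, "mean"].to_numpy()
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            continue
        v = vals[ok]
        if mode == "zscore":
            sd = v.std(ddof=1)
            z = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
        else:
            span = v.max() - v.min()
            z = np.zeros_like(v) if span == 0 else (v - v.min()) / span
        filled = np.full(len(vals), np.nan)
        filled[ok] = z
        normalized[np.asarray([out.index.get_loc(i) for i in idx])] = filled
    out["normalized"] = normalized
    return out
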