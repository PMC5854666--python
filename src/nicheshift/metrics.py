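"""Impact statistics over protected areas and protected land.

Core quantities, with G the species gained, L the species lost and refSR
the reference-period modelled richness of a protected area (pooled over its
covering cells):

    rG  = 100 * G / refSR                 relative species gain (%)
    rL  = 100 * L / refSR                 relative species loss (%)
    T   = 100 * (G + L) / (refSR + G)     species turnover (%)
    dPR = 100 * (futPR - refPR) / refPR   protected-range change (%)

T ranges from 0 (composition unchanged) to 100 (full turnover: every
reference species lost, whatever the gain). Representativity of a protected
area is the fraction of its region's modelled species pool also present in
the cells containing the protected area, computed per period at three
nested scales (study area, province, region). Protected range PR of a
species is the total protected land area overlapping its modelled range.

Undefined records (refSR = 0, empty region pool, refPR = 0) are flagged and
excluded from distributions, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

SCALES = ("study_area", "province", "region")


# ---------------------------------------------------------------------------
# scalar impact statistics
# ---------------------------------------------------------------------------

def relative_gain(gain: int, ref_richness: int) -> float:
    """rG = 100 * G / refSR (percent). Undefined for refSR = 0."""
    if ref_richness <= 0:
        raise ValueError("relative gain undefined for refSR = 0")
    if gain < 0:
        raise ValueError("gain must be >= 0")
    return 100.0 * gain / ref_richness


def relative_loss(loss: int, ref_richness: int) -> float:
    """rL = 100 * L / refSR (percent), bounded by 100 since L <= refSR."""
    if ref_richness <= 0:
        raise ValueError("relative loss undefined for refSR = 0")
    if loss < 0:
        raise ValueError("loss must be >= 0")
    if loss > ref_richness:
        raise ValueError("loss exceeds reference richness "
                         "(upstream bookkeeping bug)")
    return 100.0 * loss / ref_richness


def turnover(gain: int, loss: int, ref_richness: int) -> float:
    """T = 100 * (G + L) / (refSR + G) (percent).

    0 when composition does not change; 100 iff every reference species is
    lost (L = refSR), for any G.
    """
    if gain < 0 or loss < 0 or ref_richness < 0:
        raise ValueError("counts must be >= 0")
    if loss > ref_richness:
        raise ValueError("loss exceeds reference richness")
    denom = ref_richness + gain
    if denom == 0:
        raise ValueError("turnover undefined for refSR + G = 0")
    return 100.0 * (gain + loss) / denom


def representativity(pa_cells: np.ndarray, region_cells: np.ndarray,
                     presence: pd.DataFrame) -> float:
    """|species pool over PA cells| / |species pool over region cells|.

    Equals 1 when every species predicted to occur in the region is also
    predicted in the cells containing the protected area. ``presence`` is a
    species x cells binary matrix for one period.
    """
    region_cells = np.asarray(region_cells, dtype=int)
    pa_cells = np.asarray(pa_cells, dtype=int)
    region_pool = presence.iloc[:, region_cells].to_numpy().any(axis=1)
    n_region = int(region_pool.sum())
    if n_region == 0:
        raise ValueError("representativity undefined: empty region pool")
    pa_pool = presence.iloc[:, pa_cells].to_numpy().any(axis=1)
    # PA cells lie inside the region, so the PA pool is a subset
    return float((pa_pool & region_pool).sum() / n_region)


# ---------------------------------------------------------------------------
# protected range
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtectionChangeRecord:
    species_id: str
    ref_pr: float       # protected land overlapping the reference range
    future_pr: float
    delta_pr: float | None   # percent; None when excluded
    excluded: bool = False
    reason: str = ""


def protected_range_change(species_id: str,
                           ref_presence: np.ndarray,
                           fut_presence: np.ndarray,
                           protected_land: np.ndarray
                           ) -> ProtectionChangeRecord:
    """PR per period = sum of protected land over the species' range cells;
    dPR = 100 * (futPR - refPR) / refPR.

    Species whose reference range overlaps no protected land (refPR = 0)
    are excluded with the reason recorded.
    """
    ref_pr = float(protected_land[np.asarray(ref_presence) == 1].sum())
    fut_pr = float(protected_land[np.asarray(fut_presence) == 1].sum())
    if ref_pr == 0.0:
        return ProtectionChangeRecord(
            species_id=species_id, ref_pr=0.0, future_pr=fut_pr,
            delta_pr=None, excluded=True,
            reason="reference range does not overlap protected land")
    delta = 100.0 * (fut_pr - ref_pr) / ref_pr
    return ProtectionChangeRecord(species_id=species_id, ref_pr=ref_pr,
                                  future_pr=fut_pr, delta_pr=delta)


# ---------------------------------------------------------------------------
# distributions over protected land
# ---------------------------------------------------------------------------

def land_area_distribution(values: np.ndarray,
                           protected_land: np.ndarray,
                           edges: np.ndarray) -> pd.DataFrame:
    """Share of total protected land per metric class.

    ``edges`` are strictly increasing class boundaries; classes are
    ``[e0, e1), [e1, e2), ..., [e_last, inf)`` (the top class is open, so a
    bar at the right end gathers everything at or above the last edge).
    Cells with zero protected land or an undefined (NaN) metric contribute
    nothing; shares sum to 1 over the remaining protected land.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("class edges must be strictly increasing")
    values = np.asarray(values, dtype=float)
    land = np.asarray(protected_land, dtype=float)
    ok = (land > 0) & ~np.isnan(values) & (values >= edges[0])
    total = land[ok].sum()
    idx = np.digitize(values[ok], edges) - 1  # class index per cell
    shares = np.zeros(edges.size)
    for i in range(edges.size):
        shares[i] = land[ok][idx == i].sum() / total if total > 0 else 0.0
    labels = [f"[{edges[i]:g}, {edges[i+1]:g})" for i in range(edges.size - 1)]
    labels.append(f">= {edges[-1]:g}")
    return pd.DataFrame({"class": labels, "lower_edge": edges,
                         "land_share": shares})


def pa_count_distribution(values: np.ndarray, edges: np.ndarray
                          ) -> pd.DataFrame:
    """Proportion of protected areas per metric class (same class rule)."""
    out = land_area_distribution(values, np.ones_like(values, dtype=float),
                                 edges)
    return out.rename(columns={"land_share": "pa_share"})


# ---------------------------------------------------------------------------
# paired comparison and robust summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    statistic: float | None    # V = sum of ranks of positive differences
    p_value: float | None
    n_used: int                # pairs remaining after zero removal
    n_zero: int
    median_shift: float
    no_change: bool = False


def compare_periods(reference: np.ndarray, future: np.ndarray,
                    exact_max_n: int = 25) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired per-PA values.

    Zero differences are dropped before ranking (classic procedure); V is
    the sum of midranks of the positive differences. The exact null is used
    for n <= ``exact_max_n`` untied pairs, the normal approximation with
    tie correction otherwise. If every difference is zero the test is
    undefined and an explicit "no change" outcome is returned.
    """
    reference = np.asarray(reference, dtype=float)
    future = np.asarray(future, dtype=float)
    if reference.shape != future.shape or reference.size < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    d = future - reference
    nz = d[d != 0]
    n_zero = int(d.size - nz.size)
    median_shift = float(np.median(d))
    if nz.size == 0:
        return PairedTestResult(statistic=None, p_value=None, n_used=0,
                                n_zero=n_zero, median_shift=0.0,
                                no_change=True)
    ranks = rankdata(np.abs(nz))
    v = float(ranks[nz > 0].sum())
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= exact_max_n and not has_ties) \
        else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return PairedTestResult(statistic=v, p_value=float(res.pvalue),
                            n_used=int(nz.size), n_zero=n_zero,
                            median_shift=median_shift)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    mad: float   # raw median absolute deviation (unscaled)


def summarize(values) -> SummaryStats:
    """Mean +/- SD and median +/- MAD; both always computed so the
    reporting layer can pick per its skew rule."""
    x = np.asarray([v for v in np.ravel(values) if not np.isnan(v)],
                   dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty input")
    med = float(np.median(x))
    return SummaryStats(n=int(x.size),
                        mean=float(x.mean()),
                        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
                        median=med,
                        mad=float(np.median(np.abs(x - med))))


# ---------------------------------------------------------------------------
# per-PA impact table
# ---------------------------------------------------------------------------

def assign_region(pa_cells: np.ndarray, labels: np.ndarray) -> int | None:
    """Region/province label of a PA whose cells may straddle boundaries.

    Majority rule over covering cells; an exact tie gives None (the PA is
    excluded from that scale's statistics and logged upstream).
    """
    vals, counts = np.unique(labels[np.asarray(pa_cells, dtype=int)],
                             return_counts=True)
    top = counts.max()
    winners = vals[counts == top]
    return int(winners[0]) if winners.size == 1 else None


def impact_table(overlay, hierarchy, ref_presence: pd.DataFrame,
                 fut_presence: pd.DataFrame) -> pd.DataFrame:
    """Per-protected-area impact records.

    Columns: G, L, refSR, futureSR, rG, rL, T (NaN where undefined) and
    representativity per scale and period. Region/province membership uses
    the majority of covering cells; ties leave that scale NaN.
    """
    from .overlay import aggregate_cell_values

    all_cells = np.arange(overlay.grid.n_cells)
    rows = []
    for pa_id, cells in overlay.covering.items():
        pool = aggregate_cell_values(cells, ref_presence, fut_presence)
        rec: dict[str, object] = {
            "pa_id": pa_id, "n_cells": cells.size,
            "G": pool.gain, "L": pool.loss,
            "refSR": pool.ref_richness, "futureSR": pool.future_richness,
        }
        if pool.ref_richness > 0:
            rec["rG"] = relative_gain(pool.gain, pool.ref_richness)
            rec["rL"] = relative_loss(pool.loss, pool.ref_richness)
        else:
            rec["rG"] = rec["rL"] = float("nan")
        rec["T"] = (turnover(pool.gain, pool.loss, pool.ref_richness)
                    if pool.ref_richness + pool.gain > 0 else float("nan"))
        scale_cells = {
            "study_area": all_cells,
            "province": None, "region": None,
        }
        p = assign_region(cells, hierarchy.province_of)
        r = assign_region(cells, hierarchy.region_of)
        if p is not None:
            scale_cells["province"] = hierarchy.province_cells(p)
        if r is not None:
            scale_cells["region"] = hierarchy.region_cells(r)
        for scale in SCALES:
            for period, mat in (("reference", ref_presence),
                                ("future", fut_presence)):
                col = f"repr_{scale}_{period}"
                sc = scale_cells[scale]
                if sc is None:
                    rec[col] = float("nan")
                    continue
                try:
                    rec[col] = representativity(cells, sc, mat)
                except ValueError:
                    rec[col] = float("nan")
        rows.append(rec)
    return pd.DataFrame(rows)


def protection_change_table(ref_presence: pd.DataFrame,
                            fut_presence: pd.DataFrame,
                            protected_land: np.ndarray) -> pd.DataFrame:
    """Per-species protected-range records (refPR, futurePR, dPR)."""
    rows = []
    for sid in ref_presence.index:
        rec = protected_range_change(
            sid, ref_presence.loc[sid].to_numpy(),
            fut_presence.loc[sid].to_numpy(), protected_land)
        rows.append({"species_id": sid, "refPR": rec.ref_pr,
                     "futurePR": rec.future_pr,
                     "dPR": rec.delta_pr if rec.delta_pr is not None
                     else float("nan"),
                     "excluded": rec.excluded, "reason": rec.reason})
    return pd.DataFrame(rows)
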