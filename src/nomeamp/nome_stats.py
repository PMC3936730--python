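"""Accessibility statistics over a filtered clone-call matrix.

Implements the quantities a clone-based NOMe-seq analysis reports:

* per-GpC-site percent inaccessibility,
  100 · n_inaccessible / (n_inaccessible + n_accessible), ambiguous
  molecules excluded from the denominator;
* the 100-bp windowed profile (unweighted mean over sites per window);
* condition comparisons by Pearson chi-square (df = 1) at one GpC site
  per 100-bp window, with a small-sample exact option;
* per-molecule footprints — maximal runs of inaccessible GpC sites —
  classified nucleosome-sized when their span reaches ~150 bp, and the
  dual accessible runs (NDR candidates);
* plot-ready bubble structures (one row per molecule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .calls import Call, CloneCallMatrix
from .reference import SiteRegistry

__all__ = [
    "SiteStat",
    "Footprint",
    "percent_inaccessible",
    "site_stats",
    "window_profile",
    "select_test_sites",
    "chi_square_2x2",
    "exact_test_2x2",
    "compare_conditions",
    "call_footprints",
    "call_open_runs",
    "bubble_matrix",
    "NUCLEOSOME_SIZED",
    "SUBTHRESHOLD",
]

NUCLEOSOME_SIZED = "NUCLEOSOME_SIZED"
SUBTHRESHOLD = "SUBTHRESHOLD"


@dataclass(frozen=True)
class SiteStat:
    site: int
    n_inaccessible: int
    n_accessible: int
    n_ambiguous: int
    percent_inaccessible: float  # NaN when no determinate molecule

    @property
    def defined(self) -> bool:
        return not np.isnan(self.percent_inaccessible)


@dataclass(frozen=True)
class Footprint:
    clone_id: str
    start: int          # position of outermost inaccessible site
    end: int            # inclusive
    n_sites: int
    classification: str

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def percent_inaccessible(matrix: CloneCallMatrix, site: int) -> SiteStat:
    """Percent of molecules inaccessible at one GpC site.

    percent = 100 · n_inaccessible / (n_inaccessible + n_accessible);
    molecules with an ambiguous call at the site are excluded from the
    denominator.  When every molecule is ambiguous the percentage is
    undefined and reported as NaN (never as 0).
    """
    if site not in set(matrix.registry.gch_sites):
        raise ValueError(f"site {site} is not a GCH accessibility reporter")
    retained, converted, ambiguous = matrix.counts_at(site)
    determinate = retained + converted
    pct = 100.0 * converted / determinate if determinate else float("nan")
    return SiteStat(site=site, n_inaccessible=converted,
                    n_accessible=retained, n_ambiguous=ambiguous,
                    percent_inaccessible=pct)


def site_stats(matrix: CloneCallMatrix) -> pd.DataFrame:
    """Per-site statistics for every GCH site, ordered by coordinate."""
    rows = [asdict(percent_inaccessible(matrix, s))
            for s in sorted(matrix.registry.gch_sites)]
    return pd.DataFrame(rows)


def window_profile(stats: pd.DataFrame, window: int = 100,
                   length: int | None = None) -> pd.DataFrame:
    """Average per-site percent inaccessibility in fixed windows.

    Windows tile [0, length) at ``window`` bp; the value is the
    unweighted mean over GCH sites whose position falls in the window.
    Windows without any site (or without any determinate site value)
    are flagged empty, not interpolated.
    """
    if stats.empty:
        raise ValueError("need at least one site statistic")
    if length is None:
        length = int(stats["site"].max()) + 1
    starts = np.arange(0, length, window)
    rows = []
    for start in starts:
        sel = stats[(stats["site"] >= start) & (stats["site"] < start + window)]
        values = sel["percent_inaccessible"].dropna()
        rows.append({
            "window_start": int(start),
            "window_center": start + window / 2.0,
            "mean_percent_inaccessible":
                float(values.mean()) if len(values) else float("nan"),
            "n_sites": int(len(values)),
            "empty": len(values) == 0,
        })
    return pd.DataFrame(rows)


def select_test_sites(registry: SiteRegistry, stride: int = 100) -> list[int]:
    """One GpC site per ``stride``-bp window: the site nearest the
    window center (ties broken toward the smaller coordinate).
    Windows without a GCH site are skipped."""
    if stride <= 0:
        raise ValueError("stride must be positive")
    sites = sorted(registry.gch_sites)
    if not sites:
        return []
    selected = []
    for start in range(0, max(sites) + 1, stride):
        in_window = [s for s in sites if start <= s < start + stride]
        if not in_window:
            continue
        center = start + stride / 2.0
        selected.append(min(in_window, key=lambda s: (abs(s - center), s)))
    return selected


def chi_square_2x2(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson chi-square (df = 1, no continuity correction) on 2×2
    tables; vectorised over leading axes of shape (..., 2, 2).

    A zero row or column margin leaves the statistic undefined (NaN).
    """
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=-1)                    # (..., 2)
    cols = t.sum(axis=-2)                    # (..., 2)
    total = rows.sum(axis=-1)                # (...,)
    expected = (rows[..., :, None] * cols[..., None, :]
                / np.where(total == 0, np.nan, total)[..., None, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.sum((t - expected) ** 2 / expected, axis=(-2, -1))
    bad = (rows == 0).any(axis=-1) | (cols == 0).any(axis=-1)
    stat = np.where(bad, np.nan, stat)
    pvalue = sstats.chi2.sf(stat, df=1)
    return stat, pvalue


def exact_test_2x2(table: np.ndarray, method: str = "midp") -> float:
    """Two-sided exact test on a 2×2 table.

    ``midp`` (default) returns the mid-p value: the probability of
    conditional tables strictly less likely than the observed one plus
    half the probability of those equally likely.  The mid-p correction
    removes most of the conservatism the discreteness of Fisher's test
    causes at clone-level sample sizes.  ``fisher`` gives the classical
    (conservative) Fisher p-value.
    """
    t = np.asarray(table, dtype=int)
    if method == "fisher":
        return float(sstats.fisher_exact(t)[1])
    if method != "midp":
        raise ValueError(f"unknown exact method {method!r}")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n1, m, total = a + b, a + c, a + b + c + d
    if total == 0:
        return float("nan")
    lo = max(0, m - (c + d))
    hi = min(m, n1)
    ks = np.arange(lo, hi + 1)
    probs = sstats.hypergeom.pmf(ks, total, n1, m)
    p_obs = sstats.hypergeom.pmf(a, total, n1, m)
    eps = 1e-9 * max(p_obs, 1e-300)
    smaller = probs[probs < p_obs - eps].sum()
    equal = probs[np.abs(probs - p_obs) <= eps].sum()
    return float(smaller + 0.5 * equal)


def _site_counts(matrix: CloneCallMatrix, site: int) -> tuple[int, int]:
    retained, converted, _ = matrix.counts_at(site)
    return retained, converted


def compare_conditions(matrix_a: CloneCallMatrix,
                       matrix_b: CloneCallMatrix,
                       test_sites: list[int] | None = None,
                       stride: int = 100,
                       method: str = "chisquare",
                       adjust: str | None = None) -> pd.DataFrame:
    """Per-site condition comparison on the 2×2 table of
    (condition) × (accessible, inaccessible); ambiguous calls excluded.

    ``method`` is ``chisquare`` (Pearson, df = 1, no continuity
    correction), ``midp`` or ``fisher``.  p-values are reported per
    site without multiple-testing adjustment; pass ``adjust='bh'`` for
    Benjamini–Hochberg q-values.  Sites where a margin of the table is
    zero are reported with an undefined statistic.
    """
    reg_a = set(matrix_a.registry.gch_sites)
    if reg_a != set(matrix_b.registry.gch_sites):
        raise ValueError("matrices do not share a site registry")
    if test_sites is None:
        test_sites = select_test_sites(matrix_a.registry, stride=stride)

    rows = []
    for site in test_sites:
        if site not in reg_a:
            raise ValueError(f"test site {site} is not a GCH site")
        acc_a, inacc_a = _site_counts(matrix_a, site)
        acc_b, inacc_b = _site_counts(matrix_b, site)
        table = np.array([[acc_a, inacc_a], [acc_b, inacc_b]])
        if method == "chisquare":
            stat, pvalue = chi_square_2x2(table)
            stat, pvalue = float(stat), float(pvalue)
        else:
            stat = float("nan")
            zero_margin = (table.sum(axis=0) == 0).any() or \
                          (table.sum(axis=1) == 0).any()
            pvalue = float("nan") if zero_margin \
                else exact_test_2x2(table, method=method)
        rows.append({
            "site": site,
            "accessible_a": acc_a, "inaccessible_a": inacc_a,
            "accessible_b": acc_b, "inaccessible_b": inacc_b,
            "statistic": stat, "df": 1, "pvalue": pvalue,
            "undefined": bool(np.isnan(pvalue)),
        })
    result = pd.DataFrame(rows)
    if adjust == "bh" and len(result):
        mask = ~result["pvalue"].isna()
        qvalues = np.full(len(result), np.nan)
        if mask.any():
            qvalues[mask.to_numpy()] = multipletests(
                result.loc[mask, "pvalue"], method="fdr_bh")[1]
        result["qvalue"] = qvalues
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return result


def _runs(positions: list[int], calls: np.ndarray, target: Call,
          opposite: Call) -> list[tuple[int, int, int]]:
    """Maximal runs of ``target`` calls over ordered sites.

    Ambiguous sites neither break a run nor extend its ends; a run is
    delimited by ``opposite`` calls (or the molecule ends) and reported
    by its outermost ``target`` sites (start, end, n_target_sites).
    """
    runs = []
    current: list[int] = []
    for pos, call in zip(positions, calls):
        if call == target:
            current.append(pos)
        elif call == opposite:
            if current:
                runs.append((current[0], current[-1], len(current)))
            current = []
        # ambiguous: skip
    if current:
        runs.append((current[0], current[-1], len(current)))
    return runs


def _call_runs(matrix: CloneCallMatrix, target: Call, min_span: int,
               big_label: str,
               extend_to_midpoints: bool = False) -> list[Footprint]:
    opposite = Call.CONVERTED if target == Call.RETAINED else Call.RETAINED
    positions = sorted(matrix.registry.gch_sites)
    out = []
    for clone_id in matrix.clone_ids:
        calls = matrix.calls.loc[clone_id, positions].to_numpy()
        opp_positions = [p for p, c in zip(positions, calls)
                         if c == opposite]
        for start, end, n in _runs(positions, calls, target, opposite):
            if extend_to_midpoints:
                before = [p for p in opp_positions if p < start]
                after = [p for p in opp_positions if p > end]
                if before:
                    start = (before[-1] + start + 1) // 2
                if after:
                    end = (after[0] + end) // 2
            span = end - start + 1
            out.append(Footprint(
                clone_id=clone_id, start=start, end=end, n_sites=n,
                classification=big_label if span >= min_span
                else SUBTHRESHOLD))
    return out


def call_footprints(matrix: CloneCallMatrix, min_span: int = 150,
                    extend_to_midpoints: bool = False) -> list[Footprint]:
    """Per-molecule inaccessible runs; NUCLEOSOME_SIZED when the span
    between the outermost inaccessible sites (inclusive) reaches
    ``min_span`` bp (~ the DNA a nucleosome covers).

    With ``extend_to_midpoints`` the run is widened to the midpoints
    toward the nearest flanking accessible sites — an upper-bound span
    convention, versus the default conservative one.
    """
    return _call_runs(matrix, Call.CONVERTED, min_span, NUCLEOSOME_SIZED,
                      extend_to_midpoints=extend_to_midpoints)


def call_open_runs(matrix: CloneCallMatrix, min_span: int = 147,
                   extend_to_midpoints: bool = False) -> list[Footprint]:
    """Per-molecule accessible runs (NDR candidates); classified
    NUCLEOSOME_SIZED when long enough to exclude a nucleosome."""
    return _call_runs(matrix, Call.RETAINED, min_span, NUCLEOSOME_SIZED,
                      extend_to_midpoints=extend_to_midpoints)


def footprints_to_frame(footprints: list[Footprint]) -> pd.DataFrame:
    rows = [dict(asdict(f), span=f.span) for f in footprints]
    columns = ["clone_id", "start", "end", "span", "n_sites",
               "classification"]
    return pd.DataFrame(rows, columns=columns)


def footprints_to_bed(footprints: list[Footprint], path: str | Path,
                      chrom: str = "amplicon") -> None:
    """BED6: 0-based half-open span, name = clone id, score = span."""
    with open(path, "w") as fh:
        for f in footprints:
            fh.write(f"{chrom}\t{f.start}\t{f.end + 1}\t{f.clone_id}"
                     f"\t{f.span}\t+\n")


def bubble_matrix(matrix: CloneCallMatrix,
                  footprints: list[Footprint] | None = None) -> dict:
    """Plot-ready molecule × site structure for bubble charts.

    Per molecule: the ordered GCH site states ('accessible',
    'inaccessible', 'ambiguous') and bar intervals for its
    nucleosome-sized footprints.  JSON-serialisable.
    """
    if footprints is None:
        footprints = call_footprints(matrix)
    state_name = {Call.RETAINED: "accessible",
                  Call.CONVERTED: "inaccessible",
                  Call.AMBIGUOUS: "ambiguous"}
    positions = sorted(matrix.registry.gch_sites)
    bars: dict[str, list[list[int]]] = {c: [] for c in matrix.clone_ids}
    for f in footprints:
        if f.classification == NUCLEOSOME_SIZED:
            bars[f.clone_id].append([f.start, f.end])
    return {
        "sites": positions,
        "molecules": [
            {
                "clone_id": clone_id,
                "states": [state_name[Call(v)] for v in
                           matrix.calls.loc[clone_id, positions]],
                "bars": bars[clone_id],
            }
            for clone_id in matrix.clone_ids
        ],
    }


def bubble_round_trip(structure: dict) -> dict:
    """Serialise and re-load a bubble structure (JSON)."""
    return json.loads(json.dumps(structure))
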