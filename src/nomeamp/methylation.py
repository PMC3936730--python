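"""Endogenous CpG methylation maps and CpG-rich region detection.

Bisulfite genomic clones are aligned and called with the same machinery
as NOMe-seq clones; here only the HCG sites are interpreted
(RETAINED = methylated, CONVERTED = unmethylated).  CpG-rich regions
are found with a Takai–Jones-style sliding-window scan: 200-bp windows
stepping 1 bp must reach both %GC and observed/expected-CpG thresholds;
overlapping qualifying windows are merged, the merged region is trimmed
to begin and end at a CpG, and the trimmed region is re-checked against
all three thresholds including a minimum length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import Call, CloneCallMatrix

__all__ = [
    "MethylationMap",
    "CpGRichRegion",
    "methylation_percent",
    "site_methylation",
    "lollipop_matrix",
    "cpg_island_scan",
    "compare_profiles",
]


@dataclass(frozen=True)
class CpGRichRegion:
    start: int          # 0-based inclusive
    end: int            # exclusive
    gc_percent: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MethylationMap:
    """clones × HCG-site methylation calls for one sample.

    ``calls`` values are :class:`Call` (RETAINED = methylated).
    """

    calls: pd.DataFrame
    sample: str = ""

    @classmethod
    def from_call_matrix(cls, matrix: CloneCallMatrix,
                         sample: str = "") -> "MethylationMap":
        sites = sorted(matrix.registry.hcg_sites)
        return cls(calls=matrix.calls[sites].copy(), sample=sample)

    @property
    def sites(self) -> list[int]:
        return list(self.calls.columns)

    @property
    def n_clones(self) -> int:
        return len(self.calls)


def methylation_percent(mmap: MethylationMap, site: int) -> float:
    """100 · n_methylated / (n_methylated + n_unmethylated) at a site;
    NaN (flagged undefined) when no determinate call exists."""
    if site not in mmap.calls.columns:
        raise ValueError(f"site {site} is not in this methylation map")
    col = mmap.calls[site].to_numpy()
    n_meth = int((col == Call.RETAINED).sum())
    n_unmeth = int((col == Call.CONVERTED).sum())
    total = n_meth + n_unmeth
    return 100.0 * n_meth / total if total else float("nan")


def site_methylation(mmap: MethylationMap) -> pd.DataFrame:
    rows = []
    for site in mmap.sites:
        col = mmap.calls[site].to_numpy()
        n_meth = int((col == Call.RETAINED).sum())
        n_unmeth = int((col == Call.CONVERTED).sum())
        rows.append({
            "site": site, "n_methylated": n_meth,
            "n_unmethylated": n_unmeth,
            "n_ambiguous": int((col == Call.AMBIGUOUS).sum()),
            "percent_methylated": 100.0 * n_meth / (n_meth + n_unmeth)
            if (n_meth + n_unmeth) else float("nan"),
        })
    return pd.DataFrame(rows)


def lollipop_matrix(mmap: MethylationMap) -> dict:
    """Plot-ready clone × site structure: filled circles = methylated,
    open = unmethylated, absent = ambiguous.  JSON-serialisable; circle
    order follows genomic coordinate."""
    name = {Call.RETAINED: "filled", Call.CONVERTED: "open",
            Call.AMBIGUOUS: "missing"}
    sites = mmap.sites
    return {
        "sample": mmap.sample,
        "sites": sites,
        "clones": [
            {"clone_id": str(clone_id),
             "circles": [name[Call(v)] for v in mmap.calls.loc[clone_id]]}
            for clone_id in mmap.calls.index
        ],
    }


def _window_stats(seq: str, start: int, end: int) -> tuple[float, float]:
    sub = seq[start:end]
    length = end - start
    n_c = sub.count("C")
    n_g = sub.count("G")
    gc = 100.0 * (n_c + n_g) / length
    n_cpg = sub.count("CG")
    oe = (n_cpg * length) / (n_c * n_g) if n_c and n_g else 0.0
    return gc, oe


def cpg_island_scan(sequence: str, min_gc: float = 55.0,
                    min_oe: float = 0.65, min_len: int = 500,
                    window: int = 200, step: int = 1
                    ) -> list[CpGRichRegion]:
    """Detect CpG-rich regions by sliding-window scan.

    obs/exp CpG = (n_CpG · L) / (n_C · n_G), defined as 0 when a window
    has no C or no G.  Qualifying windows (both %GC ≥ min_gc and
    obs/exp ≥ min_oe) are merged when they overlap; each merged region
    is trimmed so it starts and ends on a CpG dinucleotide (skipped if
    it contains none) and kept only if the trimmed region itself meets
    %GC, obs/exp and ``min_len``.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < window:
        raise ValueError(f"sequence shorter than window ({n} < {window})")

    # prefix sums make every window O(1)
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    is_c = (arr == b"C").astype(np.int64)
    is_g = (arr == b"G").astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cpg[:-1] = ((arr[:-1] == b"C") & (arr[1:] == b"G")).astype(np.int64)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])

    def stats(a: int, b: int) -> tuple[float, float]:
        length = b - a
        n_c = int(cum_c[b] - cum_c[a])
        n_g = int(cum_g[b] - cum_g[a])
        upper = min(b - 1, n - 1)  # CpG starting inside [a, b-1)
        n_cpg = int(cum_cpg[upper] - cum_cpg[a]) if upper > a else 0
        gc = 100.0 * (n_c + n_g) / length
        oe = (n_cpg * length) / (n_c * n_g) if n_c and n_g else 0.0
        return gc, oe

    starts = np.arange(0, n - window + 1, step)
    passing = []
    for a in starts:
        gc, oe = stats(int(a), int(a) + window)
        if gc >= min_gc and oe >= min_oe:
            passing.append((int(a), int(a) + window))
    if not passing:
        return []

    merged: list[list[int]] = [list(passing[0])]
    for a, b in passing[1:]:
        if a < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    regions = []
    for a, b in merged:
        first = sequence.find("CG", a, b)
        if first != -1:
            last = sequence.rfind("CG", a, b)
            a, b = first, min(last + 2, b)
        gc, oe = stats(a, b)
        if gc >= min_gc and oe >= min_oe and (b - a) >= min_len:
            regions.append(CpGRichRegion(start=a, end=b, gc_percent=gc,
                                         obs_exp_cpg=oe))
    return regions


def regions_to_bed(regions: list[CpGRichRegion], path, chrom="amplicon"):
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{chrom}\t{r.start}\t{r.end}\tCpG_rich_{i + 1}"
                     f"\t{r.length}\t+\n")


def compare_profiles(map_a: MethylationMap,
                     map_b: MethylationMap) -> pd.DataFrame:
    """Per-site methylation difference (A − B, percentage points) with
    determinate-call counts; no statistical test is attached.  Sites
    undefined in either sample are flagged, not dropped."""
    sites_a, sites_b = set(map_a.sites), set(map_b.sites)
    shared = sites_a & sites_b
    if not shared:
        raise ValueError("methylation maps share no HCG sites")
    rows = []
    for site in sorted(shared):
        pa = methylation_percent(map_a, site)
        pb = methylation_percent(map_b, site)
        col_a = map_a.calls[site].to_numpy()
        col_b = map_b.calls[site].to_numpy()
        rows.append({
            "site": site,
            "percent_a": pa, "percent_b": pb,
            "delta_percent": pa - pb,
            "n_determinate_a": int((col_a != Call.AMBIGUOUS).sum()),
            "n_determinate_b": int((col_b != Call.AMBIGUOUS).sum()),
            "undefined": bool(np.isnan(pa) or np.isnan(pb)),
        })
    return pd.DataFrame(rows)
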