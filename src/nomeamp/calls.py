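"""Per-clone per-site methylation calls and clone-level QC.

At every registry site the aligned clone base is interpreted as
C → RETAINED (protected from conversion, i.e. methylated),
T → CONVERTED (unmethylated), anything else → AMBIGUOUS.  GCG sites are
always AMBIGUOUS because enzyme and endogenous methylation are
confounded there.  Polarity at GCH sites: RETAINED means the enzyme
reached the site, i.e. the molecule was *accessible*; CONVERTED means
inaccessible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import GAP, CloneAlignment
from .reference import CH, GCG, GCH, HCG, SiteRegistry

__all__ = [
    "Call",
    "CloneCallMatrix",
    "EmptyCallMatrixError",
    "call_sites",
    "build_matrix",
    "filter_clones",
]


class Call(enum.IntEnum):
    CONVERTED = 0
    RETAINED = 1
    AMBIGUOUS = 2


class EmptyCallMatrixError(RuntimeError):
    """All clones were removed by QC — downstream stats are undefined."""


@dataclass
class CloneCallMatrix:
    """clones × cytosine-sites call matrix with per-clone QC.

    ``calls`` is an int8 DataFrame (index clone ids, columns 0-based
    site positions, values :class:`Call`); ``clone_qc`` carries
    conversion_efficiency (fraction of CH cytosines converted) and
    mismatch_rate per clone.
    """

    calls: pd.DataFrame
    registry: SiteRegistry
    clone_qc: pd.DataFrame

    @property
    def n_clones(self) -> int:
        return len(self.calls)

    @property
    def clone_ids(self) -> list[str]:
        return list(self.calls.index)

    def counts_at(self, site: int) -> tuple[int, int, int]:
        """(retained, converted, ambiguous) counts at a site."""
        col = self.calls[site].to_numpy()
        return (int((col == Call.RETAINED).sum()),
                int((col == Call.CONVERTED).sum()),
                int((col == Call.AMBIGUOUS).sum()))

    def subset(self, clone_ids) -> "CloneCallMatrix":
        return CloneCallMatrix(self.calls.loc[clone_ids],
                               self.registry,
                               self.clone_qc.loc[clone_ids])

    # --- TSV round trip (clones × sites; A/I/N at GCH, M/U/N at HCG) ---

    _GCH_CODE = {Call.RETAINED: "A", Call.CONVERTED: "I", Call.AMBIGUOUS: "N"}
    _HCG_CODE = {Call.RETAINED: "M", Call.CONVERTED: "U", Call.AMBIGUOUS: "N"}

    def to_tsv(self, path: str | Path) -> None:
        gch = set(self.registry.gch_sites)
        hcg = set(self.registry.hcg_sites)
        out = {}
        for site in self.calls.columns:
            if site in gch:
                code, ctx = self._GCH_CODE, GCH
            elif site in hcg:
                code, ctx = self._HCG_CODE, HCG
            else:
                continue
            out[f"{site}:{ctx}"] = [code[Call(v)] for v in self.calls[site]]
        frame = pd.DataFrame(out, index=self.calls.index)
        frame.index.name = "clone_id"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 registry: SiteRegistry,
                 clone_qc: pd.DataFrame | None = None) -> "CloneCallMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="clone_id")
        decode = {"A": Call.RETAINED, "I": Call.CONVERTED,
                  "M": Call.RETAINED, "U": Call.CONVERTED,
                  "N": Call.AMBIGUOUS}
        data = {}
        for column in frame.columns:
            site_str, _, ctx = column.partition(":")
            site = int(site_str)
            data[site] = np.array(
                [decode[v] for v in frame[column]], dtype=np.int8)
        calls = pd.DataFrame(data, index=frame.index)
        calls = calls[sorted(calls.columns)]
        if clone_qc is None:
            clone_qc = pd.DataFrame(
                {"conversion_efficiency": np.nan, "mismatch_rate": np.nan},
                index=frame.index)
        return cls(calls=calls, registry=registry, clone_qc=clone_qc)


def call_sites(alignment: CloneAlignment,
               registry: SiteRegistry) -> tuple[pd.Series, dict]:
    """Call every cytosine site of one aligned clone.

    Returns the per-site call row and a QC dict with
    ``conversion_efficiency`` (CONVERTED / (CONVERTED + RETAINED) over
    CH conversion-control sites) and ``ambiguous_fraction`` over the
    GCH+HCG reporter sites.
    """
    row = {}
    for pos in registry.all_cytosines:
        if pos in set(registry.gcg_sites):
            row[pos] = Call.AMBIGUOUS
            continue
        base = alignment.column_bases[pos]
        if base == "C":
            row[pos] = Call.RETAINED
        elif base == "T":
            row[pos] = Call.CONVERTED
        else:
            row[pos] = Call.AMBIGUOUS

    ch_calls = [row[p] for p in registry.ch_sites]
    n_conv = sum(1 for c in ch_calls if c == Call.CONVERTED)
    n_ret = sum(1 for c in ch_calls if c == Call.RETAINED)
    efficiency = n_conv / (n_conv + n_ret) if (n_conv + n_ret) else np.nan

    reporter = list(registry.gch_sites) + list(registry.hcg_sites)
    n_amb = sum(1 for p in reporter if row[p] == Call.AMBIGUOUS)
    amb_fraction = n_amb / len(reporter) if reporter else 0.0

    series = pd.Series({p: np.int8(c) for p, c in row.items()},
                       name=alignment.clone_id, dtype=np.int8)
    qc = {"conversion_efficiency": efficiency,
          "ambiguous_fraction": amb_fraction,
          "mismatch_rate": 1.0 - alignment.identity,
          "alignment_identity": alignment.identity}
    return series, qc


def build_matrix(rows: list[tuple[pd.Series, dict]],
                 registry: SiteRegistry) -> CloneCallMatrix:
    """Assemble call rows from :func:`call_sites` into a matrix."""
    if not rows:
        raise EmptyCallMatrixError("no clones to assemble")
    calls = pd.DataFrame([r for r, _ in rows]).astype(np.int8)
    qc = pd.DataFrame([q for _, q in rows], index=calls.index)
    qc.index.name = calls.index.name = "clone_id"
    return CloneCallMatrix(calls=calls, registry=registry, clone_qc=qc)


def filter_clones(matrix: CloneCallMatrix,
                  min_conversion: float = 0.95,
                  max_ambiguous: float = 0.2
                  ) -> tuple[CloneCallMatrix, pd.DataFrame]:
    """Remove clones with poor bisulfite conversion or too many
    ambiguous reporter-site calls.

    Returns the filtered matrix and a QC report listing every clone
    with its metrics, pass/fail status and failure reasons.  Raises
    :class:`EmptyCallMatrixError` when nothing survives.
    """
    for name, value in (("min_conversion", min_conversion),
                        ("max_ambiguous", max_ambiguous)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")

    report_rows = []
    keep = []
    for clone_id, qc in matrix.clone_qc.iterrows():
        reasons = []
        eff = qc.get("conversion_efficiency", np.nan)
        amb = qc.get("ambiguous_fraction", 0.0)
        if pd.notna(eff) and eff < min_conversion:
            reasons.append("conversion")
        if pd.notna(amb) and amb > max_ambiguous:
            reasons.append("ambiguous")
        if not reasons:
            keep.append(clone_id)
        report_rows.append({
            "clone_id": clone_id,
            "conversion_efficiency": eff,
            "ambiguous_fraction": amb,
            "passed": not reasons,
            "reason": ";".join(reasons),
        })
    report = pd.DataFrame(report_rows).set_index("clone_id")
    if not keep:
        raise EmptyCallMatrixError(
            f"all {matrix.n_clones} clones failed QC "
            f"(min_conversion={min_conversion}, "
            f"max_ambiguous={max_ambiguous})")
    return matrix.subset(keep), report
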