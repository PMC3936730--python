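"""Amplicon references and cytosine-context classification.

NOMe-seq reads out two orthogonal methylation signals on the same
bisulfite-converted molecule: exogenous GpC methylation deposited by
M.CviPI on accessible chromatin, and endogenous CpG methylation.  The
two are disambiguated purely by sequence context of the cytosine:

* ``GCH`` — C preceded by G and not followed by G: accessibility
  reporter (M.CviPI only).
* ``HCG`` — C followed by G and not preceded by G: endogenous
  methylation reporter.
* ``GCG`` — both contexts overlap; the signals are confounded and the
  site is excluded from calling.
* ``CH``  — any other cytosine: bisulfite-conversion control.

Coordinates are 0-based indices of the cytosine itself; display labels
use signed distance to a genomic anchor (e.g. the TSS) so a site can be
reported as "-9.9 kb".
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GCH",
    "HCG",
    "GCG",
    "CH",
    "SiteRegistry",
    "AmpliconReference",
    "classify_sites",
    "convert_reference",
]

_VALID_BASES = frozenset("ACGT")

GCH = "GCH"
HCG = "HCG"
GCG = "GCG"
CH = "CH"


@dataclass(frozen=True)
class SiteRegistry:
    """Partition of all cytosine positions of a reference into the four
    NOMe-seq context classes.  Positions are 0-based indices of the C."""

    gch_sites: tuple[int, ...]
    hcg_sites: tuple[int, ...]
    gcg_sites: tuple[int, ...]
    ch_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        sets = [set(self.gch_sites), set(self.hcg_sites),
                set(self.gcg_sites), set(self.ch_sites)]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if total != len(union):
            raise ValueError("site classes must be disjoint")

    @property
    def all_cytosines(self) -> tuple[int, ...]:
        return tuple(sorted(
            set(self.gch_sites) | set(self.hcg_sites)
            | set(self.gcg_sites) | set(self.ch_sites)))

    def context_of(self, pos: int) -> str:
        if pos in self._lookup:
            return self._lookup[pos]
        raise KeyError(f"position {pos} is not a cytosine of this reference")

    @property
    def _lookup(self) -> dict[int, str]:
        # small registries; rebuild on demand to keep the dataclass frozen
        d: dict[int, str] = {}
        for name, sites in ((GCH, self.gch_sites), (HCG, self.hcg_sites),
                            (GCG, self.gcg_sites), (CH, self.ch_sites)):
            for p in sites:
                d[p] = name
        return d


@dataclass
class AmpliconReference:
    """A named amplicon sequence with a genomic offset.

    ``genomic_offset`` is the signed genomic coordinate (bp relative to
    the anchor, typically the TSS) of position 0 of ``sequence``.
    """

    name: str
    sequence: str
    genomic_offset: int = 0
    _registry: SiteRegistry | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = [(i, b) for i, b in enumerate(self.sequence)
               if b not in _VALID_BASES]
        if bad:
            i, b = bad[0]
            raise ValueError(
                f"invalid base {b!r} at position {i} in reference "
                f"{self.name!r}: alphabet is A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def registry(self) -> SiteRegistry:
        if self._registry is None:
            self._registry = classify_sites(self)
        return self._registry

    def kb_label(self, pos: int) -> str:
        """Signed-kb display label of an internal position, e.g. '-9.9 kb'."""
        kb = (pos + self.genomic_offset) / 1000.0
        return f"{kb:+.1f} kb".replace("+", "")


def classify_sites(reference: AmpliconReference | str) -> SiteRegistry:
    """Classify every cytosine of a reference into GCH/HCG/GCG/CH.

    A missing neighbour at the sequence boundary is treated as a
    non-G base (H), so a terminal ``GC`` still counts as GCH and an
    initial ``CG`` as HCG.

    Raises ``ValueError`` (with position) on characters outside A/C/G/T.
    """
    seq = reference.sequence if isinstance(reference, AmpliconReference) \
        else reference.upper()
    if not seq:
        raise ValueError("empty sequence")
    for i, b in enumerate(seq):
        if b not in _VALID_BASES:
            raise ValueError(f"invalid base {b!r} at position {i}")

    gch, hcg, gcg, ch = [], [], [], []
    for i, b in enumerate(seq):
        if b != "C":
            continue
        prev_g = i > 0 and seq[i - 1] == "G"
        next_g = i + 1 < len(seq) and seq[i + 1] == "G"
        if prev_g and next_g:
            gcg.append(i)
        elif prev_g:
            gch.append(i)
        elif next_g:
            hcg.append(i)
        else:
            ch.append(i)
    return SiteRegistry(tuple(gch), tuple(hcg), tuple(gcg), tuple(ch))


def convert_reference(reference: AmpliconReference | str) -> str:
    """Fully bisulfite-converted top strand: every C read as T.

    Used as the alignment target for clone registration.
    """
    seq = reference.sequence if isinstance(reference, AmpliconReference) \
        else reference.upper()
    return seq.replace("C", "T")
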