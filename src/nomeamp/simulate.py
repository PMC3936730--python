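"""Synthetic amplicons, single-molecule chromatin states and qPCR tables.

The generator emulates the data a clone-based NOMe-seq experiment
produces: each sequenced molecule comes from one cell, the cell is in
one of a small number of chromatin states (e.g. nucleosome over the
enhancer vs. a nucleosome-depleted region), the GpC methyltransferase
marks the accessible GpC sites of that molecule, bisulfite conversion
turns every unmethylated cytosine into thymine, and Sanger sequencing
adds rare substitution errors.  Ground truth (the sampled state and the
per-site protection/methylation flags) is returned as a sidecar table
keyed by clone id, so downstream calls can be checked exactly.

Clones model the top (bisulfite-converted sense) strand only.  Filler
bases outside planned GpC/CpG sites are drawn from {A, T} so no
accidental cytosine contexts arise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import GCG, GCH, HCG, AmpliconReference

__all__ = [
    "CellState",
    "ChromatinStateModel",
    "NoiseModel",
    "EndogenousMethylationProfile",
    "SimulatedClones",
    "make_reference",
    "simulate_clones",
    "simulate_ct_table",
    "PERFECT_NOISE",
]


def _check_prob(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class CellState:
    """One chromatin configuration a cell can be in.

    ``protected_intervals`` are [start, end) spans (reference
    coordinates) occupied by a nucleosome or bound protein; GpC sites
    inside them are enzyme-accessible only with probability
    ``occluded_accessibility`` (leakage), sites outside with
    ``linker_accessibility``.
    """

    weight: float
    protected_intervals: tuple[tuple[int, int], ...] = ()
    linker_accessibility: float = 1.0
    occluded_accessibility: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("state weight must be >= 0")
        _check_prob(self.linker_accessibility, "linker_accessibility")
        _check_prob(self.occluded_accessibility, "occluded_accessibility")
        for start, end in self.protected_intervals:
            if end <= start or start < 0:
                raise ValueError(
                    f"invalid protected interval [{start}, {end})")

    def protects(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.protected_intervals)


@dataclass(frozen=True)
class ChromatinStateModel:
    """Mixture of cell states; weights must sum to 1."""

    states: tuple[CellState, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("need at least one cell state")
        total = sum(s.weight for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state weights must sum to 1, got {total}")

    def validate_bounds(self, length: int) -> None:
        for s in self.states:
            for start, end in s.protected_intervals:
                if end > length:
                    raise ValueError(
                        f"protected interval [{start}, {end}) exceeds "
                        f"reference length {length}")

    def accessibility(self, pos: int) -> float:
        """Marginal probability a GpC at ``pos`` is enzyme-accessible."""
        return sum(
            s.weight * (s.occluded_accessibility if s.protects(pos)
                        else s.linker_accessibility)
            for s in self.states)


@dataclass(frozen=True)
class NoiseModel:
    """Per-site Bernoulli error model of the assay chemistry.

    enzyme_efficiency
        probability an accessible GpC is actually methylated by M.CviPI
        (the two sequential enzyme incubations collapsed into one
        success probability).
    bisulfite_conversion_rate
        probability an unmethylated C reads as T.
    inappropriate_conversion_rate
        probability a methylated C reads as T.
    seq_error_rate
        per-base substitution probability applied last.
    """

    enzyme_efficiency: float = 1.0
    bisulfite_conversion_rate: float = 1.0
    inappropriate_conversion_rate: float = 0.0
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob(self.enzyme_efficiency, "enzyme_efficiency")
        _check_prob(self.bisulfite_conversion_rate,
                    "bisulfite_conversion_rate")
        _check_prob(self.inappropriate_conversion_rate,
                    "inappropriate_conversion_rate")
        _check_prob(self.seq_error_rate, "seq_error_rate")


PERFECT_NOISE = NoiseModel()


@dataclass(frozen=True)
class EndogenousMethylationProfile:
    """Per-HCG-site endogenous methylation probabilities.

    ``default`` is used for HCG sites absent from ``probs``; models
    cell-line-specific patterns (a hypomethylated enhancer is default 0,
    a hypermethylated one default close to 1).
    """

    probs: tuple[tuple[int, float], ...] = ()
    default: float = 0.0

    def __post_init__(self) -> None:
        _check_prob(self.default, "default methylation probability")
        for pos, p in self.probs:
            _check_prob(p, f"methylation probability at {pos}")

    @classmethod
    def uniform(cls, p: float) -> "EndogenousMethylationProfile":
        return cls(default=p)

    def prob(self, pos: int) -> float:
        for site, p in self.probs:
            if site == pos:
                return p
        return self.default

    def validate_sites(self, reference: AmpliconReference) -> None:
        hcg = set(reference.registry.hcg_sites)
        for pos, _ in self.probs:
            if pos not in hcg:
                raise ValueError(
                    f"methylation profile position {pos} is not an HCG "
                    f"site of reference {reference.name!r}")


@dataclass
class SimulatedClones:
    """Clone sequences plus the ground truth behind them."""

    clones: list[tuple[str, str]]                 # (clone id, sequence)
    truth: pd.DataFrame                           # clone_id,pos,context,...
    clone_states: pd.DataFrame                    # clone_id,state_index,label


def make_reference(length: int, gpc_spacing: int,
                   cpg_block_spec: list[tuple[int, int, float]] | None = None,
                   seed: int = 0, name: str = "amplicon",
                   genomic_offset: int = 0,
                   ch_spacing: int | None = None) -> AmpliconReference:
    """Build an amplicon with GpC sites on a regular grid and CpG sites
    concentrated in the requested blocks.

    ``cpg_block_spec`` rows are (start, end, cpg_density) with density in
    CpG dinucleotides per bp of block.  ``ch_spacing`` optionally plants
    isolated cytosines (CH conversion controls) on their own grid.  GpC
    placement skips positions that would collide with a CpG block.
    Filler is A/T, so outside the plan no cytosine context can occur;
    inside a block a density above ~1/3 forces adjacent CGs and hence
    GCG contexts.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if gpc_spacing < 2:
        raise ValueError("gpc_spacing must be >= 2")
    blocks = sorted(cpg_block_spec or [])
    for start, end, density in blocks:
        if start < 0 or end > length or end <= start:
            raise ValueError(f"CpG block [{start}, {end}) out of bounds")
        if not 0.0 <= density <= 0.5:
            raise ValueError("cpg_density must be in [0, 0.5]")
    for (s1, e1, _), (s2, e2, _) in zip(blocks, blocks[1:]):
        if s2 < e1:
            raise ValueError(
                f"CpG blocks [{s1},{e1}) and [{s2},{e2}) overlap")

    rng = np.random.default_rng(seed)
    seq = rng.choice(list("AT"), size=length).tolist()

    occupied: list[tuple[int, int]] = []  # planted dinucleotide spans
    for start, end, density in blocks:
        n_cpg = int(round(density * (end - start)))
        if n_cpg == 0:
            continue
        step = max(2, (end - start) // n_cpg)
        if step == 2 and density <= 1 / 3:
            step = 3
        p = start
        while p + 1 < end:
            seq[p], seq[p + 1] = "C", "G"
            occupied.append((p, p + 2))
            p += step

    def collides(a: int, b: int) -> bool:
        # 1-bp margin so a planted GC cannot create GCG/HCG next to a CG
        return any(a < e + 1 and b + 1 > s for s, e in occupied)

    p = gpc_spacing // 2
    while p + 1 < length:
        if not collides(p, p + 2):
            seq[p], seq[p + 1] = "G", "C"
            occupied.append((p, p + 2))
        p += gpc_spacing

    if ch_spacing is not None:
        if ch_spacing < 2:
            raise ValueError("ch_spacing must be >= 2")
        p = ch_spacing // 2 + 3  # off-phase from the GpC grid
        while p < length:
            if not collides(p, p + 1):
                seq[p] = "C"
                occupied.append((p, p + 1))
            p += ch_spacing

    return AmpliconReference(name=name, sequence="".join(seq),
                             genomic_offset=genomic_offset)


def simulate_clones(reference: AmpliconReference,
                    model: ChromatinStateModel,
                    meth: EndogenousMethylationProfile | None = None,
                    noise: NoiseModel = PERFECT_NOISE,
                    n_clones: int = 15,
                    clone_prefix: str = "clone") -> SimulatedClones:
    """Draw ``n_clones`` i.i.d. single molecules and push them through
    enzyme treatment, bisulfite conversion and sequencing error.

    The default clone count (15) matches the sequencing depth of a
    typical clone-based amplicon experiment.  Ground truth rows carry,
    for every cytosine of every clone: its context, whether the sampled
    state protected it, whether it ended up methylated, and the final
    read base.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    meth = meth or EndogenousMethylationProfile()
    model.validate_bounds(len(reference))
    meth.validate_sites(reference)

    rng = np.random.default_rng(noise.seed)
    registry = reference.registry
    ref_seq = reference.sequence
    weights = np.array([s.weight for s in model.states])
    weights = weights / weights.sum()

    c_positions = registry.all_cytosines
    context = {p: registry.context_of(p) for p in c_positions}

    clones: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    state_rows: list[dict] = []
    bases = np.array(list("ACGT"))

    for k in range(n_clones):
        clone_id = f"{clone_prefix}_{k:03d}"
        si = int(rng.choice(len(model.states), p=weights))
        state = model.states[si]
        state_rows.append({"clone_id": clone_id, "state_index": si,
                           "state_label": state.label})

        read = list(ref_seq)
        for pos in c_positions:
            ctx = context[pos]
            protected = state.protects(pos)
            if ctx in (GCH, GCG):
                p_acc = (state.occluded_accessibility if protected
                         else state.linker_accessibility)
                accessible = rng.random() < p_acc
                methylated = accessible and \
                    rng.random() < noise.enzyme_efficiency
            elif ctx == HCG:
                methylated = rng.random() < meth.prob(pos)
            else:  # CH: conversion control, never methylated
                methylated = False
            if methylated:
                converted = rng.random() < noise.inappropriate_conversion_rate
            else:
                converted = rng.random() < noise.bisulfite_conversion_rate
            if converted:
                read[pos] = "T"
            truth_rows.append({
                "clone_id": clone_id, "pos": pos, "context": ctx,
                "protected": protected, "methylated": bool(methylated),
                "read_base": read[pos],
            })

        if noise.seq_error_rate > 0:
            hits = np.nonzero(rng.random(len(read)) < noise.seq_error_rate)[0]
            for i in hits:
                alternatives = bases[bases != read[i]]
                read[i] = str(rng.choice(alternatives))
            if len(hits):
                errs = set(int(i) for i in hits)
                for row in truth_rows[-len(c_positions):]:
                    if row["pos"] in errs:
                        row["read_base"] = read[row["pos"]]

        clones.append((clone_id, "".join(read)))

    truth = pd.DataFrame(truth_rows)
    clone_states = pd.DataFrame(state_rows)
    return SimulatedClones(clones=clones, truth=truth,
                           clone_states=clone_states)


def simulate_ct_table(recoveries: dict,
                      assay_spec: list[tuple[str, str, float]],
                      noise_sd: float = 0.0, seed: int = 0,
                      replicates: int = 2, baseline_ct: float = 18.0,
                      positions: dict[str, float] | None = None,
                      input_noise_sd: float = 0.0) -> pd.DataFrame:
    """Simulate a qPCR Ct table from known relative quantities.

    ``recoveries`` maps (region, condition) — or plain region — to the
    template quantity the assay recovers, as a fraction of total input
    for ChIP/FAIRE or a relative abundance for RT.  ``assay_spec`` rows
    are (region, assay, input_fraction); ChIP/FAIRE rows get paired
    INPUT rows whose template quantity is the input aliquot fraction.

    Ct = baseline − log2(quantity) + N(0, noise_sd); with noise_sd = 0
    the downstream percent-of-input computation recovers the simulated
    recovery fraction exactly.  ``noise_sd`` applies to assay reactions;
    INPUT reference reactions are quantified from abundant template and
    get ``input_noise_sd`` (0 by default, configurable).
    """
    if noise_sd < 0 or input_noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    positions = positions or {}
    norm: dict[tuple[str, str], float] = {}
    for key, q in recoveries.items():
        region, condition = key if isinstance(key, tuple) else (key, "")
        if q <= 0:
            raise ValueError(
                f"quantity for {region!r}/{condition!r} must be > 0")
        norm[(region, condition)] = float(q)

    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def emit(region: str, assay: str, condition: str, quantity: float,
             input_fraction: float) -> None:
        sd = input_noise_sd if assay == "INPUT" else noise_sd
        for rep in range(1, replicates + 1):
            ct = baseline_ct - math.log2(quantity)
            if sd > 0:
                ct += rng.normal(0.0, sd)
            rows.append({
                "region": region,
                "position_bp": positions.get(region, float("nan")),
                "assay": assay, "condition": condition, "replicate": rep,
                "ct": ct, "input_fraction": input_fraction,
            })

    for region, assay, input_fraction in assay_spec:
        assay = assay.upper()
        if assay in ("CHIP", "FAIRE"):
            if not 0 < input_fraction <= 1:
                raise ValueError("input_fraction must be in (0, 1]")
        conditions = sorted({c for (r, c) in norm if r == region})
        if not conditions:
            raise ValueError(f"no quantity given for region {region!r}")
        for condition in conditions:
            q = norm[(region, condition)]
            emit(region, assay, condition, q, input_fraction)
            if assay in ("CHIP", "FAIRE"):
                emit(region, "INPUT", condition, input_fraction,
                     input_fraction)

    return pd.DataFrame(rows)
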