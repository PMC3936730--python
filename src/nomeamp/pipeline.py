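"""High-level stage functions shared by the CLI and by tests.

Also owns the plain-text simulation config (YAML) that pins down a
reproducible run: reference plan, chromatin-state mixture per
condition, endogenous methylation, noise model and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

from .align import CloneRejected, align_clone
from .calls import CloneCallMatrix, build_matrix, call_sites, filter_clones
from .reference import AmpliconReference
from .simulate import (CellState, ChromatinStateModel,
                       EndogenousMethylationProfile, NoiseModel,
                       SimulatedClones, make_reference, simulate_clones)

__all__ = [
    "call_clones",
    "call_and_filter",
    "SimulationConfig",
    "run_simulation",
]


def call_clones(reference: AmpliconReference,
                clones: list[tuple[str, str]],
                min_identity: float = 0.8,
                max_length_deviation: float = 0.2
                ) -> tuple[CloneCallMatrix, list[tuple[str, str]]]:
    """Align every clone and call all cytosine sites.

    Returns the assembled call matrix and the list of
    (clone_id, reason) for clones rejected at alignment.
    """
    registry = reference.registry
    rows = []
    rejected: list[tuple[str, str]] = []
    for clone_id, seq in clones:
        try:
            alignment = align_clone(
                seq, reference, clone_id=clone_id,
                min_identity=min_identity,
                max_length_deviation=max_length_deviation)
        except CloneRejected as exc:
            rejected.append((clone_id, exc.reason))
            continue
        rows.append(call_sites(alignment, registry))
    matrix = build_matrix(rows, registry)
    return matrix, rejected


def call_and_filter(reference: AmpliconReference,
                    clones: list[tuple[str, str]],
                    min_identity: float = 0.8,
                    min_conversion: float = 0.95,
                    max_ambiguous: float = 0.2
                    ) -> tuple[CloneCallMatrix, pd.DataFrame,
                               list[tuple[str, str]]]:
    """Full calling stage: align, call, clone-QC filter."""
    matrix, rejected = call_clones(reference, clones,
                                   min_identity=min_identity)
    filtered, report = filter_clones(matrix, min_conversion=min_conversion,
                                     max_ambiguous=max_ambiguous)
    return filtered, report, rejected


# --------------------------------------------------------------------
# simulation config

_TOP_KEYS = {"seed", "reference", "noise", "n_clones", "conditions"}
_REF_KEYS = {"length", "gpc_spacing", "cpg_blocks", "name",
             "genomic_offset", "ch_spacing"}
_NOISE_KEYS = {"enzyme_efficiency", "bisulfite_conversion_rate",
               "inappropriate_conversion_rate", "seq_error_rate"}
_STATE_KEYS = {"weight", "protected_intervals", "linker_accessibility",
               "occluded_accessibility", "label"}
_COND_KEYS = {"states", "methylation"}
_METH_KEYS = {"default", "sites"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}")


@dataclass
class SimulationConfig:
    seed: int
    reference: dict
    noise: dict
    n_clones: int
    conditions: dict[str, dict]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, where=str(path))

    @classmethod
    def from_dict(cls, raw: dict, where: str = "config") -> "SimulationConfig":
        if not isinstance(raw, dict):
            raise ValueError(f"{where}: config must be a mapping")
        _check_keys(raw, _TOP_KEYS, where)
        reference = dict(raw.get("reference", {}))
        _check_keys(reference, _REF_KEYS, f"{where}:reference")
        noise = dict(raw.get("noise", {}))
        _check_keys(noise, _NOISE_KEYS, f"{where}:noise")
        conditions = raw.get("conditions")
        if not conditions:
            raise ValueError(f"{where}: at least one condition is required")
        for name, cond in conditions.items():
            _check_keys(dict(cond), _COND_KEYS, f"{where}:conditions:{name}")
            for state in cond.get("states", []):
                _check_keys(dict(state), _STATE_KEYS,
                            f"{where}:conditions:{name}:states")
            _check_keys(dict(cond.get("methylation", {}) or {}), _METH_KEYS,
                        f"{where}:conditions:{name}:methylation")
        return cls(seed=int(raw.get("seed", 0)), reference=reference,
                   noise=noise, n_clones=int(raw.get("n_clones", 15)),
                   conditions=conditions)

    def to_yaml(self, path) -> None:
        raw = {"seed": self.seed, "reference": self.reference,
               "noise": self.noise, "n_clones": self.n_clones,
               "conditions": self.conditions}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def build_reference(self) -> AmpliconReference:
        ref = self.reference
        blocks = [(b["start"], b["end"], b["density"])
                  for b in ref.get("cpg_blocks", [])]
        return make_reference(
            length=int(ref.get("length", 600)),
            gpc_spacing=int(ref.get("gpc_spacing", 20)),
            cpg_block_spec=blocks, seed=self.seed,
            name=ref.get("name", "amplicon"),
            genomic_offset=int(ref.get("genomic_offset", 0)),
            ch_spacing=(int(ref["ch_spacing"])
                        if ref.get("ch_spacing") else None))

    def build_model(self, condition: str) -> ChromatinStateModel:
        states = []
        for s in self.conditions[condition].get("states", []):
            states.append(CellState(
                weight=float(s.get("weight", 1.0)),
                protected_intervals=tuple(
                    (int(a), int(b))
                    for a, b in s.get("protected_intervals", [])),
                linker_accessibility=float(
                    s.get("linker_accessibility", 1.0)),
                occluded_accessibility=float(
                    s.get("occluded_accessibility", 0.0)),
                label=str(s.get("label", ""))))
        return ChromatinStateModel(states=tuple(states))

    def build_methylation(self,
                          condition: str) -> EndogenousMethylationProfile:
        meth = self.conditions[condition].get("methylation") or {}
        sites = tuple((int(p), float(v))
                      for p, v in (meth.get("sites") or {}).items())
        return EndogenousMethylationProfile(
            probs=sites, default=float(meth.get("default", 0.0)))

    def build_noise(self, condition_index: int) -> NoiseModel:
        return NoiseModel(
            enzyme_efficiency=float(
                self.noise.get("enzyme_efficiency", 1.0)),
            bisulfite_conversion_rate=float(
                self.noise.get("bisulfite_conversion_rate", 1.0)),
            inappropriate_conversion_rate=float(
                self.noise.get("inappropriate_conversion_rate", 0.0)),
            seq_error_rate=float(self.noise.get("seq_error_rate", 0.0)),
            seed=(self.seed + 1000 * (condition_index + 1)) % (2 ** 31))


def run_simulation(config: SimulationConfig
                   ) -> tuple[AmpliconReference,
                              dict[str, SimulatedClones]]:
    """Build the reference and simulate clone sets for every condition."""
    reference = config.build_reference()
    results: dict[str, SimulatedClones] = {}
    for index, condition in enumerate(sorted(config.conditions)):
        results[condition] = simulate_clones(
            reference,
            config.build_model(condition),
            meth=config.build_methylation(condition),
            noise=config.build_noise(index),
            n_clones=config.n_clones,
            clone_prefix=f"{condition}_clone")
    return reference, results
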