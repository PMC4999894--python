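"""Configuration objects and default propensity tables for the built-in predictors.

The per-residue scorers shipped here are simplified, fully documented stand-ins
for the heavyweight disorder / secondary-structure / binding-site predictors a
production study would run.  They share the pipeline contract that matters —
full-protein prediction, segment excision, inclusive thresholds — while keeping
every number in the package reproducible from these tables alone.  Genuine
predictor output can be imported per residue and overlaid at any point
(:func:`readthrough.predictors.import_scores`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict

import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: TOP-IDP-style disorder propensities (higher = more disorder-promoting).
DISORDER_PROPENSITY: Dict[str, float] = {
    "A": 0.060, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.020,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

#: Chou-Fasman helix conformational preferences.
HELIX_PROPENSITY: Dict[str, float] = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.14, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}

#: Chou-Fasman strand conformational preferences.
STRAND_PROPENSITY: Dict[str, float] = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

#: Kyte-Doolittle hydropathy rescaled to [-1, 1]; proxy for the energy a
#: residue can gain by folding onto a globular partner.
INTERACTION_PROPENSITY: Dict[str, float] = {
    "I": 1.000, "V": 0.933, "L": 0.844, "F": 0.622, "C": 0.556,
    "M": 0.422, "A": 0.400, "G": -0.089, "T": -0.156, "S": -0.178,
    "W": -0.200, "Y": -0.289, "P": -0.356, "H": -0.711, "E": -0.778,
    "Q": -0.778, "D": -0.778, "N": -0.778, "K": -0.867, "R": -1.000,
}


@dataclass
class PredictorConfig:
    """Parameters of the built-in per-residue scorers.

    Windows are centred on the scored residue and truncated (never padded) at
    the termini; thresholds are inclusive throughout.
    """

    disorder_propensity: Dict[str, float] = field(
        default_factory=lambda: dict(DISORDER_PROPENSITY))
    disorder_window: int = 21
    disorder_logistic_gain: float = 10.0
    disorder_logistic_center: float = 0.05

    seg_window: int = 12
    seg_trigger: float = 2.2   # K2_1, bits
    seg_extend: float = 2.5    # K2_2, bits

    ss_helix_propensity: Dict[str, float] = field(
        default_factory=lambda: dict(HELIX_PROPENSITY))
    ss_strand_propensity: Dict[str, float] = field(
        default_factory=lambda: dict(STRAND_PROPENSITY))
    ss_window: int = 6
    ss_threshold: float = 1.0

    binding_interaction_propensity: Dict[str, float] = field(
        default_factory=lambda: dict(INTERACTION_PROPENSITY))
    binding_window: int = 11
    binding_logistic_gain: float = 4.0
    binding_logistic_center: float = 0.0

    theta_disorder: float = 0.5
    theta_elm_disorder: float = 0.4
    theta_binding: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_disorder < 1.0:
            raise ValueError("theta_disorder must lie in (0, 1)")
        if not 0.0 < self.theta_elm_disorder < 1.0:
            raise ValueError("theta_elm_disorder must lie in (0, 1)")
        if not 0.0 < self.theta_binding < 1.0:
            raise ValueError("theta_binding must lie in (0, 1)")
        if self.seg_trigger > self.seg_extend:
            raise ValueError("seg_trigger (K2_1) must be <= seg_extend (K2_2)")
        for name in ("disorder_window", "seg_window", "ss_window",
                     "binding_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PredictorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)
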