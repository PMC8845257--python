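"""Variable reduction, log transform, isometric size, and size correction.

The packaged default :class:`ReductionSchema` collapses 70 raw linear
measurements to 36 analysis variables: serial leg segments are summed
into proximal (trochanter + femur) and distal (patella + tibia +
metatarsus) parts, the five metasoma segment lengths are summed while
their heights and widths are averaged, paired left/right pedipalp
measurements are averaged, and everything else passes through.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ecomorph.io_formats import TraitTable

__all__ = [
    "ReductionSchema",
    "default_reduction_schema",
    "reduce_variables",
    "log_transform",
    "iso_size",
    "size_correct",
]

_COMBINATORS = ("sum", "mean", "identity")

LEG_SEGMENTS_PROXIMAL = ("trochanter", "femur")
LEG_SEGMENTS_DISTAL = ("patella", "tibia", "metatarsus")
METASOMA_SEGMENTS = tuple(f"metasoma_{i}" for i in range(1, 6))
PEDIPALP_PARTS = (
    "pedipalp_femur_length",
    "pedipalp_femur_width",
    "pedipalp_femur_height",
    "pedipalp_patella_length",
    "pedipalp_patella_width",
    "pedipalp_patella_height",
    "pedipalp_chela_length",
    "pedipalp_chela_width",
    "pedipalp_chela_height",
    "pedipalp_movable_finger_length",
)
BODY_SINGLE = (
    "carapace_length",
    "carapace_anterior_width",
    "carapace_posterior_width",
    "carapace_height",
    "median_eyes_distance",
    "mesosoma_length",
    "mesosoma_width",
    "sternum_length",
    "sternum_width",
    "genital_operculum_length",
    "pectine_length",
    "pectine_width",
    "telson_vesicle_length",
    "telson_vesicle_width",
    "telson_vesicle_height",
)


@dataclass
class ReductionSchema:
    """Mapping from each output variable to its inputs and combinator.

    ``outputs`` maps output name -> ``{"inputs": [...], "op": "sum" |
    "mean" | "identity"}``.  Raw variables not referenced by any output
    pass through unchanged (identity), preserving their input order.
    """

    outputs: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, spec in self.outputs.items():
            op = spec.get("op")
            if op not in _COMBINATORS:
                raise ValueError(f"output {name!r}: unknown combinator {op!r}")
            inputs = spec.get("inputs", [])
            if not inputs:
                raise ValueError(f"output {name!r}: empty input list")
            if len(set(inputs)) != len(inputs):
                raise ValueError(f"output {name!r}: input variable used twice")
            if op == "identity" and len(inputs) != 1:
                raise ValueError(f"output {name!r}: identity takes one input")

    @property
    def consumed(self) -> set[str]:
        return {v for spec in self.outputs.values() for v in spec["inputs"]}

    @classmethod
    def from_json(cls, path) -> "ReductionSchema":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.outputs, fh, indent=1, sort_keys=True)


def raw_variable_names() -> list[str]:
    """The 70 raw measurement names the default schema expects."""
    names: list[str] = list(BODY_SINGLE)
    names += [f"metasoma_{i}_length" for i in range(1, 6)]
    names += [f"metasoma_{i}_height" for i in range(1, 6)]
    names += [f"metasoma_{i}_width" for i in range(1, 6)]
    for leg in range(1, 5):
        for seg in LEG_SEGMENTS_PROXIMAL + LEG_SEGMENTS_DISTAL:
            names.append(f"leg_{leg}_{seg}_length")
    for side in ("left", "right"):
        names += [f"{side}_{part}" for part in PEDIPALP_PARTS]
    return names


def default_reduction_schema() -> ReductionSchema:
    """Packaged 70 -> 36 reduction."""
    outputs: dict[str, dict] = {}
    for leg in range(1, 5):
        outputs[f"leg_{leg}_proximal_length"] = {
            "inputs": [f"leg_{leg}_{s}_length" for s in LEG_SEGMENTS_PROXIMAL],
            "op": "sum",
        }
        outputs[f"leg_{leg}_distal_length"] = {
            "inputs": [f"leg_{leg}_{s}_length" for s in LEG_SEGMENTS_DISTAL],
            "op": "sum",
        }
    outputs["metasoma_length"] = {
        "inputs": [f"metasoma_{i}_length" for i in range(1, 6)],
        "op": "sum",
    }
    outputs["metasoma_height"] = {
        "inputs": [f"metasoma_{i}_height" for i in range(1, 6)],
        "op": "mean",
    }
    outputs["metasoma_width"] = {
        "inputs": [f"metasoma_{i}_width" for i in range(1, 6)],
        "op": "mean",
    }
    for part in PEDIPALP_PARTS:
        outputs[part] = {
            "inputs": [f"left_{part}", f"right_{part}"],
            "op": "mean",
        }
    return ReductionSchema(outputs)


def reduce_variables(raw: TraitTable, schema: ReductionSchema) -> TraitTable:
    """Combine raw measurements into analysis variables (stage=reduced)."""
    if raw.stage != "raw":
        raise ValueError(f"expected stage=raw, got {raw.stage}")
    missing = schema.consumed - set(raw.variable_names)
    if missing:
        raise ValueError(f"schema references missing variables: {sorted(missing)}")
    col = {v: i for i, v in enumerate(raw.variable_names)}
    names: list[str] = []
    cols: list[np.ndarray] = []
    for name, spec in schema.outputs.items():
        block = raw.values[:, [col[v] for v in spec["inputs"]]]
        if spec["op"] == "sum":
            cols.append(block.sum(axis=1))
        elif spec["op"] == "mean":
            cols.append(block.mean(axis=1))
        else:
            cols.append(block[:, 0])
        names.append(name)
    consumed = schema.consumed
    for v in raw.variable_names:
        if v not in consumed:
            names.append(v)
            cols.append(raw.values[:, col[v]])
    return TraitTable(list(raw.species_ids), np.column_stack(cols), names, "reduced")


def log_transform(t: TraitTable) -> TraitTable:
    """Elementwise natural log (stage reduced -> log)."""
    if t.stage not in ("raw", "reduced"):
        raise ValueError(f"expected a linear-scale table, got stage={t.stage}")
    if np.any(t.values <= 0):
        raise ValueError("log transform requires strictly positive values")
    return TraitTable(
        list(t.species_ids), np.log(t.values), list(t.variable_names), "log"
    )


def iso_size(t: TraitTable) -> np.ndarray:
    """Project each species' log-trait row onto the unit isometric vector.

    With p variables the isometric vector is ``(1/sqrt(p), ..., 1/sqrt(p))``,
    so IsoSize is the row sum divided by sqrt(p).
    """
    if t.stage != "log":
        raise ValueError(f"expected stage=log, got {t.stage}")
    p = t.n_variables
    if p == 0:
        raise ValueError("trait table has no variables")
    return t.values.sum(axis=1) / np.sqrt(p)


def size_correct(t: TraitTable, s: np.ndarray) -> TraitTable:
    """Residuals of each log trait regressed on IsoSize (OLS with intercept).

    Output columns have zero mean and zero sample correlation with ``s``.
    Accepts an already-corrected table too, on which it is a no-op up to
    numerical tolerance (residuals are orthogonal to IsoSize).
    """
    if t.stage not in ("log", "size_corrected"):
        raise ValueError(f"expected stage=log, got {t.stage}")
    s = np.asarray(s, dtype=float)
    if s.shape != (t.n_species,):
        raise ValueError("IsoSize length does not match trait table")
    if np.ptp(s) == 0:
        raise ValueError("IsoSize is constant; regression undefined")
    X = np.column_stack([np.ones_like(s), s])
    beta, *_ = np.linalg.lstsq(X, t.values, rcond=None)
    resid = t.values - X @ beta
    return TraitTable(
        list(t.species_ids), resid, list(t.variable_names), "size_corrected"
    )
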