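"""Assembly of per-variant feature vectors from structure, property tables and PSSMs.

Three published feature sets are supported:

* ``BIOPHYS14`` — 14 structure/physicochemistry descriptors,
* ``EVO2`` — the two PSSM substitution-score deltas (NR, UniRef50),
* ``COMBINED12`` — 11 of the biophysical descriptors (neighbor vector and the
  two steric parameters dropped as redundant) plus the NR PSSM delta.

Feature order within a set is fixed and serialized with every vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .aatables import PropertyTable
from .datasets import VariantSpec
from .pssm import PssmMatrix, delta_pssm
from .structure import (
    MembraneModel,
    StructureModel,
    functional_density,
    membrane_burial,
    neighbor_vector,
    pore_axis_distance,
)


class FeatureError(ValueError):
    """Unknown feature set, inconsistent variant, or malformed vector."""


BIOPHYS14 = (
    "hydrophobicity_mut",
    "polarizability_mut",
    "fd_polarizability_6.5A",
    "fd_polarizability_12A",
    "fd_hydrophobicity_1A",
    "fd_hydrophobicity_6.5A",
    "delta_h_donors",
    "delta_h_acceptors",
    "delta_vdw_volume",
    "pore_axis_distance",
    "membrane_burial",
    "neighbor_vector",
    "steric_mut",
    "steric_native",
)

EVO2 = ("delta_pssm_nr", "delta_pssm_uniref50")

COMBINED12 = tuple(
    f for f in BIOPHYS14 if f not in ("neighbor_vector", "steric_mut", "steric_native")
) + ("delta_pssm_nr",)

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "BIOPHYS14": BIOPHYS14,
    "EVO2": EVO2,
    "COMBINED12": COMBINED12,
}

#: Features that are differences (mutant minus wild type); they vanish for
#: non-perturbing variants by construction.
DELTA_FEATURES = frozenset(
    {"delta_h_donors", "delta_h_acceptors", "delta_vdw_volume",
     "delta_pssm_nr", "delta_pssm_uniref50"}
)


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered real-valued features for one variant."""

    variant: VariantSpec
    feature_set: str
    values: tuple[float, ...]

    def __post_init__(self):
        if self.feature_set not in FEATURE_SETS:
            raise FeatureError(f"unknown feature set {self.feature_set!r}")
        if len(self.values) != len(FEATURE_SETS[self.feature_set]):
            raise FeatureError(
                f"{self.feature_set} expects {len(FEATURE_SETS[self.feature_set])} "
                f"features, got {len(self.values)}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_SETS[self.feature_set]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[self.names.index(name)]


def build_feature_vector(
    variant: VariantSpec,
    structure: StructureModel | None,
    table: PropertyTable,
    pssms: dict[str, PssmMatrix] | None = None,
    feature_set: str = "COMBINED12",
    membrane: MembraneModel | None = None,
) -> FeatureVector:
    """Compute one variant's features in the canonical order of ``feature_set``."""
    names = FEATURE_SETS.get(feature_set)
    if names is None:
        raise FeatureError(f"unknown feature set {feature_set!r}")
    pssms = pssms or {}
    needs_structure = any(not n.startswith("delta_pssm") for n in names)
    if needs_structure:
        if structure is None:
            raise FeatureError(f"{feature_set} requires a structure")
        native = structure.wt_aa(variant.position)
        if native != variant.wt_aa:
            raise FeatureError(
                f"wild-type mismatch at {variant.position}: structure has "
                f"{native}, variant claims {variant.wt_aa}"
            )

    def compute(name: str) -> float:
        if name == "hydrophobicity_mut":
            return table.get(variant.mut_aa, "hydrophobicity")
        if name == "polarizability_mut":
            return table.get(variant.mut_aa, "polarizability")
        if name == "steric_mut":
            return table.get(variant.mut_aa, "steric_parameter")
        if name == "steric_native":
            return table.get(variant.wt_aa, "steric_parameter")
        if name.startswith("delta_h_donors"):
            return table.delta(variant.wt_aa, variant.mut_aa, "n_h_donors")
        if name == "delta_h_acceptors":
            return table.delta(variant.wt_aa, variant.mut_aa, "n_h_acceptors")
        if name == "delta_vdw_volume":
            return table.delta(variant.wt_aa, variant.mut_aa, "vdw_volume")
        if name.startswith("fd_"):
            prop, radius = _parse_fd_name(name)
            return functional_density(
                structure, variant.position, table, prop, radius, variant.mut_aa
            )
        if name == "pore_axis_distance":
            return pore_axis_distance(structure, variant.position)
        if name == "membrane_burial":
            return membrane_burial(structure, variant.position, membrane)
        if name == "neighbor_vector":
            return neighbor_vector(structure, variant.position)
        if name.startswith("delta_pssm"):
            tag = name.split("_")[-1]
            matrix = _find_pssm(pssms, tag)
            return float(delta_pssm(matrix, variant))
        raise FeatureError(f"unknown feature {name!r}")

    return FeatureVector(variant, feature_set, tuple(float(compute(n)) for n in names))


def _parse_fd_name(name: str) -> tuple[str, float]:
    # e.g. "fd_polarizability_6.5A" -> ("polarizability", 6.5)
    _, prop, radius = name.split("_")
    return prop, float(radius.rstrip("A"))


def _find_pssm(pssms: dict[str, PssmMatrix], tag: str) -> PssmMatrix:
    for key, m in pssms.items():
        if key.lower() == tag.lower():
            return m
    raise FeatureError(f"no PSSM supplied for database tag {tag!r}")


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack vectors into a DataFrame (variant id columns + canonical feature order)."""
    if not vectors:
        return pd.DataFrame()
    names = vectors[0].names
    if any(v.feature_set != vectors[0].feature_set for v in vectors):
        raise FeatureError("mixed feature sets in one table")
    rows = [
        {"variant": v.variant.name, "position": v.variant.position,
         **dict(zip(names, v.values))}
        for v in vectors
    ]
    return pd.DataFrame(rows, columns=["variant", "position", *names])


class FeatureScaler:
    """Per-feature z-scoring fitted on training data only; constant features map to 0."""

    def __init__(self):
        self._scaler = StandardScaler()
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise FeatureError("scaler needs >= 2 training vectors")
        self._scaler.fit(X)
        self.n_features_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._scaler.transform(np.atleast_2d(np.asarray(X, dtype=float)))

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return self._scaler.inverse_transform(np.atleast_2d(np.asarray(X, dtype=float)))

    def to_dict(self) -> dict:
        return {
            "mean": self._scaler.mean_.tolist(),
            "scale": self._scaler.scale_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        obj = cls()
        mean = np.asarray(d["mean"], dtype=float)
        scale = np.asarray(d["scale"], dtype=float)
        obj._scaler.mean_ = mean
        obj._scaler.scale_ = scale
        obj._scaler.var_ = scale**2
        obj._scaler.n_features_in_ = len(mean)
        obj.n_features_ = len(mean)
        return obj
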