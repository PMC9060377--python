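"""Per-amino-acid scalar property tables and substitution deltas.

The shipped table (``data/aa_properties.tsv``) carries six side-chain
descriptors per canonical residue: a hydrophobicity scale (positive = more
hydrophobic), a normalized polarizability parameter, a graph shape (steric)
index, hydrogen-bond donor and acceptor site counts, and a normalized van der
Waals volume.  Sources and normalization notes live in the table header; users
can point any consumer at their own TSV with the same columns.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

CANONICAL_AAS = "ACDEFGHIKLMNPQRSTVWY"

PROPERTY_NAMES = (
    "hydrophobicity",
    "polarizability",
    "steric_parameter",
    "n_h_donors",
    "n_h_acceptors",
    "vdw_volume",
)


class PropertyLookupError(KeyError):
    """Unknown residue code or property name."""


class PropertyTable:
    """Residue-by-property table with delta (mutant minus wild-type) lookups."""

    def __init__(self, frame: pd.DataFrame):
        missing = set(CANONICAL_AAS) - set(frame.index)
        if missing:
            raise ValueError(f"property table missing residues: {sorted(missing)}")
        missing_cols = set(PROPERTY_NAMES) - set(frame.columns)
        if missing_cols:
            raise ValueError(f"property table missing columns: {sorted(missing_cols)}")
        if (frame["vdw_volume"].drop("G") <= 0).any():
            raise ValueError("vdw_volume must be positive for non-glycine residues")
        for col in ("n_h_donors", "n_h_acceptors"):
            if (frame[col] < 0).any():
                raise ValueError(f"{col} must be non-negative")
        self._frame = frame.loc[list(CANONICAL_AAS), list(PROPERTY_NAMES)].astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def get(self, aa: str, property_name: str) -> float:
        if property_name not in PROPERTY_NAMES:
            raise PropertyLookupError(f"unknown property {property_name!r}")
        if aa not in CANONICAL_AAS:
            raise PropertyLookupError(f"unknown residue code {aa!r}")
        return float(self._frame.at[aa, property_name])

    def delta(self, wt_aa: str, mut_aa: str, property_name: str) -> float:
        """Signed property change of the substitution, mutant minus wild type."""
        return self.get(mut_aa, property_name) - self.get(wt_aa, property_name)


def load_property_table(path: str | Path | None = None) -> PropertyTable:
    """Load the shipped property TSV, or a user-supplied one with the same layout."""
    if path is None:
        resource = importlib.resources.files("kvarpred.data") / "aa_properties.tsv"
        with importlib.resources.as_file(resource) as p:
            frame = pd.read_csv(p, sep="\t", comment="#", index_col="aa")
    else:
        frame = pd.read_csv(path, sep="\t", comment="#", index_col="aa")
    return PropertyTable(frame)
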