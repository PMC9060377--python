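"""Synthetic structures, PSSMs and variant datasets with known ground truth.

The generator emulates the study's inputs at desk scale: an idealized
multi-helix bundle arranged symmetrically around a pore (z) axis and spanning
a slab membrane; a PSSM whose wild-type scores rise with a tunable
conservation level; and a variant table whose four binary labels follow a
planted monotone rule on chosen features (sign of a linear score in
standardized feature units plus Gaussian logit noise).  Everything is a pure
function of (spec, seed) and a manifest records the planted truth, so
parameter-recovery tests are falsifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .aatables import CANONICAL_AAS, PropertyTable, load_property_table
from .datasets import PARAMETERS, VariantSpec
from .features import FEATURE_SETS, build_feature_vector
from .pssm import PssmMatrix, write_pssm
from .structure import StructureModel

HELIX_RISE = 1.5          # Angstrom per residue along the helix axis
HELIX_TWIST_DEG = 100.0   # degrees per residue
HELIX_RADIUS = 2.3        # Angstrom, Calpha distance from the helix axis


class SyntheticSpecError(ValueError):
    """Non-physical geometry or inconsistent planted-rule specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-scale defaults: a 15-helix bundle of 345 resolved residues
    crossing a 30 A membrane core, 125 'experimental' missense variants with
    planted labels plus one non-perturbing variant per resolved residue."""

    n_helices: int = 15
    residues_per_helix: int = 23      # 15 * 23 = 345, the resolved-model size
    bundle_radius: float = 15.0       # Angstrom, helix axis distance from pore axis
    membrane_span: float = 40.0       # Angstrom, slab thickness the bundle crosses
    n_experimental: int = 125
    conservation: float = 0.6
    # planted rule: per output, {feature name: coefficient}; labels are
    # 1{sum_f beta_f * z(f) + sigma * eps > 0} on standardized features
    planted_betas: dict = None
    noise_sigma: float = 0.5
    feature_set: str = "COMBINED12"
    seed: int = 0

    def __post_init__(self):
        if self.n_helices < 1 or self.residues_per_helix < 1:
            raise SyntheticSpecError("need at least one helix and one residue")
        if self.bundle_radius <= 0 or self.membrane_span <= 0:
            raise SyntheticSpecError("radius and membrane span must be positive")
        if not 0.0 <= self.conservation <= 1.0:
            raise SyntheticSpecError("conservation must lie in [0, 1]")
        if self.planted_betas is None:
            object.__setattr__(self, "planted_betas", default_planted_betas())
        features = FEATURE_SETS[self.feature_set]
        for out, betas in self.planted_betas.items():
            if out not in PARAMETERS:
                raise SyntheticSpecError(f"unknown output {out!r}")
            if not betas:
                raise SyntheticSpecError(f"empty planted feature set for {out}")
            for f in betas:
                if f not in features:
                    raise SyntheticSpecError(
                        f"planted feature {f!r} not in feature set {self.feature_set}"
                    )


def default_planted_betas() -> dict:
    """Planted effects, one dominant (|beta| = 4) and one secondary (|beta| = 2)
    delta-type feature per output.  Delta features vanish for non-perturbing
    variants, keeping the planted rule consistent with their all-normal labels."""
    return {
        "iks": {"delta_pssm_nr": -4.0},
        "vhalf": {"delta_vdw_volume": 4.0, "delta_pssm_nr": -2.0},
        "tau_act": {"delta_h_donors": -4.0, "delta_pssm_nr": -2.0},
        "tau_deact": {"delta_h_acceptors": 4.0, "delta_pssm_nr": -2.0},
    }


def make_structure(spec: SyntheticSpec) -> StructureModel:
    """Idealized alpha-helix bundle around the z axis spanning the membrane.

    Helix h runs vertically at ``bundle_radius`` from the pore axis, rotated
    2*pi*h/n_helices around it; residues advance 1.5 A in z and 100 degrees of
    twist on a 2.3 A helix radius.  Positions are numbered 1..n consecutively
    across helices.  Residue identities are sampled uniformly, seeded.
    """
    rng = np.random.default_rng([spec.seed, 101])
    positions, aas, points = [], [], []
    pos = 0
    # center each helix on the membrane mid-plane; ends may poke into solution
    z0 = -HELIX_RISE * (spec.residues_per_helix - 1) / 2
    for h in range(spec.n_helices):
        phi = 2 * np.pi * h / spec.n_helices
        cx, cy = spec.bundle_radius * np.cos(phi), spec.bundle_radius * np.sin(phi)
        for i in range(spec.residues_per_helix):
            pos += 1
            theta = np.deg2rad(HELIX_TWIST_DEG) * i + phi
            positions.append(pos)
            aas.append(rng.choice(list(CANONICAL_AAS)))
            points.append(
                [
                    cx + HELIX_RADIUS * np.cos(theta),
                    cy + HELIX_RADIUS * np.sin(theta),
                    z0 + HELIX_RISE * i,
                ]
            )
    return StructureModel(
        np.array(positions),
        np.array(aas, dtype=object),
        np.array(points),
        axis_point=np.zeros(3),
        axis_dir=np.array([0.0, 0.0, 1.0]),
    )


def write_structure_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write representative points as CA-only ATOM records (chain A)."""
    one_to_three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    }
    with open(path, "w") as fh:
        for i, (pos, aa, pt) in enumerate(
            zip(structure.positions, structure.wt_aas, structure.points), start=1
        ):
            fh.write(
                f"ATOM  {i:5d}  CA  {one_to_three[str(aa)]} A{int(pos):4d}    "
                f"{pt[0]:8.3f}{pt[1]:8.3f}{pt[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def make_pssm(
    sequence: str, conservation: float, seed: int, source: str = "NR"
) -> PssmMatrix:
    """Synthetic log-odds matrix with position-specific conservation.

    Real profiles mix strongly conserved and variable positions, so each
    position draws its own conservation level c_i from a Beta distribution
    with mean ``conservation`` (concentration 4); the wild-type letter scores
    around ``2 + 9*c_i`` and every other residue around ``-1 - 4*c_i``, with
    seeded integer-rounded Gaussian noise (sd 1.5).  At conservation 1.0 the
    WT score is strictly maximal at every position.
    """
    if not sequence:
        raise SyntheticSpecError("empty sequence")
    if not 0.0 <= conservation <= 1.0:
        raise SyntheticSpecError("conservation must lie in [0, 1]")
    rng = np.random.default_rng([seed, 202])
    L = len(sequence)
    from .pssm import PSSM_ALPHABET

    kappa = 4.0
    if conservation in (0.0, 1.0):
        c = np.full(L, conservation)
    else:
        c = rng.beta(conservation * kappa, (1.0 - conservation) * kappa, size=L)
    scores = np.rint(-1.0 - 4.0 * c[:, None] + 1.5 * rng.standard_normal((L, 20)))
    wt_scores = np.rint(2.0 + 9.0 * c + 1.5 * rng.standard_normal(L))
    for i, aa in enumerate(sequence):
        col = PSSM_ALPHABET.index(aa)
        if conservation >= 1.0:
            scores[i, col] = max(wt_scores[i], scores[i].max() + 1)
        else:
            scores[i, col] = wt_scores[i]
    return PssmMatrix(sequence, scores.astype(int), source=source)


def make_variant_dataset(
    structure: StructureModel,
    pssms: dict[str, PssmMatrix],
    spec: SyntheticSpec,
    table: PropertyTable | None = None,
):
    """Sample missense variants, compute real features, plant labels.

    Returns ``(variants, X, Y, experimental, manifest)``: the sampled missense
    variants followed by one non-perturbing variant per resolved residue, the
    raw feature matrix, the (n, 4) binary label matrix, the experimental mask,
    and a manifest recording betas, sigma and seed.

    Labels for the sampled missense variants follow the planted rule
    ``1{sum_f beta_f * z(f) + sigma * eps > 0}`` with ``z`` standardized over
    the missense variants; non-perturbing variants are labeled all-normal,
    mirroring the augmentation convention of the real dataset.
    """
    table = table or load_property_table()
    rng = np.random.default_rng([spec.seed, 303])
    resolved = structure.resolved_positions()
    # sample unique (position, mutant) pairs uniformly
    variants: list[VariantSpec] = []
    seen = set()
    while len(variants) < spec.n_experimental:
        pos, wt = resolved[rng.integers(len(resolved))]
        mut = CANONICAL_AAS[rng.integers(20)]
        if mut == wt or (pos, mut) in seen:
            continue
        seen.add((pos, mut))
        variants.append(VariantSpec(pos, wt, mut))
    nonpert = [VariantSpec(p, a, a) for p, a in resolved]
    all_variants = variants + nonpert

    names = FEATURE_SETS[spec.feature_set]
    X = np.array(
        [
            build_feature_vector(v, structure, table, pssms, spec.feature_set).values
            for v in all_variants
        ]
    )
    n_exp = len(variants)
    Xexp = X[:n_exp]
    mu = Xexp.mean(axis=0)
    sd = Xexp.std(axis=0)
    sd[sd == 0] = 1.0

    Y = np.zeros((len(all_variants), 4), dtype=int)
    for j, out in enumerate(PARAMETERS):
        betas = spec.planted_betas.get(out, {})
        logit = np.zeros(n_exp)
        for f, b in betas.items():
            col = names.index(f)
            logit += b * (Xexp[:, col] - mu[col]) / sd[col]
        logit += spec.noise_sigma * rng.standard_normal(n_exp)
        Y[:n_exp, j] = (logit > 0).astype(int)

    experimental = np.zeros(len(all_variants), dtype=bool)
    experimental[:n_exp] = True
    manifest = {
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "planted_betas": spec.planted_betas,
        "feature_set": spec.feature_set,
        "n_experimental": n_exp,
        "n_nonperturbing": len(nonpert),
        "standardization": {"mean": mu.tolist(), "sd": sd.tolist()},
    }
    return all_variants, X, Y, experimental, manifest


def simulate_directory(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write structure.pdb, pssm_nr.txt, pssm_uniref50.txt, variants.csv and
    manifest.json for a fully reproducible fixture; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure = make_structure(spec)
    write_structure_pdb(structure, out_dir / "structure.pdb")
    seq = "".join(str(a) for a in structure.wt_aas)
    pssms = {
        "NR": make_pssm(seq, spec.conservation, spec.seed, source="NR"),
        "UniRef50": make_pssm(seq, spec.conservation, spec.seed + 1, source="UniRef50"),
    }
    write_pssm(pssms["NR"], out_dir / "pssm_nr.txt")
    write_pssm(pssms["UniRef50"], out_dir / "pssm_uniref50.txt")
    variants, X, Y, experimental, manifest = make_variant_dataset(structure, pssms, spec)
    import pandas as pd

    rows = []
    for v, y, is_exp in zip(variants, Y, experimental):
        # encode planted labels as %WT values that reproduce them under the
        # default criteria (normal -> 100, dysfunctional -> 0/200 by direction)
        rows.append(
            {
                "variant": v.name,
                "iks_pct": 100.0 if y[0] == 0 else 30.0,
                "vhalf_pct": 100.0 if y[1] == 0 else 200.0,
                "tau_act_pct": 100.0 if y[2] == 0 else 300.0,
                "tau_deact_pct": 100.0 if y[3] == 0 else 30.0,
                "experimental": int(is_exp),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "variants.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
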