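import numpy as np
import pytest

import kvarpred as kv
from kvarpred.synthetic import SyntheticSpec, make_structure, make_pssm


@pytest.fixture(scope="session")
def table():
    return kv.load_property_table()


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale bundle: 4 helices x 12 residues, 30 missense variants."""
    return SyntheticSpec(n_helices=4, residues_per_helix=12, n_experimental=30, seed=11)


@pytest.fixture(scope="session")
def small_structure(small_spec):
    return make_structure(small_spec)


@pytest.fixture(scope="session")
def small_pssms(small_structure, small_spec):
    seq = "".join(map(str, small_structure.wt_aas))
    return {
        "NR": make_pssm(seq, 0.6, small_spec.seed, source="NR"),
        "UniRef50": make_pssm(seq, 0.6, small_spec.seed + 1, source="UniRef50"),
    }


@pytest.fixture(scope="session")
def study_bundle():
    """The study-scale synthetic dataset: 345 resolved residues, 125 missense
    variants with planted labels + 345 non-perturbing, features included."""
    spec = SyntheticSpec(seed=1)
    structure = make_structure(spec)
    seq = "".join(map(str, structure.wt_aas))
    pssms = {
        "NR": make_pssm(seq, spec.conservation, spec.seed, source="NR"),
        "UniRef50": make_pssm(seq, spec.conservation, spec.seed + 1, source="UniRef50"),
    }
    variants, X, Y, experimental, manifest = kv.make_variant_dataset(
        structure, pssms, spec
    )
    return {
        "spec": spec,
        "structure": structure,
        "pssms": pssms,
        "variants": variants,
        "X": X,
        "Y": Y,
        "experimental": experimental,
        "manifest": manifest,
    }
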