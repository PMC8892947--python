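import numpy as np
import pytest

from rnpkit.seq_struct_io import Ensemble, classify_residue
from rnpkit.library_design import (
    DegenerateCodon,
    LibraryScheme,
    PositionPool,
    design_codon,
)


def make_ensemble(atoms, frames):
    """Build an Ensemble from (chain, res_id, res_name, atom_name, element)
    tuples and a list of per-frame coordinate arrays."""
    chains = np.array([a[0] for a in atoms], dtype="U4")
    res_ids = np.array([a[1] for a in atoms], dtype=int)
    res_names = np.array([a[2] for a in atoms], dtype="U5")
    names = np.array([a[3] for a in atoms], dtype="U6")
    elements = np.array([a[4] for a in atoms], dtype="U2")
    polymer = np.array([classify_residue(r) for r in res_names], dtype="U7")
    return Ensemble(
        atom_names=names,
        elements=elements,
        res_names=res_names,
        res_ids=res_ids,
        chain_ids=chains,
        polymer_class=polymer,
        coords=np.asarray(frames, dtype=float),
    )


def make_scheme(pool_sets, name="test-scheme"):
    """LibraryScheme from a list of allowed-residue sets (exact-cover codons)."""
    pools, codons = [], []
    for i, allowed in enumerate(pool_sets):
        allowed = frozenset(allowed)
        wt = sorted(allowed)[0]
        pools.append(PositionPool(i + 1, wt, allowed, len(allowed) == 1))
        codons.append(design_codon(allowed))
    alphabet = frozenset().union(*[set(p) for p in pool_sets])
    return LibraryScheme(name, pools, codons, alphabet)


@pytest.fixture
def motif_scheme():
    """10-position scheme whose peptides can carry an 'EVEV' motif at
    positions 3-6; diversity 8748 so a top-100 list is selective."""
    return make_scheme(
        [
            {"S"},
            {"D", "A"},
            {"E", "G"},
            {"V", "I", "L"},
            {"E", "G"},
            {"V", "D", "G"},
            {"A", "P", "T"},
            {"I", "L", "V"},
            {"A", "P", "T"},
            {"I", "L", "V"},
        ]
    )
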