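# rnpkit

Tools for asking how a protein stripped of cationic and aromatic residues can
still bind RNA — and for analyzing every computational stage of the experiment
that answers it. `rnpkit` covers the full loop around an in-vitro-evolution
campaign on an RNA-binding domain (the C-terminal domain of ribosomal protein
uL11 bound to a 58-nt rRNA fragment is the motivating system):

1. **Library design** (`rnpkit.library_design`) — build per-position
   substitution pools restricted to a reduced amino-acid alphabet (e.g. the ten
   prebiotically plausible residues G, A, D, E, V, S, I, L, P, T) and encode
   each pool as an optimal degenerate codon by exhaustive search over all
   15³ = 3,375 IUPAC codons, minimizing (off-target residues, stop codons,
   degeneracy) lexicographically. Exact protein/DNA diversity accounting.
2. **Selection analysis** (`rnpkit.selection_analysis`) — per-round peptide
   counting from flanked reads, rank-abundance tables, position frequency
   matrices and sequence logos (letter height = frequency × information
   content, IC = log₂20 − H in bits), enrichment trajectories and consensus
   motifs.
3. **Binding kinetics** (`rnpkit.binding_kinetics`) — simulate and globally
   fit two-phase surface-binding sensorgrams with the 1:1 Langmuir model:
   R(t) = R_eq·(1 − e^−(k_on·C + k_off)·t) during association with
   R_eq = R_max·C/(C + K_D), then exponential decay e^−k_off·(t−t_switch);
   K_D = k_off/k_on.
4. **Interface analysis** (`rnpkit.interface_analysis`) — over a multi-model
   PDB ensemble: direct protein–RNA H-bonds (donor–acceptor ≤ 3.0 Å,
   D–H–A ≥ 135° when hydrogens exist), water bridges, metal-ion bridges
   (Mg²⁺ ≤ 3.0 Å, K⁺ ≤ 3.5 Å to protein/RNA O/N), each with per-frame
   occupancies; VOLMAP-style voxel occupancy grids (OpenDX export); Kabsch
   superposition and backbone RMSD restricted to secondary-structure elements.
5. **Synthetic data** (`rnpkit.synthetic_data`) — ground-truth generators for
   every input: degenerate-library sampling, multi-round selection as
   frequency-proportional multinomial resampling with per-motif retention
   weights, and toy protein–RNA ensembles with H-bonds/bridges planted at
   known occupancies.

## Worked example

```python
import numpy as np
import rnpkit as rk
from rnpkit.synthetic_data import SelectionSimSpec, DEFAULT_FLANK5, DEFAULT_FLANK3
from rnpkit.binding_kinetics import round_sig

# a synthetic 69-position early-alphabet scheme, 18 randomized positions
scheme = rk.LibraryScheme.from_json("data/example_scheme_synthetic.json")
prot, dna, frac = rk.diversity(scheme)
print(f"protein variants: {prot:.2e}  randomized fraction: {frac:.2%}")

# five selection rounds with a 1.8x advantage for an 'EV' motif
spec = SelectionSimSpec(scheme, n_reads_per_round=10_000, n_rounds=5,
                        fitness={"EV": 1.8}, seed=42)
res = rk.simulate_selection(spec)
final = rk.count_peptides(res.reads[-1], DEFAULT_FLANK5, DEFAULT_FLANK3)
pep, count, f = rk.rank_abundance(final, 1)[0]
print(f"top clone after 5 rounds: {count} reads ({f:.2%})")

# simulate-and-refit a slow-kinetics variant (k_on 1.6e3, k_off 3.6e-6)
params = rk.KineticParams(k_on=1.6e3, k_off=3.6e-6, R_max=100.0)
times = np.arange(0.0, 900.0, 1.0)
curves = [rk.simulate_sensorgram(params, c, times, t_switch=300.0)
          for c in (11e-6, 5.5e-6, 2.75e-6)]
fit = rk.fit_one_to_one(curves)
print(f"fitted K_D = {round_sig(fit.K_D, 2):.1e} M")
```

prints

```
protein variants: 1.22e+10  randomized fraction: 26.09%
top clone after 5 rounds: 60 reads (0.60%)
fitted K_D = 2.2e-09 M
```

The library holds ~10¹⁰ protein variants with 26% of positions randomized; a
modest motif advantage makes the best clone visibly enriched (0.60% of reads
versus ~10⁻⁸ naive frequency); and refitting noise-free sensorgrams recovers
K_D = k_off/k_on = 2.2×10⁻⁹ M exactly.

A `rnpkit` console script exposes the same stages from the shell:
`rnpkit design-library`, `rnpkit analyze-selection`, `rnpkit
simulate-kinetics`, `rnpkit fit-kinetics`, `rnpkit analyze-interface` and
`rnpkit simulate {library,selection,ensemble}`.

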