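# connsyn

Ising dynamics on structural connectomes: synergy profiling, criticality
precursors, and robust associations with age.

## The problem

Diffusion tractography yields weighted, undirected *structural connectomes*:
matrices `J_ij` of streamline counts between brain regions. A long-standing
question is how this static geometry constrains information processing. One
productive approach runs an abstract dynamical model — here the Ising model
with Glauber dynamics — on the measured connectome and analyzes the
simulated activity with information theory.

`connsyn` implements that analysis end to end, for anyone who wants to

* simulate spin dynamics `s_i = ±1` on an arbitrary weighted network with the
  Hamiltonian `H = -½ Σ_ij J_ij s_i s_j` and Glauber flip probability
  `p(s_i → -s_i) = 1 / (1 + exp(β ΔE_i))`, `ΔE_i = 2 s_i Σ_j J_ij s_j`;
* locate the critical state at the susceptibility peak,
  `χ = N β (⟨m²⟩ − ⟨|m|⟩²)`;
* measure directed information flow with the plugin transfer entropy
  `T_{jk→i} = I(s̃_i ; s_j, s_k | s_i)` (`s̃_i` is the target one step ahead)
  and decompose it into unique, redundant and synergistic parts,

  ```
  T_{jk→i} = U_j + U_k + R + S,   T_j = U_j + R,   T_k = U_k + R,
  ```

  closing the system either with the minimum-mutual-information rule
  `R = min(T_j, T_k)` or with the Bertschinger-style constrained
  minimization `S = T(p) − min_{q ∈ Δ_p} T(q)`;
* average synergy over all triplets targeting each node (*incoming synergy*)
  and relate it to node strength, betweenness and closeness;
* run the whole pipeline per subject across a cohort and test each node's
  synergy-age association with a skipped (outlier-resistant) Spearman
  correlation under Hochberg family-wise error control.

Because the original cohort data are not redistributable, the package ships
a first-class synthetic-data module: periodic lattices for validation,
heterogeneous rich-club connectomes emulating a group-average network, and
aging cohorts with planted node-specific connectivity trends whose recovery
exercises every stage of the pipeline.

## Worked example

```bash
python examples/lattice_criticality.py
```

prints the susceptibility profile of a 16×16 periodic lattice and ends with

```
critical beta (chi peak): 0.4368
expected: ~0.44 (2D Ising critical coupling, finite-size shifted)
```

— the sweep recovers the known 2D Ising critical coupling
`β_c = ln(1+√2)/2 ≈ 0.4407` up to finite-size and grid resolution.

```bash
python examples/information_decomposition.py
```

simulates a 20-node network near criticality and decomposes the transfer
entropy into one spin from two drivers:

```
MMI decomposition of T((7, 12) -> 4):
  joint TE     = 0.01536 bits
  unique(7)    = 0.01073
  unique(12)   = 0.00000
  redundancy   = 0.00276
  synergy      = 0.00186
```

The Bertschinger route prints the same numbers to the displayed precision —
on spin data the two synergy definitions agree closely. The other examples
(`average_connectome_analysis.py`, `aging_cohort_analysis.py`) run the two
end-to-end workflows: the first reports the hub-synergy precursor (hubs'
incoming synergy peaking at β below the susceptibility peak) and the
synergy-topology correlations; the second recovers planted aging effects in
a 60-subject cohort with no false positives at Hochberg-corrected α = 0.05.

## Layout

```
src/connsyn/
  connectome.py   I/O, validation, averaging, density threshold, topology
  synth.py        lattices, rich-club connectomes, aging cohorts
  ising.py        Glauber dynamics, temperature sweeps, susceptibility
  pid.py          transfer entropy, MMI and Bertschinger decompositions
  triplets.py     triplet selection, per-node synergy/TE profiles
  age.py          skipped Spearman, Hochberg FWER, cohort association
  pipeline.py     the two orchestrated workflows, seeded and checkpointed
examples/         one narrative script per capability
docs/methods.md   model, estimators, parameter choices, limitations
```
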