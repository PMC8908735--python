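# arrestkin

Replica release-kinetics analysis of arrest-peptide (AP) extraction from
the ribosome exit tunnel.

Translational arrest peptides such as human XBP1u stall the ribosome by
wedging into the exit tunnel; an external pull on the nascent chain can
release the stall.  Simulation studies probe this with ratchet-biased
(adiabatic-bias MD) replica ensembles: the N-terminus is gently biased
toward a point in the solvent and, per replica, one records when each
residue i first leaves its tunnel site (t^i), when the C-terminal Met260
detaches from the PTC, how long full extraction takes, and how far the
N-terminus travels.  The per-residue residence increments

    ⟨Δt^i⟩ = ⟨t^i⟩ − ⟨t^(i−1)⟩

form a kinetic signature that separates strong stallers from weak ones
and can be ranked against the experimentally measured fraction of
full-length protein, f_L.

`arrestkin` implements that entire analysis as a tested pipeline for
people who build or consume such replica studies: a calibrated
synthetic-event generator for the wild type and four XBP1u variants
(S255A, W256A, C247K/S255A, C247S/P254C/S255A), a renderer that turns
event tables into 3D bead trajectories in a toy exit tunnel, a desk-scale
ratchet-biased Langevin engine, contact-persistence analysis of the
stalled state, the five extraction metrics, and variant ranking.
See `docs/methods.md` for the model and its assumptions.

## Worked example

Twenty replicas of the wild-type AP, analyzed end to end:

```python
from arrestkin.kinetics import ensemble_profile
from arrestkin.synth import default_variant_configs, sample_ensemble

config = default_variant_configs()["WT"]
tables = sample_ensemble(config, master_seed=1)     # 20 replicas
vk = ensemble_profile(tables, f_L=config.f_L)
print(f"detach  ⟨t⟩_M260 = {vk.t_M260[0]:.1f} ± {vk.t_M260[1]:.1f} ns "
      f"({vk.n_detached}/{vk.n_replicas} replicas)")
print(f"extract ⟨T⟩      = {vk.T_extraction[0]:.1f} ± "
      f"{vk.T_extraction[1]:.1f} ns ({vk.n_exited}/{vk.n_replicas} exited)")
print(f"covered  D       = {vk.D_mean[0]:.2f} nm")
```

prints

```
detach  ⟨t⟩_M260 = 12.6 ± 0.4 ns (20/20 replicas)
extract ⟨T⟩      = 48.1 ± 1.5 ns (20/20 exited)
covered  D       = 12.50 nm
```

— the wild type detaches in every replica after ~13 ns, is fully
extracted ~48 ns later, and the N-terminus covers the full 12.5 nm CV
span.  The same ensembles for the double mutant C247K/S255A give 0/20
detachments (the Lys247 anchor never lets go), and ranking all five
variants by these kinetics reproduces the experimental potency order
with WT ≈ W256A as the weakest stallers.

The numbered scripts under `analysis/` run the full narrative — ensemble
simulation, render/recover round trip, spring-constant sweep, stalled
contact analysis, Δt signatures, ranking — writing their tables under
`results/`:

```sh
python analysis/01_simulate_events.py
python analysis/03_spring_sweep.py
...
```

An `arrestkin` command-line interface wraps the same stages
(`arrestkin simulate-events`, `arrestkin render`, `arrestkin spring-sweep`,
`arrestkin run`, `arrestkin report`, ...).

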