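# hydropore

Constant-(N, P, T) lattice Monte Carlo of a hydrophobic homopolymer in
explicit cell-model water, confined in a hydrophobic slit pore.

Water is modelled on a compressible 2D square lattice: every cell holds one
molecule carrying four six-state bonding indices, and a hydrogen bond (HB)
forms on a nearest-neighbour pair when the facing indices match and the
global cell volume satisfies `v/v0 < 2`. The Hamiltonian combines a
truncated Lennard-Jones term over all water pairs, the two-body HB energy
`J`, a many-body cooperativity term `Jsigma` among each molecule's indices,
and a strengthened HB (`+0.83 J`) for water in the hydration shell of the
chain or the walls, whose volume is also more compressible than bulk. The
36-residue chain is a self-avoiding walk with no direct energies of its own:
folding, unfolding and adsorption are driven entirely by the solvent. The
degree of folding is the number of contact points `N_CP` (nearest-neighbour,
chain-nonadjacent residue pairs), bounded by `N_CP_max = 25` for 36 residues.

The model reproduces a reentrant coil-globule transition: `N_CP(T)` at fixed
low pressure rises to a globular maximum at intermediate temperature and
falls again on both the cold and the hot side. See
[docs/methods.md](docs/methods.md) for the full model definition, parameter
table, sampling schedule, and known limitations (including the quantitative
deviations from the phenomenology the acceptance criteria encode).

## Worked example

```python
from hydropore.engine import RunConfig, run_simulation
from hydropore.analysis import summarize, classify_conformation

cfg = RunConfig(T_star=0.2, P_star=0.1, n_steps=20_000, n_equil=5_000,
                sample_every=50, seed=7, cluster_equil=True)
df = run_simulation(cfg)                       # pandas DataFrame, one row per sample
s = summarize(df, cfg.T_star, cfg.P_star)
print(f"<N_CP> = {s.mean_N_CP:.2f} +- {s.se_N_CP:.2f}")
print(classify_conformation(s.mean_N_CP, 36))
```

Output (about 30 s on one CPU core):

```
samples            : 300
<N_CP>             : 20.93 +- 0.50  (max 25)
conformation       : globule
<N_HB>             : 1258.4
shell HBs <N_HBphi>: 65.0
<v/v0>             : 1.291
adsorbed fraction  : 1.00
```

At (T* = 0.2, P* = 0.1) the chain is a globule adsorbed on the pore wall;
heating toward T* = 0.6 or cooling toward T* = 0.05 unfolds it.

The same run from the command line, with a trajectory CSV and a text
snapshot of the final configuration:

```
hydropore run --T 0.2 --P 0.1 --steps 20000 --equil 5000 --sample-every 50 \
              --seed 7 --out traj.csv --snapshot final.txt
hydropore fixture snake6x6 --out snake.txt   # maximally compact reference, N_CP = 25
```

Snapshots are plain text (`W` water, `X` wall, `R` residue, plus a header
with `L`, `wall_row`, `v_rel` and the chain coordinates) and round-trip
through `hydropore.snapshots`. Phase-diagram sweeps and analysis:

```
hydropore sweep --config sweep.cfg --out summaries.csv
hydropore analyze --summaries summaries.csv --out analysis.json
```

`analysis.json` contains the 30/40/50% stability regions of the globule and
the per-pressure spinodal scan.

## Reproduction

Everything published by this package is regenerable from a config and a seed;
trajectory headers embed both.

- `python -m pytest -q tests/` runs the full suite, including
  `tests/test_acceptance.py` (one test per acceptance criterion, with
  scaled-down run lengths but unchanged thresholds; the criteria on the
  coil-globule pressure thresholds, the 55% compactness maximum, and the
  liquid-to-gas spinodal fail honestly with this Hamiltonian - see
  docs/methods.md, "Known limitations").
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the headline quantities (contact-point maximum, schedule count,
  HB-breaking distance, free-spin bonded fraction, coil-globule peaks,
  compactness maxima, spinodal count) and writes them as JSON with sample
  sizes.
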