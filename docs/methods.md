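# Methods

## Model

`hydropore` simulates a coarse-grained hydrophobic homopolymer in explicit
cell-model water, confined between the hydrophobic walls of a slit pore, on a
two-dimensional square lattice.

### Geometry

The lattice is an `L x L` grid (default `L = 40`) with periodic boundary
conditions in both directions. Row `y = 0` is a row of inert wall cells; by
periodicity this single row acts as both the floor and the ceiling of a slit
pore of height `L - 1`. Every non-wall cell is occupied either by one water
molecule or by one chain residue. The chain is a self-avoiding walk of
`N_R = 36` residues on nearest-neighbour (NN) cells; it may never overlap the
wall. With the default geometry there are `N_W = L^2 - L - N_R = 1524` water
cells.

All cells share one global volume scalar `v >= v0` (the average cell volume,
`v0` the molecular hard-core volume), so the lattice is compressible: the NN
distance is `r_NN = l * r0` with `l = (v/v0)^(1/3)` and `r0 = v0^(1/3) =
2.9 A`.

### Degrees of freedom and Hamiltonian

Each water molecule `i` carries four bonding indices `sigma_ij` taking `q = 6`
values, one facing each NN direction. A hydrogen bond (HB) exists on a NN
water-water pair when the two facing indices are equal and bonding is
permitted, i.e. `v/v0 < 2`. The 1-in-6 matching probability encodes the
orientational entropy lost on bonding; the `v/v0 < 2` switch encodes the HB
breaking distance `r_max = r0 * 2^(1/3) = 3.65 A`, the separation at which
`(r0/r)^3` drops below 1/2.

The enthalpy, in reduced units (energies in `4*eps` with `eps = 5.8 kJ/mol`,
volumes in `v0`, pressures in `4*eps/v0`), is

```
H = U_vdw - J*N_HB - Jsigma*N_sigma - dJphi*N_HBphi + P*V_tot
V_tot = L^2*v + vHB*N_HB - k1*P*vHB*N_HBphi
```

- `U_vdw`: truncated 12-6 Lennard-Jones sum `4*eps[(r0/r)^12 - (r0/r)^6]`
  over all water-water pairs within a cutoff of `6 r0`, with a hard core at
  `r0` (well depth `eps`, i.e. 0.25 in reduced units). Distances scale with
  the global `l`, so this term couples the volume to the water structure.
- `-J*N_HB`: two-body HB energy, `J = 0.3`.
- `-Jsigma*N_sigma`: HB cooperativity; `N_sigma` counts, per water molecule,
  the equal pairs among its own four indices (0..6 each), `Jsigma = 0.05`.
- `-dJphi*N_HBphi`: hydration-shell bonus. The shell is the set of water
  cells lattice-adjacent to a residue or wall cell; `N_HBphi` counts HBs with
  both partners in the shell; `dJphi = 0.83*J`. Interfacial HBs are thus
  stronger than bulk HBs.
- Each HB adds a volume `vHB = 0.5`; shell HBs have their volume reduced by
  `k1*P*vHB` (`k1 = 1` in reduced units), making the shell more compressible
  than bulk water.

The chain itself is purely hydrophobic: residue-residue and residue-water
energies are zero, so folding is driven entirely by the solvent. The folding
observable is the number of contact points `N_CP` (NN residue pairs
nonadjacent along the chain), with the exact bound
`N_CP_max = 2n - ceil(2*sqrt(n)) - (n - 1) = 25` for `n = 36`.

## Monte Carlo

Sampling is constant-(N, P, T) Metropolis. One MC step performs, in random
order:

- `N_R` chain-move attempts: corner flips (including end rotations),
  crankshafts, pivots of the shorter arm, and whole-chain translations, chosen
  with equal weight. Displaced water is backfilled so occupancy is conserved;
  moves overlapping the wall or the chain are rejected. By default the
  translation moves are biased (never proposing motion away from the wall),
  which breaks top-down symmetry and models facilitated adsorption; `bias =
  False` restores a symmetric proposal.
- `4*(L^2 - N_R)` bonding-index attempts (6256 for the default geometry): a
  uniformly random water slot is assigned a uniformly random new value.
- one volume attempt: `v' ~ U[v - dv, v + dv]` with `dv = 0.05`, rejected if
  `v' < v0`; the enthalpy change includes the Lennard-Jones rescaling, the
  `P*V` work, and the HB on/off switch if `v` crosses `2 v0`.

Optionally, runs are pre-equilibrated with a cluster algorithm for the
bonding indices (Wolff-style growth over matching facing/intra-cell index
pairs), which decorrelates the sigma field far faster than single flips at
low temperature.

All observables (`N_HB`, `N_HBphi`, `N_sigma`, the Lennard-Jones pair-distance
table, shell membership) are maintained incrementally and validated against
from-scratch recomputation to 1e-10 (see the property tests).

### Performance choices

The hot loops are compiled with numba. Two optimizations matter:

- Bonding-index flips draw a single uniform variate decomposed into (cell,
  direction, new value), and the acceptance probability is read from a
  precomputed table indexed by the discrete change in (match count, shell
  match count, intra-cell pairs) and the volume switch - the enthalpy change
  of a single flip takes only 63 distinct values per volume branch, so no
  exponentials are evaluated in the loop. The single-draw decomposition
  deviates from exact uniformity only at the 2^-53 level.
- Chain moves reuse preallocated scratch buffers and branch-based periodic
  wrapping instead of hardware modulo.

Throughput is roughly 1000 MC steps/s for the default `L = 40` system on one
CPU core.

## Default parameters

| quantity | value |
|---|---|
| `L`, `N_R` | 40, 36 |
| `J`, `Jsigma`, `dJphi` | 0.3, 0.05, 0.249 (= 0.83 J) |
| `vHB`, `k1`, `q` | 0.5, 1, 6 |
| LJ well depth / hard core / cutoff | 0.25, `r0`, `6 r0` |
| volume step `dv` | 0.05 |
| `eps`, `r0` (absolute) | 5.8 kJ/mol, 2.9 A |

Temperatures `k_B T/(4 eps)` from 0.05 to 0.6 and pressures `P v0/(4 eps)`
from -0.2 to 0.6 span the studied phase diagram. Below `T* ~ 0.05` the sigma
dynamics become glassy and the engine logs a warning.

## Run sizes

Full-study schedules use `10^6` steps per state point (`10^4` equilibration,
sampling every 100 steps). The test suite and the acceptance script use
scaled-down schedules chosen by this package for a single-CPU time budget:
25,000-30,000 steps per state point with cluster pre-equilibration for
chain-phase quantities, and 5,000-6,000 steps per point for volume/spinodal
scans (the global volume equilibrates within ~2,000 steps). Convergence was
checked by running T* = 0.3 state points from opposite initial conformations
(rod, `N_CP = 0`, and maximally compact snake, `N_CP = 25`): first-half and
second-half means agree and both starts converge to the same `N_CP` within
one standard error at this schedule.

## Known limitations

- **Single global volume.** Because `v` is one scalar, crossing the HB
  permission switch at `v = 2 v0` in a volume move costs roughly
  `(J - P*vHB)*N_HB` at once (hundreds of `4 eps`), so a hydrogen-bonded
  liquid can never evaporate during a run at the studied temperatures: the
  liquid branch is dynamically absorbing, and no liquid-to-gas volume
  discontinuity appears below `T* = 0.6` anywhere on the default pressure
  grid. A model with local volume fluctuations would allow the gas phase to
  nucleate; with the global scalar, the liquid minimum of `H(v)` is also
  temperature-independent, so heating cannot destabilize it. The
  corresponding acceptance test documents this as an expected failure of the
  stated criterion.
- **Collapse-prone equilibrium.** With the parameter set above, the
  equilibrium chain is more globular than the coil-globule phenomenology the
  criteria encode: converged (two-sided) runs give peak `<N_CP>` around
  70-90% of `N_CP_max` for `P* = 0.1..0.5` instead of a maximum near 55%, and
  the pressure thresholds at 50%/40%/30% compactness are not reproduced. The
  reentrant (nonmonotonic in `T`) shape of `N_CP(T)` at low pressure *is*
  reproduced. The audit (two-sided convergence checks, Lennard-Jones
  convention check, shell-definition review) found no bookkeeping error: the
  incremental energies match brute-force recomputation to 1e-10, so this is a
  property of the Hamiltonian and parameter set as implemented.
- Two-dimensional lattice water; no electrostatics; wall is a hard inert row
  (no wall-water attraction); chain moves use a fixed move mix and the
  adsorption bias is a modelling choice, not a physical force.
- `T* <= 0.05` state points are glassy and not reliably equilibrated.
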