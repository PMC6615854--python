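# bundlesim

Mechanochemical simulation of actin bundles — semiflexible filaments,
α-actinin crosslinkers and myosin minifilaments evolved by alternating
next-reaction-method stochastic chemistry with conjugate-gradient mechanical
equilibration — plus the morphology-classification pipeline that turns
trajectory archives into bundle-like (BL), aster-like (AL),
aster–bundle-intermediate (ABI) and catastrophe (Type A/B) labels via
end-distance distributions, Jensen–Shannon divergence and complete-linkage
clustering.

## Layout

| module | contents |
|---|---|
| `bundlesim.mechanics` | bead–cylinder filaments, stretching/bending/excluded-volume/spring energies with analytic gradients, Polak–Ribière CG minimizer |
| `bundlesim.chemistry` | next-reaction engine, Brownian-ratchet / slip-bond / parallel-cluster catch-bond / force–velocity rate laws, voxelized diffusing species, binding-site search |
| `bundlesim.protocol` | initial unipolar/apolar hexagonal bundles, the chemistry↔mechanics evolution loop, flexible simulation volume, steady-state detection, condition grids |
| `bundlesim.morphology` | Dis++/Dis−−/Dis+− distributions, JSD, complete linkage, order parameters, catastrophe taxonomy, axial species distributions |
| `bundlesim.fixtures` | seeded synthetic labeled networks (bundle/aster/intermediate/sarcomere/fragmented/sparse) and toy reaction systems |
| `bundlesim.snapio` / `bundlesim.cli` | versioned plain-text snapshot format, YAML configs, CLI |
| `bundlesim.campaign` | desk-scale analogues of the published condition campaigns |

## CLI

```sh
bundlesim simulate --config config.yaml --seed 1 --out traj.snap
bundlesim grid     --spec grid.yaml --out archive/
bundlesim classify --archive archive/ --out labels.tsv   # + labels.nwk dendrogram
bundlesim fixtures --fixture-class aster --n 30 --seed 1 --out aster.snap
bundlesim report   --archive traj.snap
```

Configs are YAML mappings onto `SimulationConfig` (with nested `mech:` and
`chem:` blocks); units are nm / s / pN / μM. Exit codes: 2 config error,
3 runtime failure, 4 mechanics-convergence warnings.

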