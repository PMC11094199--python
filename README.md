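# ubam

Modelling toolkit for a three-compartment social-contagion model —
**U**naware, **B**ootlegger (active spreader), **A**ware — coupled to a global
media-awareness field `m` that suppresses transmission through a Holling
type-II response `Theta = m / (c + m)` and grows with the spreader fraction
(`dm/dt = phi*b - phi0*(m - m0)`).

Four analysis routes are provided over the same nine-parameter model:

| module | contents |
|---|---|
| `ubam.homogeneous` | well-mixed ODE system: trajectories, piracy-free and endemic equilibria, reproduction number `R_m`, normalized sensitivities, media thresholds (`c_th`, `m0_th`), bifurcation scans |
| `ubam.degree_block` | degree-based mean field: per-degree ODEs, epidemic threshold `<k>^2/<k^2>`, early-growth condition, steady-state self-consistency solver |
| `ubam.netsim` | stochastic agent-based simulation on explicit graphs (ER, BA, or KONECT-style edge lists), degree-stratified observables, media/bootlegger peak timing |
| `ubam.fitting` | bounded multi-start least-squares calibration to daily-count series, with synthetic-series generation for recovery studies |
| `ubam.interface` | config validation, CSV output, `ubam` CLI |

## CLI

All subcommands need a JSON/YAML config with a `params` block naming the nine
positive constants `mu, alpha, beta, rho, gamma, phi, phi0, c, m0`; optional
`init` and `integration` blocks are filled with defaults. The effective
config is echoed into the output directory, so every run is reproducible
from the echo plus `--seed`.

```bash
cat > config.json <<'EOF'
{"params": {"mu": 0.05, "alpha": 2, "beta": 0.01, "rho": 0.3, "gamma": 0.08,
            "phi": 0.5, "phi0": 0.1, "c": 5, "m0": 4}}
EOF

ubam simulate-ode --config config.json --out run/ --t-end 500
ubam equilibria   --config config.json --out run/
ubam thresholds   --config config.json --out run/
ubam sensitivity  --config config.json --out run/
ubam bifurcation  --config config.json --out run/ --sweep alpha --min 0.01 --max 4
ubam degree-block --config config.json --out run/ --distribution poisson --mean-degree 10
ubam network-sim  --config config.json --out run/ --graph er --n 1000 \
                  --mean-degree 10 --replicates 10 --seed 1
ubam fit          --config config.json --out run/ --data views.csv \
                  --free alpha,rho,gamma,scale --seed 1
```

`network-sim` supports two contact models: `--contact annealed` (default;
each node of degree k sees `k * psi` effective neighbours — the stochastic
counterpart of the degree-block mean field) and `--contact quenched`
(actual neighbour counts on the fixed graph; dynamic pair correlations then
depress the steady state by several percent relative to the mean field).

## Notes

- Initial conditions with `u + b + a < 1` are accepted; the deficit is
  assigned to the aware class with a logged warning.
- The steady-state per-degree bootlegger fraction `b_k` increases with
  degree through the bulk of any realistic degree distribution, but turns
  over at very high degree where the positive-peer conversion term
  `rho_n * k * psi_a` dominates.
- Stability labels come from the numerically differentiated 4x4 Jacobian
  (central differences, step 1e-7); one eigenvalue is structurally zero
  along the simplex-conservation direction and is ignored by the
  classification tolerance.
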