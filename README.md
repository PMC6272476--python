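# molsample

Evolutionary conformational sampling and flexible docking in one engine.

`molsample` treats "folding" (torsional sampling of a free molecule) and
"docking" (positioning a ligand in a rigid site) as the same problem: a
genetic algorithm whose crossover and mutation operators act on a
fragment decomposition of the molecule. Fragments still bonded to the
rest of the molecule are recombined by torsion exchange; loose fragments
(a ligand relative to a fixed receptor) are recombined by detaching and
re-docking them against interaction hot spots. Conformers are scored by
an AMBER/GAFF-style force field extended with continuum desolvation, a
hydrophobic-contact bonus, smooth per-pair termination, and
chirality/out-of-plane restraints. Population diversity is maintained
through differentiable pairwise interaction fingerprints (PIFs) rather
than RMSD clustering.

## Quick start

```python
import numpy as np
from molsample import (EvolutionConfig, SamplingContext, build_layout,
                       evolve, get_scheme)
from molsample.fixtures import make_fixture

fx = make_fixture("butane", seed=7)
ctx = SamplingContext(fx.mol, get_scheme("core"))
layout = build_layout(fx.mol)
config = EvolutionConfig(strategy="evol", population_size=50,
                         generations=100, seed=2025)
result = evolve(ctx, layout, config, fx.mol.coords)
print(result.best.energy, len(result.archive))
```

Docking uses the same machinery with a rigid (fixed-atom) site:

```python
from molsample import redock, success_rate
from molsample.fixtures import make_fixture

fx = make_fixture("cavity_hydrophobic", seed=2)
ctx = SamplingContext(fx.mol, get_scheme(fx.scheme_name),
                      hot_spots=fx.hot_spots)
layout = build_layout(fx.mol)
config = EvolutionConfig(strategy="evol", population_size=8,
                         generations=100, p_mut=0.25, p_cross=0.25)
pools, summary = redock(ctx, layout, fx.start, fx.planted,
                        fx.ligand_atoms, fx.site_center, config,
                        n_runs=10, base_seed=100)
print(success_rate([summary["top_rmsd"].tolist()], 1.0))
```

## Command line

The console script `molsample` exposes four subcommands:

- `molsample sample MOLFILE --seed N --scheme core --out PREFIX` —
  conformational sampling of a free molecule; writes the archive as a
  multi-record SDF plus a TSV run log.
- `molsample dock --site SITE.sdf --ligand LIG.sdf --seed N --out PREFIX`
  — flexible docking into a rigid site (hot spots auto-detected unless
  given via `--hot-spots`).
- `molsample rescan --poses POOL.sdf --scheme fit` — rescore a pose pool
  under a named parameter scheme, or run the hydrophobic-constant grid
  scan with `--scan --reference NATIVE.sdf`.
- `molsample fixtures NAME --seed N --out-dir DIR` — regenerate the
  bundled deterministic test systems as SDF files.

Run configurations can also be given as YAML (`--config run.yaml`) with
keys matching `EvolutionConfig` plus `scheme` and per-constant overrides.

## Package layout

| Module | Contents |
| --- | --- |
| `molsample.chem` | molecular model, typing, roles, symmetry sets, fragments |
| `molsample.params` | parameter tables, frcmod reader, the three named schemes |
| `molsample.forcefield` | energy terms, analytic gradients, per-pair cutoffs |
| `molsample.fingerprints` | PIF layout/values, originality, symmetry-aware RMSD |
| `molsample.operators` | local optimization, docking moves, crossover/mutation |
| `molsample.evolution` | steady-state / generational / elitist GA loops, archive |
| `molsample.pipeline` | site preparation, pose filtering, redocking, triplet scan |
| `molsample.io` | SDF/MOL2 readers and writers, index lists, YAML configs |
| `molsample.fixtures` | deterministic toy systems used by the test suite |

See `docs/methods.md` for the scientific background and the exact
functional forms.

## Testing

```bash
python -m pytest -q tests/            # full suite
python scripts/acceptance.py --seed 42 --out acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion;
`scripts/acceptance.py` recomputes the headline quantities (gradient
accuracy, basin coverage, redocking success rate, scheme contrast,
scan recovery, determinism) and writes them as JSON. All randomness in
both derives from explicit seeds; identical seeds reproduce identical
results bit for bit.
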