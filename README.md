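# crnosc — oscillation analysis for small mass-action reaction networks

`crnosc` decides, exactly, whether a small chemical reaction network can
oscillate under mass-action kinetics.  It targets the class where complete
answers exist: **three-reaction networks of rank two with bimolecular
(at most) source complexes** — "quadratic" networks, whose mass-action
ODE is a quadratic polynomial system

```
dx/dt = Γ (κ ∘ x^{Γₗᵀ}),
```

with `Γ` the stoichiometric matrix (one reaction vector per column), `Γₗ`
the source matrix, and `κ > 0` the rate constants.  The package is for
researchers in chemical reaction network theory and systems biology who
want machine-checkable versions of the structural arguments
(positive dependence of reaction vectors, Bendixson–Dulac divergence
tests, reduced-Jacobian sign rules, focal values) and of the resulting
censuses of oscillatory networks.

## What it computes

* **Structural predicates** (exact rational arithmetic throughout):
  rank, molecularity profile, trivial species, collinearity of sources,
  and dynamical nontriviality — `ker Γ ∩ ℝ₊ᵐ ≠ ∅` — with a Stiemke-style
  witness either way (a strictly positive kernel vector, or `v` with
  `Γᵀv ≩ 0`).  For three-reaction rank-two networks the kernel is spanned
  by the cross product `u = c × d` of two independent rows of `Γ`.
* **Equilibria and stability.**  Positive equilibria of `(n, 3, 2)`
  systems solve a *log-linear* system (`κ ∘ x̄^{Γₗᵀ} = μu`), so existence
  and uniqueness are read off the linear algebra, not from Newton runs.
  The reduced Jacobian on a stoichiometric class is assembled as
  `J_red = μ [cᵀ; dᵀ] Δ_u Γₗᵀ Δ_{1/x̄} Γ̃` and its determinant sign is
  cross-checked against a Cauchy–Binet expansion over species pairs and
  against the product of the two nonzero eigenvalues of the full
  Jacobian.  For planar systems the first focal value L1 is computed from
  the planar normal form (the RHS is quadratic, so only second
  derivatives enter); `L1 < 0` at a Hopf point means a supercritical
  bifurcation and a stable limit cycle.
* **Classification.**  The complete decision procedure for
  three-reaction quadratic networks: the ten planar source-complex cases
  (centers in case 7, a vertical Hopf family in case 8, supercritical
  Hopf families in cases 9 and 10, nothing in cases 1–6), and the general
  trimolecular theorem for any number of species — every oscillatory
  network is a generalized Lotka center, the Ivanova cycle, or the lifted
  Lotka–Volterra–Autocatalator (LVA), so isolated periodic orbits require
  a target of molecularity ≥ 4.
* **Censuses.**  Exhaustive, canonicalized enumerations reproducing the
  exact counts: 10 planar source cases; exactly 4 tetramolecular networks
  with a (supercritical) Andronov–Hopf bifurcation and none at
  molecularity 3; 16 quadratic trimolecular networks admitting a periodic
  orbit; minimal target molecularity 7 for the second supercritical
  family; 2 supercritical source cases; 3 reactions needed for
  oscillation.
* **Numerics as corroboration only:** simulation (`DOP853`, tight
  tolerances), Poincaré return-map periodicity tests, conserved-quantity
  drift monitoring, and limit-cycle amplitude tracking on the unstable
  side of a Hopf point.  No verdict depends on floating point.

## Worked example

The simplest quadratic network with a stable limit cycle:

```bash
crnosc analyze --inline "2X -> 3X + Y; X + Y -> Y; Y -> 0" --kappa "k1=1,k2=1,k3=1"
```

prints (abridged):

```json
{
  "rank": 2,
  "molecularity": [2, 4],
  "dynamically_nontrivial": true,
  "kernel_sign_vector": [1, 1, 1],
  "verdict": {
    "outcome": "supercritical_hopf",
    "fired_rule": "planar_case9",
    "certificate": {"case": 9, "c": [1, -1, 0], "d": [1, 0, -1], "u": [1, 1, 1]}
  },
  "equilibrium": {"x": [1.0, 1.0], "mu": 1.0}
}
```

Reading this: the three reaction vectors are positively dependent
(`u = (1,1,1) > 0`, so positive equilibria are possible), the sources
`2X, X+Y, Y` form case 9 of the planar classification, and the integer
conditions of that case hold — the system undergoes a supercritical
Andronov–Hopf bifurcation (at `κ₁ = κ₂`; here the equilibrium `(1, 1)` is
exactly the bifurcation point).  In Python,

```python
from crnosc import MassActionSystem, NETWORK_4, first_focal_value
fv = first_focal_value(MassActionSystem(NETWORK_4, (1.0, 1.0, 1.0)))
print(fv.l1)        # -0.125  -> supercritical, stable limit cycle nearby
```

The census of all tetramolecular networks with a Hopf bifurcation:

```bash
crnosc enumerate --census tetra-hopf
```

returns the four networks `2X → 3X+Y, X+Y → (1+d)Y, Y → 0` for
`d = 0..3`, each `supercritical_hopf` — and re-running with targets
capped at molecularity 3 returns none, which is the statement that
trimolecular quadratic three-reaction systems have no isolated periodic
orbits.

## Layout

| module | contents |
|---|---|
| `crnosc.network` | complexes, reactions, parsing/writing, Γ/Γₗ, rank, nontriviality certificates, canonical forms, trimolecularization |
| `crnosc.dynamics` | mass-action RHS/Jacobian, log-linear equilibria, first integrals, simulation, return-map periodicity |
| `crnosc.stability` | reduced Jacobian + Cauchy–Binet sign rule, planar det/trace formulas, first focal value, Hopf-side amplitude checks |
| `crnosc.classify` | source-case normalization, the planar ten-case decision, the general trimolecular decision, regime analyses |
| `crnosc.census` | exhaustive enumeration and the six censuses |
| `crnosc.cli` | `crnosc analyze / classify / simulate / enumerate` |

See `docs/methods.md` for the model assumptions, formulas, numerical
choices and limitations.
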