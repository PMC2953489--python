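# popgames

Replicator dynamics for **two populations with incompatible preferences and
unequal power** — a quantitative toolkit for studying when interacting groups
break down into mutual defection, keep separate "subcultures", converge on a
shared behavioral norm, or polarize and undergo revolutionary regime shifts.

It is aimed at researchers in evolutionary game theory, social dynamics and
theoretical biology who want reproducible phase portraits, equilibrium and
stability analysis, basin-of-attraction maps, and a finite-population
stochastic counterpart for this class of models.

## The model

Population 1 prefers behavior 1, population 2 prefers behavior 2; each calls
its own preferred behavior "cooperative", so population 2's payoff matrices
are the mirrored forms of population 1's.  A symmetric 2×2 game with payoffs
T, R, P, S enters only through

```
B = S − P,   C = R − T,
```

whose signs select the game: prisoner's dilemma (B<0, C<0), snowdrift
(B>0, C<0), stag hunt (B<0, C>0), harmony (B>0, C>0).  The state is
(p, q) ∈ [0,1]²: p is the fraction of population 1 showing behavior 1, q the
fraction of population 2 showing behavior 2.  With in-group parameters
b_a, c_a, out-group parameters B_a, C_a, and relative power f of
population 1, proportional imitation within each population gives

```
dp/dt = p(1−p) G₁,   G₁ = f[c₁p + b₁(1−p)] + (1−f)[C₁(1−q) + B₁q]
dq/dt = q(1−q) G₂,   G₂ = (1−f)[c₂q + b₂(1−q)] + f[C₂(1−p) + B₂p]
```

Because G₁, G₂ are affine in (p, q), every stationary state is available in
closed form (corners, edge solves, an interior solve, or a whole line of
equilibria when the two zero-sets coincide, e.g. for |B| = |C|).  The package
also implements the **costly punishment** transformation
(b′ = b − γ, c′ = c + β in-group; B′ = B − γ − β_other cross-group), which
turns an in-group prisoner's dilemma into a stag hunt while the cross-group
game stays a prisoner's dilemma, and the **group pressure** transformation
(B′ = B − g, C′ = C + g).

## Worked example

The two-population snowdrift game with B = 1, C = −2 and a strong
population 1 (f = 0.8):

```
$ popgames fixpoints --fixture fig5C
(0.000000, 0.000000)  corner   saddle
(1.000000, 0.000000)  corner   unstable
(0.000000, 1.000000)  corner   unstable
(1.000000, 1.000000)  corner   saddle
(0.166667, 0.000000)  edge     stable
(0.416667, 1.000000)  edge     saddle

$ popgames simulate --fixture fig5C
converged=True final=(0.16666666966666666, 0.0)
```

The unique attractor is the edge point (1/6, 0): the stronger population
*polarizes* — only a sixth of it cooperates — while everybody in the weaker
population adopts population 1's preferred behavior, coordinating with the
stronger population's minority.  The population-weighted cooperation

```python
>>> from popgames import GameParams, find_attractor, overall_cooperation
>>> g = GameParams.shorthand(1, -2, 0.8)
>>> res = find_attractor(g, (0.5, 0.5))
>>> round(overall_cooperation(g, res.state), 6)
0.333333
```

equals |B|/(|B|+|C|) = 1/3 exactly — the one-population snowdrift
expectation of the stronger population, enforced by controlling the weaker
one.  Swapping the magnitudes (B = 2, C = −1) flips the attractor
discontinuously to (5/6, 1): the weaker population's coordinate jumps from
0 to 1, the model's "revolutionary" transition (`popgames sweep --f 0.8`
locates it along the cubic path C = −B³).

Other entry points: `popgames basins` (basin maps, optional PNG),
`popgames phase-diagram` (norm formation over power f and benefit ratio
b/c), `popgames abm` (finite-population proportional imitation), and
`popgames fixtures` (the built-in benchmark scenarios fig2A…fig7B).

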