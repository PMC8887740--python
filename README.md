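# acam — an apposed-cortex adhesion model of epithelial tissue

`acam` is a 2D simulator of epithelial tissue mechanics for studying cell
intercalation (T1 neighbour exchanges) and rosette formation as
*continuous* processes.  Unlike vertex models, which collapse each
cell–cell contact onto a single shared edge anchored at material
vertices, here every cell's junctional actomyosin cortex is its own
closed viscoelastic rod, and neighbouring cortices are coupled by
explicit adhesion bonds that stretch, saturate and turn over.  Vertices
are merely the geometric places where three or more cortices approach:
cortical material can flow past them, apposed cortices can slip, and
junctions can shrink, uncouple and re-form without any topological
surgery.

The mechanics, in the field's standard notation: each cortex carries the
extensible-rod energy

    U = ∮ [ ½ κ² c² + ½ ε² ] dS ,        ε = α − 1,  c = ∂θ/∂S,

with active contraction entering morphoelastically (total stretch
λ = γ·α, only the elastic part α generates stress; motors mean γ < 1).
Bonds are saturating Hookean springs, W = ½ ω (δ − 1)² for δ ≤ δ_max,
with rest length δ₀ ≡ 1 setting the inter-cortical spacing; unbound sites
re-bind to cortices within δ_max and bonds unbind with mean lifetime
τ_adh, giving an emergent cortex–cortex sliding friction μ_adh = ω τ_adh.
On timescales beyond the cortical turnover time τ_cor the rod is a
viscoelastic fluid: every step, positions are relaxed to force balance
and rest lengths to current lengths.  Model and numerics are documented
in [`docs/methods.md`](docs/methods.md).

## A worked example

Run the standard neighbour exchange: fourteen hexagonally packed cells, a
background pre-stress γ₀ = 1 − 2·10⁻⁴ in every cortex, and identity-
sensing contractility γ = 0.94 applied only where the cortices of cells 1
and 2 face each other:

```python
from acam import replicate

tissue, trace = replicate.run_t1(tau_adh=10.0, seed=0, n_steps=150)
df = trace.observables
print(f"initial junction length L12 = {df['L12'].iloc[0]:.2f}")
print(f"minimum normalised area of the pair = {df['A12'].min():.3f}")
print(f"final new-junction length L34 = {df['L34'].iloc[-1]:.2f}")
```

which prints:

```
initial junction length L12 = 6.73
minimum normalised area of the pair = 0.919
final new-junction length L34 = 7.42
```

Reading: the shared junction (≈ 6.7 rest lengths long) contracts to zero,
the four cells meet at a 4-way configuration, and the orthogonal junction
between the previously unconnected cells 3 and 4 then extends passively
to ≈ 7 rest lengths — a complete T1.  The intercalating pair transiently
loses ≈ 8 % of its area while cortical material is pulled into the
shrinking junction; with fast adhesion turnover (`tau_adh=0.1`) the loss
is several times larger, because bonds cannot build up the friction that
stops apposed cortices from slipping.

The same machinery is exposed on the command line:

```sh
acam run config.yaml            # fixture + protocol from a YAML file
acam replicate fig3             # named reference experiments
acam sweep --kappa 0.005 0.05 --omega 0.01 0.2 -n 3
acam render out-dir             # PNG frames from saved snapshots
```

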