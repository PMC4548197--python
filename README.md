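# apoptonet

Boolean threshold-network analysis of cell-fate decisions in neuronal
apoptosis.

Neurons integrate survival signalling (growth factor via AKT/NF-κB) and
death signalling (the death ligand FasL via the caspase cascade and the
mitochondrial pathway) into an all-or-none outcome: survive, die, or pause
and repair DNA damage. `apoptonet` models this decision as a 21-protein
signed Boolean network and analyses it exhaustively: every one of the
2^19 initial states of the free vertices is simulated under clamped
inputs, the resulting attractors are collected with their basins of
attraction, attractors are classified into cellular fates, and in-silico
knockout/overexpression screens and heat-shock-protein (HSP) extensions
quantify how the survival/death balance shifts.

## The model

Each vertex *i* carries a binary state S_i(t). All vertices update
synchronously by the signed threshold rule

    W_i(t) = b_i + Σ_j a_ij · S_j(t)

    S_i(t+1) = 1        if W_i > 0
             = 0        if W_i < 0
             = S_i(t)   if W_i = 0   (ordinary vertices)
             = 0        if W_i ≤ 0   (self-degrading vertices)

with edge signs a_ij ∈ {+1, −1} and a basal term b_i = 1 for
constitutively synthesised proteins (IκB, BAD, NF-κB, p53 depending on
the wiring variant). Inputs (GF, FasL, overexpressed HSPs) are clamped
for the whole run. Three persistence gates delay regulation until the
regulator has been ON for a required run of consecutive steps: DNA damage
must persist three steps before it activates p53, and caspase-3's
inhibition of IAP and p53's transcriptional outputs require two
consecutive ON steps.

A simulation runs 15 synchronous steps (the network's longest path). The
state reached at the end is the trajectory's attractor; an attractor is
*stable* if it is a fixed point that no gate can destabilise, and
*transient* if it is a quasi-stable state that the network eventually
leaves. Fates are read off the attractor bits: caspase-8 AND caspase-3 ON
means apoptosis; caspase-8 with persistent DNA damage but no caspase-3
means DNA repair; everything else is survival.

## Worked example

```python
from apoptonet import (apoptosis_network, enumerate_attractors,
                       fate_probabilities, classify_fate)

net = apoptosis_network()                      # packaged 21-vertex asset
res = enumerate_attractors(net, {"GF": 1, "FASL": 0})
for a in res.attractors[:3]:
    print(a.state_string, a.basin_size, a.stability,
          classify_fate(a, net))
fs = fate_probabilities(res)
print("f_survival =", float(fs.f_survival))
```

prints the dominant attractors under growth factor alone:

```
000000001101101110001 330396 stable survival
111111110101101111101 162324 stable apoptosis
111111110100101111101 28600 transient apoptosis
f_survival = 0.6358413696289062
```

The first line is the survival fixed point — every anti-apoptotic
protein (IAP, AKT, BCL2, IKK, NF-κB, cFLIP, MDM2) ON and every caspase
OFF — holding ~63% of the 2^19 initial states. The second is the
full-death fixed point (caspases and the mitochondrial arm ON). The
third is a quasi-stable death state still missing BCL2, which the
network leaves once p53's persistence gate resolves. The same library
surface drives the command-line tools:

```
apoptonet enumerate --gf both --fasl both --out out/
apoptonet screen --clamp 0 --vertices BCL2,NFKB,CASP9 --out out/
apoptonet hsp --name HSP70 --out out/
```

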