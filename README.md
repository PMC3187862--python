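# ectoflux

Constraint-based model of **ectoine metabolism in *Halomonas elongata***:
the curated stoichiometric network of ectoine synthesis (EctB/EctA/EctC from
aspartate-semialdehyde and acetyl-CoA) and degradation
(DoeA/DoeB/DoeD/DoeC back to aspartate), flux balance analysis of the
glucose-to-ectoine conversion, ATP accounting of the alternative pathway
variants, exhaustive elementary-flux-mode enumeration, flux variability
analysis of the degenerate optima, and the energetics and response-time
analysis of the ectoine synthesis/degradation (futile) cycle.

The package is aimed at people working on compatible-solute metabolism and
on constraint-based modelling of small curated subsystems: everything is
desk-scale, exact where it can be (rational stoichiometry, exact mode
enumeration) and reproducible.

## The model

A stoichiometric network with matrix **S** (rows = internal metabolites,
columns = reactions) is analysed at steady state,

```
S v = 0,     lb <= v <= ub,
```

with linear programming over the flux vector *v* (flux balance analysis).
Glycolysis is lumped into one ATP-neutral reaction `glc + 2 NAD+ -> 2 PEP +
2 NADH`; the PEP–pyruvate–oxaloacetate node is kept at single-reaction
resolution because the pathway variants differ exactly there:

* **oren** — PEP carboxylase (EC 4.1.1.31) anaplerosis with GS/GOGAT
  nitrogen assimilation (1 ATP per N): net **−2 ATP** per ectoine;
* **gdh** — the same carbon routing with NADH-dependent glutamate
  dehydrogenase: net **0 ATP** (energy-neutral);
* **malic** — oxaloacetate made from pyruvate by malic enzyme
  (EC 1.1.1.38) + malate dehydrogenase (EC 1.1.1.37), so both PEP pass
  through pyruvate kinase: net **+1 ATP** per ectoine.

Degradation closes a cycle whose net effect is acetyl-CoA → acetate;
re-ligation by the AMP-forming acetate:CoA ligase (EC 6.2.1.1, lumped with
pyrophosphatase and adenylate kinase) makes the cycle cost **2 ATP per
turn**. The payoff of paying that cost is responsiveness: the turnover
(response) time of the ectoine pool — concentration divided by steady-state
flux — falls as the cycle flux rises, so a cycling pool tracks osmotic
setpoint changes faster.

## Worked example

```python
import ectoflux as ef

net = ef.load_ectoine_model()
for name in ("oren", "gdh", "malic"):
    print(f"{name:6s} net ATP per ectoine: {ef.atp_balance(net, name):+.0f}")
print("yield (gdh,   m=0):", ef.max_yield(net, "gdh", 0.0))
print("yield (malic, m=1):", ef.max_yield(net, "malic", 1.0))
print("cycle ATP drain at 1 turn/unit time:", ef.cycle_atp_cost(net, 1.0))
```

prints

```
oren   net ATP per ectoine: -2
gdh    net ATP per ectoine: +0
malic  net ATP per ectoine: +1
yield (gdh,   m=0): 1.0
yield (malic, m=1): 1.0
cycle ATP drain at 1 turn/unit time: 2.0
```

i.e. the GS/GOGAT variant costs 2 ATP per ectoine, the GDH variant is
energy-neutral and reaches a 100% molar yield only with zero maintenance
demand, while the malic-enzyme variant generates 1 ATP per ectoine and
sustains total conversion up to a maintenance drain of 1 ATP per glucose
(`m` is the ATP drained per glucose taken up).

Exhaustive enumeration of the support-minimal glucose-to-ectoine pathways:

```python
modes = ef.enumerate_modes(ef.apply_scenario(net, "synthesis"))
for m in sorted(modes, key=lambda m: m.net_atp):
    print(f"net ATP {str(m.net_atp):>4s}  {ef.classify_mode(m):10s} via "
          + ",".join(sorted(m.support & {"PPC", "MAE", "MDH", "GDH", "GS", "GOGAT"})))
```

```
net ATP   -3  cost       via GOGAT,GS,MAE,MDH,PPC
net ATP   -2  cost       via GOGAT,GS,PPC
net ATP   -1  cost       via GDH,MAE,MDH,PPC
net ATP   -1  cost       via GOGAT,GS,MAE,MDH
net ATP    0  neutral    via GDH,PPC
net ATP    0  neutral    via GDH,GOGAT,GS,MAE,MDH
net ATP    1  generating via GDH,MAE,MDH
```

All seven elementary modes are total conversions (glucose −1, ammonia −2,
ectoine +1); the three classic variants appear alongside four further
support-minimal combinations, including routes that run malate
dehydrogenase and malic enzyme in reverse as an
oxaloacetate→malate→pyruvate bypass of pyruvate kinase (see
`docs/methods.md`).

The same computations are available from the shell:

```
ectoflux atp --scenario malic          # 1.000000
ectoflux yield --scenario gdh          # 1.000000
ectoflux fva --scenario synthesis      # PPC range [0, 1]: the degenerate node
ectoflux modes --scenario synthesis --out modes.tsv
ectoflux cycle --flux 1                # 2.000000
ectoflux respond --pool 1 --k 0.5 --new-flux 2 --horizon 10 --steps 200
ectoflux synth random --mets 6 --rxns 10 --seed 1 --out toy.tsv
```

User-supplied networks use the plain-text reaction-table format documented
in `ectoflux.network` (sections `# METABOLITES` and `# REACTIONS`, rational
coefficients, `->`/`<->` equations); scenarios can be given as YAML files
with `enabled:`/`disabled:` reaction lists.

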