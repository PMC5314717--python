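# epiland

Boolean gene-regulatory-network dynamics and epigenetic-landscape
analysis of **spontaneous immortalization of human epithelial cells**.

Cultured human epithelial cells can transform without external insult:
normal epithelial cells first enter senescence and then surpass it,
emerging as mesenchymal stem-like cells with tumorigenic potential.
`epiland` packages a nine-node Boolean model of the core regulatory
module behind these transitions — NF-κB, ESE-2, Snai2, p16, p53, Rb,
E2F, Cyclin and TELase — together with the machinery to analyse it and
any other small Boolean network:

* exact synchronous dynamics: attractor enumeration and
  basin-of-attraction partitioning over the full 2^n state space;
* node clamping for in-silico loss/gain-of-function mutants and for
  constitutive conditions such as chronic inflammation (NF-κB ≡ 1);
* network reduction (collapse of simple mediator and source nodes in
  signed digraphs and Boolean networks, fixed-point preserving);
* a stochasticity-in-nodes (SIN) noise layer: each gene disobeys its
  rule with probability ξ per step, inducing hops between basins;
* the epigenetic-landscape summary built from the attractor-level
  Markov chain Π: temporal attainment order, mean first-passage times
  (MFPT), net transition rates d(i,j) = 1/MFPT(i,j) − 1/MFPT(j,i) and
  the consistent global ordering of the phenotypes.

## The model

Each gene holds a Boolean state x_i; the network updates synchronously,
x_i(t+1) = F_i(x(t)), with F_i given as a truth table over i's declared
regulators.  The packaged rule set (`src/epiland/data/core_grn.bnet`)
was selected by exhaustive constraint search over monotone,
sign-consistent candidate rules so that the model reproduces the
published behaviour of the module:

* exactly three attractors, all fixed points, matching the epithelial,
  senescent and mesenchymal stem-like expression profiles;
* basin sizes 17.97 % / 25.78 % / 56.25 % of the 512 initial states;
* with NF-κB held constitutively active, basins shift to
  6.25 % / 18.75 % / 75 % — inflammation widens the mesenchymal basin;
* under SIN noise the most probable journey of an epithelial cell is
  epithelial → senescent → mesenchymal stem-like, and the same ordering
  is the unique permutation with all positive net transition rates.

See `docs/methods.md` for the reconstruction procedure, the parameters
of the stochastic layer and known limitations (two in-silico mutants
carry one extra spurious attractor each; the attainment sequence is
noise-level dependent above ξ ≈ 0.1).

## Worked example

```
$ epiland basins
 attractor       label  count  percent
         0 mesenchymal    288    56.25
         1  epithelial     92    17.97
         2   senescent    132    25.78
```

92 of the 512 possible initial expression states converge to the
epithelial programme, 132 to senescence and 288 to the mesenchymal
stem-like state: left to its own regulatory logic, most of the state
space drains towards the potentially tumorigenic phenotype.

```
$ epiland basins --clamp "NF-kB=1"
 attractor       label  count  percent
         0 mesenchymal    192    75.00
         1  epithelial     16     6.25
         2   senescent     48    18.75
```

Chronic inflammation (NF-κB clamped on) enlarges the mesenchymal basin
from 56.25 % to 75 % at the expense of the epithelial and senescent
ones.

```
$ epiland landscape --seed 7
attainment sequence: epithelial -> senescent -> mesenchymal
consistent global ordering: epithelial -> senescent -> mesenchymal
```

With disobedience probability ξ = 0.05 per gene and step, a population
started in the epithelial attractor is most likely found epithelial
first, then senescent, then mesenchymal — and the net probability flow
across the landscape runs in the same direction.

Mutants are one call away (`epiland mutate --node Snai2 --mode gain`),
as is any user network in the plain-text rule format
(`epiland attractors --network my_model.bnet`).

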