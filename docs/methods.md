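# Methods

## The model and its assumptions

The package treats leaf metabolism as a stoichiometric network at steady
state. A flux distribution `v` must satisfy `S v = 0` with per-reaction
bounds `v_min ≤ v ≤ v_max` (all fluxes in µmol m⁻² s⁻¹, the leaf
gas-exchange convention). The biological objective is that of a mature
*source* leaf: maximise phloem sap output (sucrose plus amino acids)
rather than a biomass reaction, because a differentiated leaf no longer
builds itself. Degeneracy among alternate optima is resolved
parsimoniously — minimise `Σ|v|` subject to the phloem optimum — which
operationalises resource limitation: among all flux patterns that feed
the plant equally well, evolution is assumed to prefer the one using the
least enzyme machinery. Some experiments insert an intermediate
objective (minimise Rubisco oxygenation flux) between the phloem optimum
and the parsimony stage; stages are combined lexicographically, each
optimum locked within a relative tolerance of 1e-6 before the next stage
runs. A weighted-sum combination was considered and rejected: weights
would be free parameters, whereas the lexicographic order ("feed the
plant, then avoid photorespiration, then save protein") states the
biological priority explicitly.

Three further modelling conventions matter:

* **Proton sinks.** The protonation state of most transport substrates
  is unknown, so protons may appear/disappear freely in every
  compartment (reversible sink/source reactions). This deliberately
  forfeits any conclusion about the energetics of proton-coupled
  transport; without it, spurious futile proton cycles dominate every
  solution.
* **Fixed maintenance.** Non-growth-associated ATP hydrolysis is pinned
  (both bounds) to measured per-compartment costs: cytosol 0.0427 (plus
  the peroxisomal 0.0076, since the model has no peroxisomal ATP pool),
  chloroplast 0.1527, mitochondrion 0.0091 µmol m⁻² s⁻¹. A consequence
  worth knowing: a model given zero light is *infeasible*, not
  zero-flux, because the maintenance debt cannot be paid. Scan drivers
  therefore record per-point solver status instead of assuming
  feasibility.
* **Flux-ratio constraints** are extra zero rows of the LP
  (`v_a − r·v_b = 0`), never bound manipulations, so they compose with
  any objective and remain exact at any scale. The phloem composition
  (sucrose : amino acids 2.2 : 1, sucrose : starch 1 : 1) and the
  Rubisco oxygenation : carboxylation ratio (ambient default 0.1; the
  ratio can also be derived from a specificity `SR` and partial
  pressures as `(1/SR)·pO₂/pCO₂`) are all expressed this way.

## Two-cell composition and the dual Rubisco population

The C4 leaf is modelled by duplicating the one-cell model into `[M]`
(mesophyll) and `[B]` (bundle sheath) copies — bounds, maintenance and
ratio constraints duplicate with them — and connecting the cytosols with
reversible `[MB]` transporters (positive flux: M → B) for amino acids,
sugars, phosphorylated intermediates, C3–C6 carboxylic acids,
photorespiratory intermediates and CO₂. Oxaloacetate is excluded (low in
vivo concentration, unstable), as are protons, bicarbonate and all
charged currency metabolites (ATP, NAD(P)(H), Pi).

Because FBA is static, the CO₂-concentration dependence of Rubisco is
approximated by two enzyme populations in the bundle sheath operating on
two sealed CO₂ pools:

* mesophyll-delivered (**external**) CO₂ enters `[B]_CO2_ex_c`, may only
  move to the chloroplast (`[B]_Tr_CO2h_Ex`) and react with the *native*
  carboxylation `[B]_RBC_h_Ex`, which is ratio-coupled to the oxygenase
  `[B]_RBO_h` — externally fixed carbon always pays the photorespiratory
  tax;
* CO₂ released by bundle-sheath reactions (glycine decarboxylase, the C4
  decarboxylases, respiration) populates the **internal** pools and is
  fixed by the CCM-dependent population (`[B]_RBC_h`), which has no
  oxygenation partner — as if locally CO₂-saturated.

The pools never mix, so the model can neither feed environmental CO₂ to
the oxygenation-free enzyme nor launder internal CO₂ through the
external pool. Whether the `[MB]` CO₂ transporter may also carry CO₂
back to the mesophyll is left open by the two-pool design; we keep it
reversible like every other intercellular transporter, and the pool
sealing prevents any exploit.

Mesophyll CO₂ uptake is capped at 40 µmol m⁻² s⁻¹ (the C4 rate; the C3
one-cell default is 20), bundle-sheath uptake is zero (it is shielded
from the atmosphere), and total photon uptake is budgeted
(`[M]+[B] ≤ PPFD_total`, default 1000) with the anatomical ordering
`[B] ≤ [M]` enforced — except in light-distribution grids, which
explicitly scan ratios up to 2 and therefore pin the exact ratio with
the ordering released.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| CO₂ uptake bound | 20 / 40 µmol m⁻² s⁻¹ | one-cell / two-cell carbon limitation |
| Sucrose : amino acids | 2.2 | phloem exudate composition |
| Sucrose : starch | 1.0 | half the assimilate is stored for the night |
| Oxygenation : carboxylation | 0.1 (ambient), 1/3 (stressed) | photorespiration level |
| H⁺/ATP | 3 (chloroplast), 4 (mitochondrion) | ATP synthase stoichiometry, set by curation |
| Photons per 2 NADPH (linear flow) | 8 | lumped light reactions, 12 pmf co-produced |
| pmf per cyclic photon | 2 | tunes the ATP:NADPH supply ratio |
| pmf per NADH (respiration) | 10 | P/O ≈ 2.5 with the 4:1 synthase |
| NGAM costs | 0.0427/0.1527/0.0091/0.0076 | c/h/m/p maintenance, µmol m⁻² s⁻¹ |
| Infinity proxy | 1e6 | finite stand-in for unbounded exchanges |
| FVA slack | 1.5 % | allowed total-flux excess over the minimum |
| Grid defaults | 21 ratio pts 0–1; PPFD 0–1000 step 50 × ratio 0.1–2 step 0.1 | scan resolutions |

## The bundled reduced network

`synthetic_network` generates a ~115-reaction, four-compartment leaf
model deterministically in code, so every pipeline stage is testable
hermetically. It emulates the *structure* the analysis needs: explicit
proton-motive charge with ATP synthases (so the H⁺/ATP curation is
real), a complete photorespiratory loop releasing CO₂ and NH₄⁺ at
mitochondrial glycine decarboxylase, every C4 enzyme in its canonical
compartment, nitrate-only nitrogen assimilation, TCA/oxidative
phosphorylation with alternative oxidases, and thylakoid/mitochondrial
proton leaks (non-photochemical quenching, uncoupling proteins) so that
surplus proton-motive force is dissipated as heat rather than through
futile ATP cycles. Carbon and nitrogen are conserved exactly —
`check_conservation` returns an empty report — with one deliberate
override: the lumped phloem amino acid carries the exudate-average 5.5
carbons and 1 nitrogen, a value no chemical formula can express, stored
as metabolite metadata. The builder emits the network in its
pre-curation state (NADP-dependent malate dehydrogenases outside the
chloroplast, reversible decarboxylases, wrong synthase stoichiometry,
open plastoquinol oxidase) so the packaged declarative curation set is
exercised end to end, not just defined.

On this network the physiology comes out quantitatively plausible: the
carbon-limited one-cell optimum needs ≈190 µmol m⁻² s⁻¹ of photons,
exports ≈21 µmol m⁻² s⁻¹ O₂, saturates with light above ≈200 (one-cell)
and ≈400 (two-cell) µmol m⁻² s⁻¹, and attributes ≈97 % of ATP production
to the light reactions. The C3 → C2 → C4 trajectory reproduces: with
rising photorespiration, CO₂ diffusion plus native fixation gives way to
a glycine-decarboxylase CO₂ pump and then to a full PEPC/NADP-ME cycle
carrying the entire 40 µmol m⁻² s⁻¹; each of the three decarboxylation
enzymes alone supports a feasible C4 mode; and FVA at 1.5 % slack shows
the aspartate/alanine shuttle inside the near-optimal space of the
NAD-ME and PEP-CK modes.

**What the reduced network does not show.** Passing tests on it
demonstrate the machinery and the qualitative transitions, not
genome-scale numbers. Known deviations from full-network behaviour, all
consequences of the aggressive lumping: (i) PEPC is not near-zero at
zero photorespiration (≈10 of 40 units) because it doubles as the
anaplerotic OAA source for amino-acid export and as part of the
cheapest route that satisfies cytosolic ATP demand, and for the same
reason its rise along the photorespiration axis is not strictly
monotone at the low end; (ii) the mesophyll flux pattern is only
approximately, not exactly, identical across the three knockout modes
(the choice of transfer acid bleeds into mesophyll transaminase use);
(iii) pinning the aspartate : malate transport ratio does not shift the
preferred decarboxylase, because the reduced bundle sheath can
interconvert OAA and malate at no marginal cost; (iv) NAD-ME co-occurs
with NADP-ME only at strongly mesophyll-skewed light under saturation,
an energetic edge case of the lumped electron transport. Quantities
that belong to the full genome-scale model only (413/572 network size,
PPFD 193.7, O₂ 20.9, sucrose 0.5, 97.2 % ATP share) are asserted
exclusively against that model and reported as skipped when its SBML
file is absent.

## Numerical choices

GLPK (through optlang) solves all LPs; its simplex is deterministic, so
identical inputs give bit-identical fluxes and scan tables — the only
remaining freedom, ties among multiple minimal-`Σ|v|` solutions, is
resolved by the solver's deterministic pivoting and documented as
solver-dependent. `Σ|v|` needs no extra variables because optlang
already splits each reaction into non-negative forward/reverse parts;
reported fluxes are recombined net values. Stage locking uses a relative
tolerance of 1e-6 on `max(1, |z|)`; steady-state residuals at optima are
verified below 1e-6 · max(1, ‖v‖∞). Unbounded exchanges use ±1e6 rather
than true infinities so the parsimony objective stays finite.
Infeasible grid points (zero light, zero CO₂, zero nitrate at the
extreme ends of scans) are recorded with their status. Tests and the
acceptance script use reduced grids (3–6 points per axis) and the
bundled network, sizes chosen so the whole suite solves a few hundred
LPs of ~250 reactions each.
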