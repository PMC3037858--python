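# Methods

## The model

`tetopsim` simulates the class B (Tn10) tetracycline-resistance operon of
*E. coli* as a network of 40 species and 62 elementary irreversible reactions
(17 reversible steps stored as forward/backward pairs, 23 irreversible
mass-action steps, 5 delayed elongation steps).  The biology captured:

* **Repression.**  TetR dimerizes (equilibrium 1e8 M^-1); the dimer TetR2
  binds operator tetO1 (K ~ 1e12 M^-1), operator tetO2 (5x tighter), and the
  ~4e6 non-specific genomic sites (weakly, but they are many: roughly two
  thirds of free repressor is sequestered on chromosomal DNA).  tetO1
  occupancy silences all three promoters; tetO2 occupancy blocks the *tetA*
  promoter but leaves a reduced route to the *tetR* promoter tetP_R2.
* **Induction.**  Intracellular tetracycline (Tc) binds the two independent,
  non-cooperative sites of TetR2 — free or operator-bound — and the doubly
  loaded repressor falls off the DNA (dissociation 5.8e-3 1/s) and rebinds at
  a negligible rate.  Tc enters the cell by first-order diffusion from the
  external pool TcEx and leaves via TetA-mediated efflux.
* **Expression.**  RNA polymerase binds a promoter only when the overlapping
  promoter/operator cluster is free, forms a closed complex, opens it
  (0.013 1/s vs. 0.10 1/s dissociation, so ~11.5% of encounters transcribe),
  clears the promoter, and elongates.  Elongation of the whole transcript is
  drawn as one Gamma(number of nucleotides, 30 nt/s) delay — the sum of one
  exponential step per nucleotide.  Translation follows the same pattern with
  ribosomes at 100 codons/s (tetR: 621 nt / 207 aa; tetA: 1182 nt / 394 aa).
  A bookkeeping species `Complex` represents the locus when all five sites
  are free; its assembly reaction (1e8 1/s, treated as a plain per-second
  constant) and the four repressor-capture rewrites have no physical meaning
  and only keep the mutually exclusive occupancies consistent.
* **Turnover.**  TetR2 is degraded with a 5 h half-life, free or Tc-loaded
  (degradation of the loaded repressor releases its Tc); mRNAs decay at
  0.002 1/s; Tc photo-degrades very slowly; TetA is not degraded and is only
  diluted by division.

## The simulator

The engine is an exact SSA (direct method) over the mass-action reactions,
with three scheduled-event extensions handled by a priority race against the
next stochastic reaction: gamma elongation completions, cell division, and
dosing events.  Ties are resolved division > dose > completion > reaction.
Elongation-ready complexes (`RNAp*:DNA(..)`, `Rib*:mRNA(..)`) initiate the
moment they are created: the molecule is removed from the state, a completion
is scheduled one gamma delay later, and the polymerase/ribosome and product
reappear when it fires.  Conservation audits therefore count in-flight
machinery via the pending-completion queue, which trajectories record at
every grid point.

Cells divide every Normal(30 min, 4 min) interval (redrawn per division,
truncated at 1 s).  At division, proteins, protein:Tc complexes, mRNAs and
intracellular Tc are partitioned Binomial(n, 1/2) — a `floor(n/2)` mode
exists for ablation — while DNA sites, RNAp, Rib, anything containing them,
and the external pool stay with the tracked daughter.  Scheduled elongations
are retained (the machinery follows the tracked daughter).  One daughter is
followed, matching the study's single-cell trajectories.

The hot loop is numba-compiled; a NumPy fallback runs when numba is absent.
Each cell draws from its own stream seeded by `SeedSequence((master, index))`,
so ensembles are reproducible and order-independent.  Identical seeds give
bit-identical trajectories.

Only an exact-SSA engine is provided.  A hybrid jump/Langevin partition was
considered and dropped: at the copy numbers of this network (operators 0/1,
repressor ~ a few, peak TetA ~ hundreds) virtually no reaction qualifies as
"fast and abundant", so the partition degenerates to the exact algorithm.

## Units

The table of rate constants carries no printed units; the conventions here:

* unimolecular constants are 1/s;
* bimolecular association constants are M^-1 s^-1, converted to stochastic
  constants as k/(N_A V) (2k/(N_A V) with n(n-1)/2 combinations for the
  dimerization);  this is the only reading consistent with the stated
  equilibrium constants (e.g. dimerization 1e8 M^-1) and with the
  translation-yield calibration below;
* the four-reactant polymerase-recruitment step at the tetO2-repressed locus
  carries a single 1/(N_A V) factor, its three DNA-site reactants being 0/1
  indicator counts;
* gamma step rates are steps/s and gamma shapes are the nucleotide/codon
  counts of the two genes;
* the locus-assembly constant (1e8) is a plain 1/s bookkeeping rate;
* every constant's unit class can be overridden in configuration.

**Volume coupling.**  The cell volume is 1e-15 L at birth and doubles
exponentially over the cell's own division interval.  Whether bimolecular
propensities should track that growth is genuinely ambiguous: the
translation-yield calibration (mRNA decay tuned so ~20 proteins are completed
per transcript) is exact only with propensities fixed at the birth volume
(0.0498 initiations/s x 419 s lifetime = 20.9), while the reported
population dynamics (TetA transient peak ~113, TetR peak ~5, steady
TetR/TetR2 ~ 2/1) are matched distinctly better with volume-coupled
propensities, which yield ~15.5 proteins per transcript.  The default is
`volume_coupling="exponential"` (propensities re-read V at every event and
are piecewise-constant between events); `"fixed"` evaluates everything at the
birth volume.  The two conventions cannot both reproduce every printed
number; the acceptance report states what the default computes.

**The efflux constant.**  The Tc + TetA -> TetA efflux constant is printed as
1.  Under the molar convention its stochastic rate is ~1.7e-9 per pair per
second — dynamically negligible, so under a sustained external supply the
intracellular Tc level is set by influx versus division dilution (a few
hundred molecules) rather than by active efflux (the study reports a peak of
114 falling to 9).  Read instead as an already-stochastic per-pair constant
(1 1/s) it overshoots the other way, pinning Tc near zero.  Neither reading
reproduces the printed Tc numbers; the package defaults to the molar
convention and exposes `unit_class_overrides={"k61": "per_second"}` for the
alternative.  TetA and repressor statistics are essentially insensitive to
this choice because repressor loading, not efflux, gates induction.

## Protocols and statistics

All protocols start from the unexpressed state (zero proteins/mRNA/Tc,
300 Rib, 180 RNAp, one copy of each site, 4e6 nsDNA) and use a 60 s sampling
grid; dosing protocols run 5 h of warm-up before the perturbation, exactly as
the computational experiments are described, rather than restarting from a
saved stationary snapshot.  Default ensembles are 1,000 cells; the acceptance
checks run 100-200 cells and widen tolerances to +/-30% or three ensemble
standard errors.  "Steady state" is quantified as the time-average of the
population-mean curve over the final half of the horizon (the window is a
parameter).  Continuous administration clamps TcEx at the set level after
every event; the pulse mode simply increments TcEx.  `max_of_mean` reductions
break ties toward the earliest time; the population envelope uses per-cell
all-time extrema.  The translation yield is the pooled ratio of completed
peptide elongations to completed transcript elongations per gene.

## Degenerate inputs and numerical choices

Zero-valued rate constants are allowed (they silence a reaction); negative
overrides are rejected.  Division intervals are redrawn until positive.
Propensities are recomputed from scratch every event (62 reactions — cheaper
than a dependency graph at this size); the SSA exponential is redrawn after
every scheduled event, which is exact by memorylessness.  Sampling records
the pre-event state for grid points strictly inside an inter-event interval
and the post-event state at exact coincidences, so a dose administered on a
grid point is visible at that point.  Counts are 64-bit integers; a negative
count anywhere aborts the run as an internal error.

## Known limitations

* No Tc-ribosome binding, metal-ion:Tc complex, or TetA multimers (all
  explicitly out of model scope); no spatial effects; no extrinsic noise on
  rate constants; only one daughter lineage is followed.
* The printed polymerase-recruitment constant for the tetO2-repressed route
  (7.23e6) matches 84% of the *tetA*-promoter constant rather than 84% of
  the tetP_R2 constant that the accompanying text implies; it is encoded as
  printed and flagged, not repaired.
* The backward efflux step (4.9e-5 1/s per TetA) recreates intracellular Tc
  whenever TetA is present, Tc supply or not — encoded exactly as written;
  it contributes a trickle of a few molecules during TetA bursts.
* The unit ambiguities above mean the continuous-administration intracellular
  Tc statistics and the translation yield cannot all be matched by any single
  convention; defaults favour the reported population dynamics and the
  remaining discrepancies are reported as computed.
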