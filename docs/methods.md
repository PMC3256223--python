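# Methods

## The model class

`mirflux` simulates miRNA regulation embedded in a growth-factor signaling
pathway as a discrete-time hybrid Petri net. Places are typed molecular
species — genes, mRNAs, miRNAs, proteins, compounds, complexes, and
pseudo-objects (anti-miRNA oligonucleotides) — each holding a concentration
in nM; transitions are typed biochemical reactions. Formally the net is the
6-tuple (P, T, F, W, m, D): places, transitions, arcs, arc weights, marking,
and a per-species decay function.

Three motifs generate most of the network:

* **Gene expression.** Transcription is one-step basal expression (a single
  constitutive transcription factor is assumed, so transcription flux is
  proportional to the gene's clamped expression level). The nuclear
  transcript translocates to the cytoplasm, where it is translated; the
  cytoplasmic mRNA and the protein each own one explicit decay reaction.
  The nuclear transcript pool is drained by translocation and the
  background decay rather than an extra decay reaction, keeping the motif
  at 4 entities and 5 reactions.
* **miRNA biogenesis**, lumped to two reactions: transcription plus
  microprocessor (Drosha/DGCR8) cropping as one step, then nuclear export;
  the mature cytoplasmic miRNA decays.
* **miRNA-target binding**, lumped to one bimolecular RISC-style reaction:
  mature miRNA + target mRNA -> mRNA:miRNA complex. Silencing is
  stoichiometric sequestration — the complex decays, the miRNA is not
  re-released (catalytic silencing is not modeled; the choice is
  documented here because the alternative is equally defensible).

Anti-miRNA inhibitors are pseudo-object places whose concentration is an
experimental dial (clamped when dosed); one binding reaction per inhibitor
titrates its cognate mature miRNA into an inert complex with no downstream
activity. Families that act as one functional unit (MEK = MAP2K1 + MAP2K2,
similarly AKT, ERK, PKC, CAMK, CDKN1 and the mir-TRDD miRNA-gene set) are
*set entities*: a single simulated place carrying its member list as
metadata.

## Update rule

Each time step is synchronous:

1. every transition's speed is evaluated on the step's starting marking.
   The default rate law is mass-action-like,
   `v = k * prod(S_i^w_i) * prod(E_j^w_j) / (1 + 1.5 * sum(I_k))`,
   with substrates S, enzymes E and inhibitors I; a per-reaction
   `flux_override` can replace it (used to pin the worked example's flux).
2. fluxes are **rationed**: while any unclamped place's joint demand exceeds
   its marking, every flux drawing on the most oversubscribed place is
   scaled proportionally and demands are recomputed. This is
   order-independent and guarantees non-negativity. Clamped places are
   exempt — they are held reservoirs (ATP, ADP, EGF, gene levels), fixed
   precisely so that the pathway cannot stall on metabolite shortage.
3. input arcs lose `w*v`, output arcs gain `w*v`. Two catalysis
   conventions exist: the *consuming* convention (default,
   `consume_enzymes=True`) also moves mass along enzyme arcs and is the one
   that reproduces the printed worked example; the *conventional* one
   spares the catalyst. The in-silico studies run with conventional
   catalysis (`EXPERIMENT_CONFIG`): under the consuming convention a
   steady-state cascade transmits *flux* rather than concentration (each
   stage consumes exactly what the previous one produces), which erases the
   downstream effect of repressing an intermediate kinase — the phenomenon
   the threshold study measures.
4. background decay runs on two timescales: ordinary species lose
   `0.09 * base` every step; ligand-receptor complexes lose `0.2 * base`
   every 10th step. The decay base is the step's *starting* concentration
   for species that already existed and the post-firing concentration for
   species created this step — the only convention consistent with the
   printed worked-example table. Genes and inhibitor pools do not decay.
5. clamped species are reset to their clamp values.

Default rate constants per reaction type: complex formation (and both
binding reaction types) 0.55, phosphorylation 0.35, dephosphorylation 0.01
(0.15 when enzyme-catalyzed), transcription 0.5, translocation 0.8 (0.5 for
mRNA export), explicit decay reactions 0.02, inhibitory divisor parameter
1.5, everything else 0.35.

**Quasi-steady state** is judged over one full decay-policy cycle (10 steps
when a ligand-receptor complex is present): the slow decay arm makes the
attractor a 10-periodic orbit, so per-step deltas never vanish. A run
converges when the largest concentration change across one cycle falls
below 1e-9 nM; the default step budget is 500 (1000 for the experiment
config, since with conventional catalysis the ligand-receptor pool's only
loss is the slow decay arm, with a ~50-step time constant). All states that
are compared with each other are sampled at the same cycle phase.

## Study conditions

Simulations start from the published initial regime: EGF, ATP and ADP
clamped at 1 nM (the fixture also clamps the PIP2 lipid pool at 1 nM), all
other species at 0, gene expression levels clamped. Basal gene expression
defaults to 0.1 nM, putting steady-state transcripts in the tens of copies
per cell — the abundance regime of most mRNA species; at 1 nM the cascade
saturates, which both compresses the receptor dynamic range and lets
phosphatase disinhibition locally outweigh receptor repression. miRNA genes
default to 0 (experiments express one miRNA at a time); the default
over-expression level is 10 nM, the upper end of the physiological mRNA
range; the saturating anti-miRNA dose is 100x the miRNA gene level,
consistent with a 10–100 nM functional window for such inhibitors.

The four studies:

* **Over-expression**: one miRNA at a time versus the miRNA-free control;
  readouts are log2 ratios over all cytoplasmic mRNAs, with |log2| < 0.001
  masked (rendered white in heatmaps).
* **Dose scan**: steady-state readouts across a 0–10,000 nM miRNA
  gene-expression range.
* **Activation threshold**: the smallest receptor gene level (swept
  1e-4 – 10 nM) at which every chosen downstream readout exceeds the
  activation epsilon, 0.001 nM ≈ one molecule per cell. A
  fraction-of-maximum criterion is *not* the default: because repression
  rescales the whole response curve, a self-referenced criterion cancels
  the very effect the study measures.
* **Anti-miRNA screen**: each inhibitor alone, its cognate miRNA
  over-expressed; the control is the same over-expressed state without
  inhibitor. Effects are scored with a two-sided **paired t-test across
  all model components on log10 concentrations** (floored at 1e-6 nM, a
  sub-molecule detection floor). The pairing reflects that the same
  components are measured under two conditions; the log scale bounds the
  influence of any single large pool — on the linear scale the inert
  inhibitor:miRNA complex dominates the difference vector and drives the
  t statistic toward 1 for every inhibitor, erasing the dependence on
  target breadth. Ranking uses raw p-values at alpha = 0.05 (no
  correction), with Benjamini-Hochberg values reported in an extra column;
  ties break lexicographically.

## Synthetic data

The packaged fixture is a desk-scale EGFR pathway: EGFR + EGF ->
PI3K -> PIP3 -> PDPK1 -> AKT with AKT substrates (BAD, TP53, MDM2, CDKN1,
MTOR), a parallel MEK/ERK branch (targets ELK1, MYC, RPS6KA5), PTEN as the
PIP3-antagonizing phosphatase, a PIP3-driven PKC/CAMK side branch, and five
archetype miRNAs with their curated target sets (mir-192: 6 targets
including the receptor; mir-181c: AKT and MYC; mir-489: 4 targets;
mir-34a: 14 targets; the mir-TRDD set: the miRNA-biogenesis factors
TARBP2, RNASEN, DICER1, DGCR8). The fixture is frozen by checksum.

`random_network` draws signaling cascades (receptor, kinase chain,
peripheral substrates) with miRNA target sets from a truncated geometric
degree distribution — most miRNAs hit one or two genes, a tail hits many —
optionally biased toward cascade key nodes, and optionally containing a
strict superset/subset miRNA pair for matched comparisons. Generation is a
pure function of (parameters, seed).

What the generators do **not** emulate: transcription-factor-specific
regulation, phosphosite detail, receptor-family dimerization, measurement
noise, and cell-to-cell variability. Passing the property suite therefore
shows that the simulator and statistics behave as designed on networks of
this structure, not that the fixture quantitatively predicts any cell
line's response.

## Numerical choices

Concentrations never go negative (rationing plus clipping); log2 ratios
floor both numerator and denominator at 1e-12 nM so 0/0 comparisons read
as "no change"; the t statistic falls back to the smallest positive float
when the difference vector has zero variance but nonzero mean, and to
p = 1 when the two markings are identical. Simulations are deterministic;
repeated runs are bit-identical. Problem sizes in the shipped studies —
a ~165-entity fixture and 20 random networks of 10 genes and 6 miRNAs for
the screen property — were chosen as the smallest networks that exercise
every motif and leave the statistics well away from degeneracy.

## Known limitations

* The published full-scale model (901 entities, 1241 reactions, 241
  miRNAs, 417 binding reactions) and its exact rate law are not available;
  its census, its exact screen p-values (e.g. anti-mir-21 at 1.90e-06) and
  its 10 pM / 0.001 pM activation-threshold concentrations are therefore
  **not reproducible** here and are not asserted anywhere. The package
  covers them with structural substitutes: the desk-scale fixture
  properties, the stochastic screen-ranking property, and a census/SBML
  code path that recomputes the counts exactly when a user supplies the
  original model document.
* The printed flux formula and firing conditions of the source engine are
  not recoverable; the mass-action default here is an inference, and only
  the worked example's update arithmetic is verified exactly.
* Reaction speeds are unitless per-step rates; "one step" has no calibrated
  wall-clock duration, so dose-response positions are comparable within
  this model family but not across published timescales.
* ErbB2–4 dimerization and sequence-based target prediction are out of
  scope; targets come from the curated table only.
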