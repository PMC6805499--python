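# Methods

## Constraint-based model and FBA kernel

A metabolic model is a set of metabolites and bounded reactions with a
biomass objective. FBA solves max c·v subject to S·v = 0 and lb ≤ v ≤ ub
with `scipy.optimize.linprog` (HiGHS), primal/dual feasibility tolerances
10⁻⁹. A reported optimum must satisfy ‖S·v‖∞ ≤ 10⁻⁶ or the engine raises.
Only the optimal objective value μ is contract-stable; the returned flux
vector is one representative of possibly many alternate optima and no
secondary objective (flux minimization, pFBA) is applied. Infeasible
programs are returned as `status="infeasible"` with μ = 0 (distinctly
flagged); an unbounded objective is a hard error, because under the bounded
media constructed here it can only mean a mis-configured medium.

Growth threshold: μ < ε = 10⁻⁶ h⁻¹ counts as "no growth" everywhere
(configurable). The threshold sits far below any biologically meaningful
rate and far above LP solver noise (~10⁻⁹–10⁻¹²).

## Media as exchange bounds

Sign convention: an exchange written `A →` (coefficient −1) takes up at
negative flux, so an uptake limit u is applied as lower bound −u; the
secretion direction is never touched. Presets: `minimal_glucose` opens
glucose at 6.14 mmol/(gdw·h) and copper, cobalt, iron, protons, water,
sodium, nickel, ammonia, phosphate, sulphate and nitrate at 1000, closing
everything else; `rich` opens every non-O₂ exchange at 1000; the `oxic` /
`anoxic` overlays set only the O₂ exchange (≤ 18.5 / = 0) and leave other
exchanges untouched (`default_uptake=None` encodes overlay semantics).
Preset resolution matches exchanges by metabolite name/formula/id patterns
because compound identifiers differ between reconstructions; it is lenient
by default (unknown compounds are skipped with a logged warning) and
strict on request, and every resolved limit can be overridden explicitly.

## Essentiality scan

Deletion zeroes both bounds rather than removing the reaction, keeping
report indices aligned with the model. The scan enumerates reactions whose
stoichiometry touches an O₂ metabolite (detected by formula "O2", else by
id/name patterns, always overridable), deletes each on a fresh copy of the
medium-conditioned model, and records μ after deletion, the essentiality
verdict (μ < ε) and the O₂ role (consumes/produces/both, from the
coefficient sign). O₂ exchange and transport reactions are excluded by
default — deleting them just simulates anoxia — but flags include them.
O₂-producing reactions are scanned and labelled so users can filter. The
scan requires a growing baseline and raises otherwise, naming the baseline
μ.

## Intervention sets and the design grid

The built-in library ships as a JSON data file in the same schema users
can extend. Heterologous stoichiometries follow the named biochemistry
with quinol/quinone and reduced/oxidized thioredoxin couples; nitrate
reductase translocates 2 H⁺ per nitrate (a documented assumption), the
electrode sink is a bounded demand re-oxidizing quinol/NADH (default bound
1000), and RNR III carries a thioredoxin-recycling coupling reaction.
Species a host lacks are declared alongside the reactions and created on
addition (logged). Elemental balance is checked for C, N, O, P and S;
hydrogen/proton bookkeeping is deliberately loose, as is conventional for
lumped respiratory reactions.

The design grid expands the host with each combo (shared reactions such as
ACK inside NIKEL are added once), applies each condition, solves FBA and
classifies growth with half-open intervals: none = [0, ε), poor =
[ε, f·μ_ref), growth = [f·μ_ref, ∞), with f = 0.10 of the wild-type oxic
reference rate. The fraction is a free design choice — the source
distinction between "poor growth" and "growth" has no printed threshold —
and is configurable.

## Core-domainome subtraction

Domain presence is genome-level boolean (≥ 1 gene), InterPro accessions are
the comparison unit, and signature rows without an IPR mapping are dropped
and counted. The exclusive core is core(target) minus the union of the
background; containment in the target core and disjointness from every
background genome are asserted on every call. Categorization defaults any
unmapped accession to `unknown_function`; the shipped map covers only the
accessions with well-established roles (acetate kinase IPR000890 and the
RNR domains IPR012833/IPR012840 as ATP generation; siderophore-transport,
pilus-assembly and iron–sulfur-cluster domains as other), so real analyses
should supply their own table.

## Synthetic data: what it emulates, and what it does not

`make_toy_model` builds a deterministic 17-reaction network reproducing the
energetic logic of an obligate aerobe: lumped glycolysis (substrate-level
ATP s per glucose, 2 NADH, 2 acetyl-phosphate), an ETC reaction
(NADH + ½O₂ → NAD⁺ + P ATP), four O₂-dependent sole-producer biosynthesis
steps (heme-, NAD-precursor-, orotate-like and a class-I-RNR-like dNTP
step), fermentative NADH disposal, an overflow acetyl-phosphate
hydrolysis, a fixed maintenance drain M (lower-bounded, surplus burnable)
and a biomass reaction demanding D ATP plus the precursors. Defaults:
s = 0.5, P = 2, D = 10, M = 1, glucose cap G = 6.14 mmol/(gdw·h) (the
measured uptake rate also used by the medium preset). The parameters are
deliberately stylized — the toy reproduces *qualitative* structure (strict
aerobiosis, ATP-limited anaerobic growth, the acetate-kinase doubling),
not the absolute growth rates of any real reconstruction, and passing
tests on it demonstrate correctness of the algorithms, not predictive
accuracy on real GSMs.

The anoxic ATP budget is solved in closed form: with the four anaerobic
alternatives the growth rate is ATP-limited at μ_alt = (sG − M)/D; with
acetate kinase the acetyl-phosphate balance gives
μ_ack = ((s+1)G − M)/(D + c) where c is the total acetyl-phosphate demand
per unit biomass. The generator chooses c = D((1−s)G + M)/(2(sG − M)) so
that μ_ack = 2·μ_alt exactly, splitting c as b_p = c/2 direct precursor
and b_h = c/12 per O₂-dependent precursor (the alternatives cost 2·b_h
extra via fermentative redox disposal). Validity requires sG > M and
(1−s)G + M > 0; violations raise with the violated budget named. Because
the doubling is algebraic, tests can demand it to 10⁻⁸ without tuning.
Pseudo-formulas (ATP = "AP", NAD⁺ = "N", …) make every internal reaction
balance-checkable; exchanges and the biomass pseudo-reaction are exempt,
as is conventional.

`make_domain_tables` writes 6 target + 6 background genomes (defaults) in
the three-column simple_tsv dialect: 47 exclusive domains in all targets
and no background genome, a shared core (default 800) everywhere, and
noise domains (default 1200) included per genome independently with
probability 1 − dropout (dropout default 0.3, applying to noise only). Any
noise domain that by chance lands in all targets and no background is
forced into one background genome — part of the planted construction, so
the exclusive core is exactly identifiable for every seed. The generator
does not emulate InterProScan score columns, gene coordinates or
annotation noise correlated between genomes.

`make_random_model` emits small random bounded networks (≤ 10 reactions,
integer-ish coefficients, occasional forced fluxes that may create
infeasibility) for oracle-equivalence testing of the LP kernel against a
brute-force vertex enumerator: every LP vertex fixes at least
n − rank(S) variables at a bound, so enumerating all such fixings and
solving the residual linear system visits every vertex.

## Pipeline and reports

Stages run in order load → media sweep → O₂ scan → design grid →
domainome → combine; each stage is exactly the corresponding library call
(asserted by tests), and the combine step pairs each essential bottleneck
with design sets via a keyword-theme table (heme / NAD-precursor /
pyrimidine / dNTP), flags designs whose provenance notes an endogenous
alternative, and cross-references energy designs with shortlist domains
categorized as ATP generation. Reports are TSV/JSON; with a fixed seed a
re-run is byte-identical except the timestamped log.

## Numerical choices and limitations

* LP determinism: HiGHS on a fixed model is deterministic; μ is asserted
  reproducible to full precision, flux vectors are advisory.
* SBML serializes IEEE doubles as decimal text with 15 significant digits,
  so SBML round trips preserve numbers to ~10⁻¹⁵ relative; the JSON
  dialect round-trips bit-exactly.
* Gene–protein–reaction strings are stored (JSON) or carried through notes
  (SBML write) but never evaluated; deletions are reaction-level.
* No FVA/pFBA/MOMA/sampling; no thermodynamic or charge-balance curation
  of loaded models; double deletions are out of scope.
* Problem sizes used by the shipped tests and the acceptance script — a
  17-reaction toy, 120 random ≤ 10-reaction networks, 12 synthetic genomes
  with ~2000 domains — were chosen as comfortable desk-scale instances
  that the brute-force oracles can verify exhaustively.
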