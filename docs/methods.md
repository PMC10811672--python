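# Methods

This note records the models, conventions and numerical choices behind
`funcfix`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and residue model

Structures are read through gemmi (PDB and mmCIF) into a small internal
model: chains of polymer residues, each with the author residue number
(`auth_seq_id`, preserved verbatim) and a contiguous 1-based `seq_index`
assigned in file order. Masks and fixed-position JSON use `seq_index`,
because inverse-folding backends consume sequential numbering; reports show
both. Hetero groups (ligands, ions, waters) are kept apart from the
polymer. Alternate conformers are reduced to the highest-occupancy atom;
the first model of a multi-model file is used except in ensemble analysis.
Waters and monoatomic hetero groups are never offered as ligands unless
explicitly requested — a distance shell around a crystallographic water or
a counterion is almost never the intended design constraint.

## Design-space construction

**Ligand shell.** A residue is first-shell when any of its heavy (non-H)
atoms lies within the cutoff of any heavy ligand atom. Default cutoff:
7 Å. Contact distance between heavy atoms is the most literal reading of
"within *d* of the ligand" and is monotone in the cutoff, which the tests
exploit (shell(a) ⊆ shell(b) for a ≤ b). Cα-based variants were
deliberately not implemented; if a count calibrated against a particular
complex is needed, the cutoff is the knob to turn, not the atom rule.
When the ligand is itself a polymer chain (a peptide substrate), that
chain is excluded from its own shell.

**Conservation.** Column score = frequency of the parent's residue among
all rows, gaps in the denominator. This is the simplest statistic
consistent with "rank each amino-acid identity at each position by
conservation": it is bounded in [0, 1], equals 1 iff the column is
invariant at the parent residue, and needs no background frequencies.
Entropy-based alternatives can be added behind
`ConservationProfile.metric_name`; frequency stays the default because the
downstream operation (take the top p%) only consumes the ranking.

**Top-p% selection.** ⌈p/100·n⌉ positions, ties broken by ascending
index. Ceiling errs toward fixing more (function preservation over
aggressiveness); the deterministic tie-break makes selections nested in p,
so 30/50/70% runs produce nested masks by construction.

**Mask.** Union of selections (shell, conserved, catalytic, manual) with
merged provenance; the complement over the design chains is free. The
partition invariant (fixed ∪ free = all, fixed ∩ free = ∅) is enforced at
construction. Emission sorts keys and index lists, so identical masks are
byte-identical on disk.

## Triage

Superposition is the Kabsch algorithm: SVD of the cross-covariance of the
centered point sets, with the smallest singular direction flipped when the
optimal orthogonal map is a reflection, guaranteeing det(R) = +1. Fewer
than 3 points is rejected as under-determined. RMSD is always measured on
the residue selection it was superposed on — region-wise numbers never mix
a global fit with a local measurement unless the caller does so explicitly.

Filtering uses strict inequalities (mean pLDDT > 85.0, Cα RMSD < 1.0 Å by
default): a candidate exactly at a threshold fails. Mean pLDDT is the
unweighted mean of per-residue values — the community convention when a
single confidence number is quoted per model. Candidate models are
expected as PDB files with per-residue confidence in the B-factor column
(the structure-predictor convention); candidate and reference must have
equal length, since fixed-backbone sequence redesign preserves length, and
a mismatch raises rather than truncating silently.

## Kinetics

**Michaelis–Menten fit.** v = kcat·E·S/(Km+S), unweighted least squares
(no weighting scheme is standard for 8-point initial-rate tables).
Initialization is a deterministic multi-start: nine decade-spaced Km
guesses spanning 10⁻²–10²× the substrate range; the kcat guess inflates
the maximum observed rate by (Km₀+S_max)/S_max to correct for incomplete
saturation. The best converged start by SSR wins. Optimizer tolerances are
set to ~1e-14 so noise-free self-generated data is recovered to machine
precision (the test bound is 1e-6 relative). Standard errors come from the
Jacobian covariance; r² is 1 − SSR/SST. All-equal substrate levels raise
an unidentifiability error instead of returning a meaningless Km.

**Melt midpoint.** Two-state sigmoid between two linear baselines, six
parameters, fit by least squares; the midpoint Tm and its SE are reported.
Transition detection precedes fitting: if the residual span around a
single straight line is below 5% of the signal scale, the curve is
declared transitionless and the result carries `tm_lower_bound = T_max`
("still folded at the end of the scan") instead of a number — melting
temperatures beyond the scanned range are bounds, not estimates. If the
sigmoid fit fails, the maximum-|dS/dT| temperature is returned and flagged
`method="derivative"`. The detection statistic is scale-free, so Tm is
invariant to affine rescaling of the signal axis (raw ellipticity vs
normalized fraction folded).

**Rates and retention.** Initial rates are OLS slopes (scipy linregress)
over a time window given as a span or as an initial fraction; negative
slopes are reported as-is. Activity retention divides each rate by the
t = 0 rate; linear turnover is the OLS slope of cleaved fraction vs time.
Rates are kept in the units supplied (RFU/s stays "apparent" unless the
caller converts to μM·min⁻¹).

## Ensembles

RMSF is computed on Cα only — per-residue flexibility statements are
about the backbone, and side-chain RMSF needs rotamer bookkeeping that is
out of scope. Frames are superposed onto the first frame over the Cα
selection before RMSF; dyad distances are internal coordinates and skip
superposition entirely. The pLDDT ensemble profile uses the population
standard deviation (ddof = 0), documented so the two-model case
({80, 90} → sd 5) is unambiguous. The competence cutoff for the
Cys SG – His NE2 dyad defaults to 4.0 Å but is deliberately surfaced as a
parameter: published analyses rarely print their cutoff, and both the atom
pair (NE2 vs ND1) and the threshold are system-specific judgment calls.

Only multi-model PDB is parsed natively; binary trajectory formats are
expected to be pre-converted. This keeps the module dependency-light and
its fixtures plain-text.

## Synthetic data and what the tests show

The generators in `funcfix.fixtures` plant their truth and return it:

- **Toy structures** — ideal α-helix Cα traces (2.3 Å radius, 1.5 Å rise,
  100°/residue) with a pseudo-ligand placed radially at specified
  per-residue offsets; the generator records the realized minimum
  distances, so the shell at any cutoff is known exactly.
- **Toy MSAs** — per-column parent-identity frequency hit *exactly* by
  allocating matching rows (mismatches are substitutions or gaps), so the
  conservation round trip is exact, not statistical.
- **Rate tables / melt curves** — generated from stated (kcat, Km) or Tm
  with multiplicative (5% default) or additive (2% default) Gaussian
  noise. Defaults for the study-style fixtures: E = 0.5 μM, 8 substrate
  levels spanning 0.2–10 μM, Tm = 84 °C over a 20–95 °C scan.
- **Ensembles** — frames = base + isotropic per-residue N(0, σ²I)
  displacement; expected RMSF is σ√3·√((n−1)/n). Dyad distances are placed
  exactly at the mode values with exact frame allocation
  (round(fraction·n_frames)), so occupancy recovery is exact.

All generators take an explicit integer seed (`numpy.random.default_rng`)
and are byte-deterministic across runs and platforms.

These fixtures validate the *estimators*, not the biology: real rate
tables have correlated errors and substrate depletion, real melts have
sloping baselines and irreversibility, real MD ensembles have anisotropic,
correlated fluctuations, and real predicted models have structured (not
flat) confidence profiles. Passing tests show the statistics are computed
correctly and recover planted parameters under their own assumptions —
nothing more.

Problem sizes in the tests and acceptance script (8-point tables, 100
noisy refits, 50 melt curves, 500-frame ensembles, 20–30-residue toys)
were chosen as the smallest sizes at which the statistical tolerances are
meaningful.

## Known limitations

- The design and prediction networks are not invoked; pLDDT values in
  fixtures are planted, and numeric parity with any published pLDDT is
  not a goal (it would require the external predictor's weights).
- Conservation assumes the parent sequence aligns 1:1 with the design
  chain (position i of the profile = seq_index i); structures with
  unresolved residues need the alignment trimmed accordingly.
- The Michaelis–Menten fit assumes initial-rate conditions; no global
  progress-curve ODE fitting, no inner-filter or depletion corrections.
- The melt model is two-state; multi-domain or irreversible transitions
  will fit poorly (the r² and SE output are the diagnostic).
- No structure validation or repair; malformed files fail loudly rather
  than being fixed up.
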