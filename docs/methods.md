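# Methods

## Electron-equivalent accounting

The balance layer treats the biocathode as a continuous stirred reactor
at steady state. A reduction product leaving in the effluent at
concentration c (µmol/L) carries an electron flux of
`f · c · Q / Vc` µeq L⁻¹ d⁻¹, where f is the stoichiometric electron
demand per mole of product and Q/Vc is the dilution rate referenced to
the *empty* cathode-chamber volume. The demands are fixed by redox
stoichiometry: 2, 4, 6 and 8 electrons per mole of cis-DCE, VC, ethene
and ethane formed from TCE; 3 per Cr(VI)→Cr(III); 8 per CO₂→CH₄.
Dechlorination intermediates are additive, so the RD rate is the
factor-weighted sum over the four products; analytes missing from a
sample are treated as zero (absent, not below-zero placeholders).

A rate converts to its current equivalent as
`I[µA] = r · Vc · F / 86 400` (µeq d⁻¹ → µC s⁻¹), and the Coulombic
efficiency of process i is `CE_i = I_i / I · 100 %` against the measured
mean cell current. The methane-specific form
`I[mA] = Q · 8 · [CH₄] · F / 86 400` is algebraically identical (Vc
cancels); both routes are kept and asserted to agree to 1e−12 relative
as an internal consistency check.

**Rate units.** r is an electron-equivalent rate (µeq L⁻¹ d⁻¹)
throughout, not a compound molar rate. This is the only reading under
which the CE expression is dimensionless and the published efficiency
partitions close; the package therefore standardizes on it.

**Closure at reporting precision.** CE-excess is defined as
100 − Σ CE_i, a residual capturing electron sinks not in the product
slate (H₂ efflux, biomass). Reported CEs are quantized to a configurable
number of decimals (default 2, the finest resolution such partitions are
customarily reported at) and the excess is computed from the quantized
components with `decimal.Decimal`, making the identity
`Σ CE + CE-excess = 100` exact rather than float-approximate. Raw
unrounded CEs are retained alongside (`ce_raw`). A negative excess
(over-closed balance from measurement error) warns and is reported
as-is, never clipped.

**Averaging.** Run summaries use equal-weight arithmetic means of each
analyte and of the current over the requested time window; no
flow-weighting is applied because sampling is assumed proportional to
operation time. A series without a current column yields rates only,
with CE fields set to None rather than guessed.

**Henry partitioning.** Dissolved CH₄ may be entered directly or derived
from a headspace partial pressure as `c = K_H · p`; the default
`K_H = 1.4e−3 mol L⁻¹ atm⁻¹` is the room-temperature (25 °C) methane
solubility and is a config field since operation temperature varies.

**Reactor defaults.** Q = 0.58 L d⁻¹ and Vc = 0.821 L (HRT ≈ 1.42 d).
Vc is configuration, never hard-coded in formulas, because what counts
as "empty" volume (granule and electrode displacement) is
apparatus-specific.

**Reconstructed run fixtures.** `becath.datasets` ships two steady-state
operating conditions (TCE-only and TCE/Cr(VI) feeds). Published
characterizations of such runs report rates and efficiencies but not the
raw current, so the fixtures back-solve: the current from the RD rate
and CE-RD, then CH₄ and removed-Cr(VI) concentrations from their CEs at
that current. The dechlorination product pool is split 80/15/5 %
(VC/ethene/ethane by electron equivalents), a typical partially
dechlorinating effluent. Every output of the balance layer on these
fixtures is recomputed through the same public operations used for real
data; only the inputs are constructed.

## Capability profiling

Verdicts are decided from annotation text only (gene symbol + product
string), mirroring how published genome screens of such consortia are
tabulated. There is no homology search; percent identity is carried as
metadata and never thresholded — screens of this kind call genes present
at identities well below 50 %.

Normalization: symbols are lowercased and compared exactly (or by prefix
where a gene family/operon is the unit); products are lowercased,
punctuation-stripped and whitespace-collapsed before substring matching,
since mixed GenPept/Prokka styling ("ABC-transporter ATP-dependent" vs
"ABC transporter ATP-binding protein") differs only in punctuation.

Design choices where annotation practice is ambiguous:

- **Dehalogenase classes** are assigned with precedence anchor rdhB >
  haloacid > catalytic rdhA > hypothetical, each record counted once.
  The precedence is needed because every class keyword contains
  "dehalogenase"; it puts the most specific pattern first.
- **CRISPR-Cas** requires a cas-family symbol or a "CRISPR-associated"
  product; regulators such as LexA-family transcription factors are
  reported as auxiliary evidence but never sufficient alone.
- **Module completeness** is the fraction of pathway blocks with ≥1
  alternative present. Block boundaries for M00122 (6 cob blocks),
  M00924 (16 blocks: cysG, cbiC/D/E/G/L/M/Q/T, cfbA, cobI/M/J/K/H/B) and
  M00567 (10 blocks: fwd, ftr/fhcD, mch, mtd, mer, mtr, mcr, frh, mvh,
  hdr) are shipped as YAML catalogs — data, not code — because module
  definitions name genes but leave alternative-grouping open; an
  alternative blocking changes the denominator, not the hit logic.
  cbiD/cbiE found in a downstream-only genome count toward upstream
  completeness as ordinary block hits; no upstream/downstream boolean is
  forced from them.
- **Hydrogenase complexes** match on symbol prefixes against the whole
  symbol string, so a fused annotation like `hypC/hybG/hupF` counts only
  toward Hyp — a genuine hup gene (e.g. hupL) is still detected. This
  keeps the uptake-hydrogenase-absent verdict reproducible from tables
  that use fused symbols.
- **Cr(VI) machinery**: extracellular requires the complete mtrA+mtrB+
  mtrC conduit *and* ≥1 c-type cytochrome; intracellular requires ≥1 ABC
  ATP-dependent component, ≥1 ABC permease and an NADPH-dependent
  F420/FMN reductase (npdG). Conjunctions of presence predicates keep
  all verdicts monotone under record addition — a property the test
  suite asserts.

All verdicts are order-independent and deterministic; profiling the same
records twice yields byte-identical JSON.

## Synthetic data

`generate_series` draws each analyte i.i.d. Normal(mean, cv·mean),
truncated at zero, plus a current trace of the same form; defaults are
the TCE/Cr(VI) run conditions with cv = 0.05 and n = 50 samples. The
truncation introduces a small upward bias at cv ≳ 0.3 (irrelevant at the
default 5 %). The generator models no autocorrelation, drift, start-up
transient or sensor dropout — real monitoring data have all four — so
passing recovery tests demonstrate correct steady-state estimation, not
robustness to instrument pathologies.

`generate_genome` plants exactly the markers a requested capability
profile needs (one alternative per required block) plus decoy genes from
a fixed neutral vocabulary; at generation time the decoys are re-checked
against the loaded catalogs so vocabulary and catalogs cannot drift into
collision. Contradictory requests (a capability whose markers are
forbidden by the profile's symbol blacklist) raise. Mock genomes have no
operon structure, paralogs or partial gene calls.

`generate_asv_table` draws per-sample compositions from a symmetric
Dirichlet (concentration 0.8, giving the uneven communities typical of
biofilms) scaled to 100 %, with lineages cycled from a bundled pool of
the key biocathode taxa.

## Verification strategy and problem sizes

- Hand-arithmetic oracles freeze expected values for every rate/current
  operation (e.g. (4·30+6·5)·0.58/0.821 ≈ 105.97 µeq L⁻¹ d⁻¹).
- Property tests: homogeneity of rates in concentration and flow,
  additivity of CE over processes, exact decimal closure on 1,000 random
  component sets, unit-factor identities.
- The capability profiler is checked against a brute-force oracle —
  independently coded naive loops with hardcoded gene lists — on 100
  random genomes of ≤50 records, and for monotonicity on 200 random
  record-addition cases.
- Monte-Carlo CE recovery uses 200 replicates of 50-sample series at
  cv = 0.05 and asserts the mean recovered CE lies within ±3 standard
  errors of the generating truth (the ratio-of-means estimator's bias is
  O(cv²/n), far below that band).

These sizes keep the full suite under ~10 s while leaving each
statistical check adequately powered.

## Known limitations

- The balance is stoichiometric accounting only: no electrochemical
  kinetics, no H₂-evolution model, no gas-phase mass balance beyond the
  single Henry step; CE-excess is a residual, not a mechanistic estimate.
- Capability calls inherit the annotation's vocabulary; a genome
  annotated with unusual product phrasing needs catalog edits (YAML)
  rather than code changes.
- Module completeness treats blocks as independent presence checks; it
  does not score gene copy number, synteny or operon integrity.
- The removed-Cr(VI) concentration requires either an influent value or
  an effluent column interpreted as "removed"; the two conventions are
  documented on `summarize_run` and chosen by the caller.
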