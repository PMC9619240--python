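# Methods

## The screening procedure

`tadfscreen` implements an evolutionary high-throughput virtual screen for
organic thermally activated delayed fluorescence (TADF) emitter candidates.
The figure of merit is the vertical singlet–triplet gap ΔE_ST: molecules
with ΔE_ST below a small threshold (default 0.15 eV) can thermally
up-convert triplet excitons and are counted as "optimal". The loop over a
compound library G_n is:

1. **Generation 0.** All donor × acceptor couplings of a fragment set are
   enumerated (one single bond between the two attachment points), deduped
   by canonical SMILES, and capped (default 10³) by seeded uniform
   subsampling.
2. **Training draw.** A random fraction (default 10%) of the library is
   evaluated by the property engine.
3. **Surrogate fit.** Two random-forest regressors on 2048-bit radius-2
   binary circular fingerprints (the conventional ECFP4 configuration) are
   fit on the evaluated subset — one for ΔE_ST, one for the vertical S1
   energy E_S1 — with hyperparameters picked by 5-fold cross-validated grid
   search.
4. **Prediction.** Both properties are predicted for the *entire* library,
   training molecules included, so selection ranks everything on one scale.
5. **Analytics.** Per generation the loop records the material abundance
   ω_MA (fraction of the library with predicted ΔE_ST strictly below the
   threshold), the library-mean aromatic C–H count n_aCH, the mean
   predicted gap, an emission-color sieve on predicted E_S1 (blue > 2.80 eV,
   red < 2.50 eV, green in the closed interval between), Murcko skeleton
   frequency tables (common cores keep element/bond identity; generic cores
   erase both), and the similarity of the library to its predecessor
   (n_inter and Δ_MSPR, below).
6. **Accumulation.** Molecules with predicted gap below the threshold join a
   monotone accumulator set (union semantics, so the count never decreases).
7. **Selection + mutation.** The max(1, ⌊fraction·n⌋) molecules with the
   smallest predicted gap (ties broken lexicographically on canonical
   SMILES) become parents; the next library is parents ∪ all their mutants,
   deduped, capped with parents always retained.
8. **Termination.** At `max_generations`, or when a convergence target on
   the accumulated count and/or the abundance is met ("any" / "all" logic,
   default any).
9. **Final ranking.** Accumulated optimal molecules are ranked by ascending
   synthetic accessibility score (SAS, fragment-contribution scale ≈1
   easiest … ≈10 hardest; ties by ascending gap, then SMILES), because
   repeated framework mutation can drift into formally optimal but
   practically unmakeable structures.

## Mutation operators

Mutations act only on aromatic C–H positions (aC–H):

| Label | Operation | Sites per offspring |
|-------|-----------|---------------------|
| Sub1  | aC–H → aromatic N (slow) | 1 |
| Sub2  | aC–H → aromatic N (fast) | up to 2 |
| Sub3–Sub6 | aC–H → aC–G, G = F, CN, OMe, NMe₂ | 1 |
| Sub7–Sub10 | G drawn per site from F\|OMe, F\|NMe₂, CN\|OMe, CN\|NMe₂ | 1 |

Products failing RDKit sanitization are discarded (adjacent-N products such
as pyridazine are legitimate and kept); the parent never appears among its
own mutants. Substituent groups introduce only aromatic-inert hydrogens, so
a site, once substituted, is consumed — the library-mean n_aCH therefore
declines across generations in expectation. An exhaustive subset mode
substitutes every subset of sites at once; on biphenyl with F it maps the
2¹⁰ = 1024 position-labeled patterns onto exactly 210 distinct molecules, a
count independently confirmed by Burnside's lemma on the molecular-graph
automorphism group in the test suite.

## Property provision

Real excited-state quantum chemistry sits behind an engine contract
(`engine(smiles) -> PropertyResult`); the package ships the contract, a
file-based table stub, and a deterministic **synthetic oracle** used for all
desk-scale runs:

```
gap  = clamp(g0 − w_sub·n_sub − w_N·n_aromN − w_amine·n_diarylN + ε,  0.01, 1.5)
e_s1 = clamp(s0 − w_red·(n_aromN + n_strong) + ε′,                    1.50, 4.00)
```

with defaults g0 = 0.70 eV, w_sub = 0.06 (per F/CN/OMe/NMe₂ substituent on
an aromatic carbon), w_N = 0.05 (per aromatic ring nitrogen), w_amine = 0.10
(per non-aromatic diarylamine nitrogen), s0 = 3.30 eV, w_red = 0.08,
n_strong = NMe₂ + diarylamine count. ε is a zero-mean pseudo-noise of
amplitude 0.05 eV computed from a SHA-256 hash of the canonical SMILES, so
results are bit-reproducible and independent of evaluation order. Feature
counts come from SMARTS matching, deduplicated on the pivotal atom so
symmetric patterns are not double-counted.

Batch evaluation is gated by a completeness policy: the geometry success
fraction must reach 0.80 and the full-property success fraction 0.90,
otherwise the batch raises a completeness failure naming both achieved
ratios and the generation. A Kabsch RMSD utility (minimal RMSD over rigid
motions, via the standard SVD solution) supports geometry comparison
between engine back-ends.

## Group similarity (Δ_MSPR)

Two libraries of comparable size are compared by the Maximum Similarity
Pairing Rule: compute all cross-pair Tanimoto similarities on ECFP4
fingerprints, then repeatedly take the globally highest-similarity pair
whose members are both unused, until the smaller library is exhausted;
Δ_MSPR is the mean similarity over the pairs. Ties are broken on the
lexicographic order of the *unordered* SMILES pair, which makes the index
exactly symmetric in its arguments. Shared molecules pair at similarity
1.0, so Δ_MSPR ≥ n_inter / min(|A|, |B|), and converging libraries drive
Δ_MSPR toward 1. Greedy pairing is the contract; an assignment-optimal
variant (Hungarian algorithm) is available as a diagnostic and is never
below the greedy mean. For very unequal sizes the unpaired excess of the
larger library is ignored.

## What the synthetic data emulates — and what it does not

The shipped fragment pools (30 donors, 43 acceptors, one attachment point
each) span the usual TADF chemotypes: carbazole, phenoxazine,
phenothiazine, acridine and diarylamine donors; cyano, sulfonyl, carbonyl,
triazine, CF₃ and phosphine-oxide aromatic acceptors. They are a synthetic
stand-in, curated so that the generation-0 library under the oracle
defaults starts at a mean gap of ≈0.57 eV with essentially no optimal
molecules — the regime in which selection pressure, not the starting
library, must produce the enrichment. With these conditions the seeded toy
run (Sub3, cap 1000, 6 generations) reproduces the qualitative
phenomenology of a real screen: abundance rising by orders of magnitude,
mean gap collapsing toward the threshold, skeleton frequencies
concentrating, and Δ_MSPR climbing toward 1.

What passing these runs does *not* show: the oracle is an additive
substituent model with bounded hash noise — it has no conformational
effects, no charge-transfer physics, no failure modes (every molecule
evaluates), and its landscape is far easier for a fingerprint regressor
than TD-DFT labels would be. Quantitative trajectories (the exact abundance
or gap values per generation) are properties of the toy conditions, not
predictions about any quantum-chemistry-driven screen.

## Numerical choices

- Selection and training-draw sizes use max(1, ⌊fraction·n⌋).
- The sieve's boundary energies (exactly 2.50 or 2.80 eV) are green: the
  green band is the closed interval.
- Abundance and accumulation thresholds are strict (`gap < threshold`).
- Tanimoto of two all-zero vectors is defined as 0.
- One run seed feeds named substreams (library sampling, training draws,
  cap sampling, surrogate fitting) via `numpy` seed sequences; per-
  generation seeds are derived by offset, all below 2³¹.
- The surrogate grid is {100, 300} trees × max depth {None, 10, 20},
  scored by negative MSE over 5 shuffled folds; forests use
  `max_features=0.5` — square-root subsampling underfits badly on
  2048-bit sparse binary features at n≈100, while half-width split search
  is accurate and still cheap.
- Trajectory CSVs are written with 17 significant digits and read with
  round-trip float parsing, so serialization is lossless.
- Molecules failing sanitization are rejected at ingest or silently dropped
  only where the contract says so (mutation products); batch evaluation
  never drops molecules.

## Problem sizes

Desk-scale defaults mirror the screening conditions: library cap 10³,
10% training and selection fractions, 0.15 eV optimality threshold,
2.50/2.80 eV sieve, completeness 0.80/0.90. The test suite exercises the
full loop at cap 1000 for 6 generations (twice, for bit-reproducibility)
and a smaller cap-300, 2-generation configuration for unit-level checks.

## Known limitations

- The fragment pools are not any published ESI set; content-dependent
  conclusions (e.g. which skeleton dominates) are fixture properties.
- Only single-attachment D–A frameworks are supported (no D–π–A, D–A–D,
  crossover operators, or multi-objective sieving).
- The greedy MSPR reconstruction is one reading of "maximum similarity
  pairing"; the assignment-optimal variant is provided for sensitivity
  analysis.
- Predictions for quantum-evaluated molecules are *not* overridden by their
  computed values: selection uses predicted values uniformly.
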