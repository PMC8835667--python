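# Methods

This note documents the models, the parameter choices that matter, what the
synthetic generators do and do not emulate, and the numerical conventions —
in enough detail to re-derive the package's behaviour without reading the
code.

## The KRAB coordinate frame

All positional reasoning uses per-subdomain 1-based coordinates: A1–A42 for
KRAB-A and B1–B35 for KRAB-B, with every A position ordering before every B
position. Ancestral-type (aKRAB) domains are one residue short at A32 — the
alignment gap opposite the modern MLE motif. We represent this as an
*unmapped coordinate*: the stored residue string is always ungapped, and the
coordinate map simply has no entry at A32. This keeps string manipulation
(scoring, editing) free of gap characters while preserving cross-family
position arithmetic; the boundary between 1-based frame coordinates and
0-based string indices is crossed only inside the coordinate map.

Ambiguity codes (B, Z, U and X itself) are accepted on input and treated as
X: they occupy alignment columns (and thus count toward occupancy and
denominators) but contribute neither to emission counts nor to frequency
counts, and they score as the background under every model, i.e. neutrally
in log-odds.

## Profile HMMs

### Architecture

The model is the classic match/insert/delete plan with one node per
consensus column, in a local-in-sequence, global-in-model mode (domain-scan
semantics): flanking N and C states absorb unaligned sequence, while every
model node must be traversed by a match or delete state. There is no
multi-hit (J-state) circuit, no insert-to-delete or delete-to-insert edge,
and no insert state after the last node. N and C self-loop with the same
geometric length parameter as the null model, p = T/(T+1) for a sequence of
length T, so background-typical flanks shift the bit score only through the
fixed entry/exit transitions (bounded drift; verified empirically in the
tests).

Scores are log2 odds against a null that emits every residue from the
background composition with the same geometric length model. Forward sums
over all alignments; Viterbi takes the best one and decodes its path. Both
recursions are validated to 1e-9 against explicit enumeration of every legal
state path on small models.

### Estimation

- **Match columns**: alignment columns with residue occupancy ≥ 0.5 (the
  "remove mostly-empty columns" convention, configurable).
- **Emissions**: background-proportional pseudocounts with total weight 1.0
  per column, `(count + w·q) / (n + w)`. Dirichlet mixture priors would be
  marginally better at very small counts but are unnecessary at the group
  sizes involved here.
- **Transitions**: counted from each row's match/delete/insert usage with
  Laplace (+1) smoothing. The topology has no insert-after-delete path;
  the rare alignment rows that would need one are counted as if the insert
  were entered from the preceding match (their emissions still count).
- **Background**: uniform 1/20 by default. The original curation used an
  unstated null composition; uniform is the neutral choice and an
  alignment-derived composition can be supplied instead.

### E-values

Significance is calibrated per model by scoring `n_samples` background
sequences (default 200, drawn at the model's match length) and fitting a
Gumbel location/scale by maximum likelihood (`scipy.stats.gumbel_r.fit`).
Then `E(s) = n_db · (1 − exp(−exp(−λ(s − μ))))` with `n_db` defaulting to
the catalog size of the scoring run, mirroring database-conditional
E-values. Parameter recovery is tested (λ within 10% at n = 2000) and the
fitted tail is checked against empirical null quantiles.

Two caveats are deliberate: the forward score of a *whole* random sequence
is not a true per-domain maximum, so the Gumbel is an approximation adopted
as the package's convention; and no attempt is made to reproduce HMMER2
E-values numerically. All conclusions that depend on scores are therefore
rank/ordering-based (which model scores best; whether groups separate), not
value-based.

## Stratification

E-values at or above the curation floor (0.01) are clamped to the floor
before the −log10 transform, so no transformed score falls below 2.0;
clamped cells carry a flag and render as "<2" in report tables. Ranges in
summaries are computed on the clamped values (a clamped minimum therefore
prints as "<2"). Subgroup assignment takes the best clamped score; a strict
tie at the top — including the all-clamped row — yields "unknown" rather
than an arbitrary label, with margin 0.

The two-sample test is a two-sided Wilcoxon–Mann–Whitney implemented
in-repo: exact enumeration of all group assignments when both samples have
at most 8 values (two-sidedness by deviation of U from its mean, which for
untied data coincides with the doubled-tail convention), and a tie- and
continuity-corrected normal approximation otherwise. The exact branch is
tested against independent enumeration and against scipy; the approximation
agrees with the exact value within 0.02 at the 8+8 boundary. Two equal
constant samples return p = 1 by convention.

Curation follows the published two-threshold scheme: a permissive pass
removing entries with E ≥ 0.01 against a pooled model, and a strict pass at
E ≥ 1e-10 for truncations and spurious hits; both are exclusive at the
boundary (an entry exactly at the threshold is removed). Within-species
deduplication collapses identical domain sequences per species, keeping the
first entry and recording the merged ids; identical sequences in different
species are never merged.

## Logos and frequency tables

Column conservation is relative entropy in bits against the background,
computed from raw frequencies without pseudocounts; letter heights are
`IC · p_a` so each column's stack sums to its information content. No
small-sample correction is applied — the groups of interest are large and
the upstream logo service applies none visibly; the omission matters only
for groups of a handful of sequences. The manual display gap drawn at A32
in ancestral logos is a rendering concern; matrices keep the true columns.

Positional frequency tables report (count, denominator) per query and
subgroup, where the denominator is the number of sequences with any residue
at that column. B-subdomain positions are counted in all sequences of a
group whether or not a conserved KRAB-B exists there, matching the published
counting convention.

## The mutagenesis roadmap

Edits are data, not code: a packaged YAML roster of named scripts relative
to named wild-type A domains. An edit addresses a coordinate span
(`A27:R>V`, `A32-A34:KR>MLE`) and must match the currently mapped residues
in that span, so stale coordinates are refused with a position report.
Replacement conventions: when the replacement is shorter than the span, the
residues occupy the span's *last* coordinates (the gap leads, as in the
ancestral alignment) — inverting the MLE insertion therefore restores
gap-KR exactly; when longer, the leading residues take the span coordinates
and the surplus trails unmapped (an insertion after the span). The
double-proline helix breaker is modeled as the block replacement
`A33:L>LPP`, which keeps scripts non-overlapping while placing PP before
E34.

Constructs whose composition is stated in running text (P9Am1, P9Am10–13,
ZNF10Am1, ZNF10-PP) are fully specified; P9Am2–P9Am9 and the extended-A
variants are known only from a figure and ship as stubs that refuse
application rather than guess. Wild-type "stand-ins" are synthetic:
generator-consensus sequences with the roadmap-relevant residues forced
(S9/M20/R27/SIY and gap-KR for the PRDM9-like domain; F9/FVD/L20/V27/VMLE
for the ZNF10-like domain). They exercise every script without a fetch
step; they are not the database accessions.

## Helix geometry

Helix detection is CA-only (P-SEA-style): a window at residue i is helical
when |CA(i)−CA(i+3)| ∈ [4.6, 5.8] Å and |CA(i)−CA(i+4)| ∈ [5.6, 6.8] Å;
windows mark five residues, maximal marked runs of ≥ 5 residues become
segments, and fits with a per-residue rise outside (0.5, 2.5) Å are
discarded. No hydrogen-bond or DSSP machinery is used, keeping the module
dependency-free; the thresholds are configurable.

Axis fitting is two-stage. The seed direction comes from second differences
of the CA trace (which point radially toward the axis) via their pairwise
cross products; it is then polished by least-squares cylinder fitting
(minimizing the spread of CA-to-axis distances over direction and in-plane
offset, in the centroid frame). The polish is exact on noise-free helices
and keeps the axis within ~1.5° of truth under 0.2 Å Gaussian coordinate
noise. The axis origin comes from a least-squares circle fit of the CAs
projected onto the normal plane; rise and twist are the mean axial advance
and the mean signed angular step per residue, right-handed about the N→C
axis direction.

The register-shift measurement superposes structure b onto structure a over
an anchor of shared helix residues (Kabsch, proper rotation enforced), fits
the axis on a's anchor, and reports the signed angle between the two
probes' CA→CB directions after projection onto the axis-normal plane. For
glycine probes a CB is constructed tetrahedrally from N/CA/C with the
standard idealized coefficients, preserving L-chirality. On an ideal
100°/residue helix, inserting one residue upstream of the probe yields
exactly 100° — the analytic sibling of the ~97° side-chain reorientation
between KRAB models with and without A32/M. The anchor and probe for
reference-model comparisons (anchor = helix-2 N-terminal residues A23–A31
upstream of the indel, probe = A39) are a documented convention, since the
original choice is unstated; both are caller-configurable. pLDDT values in
B-factor columns are parsed and reported but never used to filter.

## Synthetic data

The generators emulate the *statistical signature* of the four KRAB
subgroups, not their phylogeny. A shared scaffold consensus over the
77-position frame is drawn once from a fixed seed; each group redraws a
fixed ~30% of positions with its own seed (related but separable families);
hallmark motifs are planted on top (modern: A7-8/DV, A31-34/VMLE,
B13-14/LE, B19-20/PW; ancestral: A7-8/DI, gap-KR at A32–A34, P..FM around
B7-B10; coelacanth-like: B5-10/PKPDFM and A34/E; PRDM9-like: B31/W), and
ancestral generators never emit at A32. Motif positions carry 0.9 consensus
mass (the tall logo letters), scaffold positions 0.5 (moderate
conservation) — chosen once to approximate the published logos' contrast
without claiming their exact frequencies. Divergence mixes each position's
distribution toward uniform; indels are off by default, as real KRAB
domains have a well-defined size, so sampled catalogs stay on the fixed
frame.

What this does **not** emulate: phylogenetic correlation among species
(entries are i.i.d. given their group), compositional bias of real
proteomes, fragmentary or truncated database entries, and within-group
rate variation beyond the single divergence knob. Passing the recovery
tests therefore demonstrates that the pipeline's machinery is correct and
well-calibrated on data of the stated structure — not that real curated
compilations will separate as cleanly.

Helix fixtures are ideal (CA on a regular helix, default 1.5 Å rise, 100°
twist, 2.3 Å radius; CB radially outward) or composites of such helices
joined by straight 3.5 Å-spaced coil linkers, whose inter-axis angles are
known by construction.

## Problem sizes and determinism

Every stochastic step takes an explicit seed and is bit-reproducible; the
pipeline report records all seeds and thresholds, and re-running from a
report reproduces outputs exactly. The standard study condition used by the
recovery checks is 4 groups × 50 sequences at divergence 0.1 with
half/half train–test splits and 200-sample calibration — large enough that
classification accuracy and group separation are stable across seeds,
small enough that the whole suite runs in about a minute. Path-enumeration
validation uses models of ≤ 3 nodes and sequences of ≤ 4 residues, where
the number of legal paths is in the hundreds.

## Known limitations

- E-values are internally consistent but not comparable to HMMER's; use
  rankings, not absolute values, across software.
- The Gumbel is fitted to whole-sequence forward scores (see above).
- The exact WMW branch is O(C(n_a+n_b, n_a)) and is capped at 8+8.
- Helix detection reports no per-residue confidence and will fragment
  strongly bent helices (by design: the inter-segment angle is the
  measurement of interest).
- The edit engine refuses, rather than re-anchors, scripts whose wild-type
  residues do not match; this is intentional protection against applying a
  roadmap to the wrong ortholog.
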