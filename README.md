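# krabstrat

Stratification of **ancestral vs modern KRAB domains** — a reusable, tested
pipeline for sequence analysts working on Krüppel-associated box (KRAB)
zinc-finger proteins.

The KRAB domain is the repressor module of the largest transcription-factor
family in tetrapods. Its modern form (mKRAB, e.g. human ZNF10) silences
transcription by recruiting TRIM28/KAP1; its ancestral relatives (aKRAB, found
in PRDM9 and SSX proteins and in coelacanth KZNFs) do not. The two classes
differ by a handful of residues, most tellingly a one-residue gap: aKRAB-A is
one amino acid short at position A32, where mKRAB-A carries the conserved MLE
motif (A32–A34). This package implements the computational side of dissecting
that difference:

- **Profile HMMs** (`krabstrat.hmm`): build from alignments
  (match/insert/delete plan, background-proportional pseudocounts), score
  sequences by forward and Viterbi log-odds in a local-in-sequence /
  global-in-model mode, and calibrate E-values with a Gumbel
  (extreme-value) fit to null scores:
  `E(s) = n_db · (1 − exp(−exp(−λ(s − μ))))`.
- **Subgroup stratification** (`krabstrat.stratify`): cross-score a catalog
  against a model panel, clamp E-values ≥ 0.01 to a −log10 score of 2 before
  computing medians, assign each entry to its best-scoring model, summarize
  per-group medians/ranges, and compare groups with a two-sided
  Wilcoxon–Mann–Whitney test (exact enumeration for samples of ≤ 8 values,
  tie-corrected normal approximation above).
- **Sequence logos and frequency tables** (`krabstrat.logo`): per-column
  information content above background, `IC = Σ_a p_a log2(p_a / q_a)` bits,
  with letter heights `IC · p_a`; removal of mostly-empty columns; and
  positional residue counts per subgroup (the "interaction code" readout).
- **Mutagenesis edit scripts** (`krabstrat.mutagen`): the aKRAB→mKRAB
  roadmap as data — named constructs such as `P9Am10` (S9F, M20L, R27V plus
  the gap-KR → MLE block replacement, +1 residue) applied in KRAB coordinates
  with full validation, inversion and diff inventories.
- **Helix geometry** (`krabstrat.geometry`): CA-distance helix detection,
  least-squares axis fits, inter-helix angles, Kabsch superposition, and the
  azimuthal register shift — inserting one residue into an ideal α-helix
  (100°/residue twist) rotates downstream side-chains by ~100° about the
  axis, the analytic counterpart of the ~97° reorientation seen between
  modeled KRAB structures with and without A32/M.
- **Synthetic data** (`krabstrat.synth`): generators for the four subgroup
  profiles (mKRAB, PRDM9-like, SSX-like, coelacanth-like) with planted
  hallmark motifs and the A32 gap, plus ideal/composite helix fixtures — so
  every stage runs and is tested without any download.

## Worked example

Apply the minimal gain-of-function construct to the synthetic PRDM9-A
stand-in and fuse it to a ZNF10-B subdomain:

```
$ krabstrat mutate --construct P9Am10
PRDM9-A:P9Am10-ZNF10-B: 3 substitutions, 1 block replacements, length delta +1
```

Three point substitutions (S9F, M20L, R27V) plus one block replacement (the
MLE insertion at A32–A34, which closes the ancestral gap and lengthens the
domain by one residue) — the full edit distance from an inactive ancestral
A domain to one with canonical repressor behaviour.

Measure an L-shaped two-helix body (the conserved KRAB core topology):

```
$ krabstrat geometry --pdb l_body.pdb
 helix  start  end  rise  twist
     1      1   12   1.5  100.0
     2     17   28   1.5  100.0
angle helix1-helix2: 90.0 deg
```

Both helices are detected with their generative parameters (1.5 Å rise,
100° twist per residue) and the constructed 90° inter-axis angle is
recovered.

Run the full synthetic pipeline (simulate → dedup → build HMMs → curate →
cross-score → summarize → logos → frequencies → mutants → geometry):

```
$ krabstrat run --seed 3 --out run/
report -> run/report.json (assignment accuracy 100.0%)
```

The report records every seed and threshold; re-running from a report's
configuration reproduces every output byte-identically.

## Layout

```
src/krabstrat/
  core.py       KRAB coordinate system, sequences, catalog TSV I/O
  hmm.py        profile HMM build / forward / Viterbi / EVD calibration
  stratify.py   clamping, cross-scoring, summaries, WMW test, curation
  logo.py       information content, logo matrices, frequency tables
  mutagen.py    edit grammar, script application, construct roster
  geometry.py   PDB I/O, helix detection/axes, superposition, register
  synth.py      subgroup generators, catalogs, helix fixtures
  cli.py        click front-end and pipeline orchestration
docs/methods.md  model descriptions, parameter choices, limitations
```
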