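# m6abind

Quantitative analyses of how the non-canonical m6A reader **IMP1**
(IGF2BP1) discriminates N6-methyladenosine-modified RNA from its
unmethylated counterpart — for structural biologists and RNA
biochemists who want to reproduce, extend or stress-test the
concentration-dependent-discrimination argument on their own binding
constants.

IMP1's KH34 di-domain binds the β-actin (ACTB) Zipcode element with a
modest methylation-dependent affinity gain (K_D ≈ 3.7 nM for m6A RNA
versus ≈ 20.9 nM unmodified). Unlike the 50–100-fold discrimination of
YTH readers, such a few-fold K_D differential only translates into
target selectivity in a specific concentration window — which this
package computes exactly.

## The model

For a protein P competing for unmethylated RNA and methylated meRNA
(independent 1:1 sites), free protein [P] solves the cubic mass
balance

```
[P]³ + [P]²(−[P]t + K_D^RNA + K_D^meRNA + [RNA]t + [meRNA]t)
     + [P](−[P]t(K_D^RNA + K_D^meRNA) + K_D^RNA·K_D^meRNA
            + [RNA]t·K_D^meRNA + [meRNA]t·K_D^RNA)
     − [P]t·K_D^RNA·K_D^meRNA = 0
```

and the bound species follow the isotherm
`[P·RNAᵢ] = [RNAᵢ]t·[P]/(K_Dᵢ + [P])`. The fold enhancement of the
methylated bound fraction reduces to `(K_D^RNA + [P])/(K_D^meRNA + [P])`
— largest (the K_D ratio) when free protein is scarce, 1 at saturation.

Around that core sit three supporting analyses:

- **`m6abind.bli`** — 1:1 biosensor (BLI) kinetics: per-trace
  k_obs from single-exponential fits, k_on from the k_obs-vs-concentration
  slope, k_off from single-curve dissociation analysis, K_D = k_off/k_on,
  and fold-change comparisons between conditions.
- **`m6abind.csp`** — NMR chemical-shift perturbations
  `CSP = √(ΔδH² + (0.15·ΔδN)²)`, top-n weighted summaries,
  pooled-variance t-tests, and fast-exchange titration emulation via the
  exact single-site ligand-depletion isotherm.
- **`m6abind.clip_overlap`** — BED-interval bookkeeping: replicate
  cross-link merging, strand-aware peak/m6A-site intersection, and
  length-normalised per-region signal percentages.
- **`m6abind.synth`** — synthetic datasets with ground-truth manifests
  so every stage runs and is scored with no downloads.

## Worked example

```
$ m6abind figure4 --out fig4 --grid-steps 51
wrote discrimination curves and enhancement table to fig4
$ cat fig4/enhancement.tsv
free_protein_nM	enhancement_fold
1	4.6596
5	2.9770
25	1.5993
100	1.1659
```

At 5 nM free IMP1 the methylated Zipcode is bound **2.98-fold** (≈
3-fold) more than the unmethylated one; by 25 nM the edge has shrunk to
1.6-fold and it vanishes toward saturation — methylation acts as a
context-dependent selector, not an on/off switch. The same run writes
the full bound-fraction curves, e.g. in total-protein mode at the
physiological 0.4 nM RNA:

```
$ head -4 fig4/curve_total_rna0.4.tsv
protein	free_protein	bound_unmod	bound_meth	fraction_unmod	fraction_meth
1.0	0.9203238654071253	0.0	0.0796761345928749	0.0	0.19919033648218723
2.0	1.8659046623646662	0.0	0.13409533763533346	0.0	0.33523834408833364
3.0	2.8267588009806097	0.0	0.17324119901939106	0.0	0.43310299754847764
```

Columns are total protein, solved free protein, bound RNA
concentrations (nM) and per-species bound fractions.

Other entry points: `m6abind compete --config FILE --out FILE` (custom
systems, nM/µM/M units), `m6abind bli-sim` / `m6abind bli-fit`
(simulate and fit sensorgrams), `m6abind csp` (perturbation reports),
`m6abind overlap` / `m6abind regions` (interval summaries), and
`m6abind simulate` (synthetic scenarios with truth manifests). Every
command drops a `*.provenance.json` beside its outputs.

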