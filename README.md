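# ankevo

Evolutionary and structural-dynamics analysis of ankyrin-repeat protein
families — the IκB/NF-κB inhibitor family being the motivating case.

Ankyrin-repeat domains (ARDs) are stacks of ~33-residue helix-turn-helix
repeats whose protruding "finger" loops mediate partner binding.  Gene
families built on this fold (the IκB inhibitors of NF-κB among them)
raise a linked set of questions: how did the paralogs diverge, which
alignment positions shifted evolutionary rate or biochemical character
between subfamilies, is the repeat domain under purifying selection, and
do the collective motions predicted from the fold's contact topology
match the deformations seen across solved structures?  `ankevo`
implements the full computational chain for these questions as a tested,
seedable library with synthetic-data generators for every input, so the
whole pipeline can be exercised — and its estimators validated against
known ground truth — without any external downloads.

## What is implemented

**Sequence track**

- Needleman–Wunsch global alignment (BLOSUM62, affine gaps, EMBOSS
  needle conventions) with identity/similarity percentages, inter/
  intra-group min–max range tables, and a homolog length/identity filter.
- PEST-motif detection (Rogers–Wells–Rechsteiner score: candidate
  stretches ≥ 12 residues between positive flanks, containing D/E, P and
  S/T; `score = 0.55·DEPST − 0.5·hydrophobicity`, valid at ≥ +5).
- Jukes–Cantor protein distances with pairwise deletion
  (`d = −(19/20)·ln(1 − (20/19)p)`), Saitou–Nei neighbor joining,
  nonparametric bootstrap supports, outgroup rooting.
- Type I functional divergence between two monophyletic clusters in the
  Gu framework: Fitch-parsimony substitution counts per column, a
  shared/independent gamma-rate mixture with coefficient θ fitted by
  maximum likelihood, a boundary-corrected LRT of θ = 0, and per-site
  posteriors with the θ > 0.85 candidate-site rule.
- Type II functional divergence: posterior-odds scoring of sites
  conserved within but fixed for different residues between clusters,
  with radical-change calls from the property classes
  {K,R,H}=+, {D,E}=−, {A,V,L,I,M,F,W}=hydrophobic, rest hydrophilic,
  at the > 17 odds cut-off.
- Site-wise and pairwise Ka/Ks by Nei–Gojobori (1986) counting with
  Jukes–Cantor correction and pathway averaging.

**Structure track**

- Anisotropic network model (ANM): Cα Hessian at a 15 Å cutoff,
  eigendecomposition with exactly six rigid-body modes on connected
  chains, inverse-eigenvalue-weighted mean-square fluctuations, and
  least-squares comparison against experimental B-factors.
- Structural-ensemble PCA: residue matching via sequence alignment to a
  reference, iterative Kabsch superposition, coordinate-covariance PCA
  with per-mode variance fractions and conformer projections, PC-space
  group clustering, and ANM↔PCA mode overlap (absolute eigenvector
  cosines and projection correlations).

**Synthetic data** — ideal-geometry ankyrin Cα traces, conformer
ensembles with planted principal directions and variances (optionally
scrambled by rigid transforms), protein families evolved on known trees
with gamma site rates and planted rate-shifted site fractions, and
GY94-style codon alignments with per-site ω.  Every generator is
bit-reproducible from its seed and returns its ground truth.

## Worked example

Simulate a two-clade family with 40% of sites rate-shifted in clade B,
then estimate the divergence coefficient from the sequences alone:

```bash
ankevo synth family --theta 0.4 --seed 1 --out fam
ankevo diverge --msa fam.fasta --tree fam.nwk \
    --cluster-a A1,A2,A3,A4,A5,A6 --cluster-b B1,B2,B3,B4,B5,B6 \
    --out div.json
```

`div.json` starts:

```json
{
  "theta1": 0.3419,
  "theta1_se": 0.0712,
  "lrt": 26.8897,
  "p_value": 1.077e-07,
  ...
}
```

The estimated coefficient θ̂ = 0.34 ± 0.07 recovers the planted 0.4
(rate-shift signal is attenuated by parsimony undercounting), and the
likelihood-ratio test firmly rejects θ = 0: the two clades evolved with
decoupled site rates.  Similarly, `ankevo kaks` on a codon alignment
simulated at ω = 0.3 reports `overall ka=0.1768 ks=0.4488 omega=0.3938`
— a purifying-selection call.  `ankevo pipeline demo` chains every stage
over one synthetic input set and writes a manifest of hashed outputs.

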