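# bifanr

Noise-reduced bi-factor analysis for detecting **protein sectors** —
groups of coevolving amino-acid positions — in a multiple sequence
alignment (MSA) of a protein family.

Conserved positions that evolve in a correlated way often form sectors:
sets of residues that are spatially contiguous in the tertiary
structure, functionally coherent, and quasi-independent of other such
sets. `bifanr` detects them from alignment statistics alone, for anyone
who has a family alignment (serine proteases, PDZ domains, Hsp70s, ...)
and wants candidate coupled residue groups to interpret or mutate.

## Method

Starting from an S×L alignment encoded with amino acids 1–20 and gap 0:

1. **Weighted coupling matrix.** Per-site frequencies f_i^a, joint
   frequencies f_ij^ab and background frequencies q^a give the
   covariance C_ij^ab = f_ij^ab − f_i^a f_j^b, weighted by the log-odds
   conservation weight φ_i^a = ln[f_i^a(1−q^a)/((1−f_i^a)q^a)]
   (statistical-coupling-analysis convention) and reduced over the
   amino-acid dimensions by the Frobenius norm:
   W_ij = √Σ_ab (φ_i^a φ_j^b C_ij^ab)².
2. **Noise reduction.** Rmax(i) is the mean of the top 5 % couplings of
   site i and `plus` the mean of Rmax over sites; sites with
   Rmax(i) ≤ 0.8·plus are weakly coupled to almost everything ("noise
   sites") and are removed before factor analysis.
3. **Factor retention by a shuffle null.** Every kept column is
   permuted independently across sequences and the pipeline recomputed;
   100 shuffles pool 100·n null eigenvalues into E. With
   N(i) = #{e ∈ E : e > λ_i}, the retained factor count t is the last
   index with N(t) < 100.
4. **Varimax rotation and bidirectional selection.** The t retained
   eigenvectors are varimax-rotated; for each factor and each sign the
   coefficients p(i) are compared to the mean w of their top 50 %, and
   site i joins the candidate sector when (p(i)/w ≥ r0 and p(i) > p0)
   or p(i) ≥ p1. Overlapping candidates are merged greedily around
   their intersection up to the size of the smaller parent.

The evaluation suite checks the result the way the method's users
should: internal correlation against equal-size random site sets,
statistical independence through MDI entropy (the KL divergence of the
sector's empirical joint distribution from the marginal-matched
maximum-entropy model, fitted by generalized iterative scaling),
evolutionary rates parsed from Rate4Site output, a PCA split of the
sequences by sector similarity, and sensitivity/PPV against reference
sector definitions.

## Worked example

```python
import bifanr as bf

# a synthetic family: 300 sequences x 80 columns, two planted 12-site
# sectors driven by independent binary latent traits (rho = 0.9)
al, truth = bf.generate(bf.default_spec(seed=42))

res = bf.SectorModel(al).fit(seed=7)
print(res.summary())
```

```
Bi-factor protein sector analysis
==========================================
sequences:             300
alignment columns:     80
noise sites removed:   56  (Rmax <= 0.8 * plus, plus = 1.0043)
sites analyzed:        24
null eigenvalues:      2400 (100 column shuffles)
non-random factors t:  2
  eigenvalue  1*     33.1688   N = 0
  eigenvalue  2*     28.4834   N = 0
  eigenvalue  3      -2.2730   N = 2400
sectors detected:      2
  sector 0: 12 sites (factor 0, sign +)
    col5 col10 col16 col22 col27 col33 col39 col44 col50 col56 col61 col67
  sector 1: 12 sites (factor 1, sign +)
    col3 col7 col12 col18 col24 col29 col35 col41 col47 col52 col58 col63
```

All 56 noise columns are filtered out, exactly two eigenvalues beat the
shuffle null (N = 0: no null eigenvalue exceeds them), and the two
recovered sectors match the planted site sets exactly. The evaluation
suite quantifies this:

```python
report = res.evaluate(reference=[list(s) for s in truth.sector_sites], seed=0)
print(report.to_text())
```

```
Sector evaluation report
========================
sector 0: mean coupling 2.8094 (random 1.4416 +/- 0.0986, p = 0, 12 sites)
sector 1: mean coupling 2.7827 (random 1.4369 +/- 0.0918, p = 0, 12 sites)
sectors 0+1: MDI joint 23.8491 vs sum 20.0977 (gap +3.7514; random split 19.5820)
reference 0: sensitivity 100.00%, PPV 100.00%
reference 1: sensitivity 100.00%, PPV 100.00%
```

Each sector's mean pairwise coupling is about twice the random
expectation with empirical p = 0 out of 1000 resamples, and the joint
MDI entropy of the two sectors exceeds the random re-split expectation,
supporting their statistical independence.

The same pipeline runs from the shell:

```sh
bifanr simulate --out sim --seed 42
bifanr run --input sim/alignment.fasta --out run --seed 7
bifanr run --input family.aln --template 3TGI_row_id --out out --seed 0
```

`run` writes the coupling matrix (TSV), the noise-reduction report,
factor diagnostics, sector tables (TSV/JSON), the evaluation report,
and a manifest with the seed, parameters and input checksum.

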