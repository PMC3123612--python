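# pival

Intensity-aware validation and re-ranking of SEQUEST peptide-spectrum
matches (PSMs).

Database-search engines of the SEQUEST family score a spectrum against a
*theoretical* spectrum built from a deliberately crude fragmentation model:
every major ion gets the same fixed intensity. Real ion-trap spectra look
nothing like that, and the mismatch is a major source of false
identifications. `pival` addresses this for proteomics users who
post-process SEQUEST output: it predicts intensity-realistic theoretical
spectra from a trainable fragmentation model, scores each PSM by the
similarity of the experimental spectrum to that prediction, and uses the
score to validate and re-rank the identifications, with target-decoy FDR
curves to quantify the gain.

## The model and the score

For a peptide A₁A₂⋯A_L the intensity of the cleavage event at bond *i* is

```
v_i = α · P(A_i, A_{i+1}) · f_i
```

where `P` is a 20×20 propensity for the residue pair flanking the bond,
`f_i` captures the tendency of cleavage towards the middle of the peptide
(binned over relative position so all lengths share parameters), and `α` is
a global scale. The parameters are trained by constrained non-linear least
squares on an automatically built training set: the top-XCorr confident
identifications in the input itself, with per-bond b/y ion intensities
extracted from their spectra.

Each event's intensity is distributed over the b/y ion pair, their
dehydration (−H₂O) and deamination (−NH₃) satellites, the a ion, and
isotope peaks. The per-residue neutral-loss probabilities are estimated by
an EM algorithm on a noisy-OR Bernoulli model: a fragment shows the loss
peak when at least one of its residues, each firing independently with
probability p_a, produces the loss.

Similarity between the experimental spectrum and the prediction is the
Jensen–Shannon divergence (log base 2) between the two binned, normalized
intensity distributions; the **PI score** is `1 − JSD ∈ [0, 1]`. Ranking
PSMs by PI score and counting accepted targets at a decoy-estimated FDR
gives the validation curve.

## Worked example

`pival` reads SEQUEST-style inputs: one `.dta` spectrum file (M+H and
charge header, then m/z–intensity pairs) paired by basename with one `.out`
result file (ranked candidates with XCorr, ΔCn, Sp and protein
references). The bundled simulator writes such pairs from known model
parameters, including deliberately wrong (interior-shuffled) peptides and
decoy protein references:

```
$ pival simulate --n 30 --seed 7 --out demo --fraction-incorrect 0.3
wrote 30 pairs to demo (24 correct, 6 shuffled)

$ pival validate --in demo --out demo.pix --xcorr-min 0 --dcn-min 0 \
      --train-size 25 --min-train 10 --summary demo.json
pairs: 30  retained: 30  records: 30
targets at FDR 0.005: PI 25  XCorr 19
targets at FDR 0.01: PI 25  XCorr 19
```

Reading the output: all 30 pairs passed the (here disabled) XCorr/ΔCn
filter and were scored; at an estimated FDR of 0.5 % the PI-score ranking
accepts 25 target PSMs while ranking by the simulated XCorr accepts only
19 — the intensity model separates correct from shuffled peptides that are
isobaric and composition-identical, which XCorr cannot. On real data the
defaults `--xcorr-min 2.0 --dcn-min 0.15 --train-size 3000` are the
intended ion-trap operating point. The `demo.pix` file is XML holding, per
PSM, the SEQUEST scores, the PI score and the protein references;
`demo.json` records the stage counts and fit diagnostics.

Individual spectra can be annotated with b/y/a, neutral-loss and isotope
ion labels:

```
$ pival label --dta demo/synth_00000.dta --peptide PQFVTLCWSLNHDSGAVTDR --tol 0.5
mz      intensity       ion
70.0651 22.1723 a1(+1, iso0)
...
```

and `pival curve --pix demo.pix --plot curves.png` re-plots the PI vs
XCorr comparison from an existing pix file.

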