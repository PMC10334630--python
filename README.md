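# topoms

Topological persistence transformation for MALDI mass spectrometry imaging
(MSI): position-preserving peak detection, persistence-based denoising and
compression, and downstream tumor-subtype classification.

## The problem

MALDI-MSI acquires one mass spectrum per spatial spot of a tissue section.
Discriminating cancer subtypes (for instance the lung adenocarcinoma versus
squamous-cell-carcinoma distinction) from these spectra hinges on the
signal peaks, while most of the ~10³–10⁴ m/z channels carry noise.
Classical 0-dimensional persistent homology of the upper-level-set
filtration scores each peak by its *persistence* — its relative height —
but discards the peak's m/z position, which is exactly the biomarker
information an analyst needs.

## The method

For a spectrum `f` on an ordered m/z grid, the upper-level set at threshold
`a` is `M_a = {x : f(x) ≥ a}`. Sweeping `a` downward, each local maximum
`x` births a connected component at `a* = f(x)`; the component dies at

    a+ = μ(x) = sup { a ≤ f(x) : some taller point is path-connected to x in M_a },

and the global maximum dies at the global minimum by convention. Merging
follows the elder rule (higher birth survives; ties broken by the order of
the m/z axis). The **persistence transformation** keeps the position:

    t(x) = (x, a*, a+),    reduced form  t̃(x) = (x, a* − a+),

one triple (or pair) per peak, so a spectrum with `m` peaks compresses to
`2·m` stored values. Projecting `(x, a*, a+) → (a*, a+)` recovers the
classical persistence diagram, so the transformation is a strictly finer
invariant. Retaining only the `k%` most persistent features per spectrum
denoises and compresses the data; the resulting sparse persistence matrix
`Z` feeds unpenalized logistic regression or a 1000-tree random forest,
evaluated by balanced accuracy under cross-validation grouped at the
tissue-microarray (TMA) level.

## Worked example

```python
>>> import numpy as np, topoms
>>> topoms.persistence_transformation(np.array([0., 3, 1, 2, 0]))
array([(1, 1., 3., 0., 3.), (3, 3., 2., 1., 1.)],
      dtype=[('index', '<i8'), ('position', '<f8'), ('birth', '<f8'), ('death', '<f8'), ('persistence', '<f8')])
```

The spectrum `(0, 3, 1, 2, 0)` has two peaks. The taller one (index 1,
birth 3) is the global feature and dies at the global minimum 0, giving
persistence 3; the smaller one (index 3, birth 2) merges into it at the
valley value 1, giving persistence 1. Positions are preserved, so the
mirrored spectrum — indistinguishable in the persistence diagram — yields
different triples.

A small end-to-end run with the synthetic generator:

```python
>>> data = topoms.simulate_labeled_spectra(n_per_class=100, n_exclusive=5,
...                                        groups=4, noise_sd=10.0, seed=1234)
>>> Z = topoms.transform_matrix(data.X, k=30)
>>> res = topoms.run_group_cv(
...     topoms.LabeledDataset(Z=Z, labels=data.labels, groups=data.groups),
...     model_kind="rf", scheme="logo")
>>> res.summary()["mean"]
1.0
```

Two simulated classes share 10 peaks and own 5 exclusive peaks each; after
the k=30% persistence transformation a seeded random forest separates them
perfectly in leave-one-TMA-out cross-validation (mean balanced accuracy
1.0 over the four folds).

The same pipeline is available from the shell:

```
topoms transform   --input X.csv --k 30 --out-dir out/
topoms classify-cv --matrix X.csv --labels labels.csv --k 30 --model rf
topoms simulate    --width 30 --height 30 --noise-kind gaussian \
                   --noise-param 10 --out-dir img/
topoms denoise     --image-dir img/ --k 5 --out-dir denoised/
```

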