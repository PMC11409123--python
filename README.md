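# firehawk

Fire-hawk population metaheuristic (FHO) and its adaptive-step variant
(IFHO), packaged together with a desk-scale retinal-image classification
pipeline: fuzzy impulse denoising, SMOTE class balancing, hyperparameter
tuning by validation accuracy, and cross-validated metric reporting.
Everything runs from synthetic, programmatically generated data — no
downloads, no GPU.

## What's inside

| Module | Purpose |
| --- | --- |
| `firehawk.optimizer` | FHO/IFHO: population lifecycle, hawk/prey territories, position updates, adaptive step factor, elitist main loop |
| `firehawk.benchmarks` | sphere / Rastrigin / Rosenbrock / Ackley with seeded random shifts |
| `firehawk.preprocessing` | min/max normalization, salt-and-pepper noise, fuzzy-rule impulse denoiser, PSNR |
| `firehawk.augmentation` | SMOTE on flattened image vectors |
| `firehawk.classifier` | hyperparameter decoding (`N`, learning rate, batch size), single-hidden-layer and reduced-bottleneck classifiers, IFHO tuning harness |
| `firehawk.evaluation` | confusion metrics, rank-based AUC, stratified k-fold cross-validation with in-fold SMOTE |
| `firehawk.synthdata` | synthetic labeled fundus-like images (disc, vessels, exudate/hemorrhage lesions) |
| `firehawk.cli` | `firehawk` command with `bench / simulate / denoise / augment / tune / evaluate` |

## CLI examples

```bash
# optimizer on a shifted benchmark
firehawk bench --function sphere --dim 2 --variant ifho --iters 200 --pop 30 --seed 1

# full pipeline
firehawk simulate --n 400 --dr-fraction 0.25 --size 64 --seed 1 --out-dir runs/data
firehawk denoise  --in runs/data/fundus_00000.png --out runs/denoised.png --density 0.04 --seed 1
firehawk augment  --manifest runs/data/manifest.csv --out-manifest runs/data/balanced.csv --k 5 --seed 1
firehawk tune     --manifest runs/data/balanced.csv --arch hidden_layer --pop 10 --iters 20 --seed 1 --out runs/tune.json
firehawk evaluate --manifest runs/data/manifest.csv --k 5 --seed 1 --out runs/eval.json
```

Every command echoes its configuration and seed into its JSON output;
identical config + seed reproduces byte-identical results.

## Notes

- All randomness flows through `numpy.random.Generator`; one global seed
  fans out to per-stage child streams by fixed labels.
- Maximization is handled by internal negation; results are reported on
  the caller's scale.
- Zero-denominator metrics are reported as undefined (`None`) and are
  excluded from cross-fold means, never coerced to 0 or 100.
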