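# transaug

GAN-based data augmentation for bulk gene-expression matrices, with a
full battery of generative-quality indicators and a synthetic
transcriptome simulator so every pipeline stage can be exercised without
downloading real cohort data.

## What's inside

| Module | Purpose |
| --- | --- |
| `transaug.datasets_io` | `ExpressionDataset`, synthetic transcriptome simulator, TSV/CSV I/O, log2 + min–max normalization, train/val/test splitting, Gaussian-noise augmentation baseline |
| `transaug.attention_masks` | Sparse gene-pair masks from co-expression, PPI edge lists, their union, or a degree-preserving random relabelling (lesion control) |
| `transaug.generative_models` | GAN, conditional WGAN-GP with gradient penalty, attention-GANs with a sparse softmin/L1 attention layer; training loop and sampling |
| `transaug.quality_metrics` | Fréchet distance on classifier embeddings, k-NN manifold precision/recall/F1, adversarial accuracy, gene–gene correlation score, PCA cumulative-variance spectrum, mean±std report aggregation |
| `transaug.augmentation_eval` | Task classifiers (binary cancer / tissue type), augmentation-gain curves, reverse validation, augmentation schedules, benchmark orchestration |
| `transaug.engine` | Minimal numpy reverse-mode autodiff (with double backprop, needed by the gradient penalty) backing the generative models |

Neural networks are implemented on a small numpy autodiff engine rather
than a deep-learning framework, so the package runs on a plain
scientific-Python stack; evaluation classifiers use scikit-learn MLPs.

## CLI

```bash
# simulate a TCGA-like synthetic dataset
transaug simulate --config sim.yaml --seed 0 --out data/

# split into train/val/test (round-to-nearest held-out sizes)
transaug split --data data/expression.tsv --covariates data/covariates.tsv \
    --val 0.1667 --test 0.1667 --stratify tissue --seed 0 --out splits/

# build an attention mask
transaug mask --mode coexp --data splits/train_expression.tsv \
    --threshold 0.5 --out mask.tsv

# train and sample a generative model
transaug train --model wgan-gp --data splits/train_expression.tsv \
    --covariates splits/train_covariates.tsv --seed 0 --out model.ckpt
transaug generate --model model.ckpt -m 1000 --seed 1 --out gen.tsv

# quality-indicator report
transaug evaluate --true splits/train_expression.tsv --generated gen.tsv \
    --covariates splits/train_covariates.tsv -k 50 --runs 5 --out report.json

# full comparison from a single YAML config
transaug benchmark --config bench.yaml --out results/
```

Expression tables are TSV/CSV with sample IDs in the first column and
gene IDs in the header; covariate tables carry `sample_id`, `age`,
`gender`, `tissue`, `cancer`.

## Python API sketch

```python
import transaug as ta

data = ta.simulate_transcriptome(ta.SimConfig(n_samples=600, n_genes=50, seed=0))
train, val, test = ta.split(data, ta.SplitSpec(1/6, 1/6, stratify_on="tissue", seed=0))

model = ta.train(train, ta.toy_config("wgan_gp", epochs=100, seed=0))
generated = ta.generate(model, 1000, covariate_source=train, seed=1)

report = ta.compute_report(model, train, k=50, n_runs=5, seed=0)
gain = ta.augmentation_gain(50, 1000, train, model,
                            ta.ClassifierSpec.for_task("binary"), test)
```
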