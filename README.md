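# autogs

Desk-scale genomic selection toolkit: from a VCF and a phenotype CSV to a
trained genotype-to-phenotype model, predicted phenotypes, and ranked
F1 parental combinations — with no GPU and no external data.

## What it does

- **Genotype ingestion** (`autogs.genotype_io`): reads biallelic VCF 4.x
  into an alt-allele dosage matrix, applies the standard SNP hard filter
  (QD < 2.0, QUAL < 30.0, FS > 60.0, MQ < 40.0, SOR > 3.0,
  MQRankSum < −12.5, missing rate ≥ 0.95), and imputes missing genotypes
  by per-locus mode.
- **Regulatory-window SNP selection** (`autogs.regulatory`): expands gene
  coding intervals (GFF3/BED) 2 kb upstream and 1 kb downstream
  (strand-aware) and keeps the variants falling inside the windows.
- **Encodings** (`autogs.encodings`): per-model genotype representations —
  raw (n, L) dosage, (4, L) one-hot, (3, ⌊√L⌋, ⌊√L⌋) one-hot image, and
  150-dimensional PCA scores (projection fit on training samples only).
- **Model pool** (`autogs.models`): SVM, XGBoost-style regularized
  boosting, GBDT, MLP and RF (scikit-learn backed), plus four
  convolutional architectures implemented on a small gradient-checked
  numpy engine — DeepGS (single conv branch), DLGWAS (two kernel scales
  merged by addition), DNNGP (three conv layers on PCA scores), SoyDNGP
  (VGG-style 2-D blocks) — and EnvSE, an environment-gated variant whose
  conv feature maps are reweighted channel-wise by sigmoid gates derived
  from a 64-dim embedding of 11 daily weather variables.
- **Training protocol** (`autogs.training`): seeded 8:1:1
  train/validation/test split, Adam with batch size 64, MSE loss, early
  stopping on validation MSE, accuracy reported as Pearson R on the test
  split; fitted models serialize to a single checksummed archive holding
  everything needed to reproduce predictions bit-exactly.
- **Breeding workflows** (`autogs.workflows`): train / predict /
  train+predict / select-parents / train+select; F1 genotypes are built
  from inbred parents by the expected-dosage cross rule and candidate
  crosses ranked with the top five flagged.
- **Synthetic data** (`autogs.simulate`): genotype panels (optionally with
  linkage blocks, missingness, and filter-violating quality metrics),
  additive(+dominance) traits at exact realized heritability,
  multi-environment weather series with linear trait shifts, and factorial
  inbred cross populations with ground truth.

## CLI

```bash
# make a synthetic fixture set (VCF + phenotype CSV + ground truth)
autogs simulate --n 300 --loci 200 --qtl 30 --h2 0.8 --seed 1 --out sim/

# hard-filter + keep SNPs in gene regulatory windows
autogs extract-snps --vcf sim/genotypes.vcf --genes genes.gff3 \
    --up 2000 --down 1000 --out reduced.vcf --map-out snp_gene_map.csv

# train (writes a weights archive + manifest, prints test R)
autogs train --vcf sim/genotypes.vcf --pheno sim/phenotypes.csv \
    --model DNNGP --seed 7 --out model.autogs

# predict
autogs predict --vcf new.vcf --weights model.autogs --out predictions.csv

# one-step train + predict
autogs train-predict --vcf train.vcf --pheno p.csv --model GBDT \
    --weights-out model.autogs --out predictions.csv

# rank candidate crosses of an inbred panel (top 5 flagged)
autogs select-parents --weights model.autogs --panel-vcf panel.vcf \
    --pairs pairs.csv --direction maximize \
    --out ranked.csv --top5-out top5.csv

# train + select in one step
autogs train-select --vcf train.vcf --pheno p.csv --model SVM \
    --weights-out model.autogs --panel-vcf panel.vcf --pairs pairs.csv \
    --out ranked.csv --top5-out top5.csv
```

The environment-gated model needs an environment series CSV
(`env,date,tempmax,tempmin,humidity,precip,windspeed,sealevelpressure,cloudcover,solarradiation,solarenergy,uvindex,sunlightduration`),
a phenotype CSV with an `env` column for training (`--env series.csv`),
and a `sample,env` assignment CSV for prediction (`--env-assign`).

## File formats

- genotypes: VCF 4.x, biallelic, GT required, QD/FS/MQ/SOR/MQRankSum INFO
  optional (absent metrics never disqualify a locus)
- phenotypes: CSV `sample,value[,env]`
- genes: GFF3 (feature type `gene` by default) or 6-column BED
- pair list: CSV `female,male`; inbred id list: plain text, one id per line
- model weights: single zip archive (JSON metadata + parameter blob +
  SHA-256 checksums), refused on tamper or locus mismatch
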