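#!/usr/bin/env bash
# End-to-end pipeline from the shell: simulate a trial, select the
# cohort, screen and score conmeds, select the model, scan SNPs, and
# compare the top SNP's effect with/without the statin score.
set -euo pipefail

OUT=${1:-pipeline_out}
SEED=${2:-1}

cat > "${OUT}_cfg.yaml" <<'YAML'
simulate:
  n_subjects: 1000
  n_snps: 30
primary_medication: primary_med
phenotype: hba1c_pct
pca_k: 5
# force the statin score group so the confounder stays in the model
forced: [intensive_glycemia, PC1, PC2, PC3, pre_phenotype, statin]
YAML

for stage in simulate select-cohort screen score fit scan; do
  conmedscore "$stage" -c "${OUT}_cfg.yaml" -o "$OUT" --seed "$SEED" --force
done
conmedscore compare -c "${OUT}_cfg.yaml" -o "$OUT" --seed "$SEED" --force \
  --snp snp_causal --conmed statin

echo "artifacts in $OUT/ (model.tsv, assoc.tsv, compare.json, manifests)"
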