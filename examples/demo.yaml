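# Demo: simulate a saturated Tn library selection screen and recover the
# five planted resistance genes (survival factor 50 under a bactericidal
# dose killing 99% of neutral mutants), across 3 biological replicates.
mode: simulate
seed: 1
out_dir: results/demo
min_sites: 3
simulate:
  genome_length: 200000
  gc: 0.5
  circular: true
  n_genes: 100
  mean_gene_len: 800
  density: 0.05          # 1 insert per 20 bp
  n_replicates: 3
  control_growth: 40
  samples:
    control:
      plating: 100000
      depth: 1000000
    treated:
      plating: 1000
      depth: 1000000
      baseline_survival: 0.01
  resistant:
    n: 5
    factor: 50
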