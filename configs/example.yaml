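# Small end-to-end example: a synthetic 50-line / 200-gene screen with six
# drugs, elastic-net models over five feature-set strategies, two data splits.
seed: 7
data:
  synthetic:
    n_cell_lines: 50
    n_genes: 200
    n_mutation_genes: 30
    n_cnv_segments: 10
    n_pathways: 6
    pathway_size_range: [5, 15]
    n_signatures: 5
    signature_size_range: [4, 8]
    n_tissues: 4
    n_drugs: 6
strategies: [OT, PG, OT+S, GW, GW_SEL_EN]
model_families: [en]
protocol:
  n_repetitions: 2
  en_l1_ratios: [0.5, 1.0]
  en_n_alphas: 10
  sel_n_subsamples: 10
  sel_k_grid: [10, 30]
evaluation:
  top_drugs: 5
  k_values: [1, 5]
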