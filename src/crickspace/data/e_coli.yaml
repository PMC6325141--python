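# Cellular constants: Escherichia coli, rich medium (21.5 min doubling).
organism_label: "E. coli"
N_m: 1380             # mRNAs per cell
N_p: 3.0e+6           # proteins per cell (3e6 per um^3 x ~1 um^3)
mu: 1.93              # growth rate, h^-1 (60*ln2/21.5)
alpha_deg: 0.0        # protein degradation negligible; decay is dilution only
alpha_p: 1.93         # protein decay = mu, h^-1
alpha_m: 14.9         # median mRNA decay, h^-1 (2.8 min half-life)
cv0: 0.25             # noise floor (0.27 and 0.22 in the two source assays)
l_m: 1000             # typical mRNA length, nt (cancels out of the boundary prediction)
total_transcription: 2.0562e+4  # N_m * alpha_m, mRNA h^-1
v: 21.0               # elongation speed, aa s^-1
footprint_nt: 22      # inferred prokaryotic footprint, nt (L = 7.3 codons)
beta_p_max: 1.1e+4    # top percentile of measured translation rates
rho: 1.0
reference:
  measured_k: 14.0
  measured_k_se: 3.0
  predicted_k: 13.0
  predicted_k_se: 4.0
  nonessential_k: 44.0      # boundary refit after removing essential genes
  nonessential_k_se: 9.0
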